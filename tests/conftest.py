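import numpy as np
import pytest

from somnoseq import EmissionModel, HypnogramModel, gen_cohort, gen_hypnogram, scheme


def gradcheck(build_loss, params, eps=1e-6, n_per_param=6, seed=0,
              atol_floor=1e-7):
    """Worst finite-difference vs analytic relative gradient error.

    Entries whose combined magnitude is below ``atol_floor`` are compared
    absolutely (FD roundoff dominates there).
    """
    for p in params:
        p.grad = None
    loss = build_loss()
    loss.backward()
    grads = [p.grad.copy() if p.grad is not None else np.zeros_like(p.data)
             for p in params]
    worst = 0.0
    rng = np.random.default_rng(seed)
    for pi, p in enumerate(params):
        flat = p.data.ravel()
        for i in rng.choice(flat.size, size=min(n_per_param, flat.size),
                            replace=False):
            old = flat[i]
            flat[i] = old + eps
            lp = float(build_loss().data)
            flat[i] = old - eps
            lm = float(build_loss().data)
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[pi].ravel()[i]
            denom = abs(num) + abs(ana)
            err = abs(num - ana) if denom < atol_floor else abs(num - ana) / denom
            worst = max(worst, err)
    return worst


@pytest.fixture(scope="session")
def four_scheme():
    return scheme("four")


@pytest.fixture(scope="session")
def three_scheme():
    return scheme("three")


@pytest.fixture(scope="session")
def default_hyp_model():
    return HypnogramModel()


@pytest.fixture(scope="session")
def default_emissions():
    return EmissionModel()


@pytest.fixture(scope="session")
def short_night(default_hyp_model):
    """A 120-epoch four-class hypnogram shared across read-only tests."""
    return gen_hypnogram(default_hyp_model, 120, seed=42)


@pytest.fixture(scope="session")
def labeled_cohort():
    """Six labeled three-class subject-nights (small, for I/O and CLI tests)."""
    return gen_cohort(6, "three", 60, seed=7)
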