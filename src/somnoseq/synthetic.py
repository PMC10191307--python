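"""Synthetic subject-nights with the statistical structure staging assumes.

Nights are first-order Markov hypnograms with imbalanced stage fractions
(four-class default 33/47/9/11 % wake/light/deep/REM), a clock-modulated
deep-sleep propensity so deep sleep concentrates early in the night, and
stage-conditional activity/HRM/HRSD emissions in which REM shows wake-like
heart rate but near-atonic activity. R-peak trains can be generated with
occasional spurious and missed beats to exercise the interval-correction
rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .preprocess import EpochSeries, RPeakTrain
from .stages import Hypnogram, StageScheme, scheme

DEFAULT_FOUR_CLASS_FRACTIONS = (0.33, 0.47, 0.09, 0.11)  # W / Light / Deep / REM
DEFAULT_NIGHT_EPOCHS = 960  # 8 h of 30-s epochs
DEFAULT_START_CLOCK_S = 22 * 3600.0  # lights-off 22:00


def _persistence_chain(pi: np.ndarray, persistence: float) -> np.ndarray:
    """Row-stochastic matrix with stationary distribution ``pi``.

    P = persistence * I + (1 - persistence) * 1 pi^T: each epoch the stage
    persists with the given probability, otherwise resamples from ``pi``.
    """
    K = pi.size
    return persistence * np.eye(K) + (1.0 - persistence) * np.tile(pi, (K, 1))


@dataclass
class HypnogramModel:
    """Markov model of nightly stage dynamics.

    ``deep_decay`` scales the propensity of entering/remaining in Deep by
    exp(-deep_decay * (t/T - 1/2)) across the night (centered so the
    night-average Deep fraction stays near the nominal one), emulating the
    concentration of slow-wave sleep in the first half of the night.
    """

    scheme: StageScheme = field(default_factory=lambda: scheme("four"))
    stationary_fractions: np.ndarray | None = None
    transition_matrix: np.ndarray | None = None
    persistence: float = 0.85
    deep_decay: float = 1.0
    epoch_s: float = 30.0

    def __post_init__(self):
        self.scheme = scheme(self.scheme)
        if self.stationary_fractions is None:
            if self.scheme.name == "four":
                self.stationary_fractions = np.array(DEFAULT_FOUR_CLASS_FRACTIONS)
            elif self.scheme.name == "three":
                # collapse of the four-class default: Light+Deep -> NREM
                self.stationary_fractions = np.array([0.33, 0.56, 0.11])
            elif self.scheme.name == "two":
                self.stationary_fractions = np.array([0.33, 0.67])
            else:
                self.stationary_fractions = np.array([0.33, 0.12, 0.35, 0.09, 0.11])
        self.stationary_fractions = np.asarray(self.stationary_fractions, dtype=np.float64)
        if self.stationary_fractions.size != self.scheme.K:
            raise ValueError("stationary fractions do not match scheme size")
        if np.any(self.stationary_fractions < 0) or not np.isclose(
                self.stationary_fractions.sum(), 1.0, atol=1e-9):
            raise ValueError("stationary fractions must be nonnegative and sum to 1")
        if self.transition_matrix is None:
            self.transition_matrix = _persistence_chain(self.stationary_fractions,
                                                        self.persistence)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=np.float64)
        P = self.transition_matrix
        if P.shape != (self.scheme.K, self.scheme.K):
            raise ValueError("transition matrix shape does not match scheme")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be nonnegative and sum to 1")

    @property
    def deep_index(self) -> int | None:
        for lab in ("Deep", "N3"):
            if lab in self.scheme.labels:
                return self.scheme.index(lab)
        return None

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the base chain by eigen-decomposition."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        return pi / pi.sum()


def gen_hypnogram(model: HypnogramModel, n_epochs: int, seed: int,
                  start: int | str | None = None) -> Hypnogram:
    """Sample a stage-label sequence from the hypnogram model.

    ``start`` fixes the first epoch's stage (label or code); by default it
    is drawn from the configured stationary fractions.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    P = model.transition_matrix
    K = model.scheme.K
    deep = model.deep_index
    codes = np.empty(n_epochs, dtype=np.int64)
    if start is None:
        codes[0] = rng.choice(K, p=model.stationary_fractions)
    else:
        codes[0] = model.scheme.index(start) if isinstance(start, str) else int(start)
    u = rng.random(n_epochs - 1)
    for t in range(1, n_epochs):
        row = P[codes[t - 1]]
        if deep is not None and model.deep_decay != 0.0:
            row = row.copy()
            row[deep] *= np.exp(-model.deep_decay * (t / n_epochs - 0.5))
            row /= row.sum()
        codes[t] = np.searchsorted(np.cumsum(row), u[t - 1], side="right")
    return Hypnogram(codes, model.scheme, model.epoch_s)


@dataclass(frozen=True)
class StageEmission:
    activity_mean: float
    activity_sd: float
    hrm_mean: float     # bpm
    hrm_sd: float
    hrsd_mean: float    # bpm
    hrsd_sd: float


# Defaults: wake is active with elevated heart rate; light/deep sleep lie on
# a continuum of quiet low heart rate (deliberately overlapping); REM has
# wake-like cardiac measures but near-zero activity (muscle atonia).
_FOUR_CLASS_EMISSIONS = {
    "W": StageEmission(150.0, 80.0, 70.0, 4.0, 4.0, 1.0),
    "Light": StageEmission(15.0, 10.0, 62.0, 3.0, 2.5, 0.8),
    "Deep": StageEmission(3.0, 3.0, 58.0, 3.0, 1.5, 0.5),
    "REM": StageEmission(5.0, 4.0, 69.0, 4.0, 3.5, 1.0),
}
_THREE_CLASS_EMISSIONS = {
    "W": _FOUR_CLASS_EMISSIONS["W"],
    "NREM": StageEmission(12.0, 9.0, 61.0, 3.0, 2.2, 0.8),
    "REM": _FOUR_CLASS_EMISSIONS["REM"],
}
_TWO_CLASS_EMISSIONS = {
    "W": _FOUR_CLASS_EMISSIONS["W"],
    "Sleep": StageEmission(10.0, 8.0, 62.0, 4.0, 2.5, 1.0),
}


@dataclass
class EmissionModel:
    """Stage-conditional distributions of the three coarse channels.

    Activity is truncated-at-zero Gaussian; HRM and HRSD are Gaussian
    (HRM floored at 30 bpm, HRSD at 0). ``family`` tags the noise family.
    """

    scheme: StageScheme = field(default_factory=lambda: scheme("four"))
    per_stage: dict[str, StageEmission] | None = None
    family: str = "gaussian"

    def __post_init__(self):
        self.scheme = scheme(self.scheme)
        if self.per_stage is None:
            defaults = {"four": _FOUR_CLASS_EMISSIONS, "three": _THREE_CLASS_EMISSIONS,
                        "two": _TWO_CLASS_EMISSIONS}
            if self.scheme.name not in defaults:
                raise ValueError(f"no default emissions for scheme {self.scheme.name!r}")
            self.per_stage = dict(defaults[self.scheme.name])
        missing = [lab for lab in self.scheme.labels if lab not in self.per_stage]
        if missing:
            raise ValueError(f"missing emission parameters for stages {missing}")

    @classmethod
    def well_separated(cls, scheme_: str | StageScheme = "three",
                       separation: float = 4.0) -> "EmissionModel":
        """Emissions whose stage means are >= ``separation`` SDs apart.

        Used for parameter-recovery experiments where staging should be
        close to perfectly learnable.
        """
        sch = scheme(scheme_)
        per: dict[str, StageEmission] = {}
        for i, lab in enumerate(sch.labels):
            # spread channel means on a grid with unit SDs
            per[lab] = StageEmission(activity_mean=10.0 + separation * 2.0 * i,
                                     activity_sd=2.0,
                                     hrm_mean=55.0 + separation * 3.0 * i, hrm_sd=3.0,
                                     hrsd_mean=1.0 + separation * 0.5 * i, hrsd_sd=0.5)
        return cls(sch, per)


def gen_signals(hyp: Hypnogram, em: EmissionModel, seed: int,
                subject_id: str = "synthetic",
                start_clock_s: float = DEFAULT_START_CLOCK_S) -> EpochSeries:
    """Stage-conditional activity/HRM/HRSD channels for a hypnogram."""
    if em.scheme.name != hyp.scheme.name:
        raise ValueError("emission model scheme does not match hypnogram scheme")
    rng = np.random.default_rng(seed)
    n = len(hyp)
    activity = np.empty(n)
    hrm = np.empty(n)
    hrsd = np.empty(n)
    for k, lab in enumerate(hyp.scheme.labels):
        idx = np.flatnonzero(hyp.codes == k)
        if idx.size == 0:
            continue
        p = em.per_stage[lab]
        if p.activity_sd > 0:
            a = -p.activity_mean / p.activity_sd  # truncate at zero
            activity[idx] = _stats.truncnorm.rvs(a, np.inf, loc=p.activity_mean,
                                                 scale=p.activity_sd, size=idx.size,
                                                 random_state=rng)
        else:
            activity[idx] = p.activity_mean
        hrm[idx] = np.maximum(rng.normal(p.hrm_mean, p.hrm_sd, idx.size), 30.0)
        hrsd[idx] = np.maximum(rng.normal(p.hrsd_mean, p.hrsd_sd, idx.size), 0.0)
    clock = (start_clock_s + hyp.epoch_s * np.arange(n)) % 86400.0
    return EpochSeries(subject_id, activity, hrm, hrsd, clock, stage=hyp,
                       epoch_s=hyp.epoch_s)


def gen_rpeaks(hyp: Hypnogram, em: EmissionModel, artifact_rate: float = 0.0,
               seed: int = 0) -> RPeakTrain:
    """R-peak train consistent with the stage-conditional heart rate.

    Beat-to-beat IHR oscillates around the stage HRM as a zero-mean
    sinusoid of amplitude sqrt(2) * HRSD (three cycles per epoch), so the
    epoch-mean IHR equals the configured HRM and the epoch SD the
    configured HRSD. With ``artifact_rate`` > 0, beats are spuriously
    inserted (creating intervals < 0.33 s) or dropped (intervals > 1.33 s)
    with equal probability, emulating R-point detection errors.
    """
    if not 0.0 <= artifact_rate < 0.5:
        raise ValueError("artifact_rate must be in [0, 0.5)")
    if em.scheme.name != hyp.scheme.name:
        raise ValueError("emission model scheme does not match hypnogram scheme")
    rng = np.random.default_rng(seed)
    times: list[float] = []
    t = 0.0
    n_epochs = len(hyp)
    total = n_epochs * hyp.epoch_s
    while t < total:
        e = min(int(t // hyp.epoch_s), n_epochs - 1)
        p = em.per_stage[hyp.scheme.labels[hyp.codes[e]]]
        ihr = p.hrm_mean + np.sqrt(2.0) * p.hrsd_mean * np.sin(
            2.0 * np.pi * 3.0 * t / hyp.epoch_s)
        ihr = float(np.clip(ihr, 46.0, 178.0))  # keep clean beats in-band
        t += 60.0 / ihr
        times.append(t)
    ts = np.array(times)
    if artifact_rate > 0.0:
        keep = np.ones(ts.size, dtype=bool)
        extra: list[float] = []
        u = rng.random(ts.size)
        for i in range(1, ts.size - 1):
            if u[i] < artifact_rate / 2.0:          # spurious beat
                extra.append(ts[i - 1] + 0.3 * (ts[i] - ts[i - 1]))
            elif u[i] < artifact_rate:              # missed beat
                keep[i] = False
        ts = np.sort(np.concatenate([ts[keep], np.array(extra)]))
        ts = ts[np.concatenate([[True], np.diff(ts) > 1e-6])]
    return RPeakTrain(ts)


def gen_cohort(n_subjects: int, scheme_: str | StageScheme = "four",
               n_epochs: int = DEFAULT_NIGHT_EPOCHS, seed: int = 0,
               hyp_model: HypnogramModel | None = None,
               em: EmissionModel | None = None) -> list[EpochSeries]:
    """Generate a labeled cohort of independent subject-nights."""
    sch = scheme(scheme_)
    hyp_model = hyp_model or HypnogramModel(sch)
    em = em or EmissionModel(sch)
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        hyp = gen_hypnogram(hyp_model, n_epochs, int(s1))
        cohort.append(gen_signals(hyp, em, int(s2), subject_id=f"subj{i:04d}"))
    return cohort
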