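"""Self-contained replication experiments on synthetic cohorts.

These run the full pipeline (simulate -> split -> train -> mode-voted
inference -> metrics) at CPU-friendly problem sizes and return the
quantities of interest. They back the package's end-to-end checks:
learning sanity on well-separated stages, the minority-class
false-positive effect of real-world (RW) versus inverse-frequency (IF)
loss weighting, and the benefit of pretraining before fine-tuning on a
small shifted-domain cohort.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .metrics import confusion
from .stages import Hypnogram, scheme
from .synthetic import (EmissionModel, HypnogramModel, StageEmission,
                        gen_cohort, gen_hypnogram)
from .training import SplitSpec, TrainConfig, evaluate_cohort, fine_tune, split_subjects, train_model


def _split_cohort(cohort, seed):
    ids = [s.subject_id for s in cohort]
    tr, va, te = split_subjects(ids, SplitSpec(seed=seed))
    by_id = {s.subject_id: s for s in cohort}
    return ([by_id[i] for i in tr], [by_id[i] for i in va], [by_id[i] for i in te])


def learning_sanity(seed: int = 0, n_subjects: int = 50, night_epochs: int = 240,
                    opt_epochs: int = 20, steps_per_epoch: int = 60,
                    hidden: int = 32, separation: float = 4.0) -> dict:
    """Train a reduced model on well-separated three-class nights.

    Stage emissions are separated by >= ``separation`` SDs per channel, so
    a working learner should recover staging almost perfectly; reported is
    the mode-voted test macro sensitivity (chance level 1/3).
    """
    sch = scheme("three")
    em = EmissionModel.well_separated(sch, separation)
    cohort = gen_cohort(n_subjects, sch, night_epochs, seed=seed, em=em)
    train_set, val_set, test_set = _split_cohort(cohort, seed)
    cfg = TrainConfig(scheme="three", variant="act-hr", hidden=hidden,
                      conv_channels=hidden, n_epochs=opt_epochs,
                      steps_per_epoch=steps_per_epoch, seed=seed)
    model, norm, history = train_model(train_set, val_set, cfg)
    res = evaluate_cohort(model, norm, test_set, cfg)
    return {
        "macro_sensitivity": res["metrics"]["sensitivity"],
        "accuracy": res["metrics"]["accuracy"],
        "weighted_f1": res["metrics"]["weighted_f1"],
        "confusion": res["confusion"],
        "history": history,
        "n_windows": sum(len(s) - cfg.window + 1 for s in train_set),
    }


def deep_false_positives(cm) -> int:
    """Epochs of other stages misclassified as Deep (row sum minus TP)."""
    d = list(cm.labels).index("Deep")
    return int(cm.counts[d].sum() - cm.counts[d, d])


def imbalance_comparison(seeds=(0, 1, 2), n_subjects: int = 24,
                         night_epochs: int = 300, opt_epochs: int = 18,
                         steps_per_epoch: int = 60, hidden: int = 32) -> dict:
    """IF- vs RW-weighted training on imbalanced four-class nights.

    Nights use the default stage mix (33/47/9/11 % wake/light/deep/REM,
    Deep the minority) and the default overlapping light/deep emissions.
    For each seed both losses are trained at a matched budget on identical
    data; pooled test-set confusion matrices give the number of Deep false
    positives under each loss.
    """
    results = {"if": [], "rw": [], "if_deep_tp": [], "rw_deep_tp": []}
    for seed in seeds:
        cohort = gen_cohort(n_subjects, "four", night_epochs, seed=seed)
        train_set, val_set, test_set = _split_cohort(cohort, seed)
        base = TrainConfig(scheme="four", variant="act-hr", hidden=hidden,
                           conv_channels=hidden, n_epochs=opt_epochs,
                           steps_per_epoch=steps_per_epoch, seed=seed)
        for loss in ("if", "rw"):
            cfg = replace(base, loss=loss)
            model, norm, _ = train_model(train_set, val_set, cfg)
            cm = evaluate_cohort(model, norm, test_set, cfg)["confusion"]
            d = list(cm.labels).index("Deep")
            results[loss].append(deep_false_positives(cm))
            results[f"{loss}_deep_tp"].append(int(cm.counts[d, d]))
    results["mean_if_fp"] = float(np.mean(results["if"]))
    results["mean_rw_fp"] = float(np.mean(results["rw"]))
    return results


def _shifted_emissions(em: EmissionModel, hrm_shift: float = 6.0,
                       act_scale: float = 1.6) -> EmissionModel:
    """A target domain: same stage structure, shifted channel statistics."""
    per = {}
    for lab, p in em.per_stage.items():
        per[lab] = StageEmission(p.activity_mean * act_scale, p.activity_sd * act_scale,
                                 p.hrm_mean + hrm_shift, p.hrm_sd,
                                 p.hrsd_mean, p.hrsd_sd)
    return EmissionModel(em.scheme, per)


def transfer_learning(seeds=(0, 1, 2, 3, 4), n_source: int = 12, n_target: int = 6,
                      night_epochs: int = 240, opt_epochs: int = 10,
                      steps_per_epoch: int = 50, hidden: int = 24) -> dict:
    """Pretrain on a large source cohort, fine-tune on a small shifted one.

    Compares target-domain test accuracy of the fine-tuned model against
    training directly on the small target cohort at the same budget.
    Returns per-seed accuracies and their means.
    """
    sch = scheme("three")
    src_em = EmissionModel.well_separated(sch, 3.0)
    tgt_em = _shifted_emissions(src_em)
    ft_accs, direct_accs = [], []
    for seed in seeds:
        source = gen_cohort(n_source, sch, night_epochs, seed=seed, em=src_em)
        target = gen_cohort(n_target, sch, night_epochs, seed=seed + 1000, em=tgt_em)
        t_train, t_val, t_test = target[:-2], target[-2:-1], target[-1:]
        cfg = TrainConfig(scheme="three", variant="act-hr", hidden=hidden,
                          conv_channels=hidden, n_epochs=opt_epochs,
                          steps_per_epoch=steps_per_epoch, seed=seed)
        s_train, s_val, _ = _split_cohort(source, seed)
        pre_model, pre_norm, _ = train_model(s_train, s_val, cfg)
        ft_model, _ = fine_tune(pre_model, pre_norm, t_train, t_val, cfg)
        ft_accs.append(evaluate_cohort(ft_model, pre_norm, t_test, cfg)
                       ["metrics"]["accuracy"])
        d_model, d_norm, _ = train_model(t_train, t_val, cfg)
        direct_accs.append(evaluate_cohort(d_model, d_norm, t_test, cfg)
                           ["metrics"]["accuracy"])
    return {"finetuned": ft_accs, "direct": direct_accs,
            "mean_finetuned": float(np.mean(ft_accs)),
            "mean_direct": float(np.mean(direct_accs))}


def chance_level_diagonal(K: int, n_epochs: int = 100_000, seed: int = 0) -> float:
    """Mean column-normalized diagonal (%) of a uniform-random classifier.

    The analytic value is 100/K %; Monte-Carlo with the package's own
    confusion-matrix path.
    """
    rng = np.random.default_rng(seed)
    sch = scheme({2: "two", 3: "three", 4: "four"}[K])
    truth = gen_hypnogram(HypnogramModel(sch), n_epochs, seed)
    pred = Hypnogram(rng.integers(0, K, n_epochs), sch)
    cm = confusion(pred, truth)
    return float(np.nanmean(np.diag(cm.column_normalized())))
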