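"""Whole-pipeline simulation studies: null calibration, planted-signal
recovery, and quartile-index calibration.

These routines exercise the complete analysis chain on generated cohorts and
report summary rates.  They back both the validation suite and the
reproduction script, so the study conditions (cohort sizes 9/10/10, 1100
miRNAs, planted 25 up / 9 down with 12 persistent) live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cessation as ces
from . import diffexp as de
from . import enrichment as enr
from . import synthetic as syn
from .diffexp import ThresholdConfig


def _spawn_seeds(seed: int, n: int, stream: int) -> list[int]:
    """Derive n child seeds (< 2**31) from a base seed and stream label."""
    rng = np.random.default_rng([seed, stream])
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def null_calibration(n_replicates: int = 50, n_mirna: int = 1100,
                     alpha: float = 0.01, seed: int = 0) -> dict:
    """Fraction of null features passing the p-gate alone on all-null cohorts.

    Each replicate is a 9/10/10 cohort with no planted features; the
    smoker-vs-nonsmoker LSD p is exactly t-distributed under the model, so
    the pooled pass fraction should sit near alpha.
    """
    hits = 0
    for s in _spawn_seeds(seed, n_replicates, stream=1):
        design = syn.CohortDesign(n_mirna=n_mirna, n_up=0, n_down=0, seed=s)
        expr, meta, _ = syn.generate_cohort(design)
        records = de.differential_expression(expr, meta)
        hits += int((records["p_value"] < alpha).sum())
    n_tests = n_replicates * n_mirna
    return {"fraction": hits / n_tests, "hits": hits, "n_tests": n_tests,
            "alpha": alpha}


def index_calibration(signature_size: int = 34, n_train: int = 500,
                      n_holdout: int = 500, seed: int = 0) -> dict:
    """Mean quartile index of held-out nonsmokers against trained thresholds.

    A continuous feature lands above the 3rd (or below the 1st) quartile of
    an independent nonsmoker reference with probability ~1/4, so the mean
    index should approach signature_size / 4.  The reference sample must be
    large for this: with n reference values the exceedance probability of
    the interpolated quartile is (n-dependent) order-statistic coverage, and
    only tends to 1/4 as n grows.
    """
    n_up = (signature_size + 1) // 2
    design = syn.CohortDesign(
        n_nonsmoker=n_train + n_holdout, n_smoker=2,
        n_mirna=signature_size, n_up=n_up, n_down=signature_size - n_up,
        persist_fraction=0.5, seed=_spawn_seeds(seed, 1, stream=2)[0])
    expr, meta, truth = syn.generate_cohort(design)
    ns = meta.samples_in("nonsmoker")
    train, holdout = ns[:n_train], ns[n_train:]

    directions = truth.table["direction"]
    sig_ids = list(directions.index)
    train_vals = expr.values.loc[sig_ids, train].to_numpy(dtype=float)
    q1, q3 = np.quantile(train_vals, [0.25, 0.75], axis=1)
    thresholds = pd.DataFrame({"q1": q1, "q3": q3}, index=sig_ids)
    indices = np.array([
        ces.subject_index(expr.values[s], directions, thresholds)
        for s in holdout], dtype=float)
    sem = indices.std(ddof=1) / np.sqrt(len(indices))
    return {"mean_index": float(indices.mean()),
            "expected": signature_size / 4.0,
            "sem": float(sem), "n_holdout": len(indices),
            "signature_size": signature_size}


@dataclass(frozen=True)
class RecoveryResult:
    de_recovery: float  # mean fraction of planted features selected
    persistence_recovery: float  # mean fraction of persistent truths called
    pathway_top_rate: float  # fraction of seeds ranking the planted pathway 1st
    kw_significant_rate: float  # fraction of seeds with index KW p < 0.05
    n_seeds: int


def recovery_study(n_seeds: int = 50, effect_log2: float = 2.0,
                   noise_sd_log2: float = 0.5, n_mirna: int = 1100,
                   seed: int = 0, cfg: ThresholdConfig | None = None,
                   ) -> RecoveryResult:
    """Planted-signal recovery across seeds at the emulated study size.

    Each seed plants 25 up / 9 down smoking-dependent miRNAs (12 of them
    cessation-persistent) in a 9/10/10 cohort, runs selection, persistence
    classification, the quartile index comparison, and the pathway analysis
    of the recovered persistent set against generated annotations.
    """
    cfg = cfg or ThresholdConfig()
    de_rates, persist_rates, pathway_top, kw_sig = [], [], [], []
    for s in _spawn_seeds(seed, n_seeds, stream=3):
        design = syn.CohortDesign(n_mirna=n_mirna, n_up=25, n_down=9,
                                  persist_fraction=12 / 34,
                                  effect_log2=effect_log2,
                                  noise_sd_log2=noise_sd_log2, seed=s)
        expr, meta, truth = syn.generate_cohort(design)
        records = de.differential_expression(expr, meta)
        signature = de.select_smoking_dependent(records, cfg)
        selected = set(signature["mirna_id"])
        planted = set(truth.planted())
        de_rates.append(len(selected & planted) / len(planted))

        table = ces.cessation_analysis(expr, meta, signature, cfg)
        called = set(table.loc[table["persistent"], "mirna_id"])
        truly = set(truth.persistent())
        persist_rates.append(len(called & truly) / len(truly))

        thresholds = ces.nonsmoker_quartiles(expr, meta,
                                             signature["mirna_id"])
        idx = ces.index_table(expr, meta,
                              signature.set_index("mirna_id")["direction"],
                              thresholds)
        kw_sig.append(ces.index_group_comparison(idx).p < 0.05)

        ann = syn.generate_annotation_resources(
            truth, syn.AnnotationParams(seed=s))
        filtered = enr.filter_targets_by_expression(ann.targets, ann.rpkm, cfg)
        if called:
            summary = enr.collect_persistent_targets(called, filtered,
                                                     ann.pathways)
            top = summary.pathway_stats.loc[0, "pathway"]
            pathway_top.append(top == syn.PLANTED_PATHWAY)
        else:
            pathway_top.append(False)
    return RecoveryResult(
        de_recovery=float(np.mean(de_rates)),
        persistence_recovery=float(np.mean(persist_rates)),
        pathway_top_rate=float(np.mean(pathway_top)),
        kw_significant_rate=float(np.mean(kw_sig)),
        n_seeds=n_seeds)
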