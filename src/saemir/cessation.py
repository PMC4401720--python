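"""Cessation reversibility: persistence classification, % change, and the
quartile-based smoking-dependent miRNA index.

A smoking-dependent miRNA is *cessation-persistent* when it still differs
between quitters and nonsmokers (p < 0.05, |FC| > 1.5, from the same
three-group ANOVA's LSD contrast) after three months off cigarettes, and
*reversible* otherwise.

Reversibility is quantified on the linear (anti-logged, "absolute") scale:

    % change = 100 * (smoker mean - quitter mean) / (smoker mean - nonsmoker mean)

100% is a full return to the nonsmoker level, 0% no movement; the statistic
is direction-agnostic because numerator and denominator share sign for a
true reversal.  A near-zero denominator (the miRNA never differed from
nonsmokers on the linear scale) makes the statistic undefined; such records
are flagged rather than aborting the pipeline.

The smoking-dependent miRNA index summarises a subject's global signature
load: one point per signature miRNA whose expression exceeds the nonsmoker
3rd quartile (up-regulated miRNAs) or falls below the 1st quartile
(down-regulated), strict inequalities, so a continuous null feature scores
with probability ~1/4.  Group differences in the index are tested with the
tie-corrected Kruskal-Wallis statistic followed by Dunn's pairwise z tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import (AnovaTable, ThresholdConfig, apply_gate,
                      fit_anova_matrix, lsd_contrast_table,
                      signed_fold_change)
from .exceptions import (DesignError, FormatError,
                         UndefinedReversibilityError)
from .io import ExpressionMatrix, SampleMeta

_EPS_REL = 1e-9


def percent_change(mean_ns: float, mean_s: float, mean_q: float) -> float:
    """% reversal from linear-scale group means (nonsmoker, smoker, quitter).

    Raises :class:`UndefinedReversibilityError` when the smoker-nonsmoker
    difference is zero to within relative tolerance 1e-9.
    """
    for v in (mean_ns, mean_s, mean_q):
        if not np.isfinite(v):
            raise FormatError("non-finite group mean")
    denom = mean_s - mean_ns
    scale = max(abs(mean_s), abs(mean_ns))
    if denom == 0 or abs(denom) < _EPS_REL * scale:
        raise UndefinedReversibilityError(
            "smoker and nonsmoker means coincide; % change undefined")
    return 100.0 * (mean_s - mean_q) / denom


def classify_persistence(signature: pd.DataFrame,
                         quitter_records: pd.DataFrame,
                         cfg: ThresholdConfig) -> pd.DataFrame:
    """Flag each signature miRNA persistent or reversible.

    ``signature`` needs columns mirna_id and direction (the smoking
    signature); ``quitter_records`` needs mirna_id, fold_change, p_value for
    the quitter-vs-nonsmoker contrast of every signature miRNA.  Persistent
    iff p < persist_p and |FC| > persist_fc.  ``direction_consistent``
    records whether the quitter fold-change sign matches the signature
    direction (a mismatched "persistent" call is suspect).
    """
    q = quitter_records.set_index("mirna_id")
    missing = [m for m in signature["mirna_id"] if m not in q.index]
    if missing:
        raise DesignError(
            f"signature miRNA(s) absent from quitter records: {missing[:5]}")
    fc = q.loc[signature["mirna_id"], "fold_change"].to_numpy(dtype=float)
    p = q.loc[signature["mirna_id"], "p_value"].to_numpy(dtype=float)
    persistent = (p < cfg.persist_p) & (np.abs(fc) > cfg.persist_fc)
    sig_sign = np.where(signature["direction"].to_numpy() == "up", 1.0, -1.0)
    consistent = np.sign(fc) == sig_sign
    return pd.DataFrame({
        "mirna_id": signature["mirna_id"].to_numpy(),
        "direction": signature["direction"].to_numpy(),
        "quitter_fc": fc,
        "quitter_p": p,
        "persistent": persistent,
        "direction_consistent": consistent,
    })


def group_linear_means(expr: ExpressionMatrix, meta: SampleMeta,
                       ) -> pd.DataFrame:
    """Per-miRNA group means of anti-logged (linear-scale) intensities."""
    linear = expr.linear()
    out = {}
    for g in meta.group_sizes():
        out[g] = linear[meta.samples_in(g)].mean(axis=1)
    return pd.DataFrame(out)


def cessation_analysis(expr: ExpressionMatrix, meta: SampleMeta,
                       signature: pd.DataFrame, cfg: ThresholdConfig,
                       include_gender="auto") -> pd.DataFrame:
    """Full cessation table for a three-group cohort.

    Computes the quitter-vs-nonsmoker LSD contrast from the three-group
    (+ gender) ANOVA, classifies persistence, and attaches the linear-scale
    % change per signature miRNA.  Columns: mirna_id, direction, quitter_fc,
    quitter_p, persistent, direction_consistent, percent_change,
    percent_change_defined.
    """
    sig_ids = list(signature["mirna_id"])
    sub = expr.subset(sig_ids)
    fits = fit_anova_matrix(sub, meta, include_gender)
    contrast = lsd_contrast_table(fits, "quitter", "nonsmoker")
    quitter_records = pd.DataFrame({
        "mirna_id": contrast.index,
        "fold_change": signed_fold_change(contrast["log2_diff"].to_numpy()),
        "p_value": contrast["p_value"].to_numpy(),
    })
    out = classify_persistence(signature, quitter_records, cfg)

    means = group_linear_means(sub, meta)
    pc = np.full(len(sig_ids), np.nan)
    defined = np.zeros(len(sig_ids), dtype=bool)
    for i, m in enumerate(sig_ids):
        try:
            pc[i] = percent_change(means.loc[m, "nonsmoker"],
                                   means.loc[m, "smoker_baseline"],
                                   means.loc[m, "quitter"])
            defined[i] = True
        except UndefinedReversibilityError:
            pass
    out["percent_change"] = pc
    out["percent_change_defined"] = defined
    return out


def reversal_fraction_curve(percent_changes, cutoffs) -> np.ndarray:
    """Fraction (%) of miRNAs whose % change falls below each cutoff."""
    pc = np.asarray(percent_changes, dtype=float)
    pc = pc[np.isfinite(pc)]
    if pc.size == 0:
        raise DesignError("no defined % change records")
    cuts = np.asarray(cutoffs, dtype=float)
    return np.array([100.0 * float((pc < c).sum()) / pc.size for c in cuts])


# ---------------------------------------------------------------------------
# quartile index
# ---------------------------------------------------------------------------

def nonsmoker_quartiles(expr: ExpressionMatrix, meta: SampleMeta,
                        signature_ids) -> pd.DataFrame:
    """Q1/Q3 of nonsmoker expression per signature miRNA (log2 units).

    Quantiles are interpolated empirical quantiles (the k-th of n sorted
    values sits at probability (k-1)/(n-1)); at least 4 nonsmoker samples
    are required for the quartiles to be meaningful.
    """
    ns = meta.samples_in("nonsmoker")
    if len(ns) < 4:
        raise DesignError(
            f"need >= 4 nonsmoker samples for quartiles, got {len(ns)}")
    sub = expr.subset(list(signature_ids)).values[ns].to_numpy(dtype=float)
    q1, q3 = np.quantile(sub, [0.25, 0.75], axis=1)
    return pd.DataFrame({"q1": q1, "q3": q3},
                        index=pd.Index(list(signature_ids), name="mirna_id"))


def subject_index(sample_expr: pd.Series, directions: pd.Series,
                  thresholds: pd.DataFrame) -> int:
    """Smoking-dependent miRNA index for one sample.

    One point per signature miRNA with value strictly above q3 (up-regulated
    signature direction) or strictly below q1 (down-regulated); boundary
    values score 0.
    """
    missing = [m for m in directions.index if m not in sample_expr.index]
    if missing:
        raise DesignError(f"sample missing signature miRNA(s): {missing[:5]}")
    v = sample_expr.reindex(directions.index).to_numpy(dtype=float)
    up = directions.to_numpy() == "up"
    q1 = thresholds.loc[directions.index, "q1"].to_numpy(dtype=float)
    q3 = thresholds.loc[directions.index, "q3"].to_numpy(dtype=float)
    hits = np.where(up, v > q3, v < q1)
    return int(hits.sum())


def index_table(expr: ExpressionMatrix, meta: SampleMeta,
                directions: pd.Series, thresholds: pd.DataFrame,
                ) -> pd.DataFrame:
    """Index per sample; columns sample_id, group, index."""
    sub = expr.subset(list(directions.index))
    rows = []
    group_of = meta.group_of()
    for s in meta.sample_ids:
        idx = subject_index(sub.values[s], directions, thresholds)
        rows.append({"sample_id": s, "group": group_of[s], "index": idx})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KruskalDunnResult:
    h: float
    p: float
    dunn: pd.DataFrame  # group_a, group_b, z, p_value, p_bonferroni


def _tie_sum(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p.

    Degenerate all-tied data yields H = 0, p = 1 (no information) instead of
    an error.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / len(r)
        for r in np.split(ranks, np.cumsum(sizes)[:-1])) - 3.0 * (n + 1)
    correction = 1.0 - _tie_sum(ranks) / (n ** 3 - n)
    if correction <= 0:
        return 0.0, 1.0
    h /= correction
    h = max(h, 0.0)
    df = len(groups) - 1
    return float(h), float(stats.chi2.sf(h, df))


def index_group_comparison(indices: pd.DataFrame) -> KruskalDunnResult:
    """Kruskal-Wallis across groups with Dunn's pairwise post-hoc tests.

    ``indices`` needs columns group and index; each group must have at least
    2 members.  Dunn z uses the pooled-rank variance with tie correction;
    p-values are two-sided normal, reported unadjusted with a Bonferroni
    column.
    """
    names = [g for g in ("nonsmoker", "smoker_baseline", "quitter")
             if g in set(indices["group"])]
    names += sorted(set(indices["group"]) - set(names))
    groups = [indices.loc[indices["group"] == g, "index"].to_numpy(dtype=float)
              for g in names]
    if len(groups) < 2:
        raise DesignError("need at least 2 groups")
    small = [g for g, v in zip(names, groups) if len(v) < 2]
    if small:
        raise DesignError(f"group(s) with fewer than 2 members: {small}")

    h, p = kruskal_wallis(groups)

    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    split = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
    mean_ranks = {g: r.mean() for g, r in zip(names, split)}
    sizes = {g: len(r) for g, r in zip(names, split)}
    tie_term = _tie_sum(ranks) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term

    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for a, b in pairs:
        var = base_var * (1.0 / sizes[a] + 1.0 / sizes[b])
        if var <= 0:
            z, pz = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            pz = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z),
                     "p_value": float(min(pz, 1.0)),
                     "p_bonferroni": float(min(pz * len(pairs), 1.0))})
    return KruskalDunnResult(h=h, p=p, dunn=pd.DataFrame(rows))
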