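"""Per-miRNA two-factor ANOVA with Fisher's LSD contrasts.

Model
-----
For each miRNA the log2 intensity is modelled additively as

    y = mu + group + gender + noise,        noise ~ N(0, sigma^2)

with group in {nonsmoker, smoker_baseline, quitter} and gender as a
covariate (the cohort showed gender as a source of variation).  There is no
interaction term.  Sums of squares are Type II, which for an additive model
is invariant to factor order in the unbalanced case:

    SS(group | gender) = RSS(gender-only) - RSS(full)

Fisher's LSD contrast between groups a and b re-uses the pooled residual
mean square of the full fit:

    t = (mean_a - mean_b) / sqrt(MSE * (1/n_a + 1/n_b))

on the full model's residual degrees of freedom, two-sided.  With exactly
two groups and no gender term this reduces to the pooled-variance two-sample
t test.  Quitters are treated as an independent third group; the paired
structure is deliberately ignored so that every pairwise comparison comes
from one coherent model.

Because the design matrix is shared by every miRNA row, the whole matrix is
fitted at once with QR projections; per-row fits are a thin wrapper.

Fold-changes are anti-logged differences of group mean log2 values, reported
in the signed convention (|FC| >= 1, down-regulation as negative
reciprocal).  Selection gates use strict inequalities (p < threshold,
|FC| > threshold); re-gating tables whose fold-changes were rounded for
printing should pass ``fc_inclusive=True`` so that a printed boundary value
is not dropped by a rounding artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateFitError, DesignError, FormatError
from .io import ExpressionMatrix, SampleMeta

#: Relative tolerance below which a residual sum of squares counts as zero.
_RSS_RTOL = 1e-10

CONTRASTS = {
    "smoker_vs_nonsmoker": ("smoker_baseline", "nonsmoker"),
    "quitter_vs_nonsmoker": ("quitter", "nonsmoker"),
    "smoker_vs_quitter": ("smoker_baseline", "quitter"),
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Selection thresholds; defaults are the published criteria."""

    de_p: float = 0.01
    de_fc: float = 1.5
    persist_p: float = 0.05
    persist_fc: float = 1.5
    rpkm_min: float = 0.125

    def __post_init__(self) -> None:
        if min(self.de_p, self.de_fc, self.persist_p, self.persist_fc,
               self.rpkm_min) <= 0:
            raise FormatError("thresholds must be positive")
        if self.de_fc <= 1 or self.persist_fc <= 1:
            raise FormatError("fold-change thresholds must exceed 1")


@dataclass(frozen=True)
class AnovaFit:
    """Single-miRNA two-factor fit summary."""

    group_f: float
    group_p: float
    gender_f: float  # NaN when the gender term was dropped
    gender_p: float
    mse: float
    df_resid: int
    group_means: dict[str, float]
    group_sizes: dict[str, int]


@dataclass(frozen=True)
class AnovaTable:
    """Vectorized fit over all miRNA rows of a matrix.

    ``stats`` is indexed by miRNA id with columns group_f, group_p,
    gender_f, gender_p, mse; ``group_means`` is miRNA x group (log2 scale).
    """

    stats: pd.DataFrame
    group_means: pd.DataFrame
    group_sizes: dict[str, int]
    df_resid: int

    def row(self, mirna_id: str) -> AnovaFit:
        s = self.stats.loc[mirna_id]
        return AnovaFit(
            group_f=float(s["group_f"]), group_p=float(s["group_p"]),
            gender_f=float(s["gender_f"]), gender_p=float(s["gender_p"]),
            mse=float(s["mse"]), df_resid=self.df_resid,
            group_means={g: float(v) for g, v in
                         self.group_means.loc[mirna_id].items()},
            group_sizes=dict(self.group_sizes),
        )


def _resolve_gender(meta: SampleMeta,
                    include_gender: bool | Literal["auto"]) -> bool:
    n_levels = meta.table["gender"].nunique()
    if include_gender == "auto":
        return n_levels >= 2
    if include_gender and n_levels < 2:
        raise DesignError("gender term requested but only one gender present")
    return bool(include_gender)


def _design(meta: SampleMeta, with_gender: bool):
    """Full / group-only / gender-only design matrices (treatment coding)."""
    groups = meta.table["group"].to_numpy()
    levels = [g for g in ("nonsmoker", "smoker_baseline", "quitter")
              if (groups == g).any()]
    if len(levels) < 2:
        raise DesignError("ANOVA needs at least 2 groups")
    sizes = {g: int((groups == g).sum()) for g in levels}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise DesignError(f"group(s) with fewer than 2 samples: {small}")
    n = len(groups)
    intercept = np.ones((n, 1))
    group_cols = np.column_stack([(groups == g).astype(float)
                                  for g in levels[1:]])
    parts = [intercept, group_cols]
    x_gender_only = intercept
    if with_gender:
        gender_col = (meta.table["gender"].to_numpy() == "M").astype(float)
        parts.append(gender_col[:, None])
        x_gender_only = np.column_stack([intercept, gender_col])
    x_full = np.column_stack(parts)
    x_group_only = np.column_stack([intercept, group_cols])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise DesignError("confounded design: group/gender factors are aliased")
    return x_full, x_group_only, x_gender_only, levels, sizes


def _residual_maker(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return np.eye(x.shape[0]) - q @ q.T


def fit_anova_matrix(expr: ExpressionMatrix, meta: SampleMeta,
                     include_gender: bool | Literal["auto"] = "auto",
                     ) -> AnovaTable:
    """Fit the additive group(+gender) model to every miRNA row at once."""
    if set(expr.sample_ids) != set(meta.sample_ids):
        raise DesignError("expression samples and metadata samples differ")
    with_gender = _resolve_gender(meta, include_gender)
    x_full, x_group, x_gender, levels, sizes = _design(meta, with_gender)
    y = expr.values[meta.sample_ids].to_numpy(dtype=float)  # miRNA x sample
    n = y.shape[1]

    m_full = _residual_maker(x_full)
    rss_full = ((y @ m_full) * y).sum(axis=1)
    rss_nogroup = ((y @ _residual_maker(x_gender)) * y).sum(axis=1)

    df_resid = n - x_full.shape[1]
    centered_ss = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    degenerate = rss_full <= _RSS_RTOL * (centered_ss + 1.0)
    if degenerate.any():
        bad = expr.mirna_ids[int(np.argmax(degenerate))]
        raise DegenerateFitError(
            f"zero residual variance for miRNA '{bad}': all residuals are 0"
        )
    mse = rss_full / df_resid

    df_group = len(levels) - 1
    ss_group = np.maximum(rss_nogroup - rss_full, 0.0)
    group_f = (ss_group / df_group) / mse
    group_p = stats.f.sf(group_f, df_group, df_resid)

    if with_gender:
        rss_nogender = ((y @ _residual_maker(x_group)) * y).sum(axis=1)
        ss_gender = np.maximum(rss_nogender - rss_full, 0.0)
        gender_f = ss_gender / mse  # df_gender = 1
        gender_p = stats.f.sf(gender_f, 1, df_resid)
    else:
        gender_f = np.full_like(group_f, np.nan)
        gender_p = np.full_like(group_f, np.nan)

    group_labels = meta.table["group"].to_numpy()
    means = pd.DataFrame(
        {g: y[:, group_labels == g].mean(axis=1) for g in levels},
        index=expr.mirna_ids)
    table = pd.DataFrame(
        {"group_f": group_f, "group_p": group_p,
         "gender_f": gender_f, "gender_p": gender_p, "mse": mse},
        index=pd.Index(expr.mirna_ids, name="mirna_id"))
    return AnovaTable(stats=table, group_means=means, group_sizes=sizes,
                      df_resid=df_resid)


def fit_group_gender_anova(values, meta: SampleMeta,
                           include_gender: bool | Literal["auto"] = "auto",
                           ) -> AnovaFit:
    """Fit a single miRNA's per-sample log2 values.

    ``values`` may be a pandas Series indexed by sample id or an array
    aligned with the metadata row order.
    """
    if isinstance(values, pd.Series):
        missing = [s for s in meta.sample_ids if s not in values.index]
        if missing:
            raise DesignError(f"values missing sample(s): {missing[:5]}")
        row = values.reindex(meta.sample_ids).to_numpy(dtype=float)
    else:
        row = np.asarray(values, dtype=float)
        if row.shape != (len(meta.sample_ids),):
            raise DesignError("values length does not match metadata")
    expr = ExpressionMatrix(pd.DataFrame([row], index=["_row"],
                                         columns=meta.sample_ids))
    return fit_anova_matrix(expr, meta, include_gender).row("_row")


# ---------------------------------------------------------------------------
# contrasts and fold-changes
# ---------------------------------------------------------------------------

def lsd_contrast(fit: AnovaFit, group_a: str, group_b: str,
                 ) -> tuple[float, float]:
    """Fisher's LSD contrast (log2 mean difference a-b, two-sided p)."""
    for g in (group_a, group_b):
        if g not in fit.group_means:
            raise DesignError(f"group '{g}' not present in fit")
    diff = fit.group_means[group_a] - fit.group_means[group_b]
    se = np.sqrt(fit.mse * (1.0 / fit.group_sizes[group_a]
                            + 1.0 / fit.group_sizes[group_b]))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
    return float(diff), float(min(p, 1.0))


def lsd_contrast_table(table: AnovaTable, group_a: str, group_b: str,
                       ) -> pd.DataFrame:
    """Vectorized LSD contrast for every miRNA; columns log2_diff, p_value."""
    for g in (group_a, group_b):
        if g not in table.group_sizes:
            raise DesignError(f"group '{g}' not present in fit")
    diff = (table.group_means[group_a] - table.group_means[group_b]).to_numpy()
    se = np.sqrt(table.stats["mse"].to_numpy()
                 * (1.0 / table.group_sizes[group_a]
                    + 1.0 / table.group_sizes[group_b]))
    t = diff / se
    p = np.minimum(2.0 * stats.t.sf(np.abs(t), table.df_resid), 1.0)
    return pd.DataFrame({"log2_diff": diff, "p_value": p},
                        index=table.stats.index)


def signed_fold_change(log2_diff):
    """Signed fold-change: 2**d for d >= 0, else -2**(-d); |FC| >= 1.

    Accepts scalars or arrays; a log2 difference of 0 maps to +1.
    """
    d = np.asarray(log2_diff, dtype=float)
    if not np.isfinite(d).all():
        raise FormatError("non-finite log2 difference")
    r = np.power(2.0, d)
    fc = np.where(r >= 1.0, r, -1.0 / r)
    return float(fc) if np.isscalar(log2_diff) else fc


def differential_expression(expr: ExpressionMatrix, meta: SampleMeta,
                            contrast: str = "smoker_vs_nonsmoker",
                            include_gender: bool | Literal["auto"] = "auto",
                            ) -> pd.DataFrame:
    """Per-miRNA LSD contrast with fold-changes and BH q-values.

    Returns a DataFrame with columns mirna_id, direction, log2_diff,
    fold_change, p_value, q_value (matrix row order preserved).
    """
    if contrast not in CONTRASTS:
        raise DesignError(
            f"unknown contrast '{contrast}'; valid: {sorted(CONTRASTS)}")
    group_a, group_b = CONTRASTS[contrast]
    fits = fit_anova_matrix(expr, meta, include_gender)
    res = lsd_contrast_table(fits, group_a, group_b)
    fc = signed_fold_change(res["log2_diff"].to_numpy())
    q = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
    return pd.DataFrame({
        "mirna_id": res.index,
        "direction": np.where(res["log2_diff"].to_numpy() >= 0, "up", "down"),
        "log2_diff": res["log2_diff"].to_numpy(),
        "fold_change": fc,
        "p_value": res["p_value"].to_numpy(),
        "q_value": q,
    }).reset_index(drop=True)


def apply_gate(records: pd.DataFrame, p_max: float, fc_min: float,
               fc_inclusive: bool = False) -> pd.DataFrame:
    """Keep records with p < p_max and |FC| > fc_min (strict by default).

    ``fc_inclusive=True`` admits |FC| == fc_min, appropriate when the
    fold-change column was rounded for printing.
    """
    p = records["p_value"].to_numpy(dtype=float)
    fc = np.abs(records["fold_change"].to_numpy(dtype=float))
    keep = (p < p_max) & ((fc >= fc_min) if fc_inclusive else (fc > fc_min))
    return records.loc[keep].copy()


def select_smoking_dependent(records: pd.DataFrame, cfg: ThresholdConfig,
                             fc_inclusive: bool = False) -> pd.DataFrame:
    """Smoking-dependent miRNA selection: p < de_p and |FC| > de_fc.

    Kept records are partitioned up-then-down, stably sorted by |FC|
    descending within each direction (the published table ordering).
    """
    kept = apply_gate(records, cfg.de_p, cfg.de_fc, fc_inclusive)
    kept = kept.assign(
        _dir_rank=(kept["direction"] != "up").astype(int),
        _abs_fc=np.abs(kept["fold_change"].to_numpy(dtype=float)),
    )
    kept = kept.sort_values(["_dir_rank", "_abs_fc"],
                            ascending=[True, False], kind="stable")
    return kept.drop(columns=["_dir_rank", "_abs_fc"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# hierarchical clustering of the signature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterResult:
    """Average-linkage dendrograms (scipy linkage matrices) for both axes."""

    sample_linkage: np.ndarray
    mirna_linkage: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)


def _corr_condensed(profiles: np.ndarray, labels: list[str], axis_name: str,
                    ) -> np.ndarray:
    var = profiles.var(axis=1)
    if (var == 0).any():
        bad = labels[int(np.argmax(var == 0))]
        raise DegenerateFitError(
            f"zero-variance {axis_name} '{bad}': correlation undefined")
    dist = 1.0 - np.corrcoef(profiles)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def cluster_signature(expr: ExpressionMatrix) -> ClusterResult:
    """Unsupervised clustering: distance 1 - Pearson r, average linkage.

    Returns linkage matrices for samples (columns) and miRNAs (rows); scipy's
    agglomeration breaks distance ties by first index, so results are
    deterministic.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise DesignError("clustering needs at least 2 miRNAs and 2 samples")
    vals = expr.values.to_numpy(dtype=float)
    mirna_link = linkage(_corr_condensed(vals, expr.mirna_ids, "miRNA"),
                         method="average")
    sample_link = linkage(_corr_condensed(vals.T, expr.sample_ids, "sample"),
                          method="average")
    return ClusterResult(sample_linkage=sample_link, mirna_linkage=mirna_link,
                         sample_ids=expr.sample_ids, mirna_ids=expr.mirna_ids)


# ---------------------------------------------------------------------------
# comparative CT arithmetic (qPCR validation)
# ---------------------------------------------------------------------------

def ddct_fold_change(ct_target: pd.Series, ct_control: pd.Series,
                     groups: pd.Series, reference_group: str) -> pd.Series:
    """Comparative CT relative quantification: 2**(-ddCT) per sample.

    dCT = CT(target) - CT(endogenous control); ddCT subtracts the mean dCT
    of the reference group, so a ddCT of -1 (one-cycle advantage) doubles
    the relative quantity.
    """
    ct_target = ct_target.astype(float)
    ct_control = ct_control.reindex(ct_target.index).astype(float)
    groups = groups.reindex(ct_target.index)
    if ct_target.isna().any() or ct_control.isna().any() \
            or not np.isfinite(ct_target).all() or not np.isfinite(ct_control).all():
        raise FormatError("non-finite CT value")
    dct = ct_target - ct_control
    ref = dct[groups == reference_group]
    if ref.empty:
        raise DesignError(f"reference group '{reference_group}' is empty")
    ddct = dct - ref.mean()
    return np.power(2.0, -ddct)
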