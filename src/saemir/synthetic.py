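"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design this package analyses: a small
three-group bronchoscopy cohort (9 nonsmokers, 10 smokers at baseline, the
same 10 subjects again after 3 months of cessation), log2-scale array
intensities with Gaussian noise (i.e. log-normal linear intensities), a
gender covariate shift, and planted up/down smoking-dependent miRNAs of
which a configurable fraction stays dysregulated in the quitter samples.

Model per miRNA i and sample s:

    y_is = baseline_i + gender_effect * [male] + shift_is (+ subject intercept)
           + N(0, noise_sd^2)

where shift_is is +/-effect_log2 for planted features in smoker_baseline
samples, kept in quitter samples for persistent features and zero for
reversible ones.  Quitter values are regenerated with fresh noise rather
than baseline-plus-delta, so the paired structure carries no built-in
correlation unless ``subject_sd_log2`` is set.  Gender alternates within
each group (4/5 and 5/5 at the default sizes), keeping the two-factor
design estimable at these small n.

A matching annotation generator produces miRNA category sets (one enriched
in the planted miRNAs at a configurable fold), a miRNA-to-target-gene map
whose persistent-miRNA targets concentrate in a designated "planted"
pathway, and an RPKM table with genes on both sides of the expression
floor, so the enrichment stages have planted positives to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DesignError
from .io import (ExpressionMatrix, GeneSetCollection, RpkmTable, SampleMeta,
                 TargetMap)


@dataclass(frozen=True)
class CohortDesign:
    """Cohort generator parameters (defaults mirror the emulated study)."""

    n_nonsmoker: int = 9
    n_smoker: int = 10  # quitters are the same subjects re-sampled
    n_mirna: int = 1100
    n_up: int = 25
    n_down: int = 9
    persist_fraction: float = 12.0 / 34.0
    effect_log2: float = 1.5
    gender_effect_log2: float = 0.3
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.0
    subject_sd_log2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_nonsmoker, self.n_smoker) < 2 or self.n_mirna < 1:
            raise DesignError("cohort sizes must be at least 2 per group")
        if self.n_up < 0 or self.n_down < 0 \
                or self.n_up + self.n_down > self.n_mirna:
            raise DesignError("n_up + n_down must not exceed n_mirna")
        if not 0.0 <= self.persist_fraction <= 1.0:
            raise DesignError("persist_fraction must lie in [0, 1]")
        if self.noise_sd_log2 <= 0 or self.baseline_sd_log2 < 0 \
                or self.subject_sd_log2 < 0:
            raise DesignError("noise/scale standard deviations must be valid")


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth: direction and persistence per miRNA."""

    table: pd.DataFrame  # index mirna_id; columns direction, persistence

    def __post_init__(self) -> None:
        d = self.table["direction"]
        p = self.table["persistence"]
        planted = d != "null"
        if not ((p != "not_applicable") == planted).all():
            raise DesignError(
                "persistence must be not_applicable exactly for null features")

    def planted(self, direction: str | None = None) -> list[str]:
        t = self.table
        mask = t["direction"] != "null" if direction is None \
            else t["direction"] == direction
        return list(t.index[mask])

    def persistent(self) -> list[str]:
        return list(self.table.index[self.table["persistence"] == "persistent"])

    def reversible(self) -> list[str]:
        return list(self.table.index[self.table["persistence"] == "reversible"])


def _alternating_genders(n: int) -> list[str]:
    # F first: 9 -> 4M/5F and 10 -> 5M/5F, the emulated cohort's balance
    return ["F" if i % 2 == 0 else "M" for i in range(n)]


def _split_persistent(n_up: int, n_down: int, fraction: float,
                      ) -> tuple[int, int]:
    """Largest-remainder split of round(fraction * planted) across strata."""
    total = int(round(fraction * (n_up + n_down)))
    exact = [fraction * n_up, fraction * n_down]
    floors = [min(int(np.floor(e)), cap) for e, cap in zip(exact, (n_up, n_down))]
    rem = total - sum(floors)
    order = sorted((0, 1), key=lambda i: exact[i] - np.floor(exact[i]),
                   reverse=True)
    for i in order:
        cap = (n_up, n_down)[i]
        while rem > 0 and floors[i] < cap:
            floors[i] += 1
            rem -= 1
    return floors[0], floors[1]


def generate_cohort(design: CohortDesign,
                    ) -> tuple[ExpressionMatrix, SampleMeta, TruthTable]:
    """Deterministically generate (expression, metadata, truth) for a design."""
    rng = np.random.default_rng(design.seed)
    n_m = design.n_mirna
    mirna_ids = [f"sim-miR-{i + 1:04d}" for i in range(n_m)]

    # planted features and their persistence
    planted_idx = rng.choice(n_m, size=design.n_up + design.n_down,
                             replace=False)
    up_idx = planted_idx[: design.n_up]
    down_idx = planted_idx[design.n_up:]
    n_pu, n_pd = _split_persistent(design.n_up, design.n_down,
                                   design.persist_fraction)
    direction = np.array(["null"] * n_m, dtype=object)
    persistence = np.array(["not_applicable"] * n_m, dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    persistence[up_idx] = "reversible"
    persistence[down_idx] = "reversible"
    persistence[up_idx[:n_pu]] = "persistent"
    persistence[down_idx[:n_pd]] = "persistent"
    truth = TruthTable(table=pd.DataFrame(
        {"direction": direction, "persistence": persistence},
        index=pd.Index(mirna_ids, name="mirna_id")))

    # sample frame: nonsmokers, smokers at baseline, same smokers as quitters
    rows = []
    for i in range(design.n_nonsmoker):
        rows.append((f"NS{i + 1:03d}", f"subjN{i + 1:03d}", "nonsmoker"))
    for i in range(design.n_smoker):
        rows.append((f"SM{i + 1:03d}", f"subjS{i + 1:03d}", "smoker_baseline"))
    for i in range(design.n_smoker):
        rows.append((f"QU{i + 1:03d}", f"subjS{i + 1:03d}", "quitter"))
    genders = {}
    for g, n in (("nonsmoker", design.n_nonsmoker),
                 ("smoker_baseline", design.n_smoker)):
        alt = _alternating_genders(n)
        for (sid, subj, grp), gen in zip(
                [r for r in rows if r[2] == g], alt):
            genders[subj] = gen
    meta = SampleMeta(table=pd.DataFrame(
        [{"sample_id": sid, "subject_id": subj, "group": grp,
          "gender": genders[subj]} for sid, subj, grp in rows]))

    # expression
    baselines = rng.normal(design.baseline_mean_log2, design.baseline_sd_log2,
                           size=n_m)
    shift = np.zeros(n_m)
    shift[up_idx] = design.effect_log2
    shift[down_idx] = -design.effect_log2
    persists = np.isin(np.arange(n_m),
                       np.concatenate([up_idx[:n_pu], down_idx[:n_pd]]))
    subj_ids = sorted({r[1] for r in rows})
    subj_fx = {s: rng.normal(0.0, design.subject_sd_log2) if
               design.subject_sd_log2 > 0 else 0.0 for s in subj_ids}

    cols = {}
    for sid, subj, grp in rows:
        mean = baselines + design.gender_effect_log2 * (genders[subj] == "M")
        if grp == "smoker_baseline":
            mean = mean + shift
        elif grp == "quitter":
            mean = mean + np.where(persists, shift, 0.0)
        cols[sid] = mean + subj_fx[subj] + rng.normal(
            0.0, design.noise_sd_log2, size=n_m)
    expr = ExpressionMatrix(pd.DataFrame(
        cols, index=pd.Index(mirna_ids, name="mirna_id")))
    return expr, meta, truth


@dataclass(frozen=True)
class AnnotationParams:
    """Sizes and planting strengths for the synthetic annotation resources."""

    n_categories: int = 10
    category_size: int = 30
    planted_category_fold: float = 8.0  # target fold-enrichment of planted set
    n_genes: int = 2000
    targets_per_mirna: int = 40
    n_pathways: int = 10
    pathway_size: int = 80
    persistent_pathway_frac: float = 0.5  # persistent targets drawn in-pathway
    frac_low_rpkm: float = 0.1
    rpkm_min: float = 0.125
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_categories, self.category_size, self.n_genes,
               self.targets_per_mirna, self.n_pathways, self.pathway_size) < 1:
            raise DesignError("annotation sizes must be positive")
        if not 0.0 <= self.persistent_pathway_frac <= 1.0 \
                or not 0.0 <= self.frac_low_rpkm < 1.0:
            raise DesignError("fractions must lie in [0, 1]")


PLANTED_CATEGORY = "category_planted"
PLANTED_PATHWAY = "pathway_planted"


@dataclass(frozen=True)
class AnnotationResources:
    """Bundle of synthetic annotation inputs for the enrichment stages."""

    categories: GeneSetCollection  # miRNA function categories
    pathways: GeneSetCollection  # gene pathway sets
    targets: TargetMap
    rpkm: RpkmTable


def generate_annotation_resources(truth: TruthTable,
                                  params: AnnotationParams,
                                  ) -> AnnotationResources:
    """Category sets, pathways, target map and RPKM table for a truth table.

    The first category is constructed to be enriched in planted miRNAs at
    roughly ``planted_category_fold`` times the background rate; remaining
    categories are uniform draws.  Persistent miRNAs draw a fraction of
    their targets from the planted pathway's genes so the pathway analysis
    has a recoverable positive.  RPKM values straddle ``rpkm_min``.
    """
    rng = np.random.default_rng(params.seed)
    mirnas = np.array(truth.table.index)
    universe = len(mirnas)
    if params.category_size > universe or params.pathway_size > params.n_genes:
        raise DesignError("requested set size exceeds its universe")

    planted = np.array(truth.planted())
    others = np.array(sorted(set(mirnas) - set(planted)))
    base_rate = len(planted) / universe
    want = min(1.0, params.planted_category_fold * base_rate)
    n_from_planted = min(len(planted), int(round(want * params.category_size)))
    cat_sets: dict[str, frozenset[str]] = {}
    parts = []
    if n_from_planted:
        parts.append(rng.choice(planted, size=n_from_planted, replace=False))
    if params.category_size - n_from_planted:
        parts.append(rng.choice(others,
                                size=params.category_size - n_from_planted,
                                replace=False))
    cat_sets[PLANTED_CATEGORY] = frozenset(np.concatenate(parts))
    for i in range(params.n_categories - 1):
        cat_sets[f"category_rand_{i + 1:02d}"] = frozenset(
            rng.choice(mirnas, size=params.category_size, replace=False))
    categories = GeneSetCollection(sets=cat_sets, universe_size=universe)

    genes = np.array([f"GENE{i + 1:05d}" for i in range(params.n_genes)])
    pathway_sets: dict[str, frozenset[str]] = {}
    planted_pathway_genes = rng.choice(genes, size=params.pathway_size,
                                       replace=False)
    pathway_sets[PLANTED_PATHWAY] = frozenset(planted_pathway_genes)
    for i in range(params.n_pathways - 1):
        pathway_sets[f"pathway_rand_{i + 1:02d}"] = frozenset(
            rng.choice(genes, size=params.pathway_size, replace=False))
    pathways = GeneSetCollection(sets=pathway_sets,
                                 universe_size=params.n_genes)

    persistent = set(truth.persistent())
    off_pathway = np.array(sorted(set(genes) - set(planted_pathway_genes)))
    pairs: list[tuple[str, str]] = []
    n_in = int(round(params.persistent_pathway_frac * params.targets_per_mirna))
    n_in = min(n_in, params.pathway_size)
    for m in mirnas:
        if m in persistent:
            chosen = np.concatenate([
                rng.choice(planted_pathway_genes, size=n_in, replace=False),
                rng.choice(off_pathway, size=params.targets_per_mirna - n_in,
                           replace=False),
            ])
        else:
            chosen = rng.choice(genes, size=params.targets_per_mirna,
                                replace=False)
        pairs.extend((m, g) for g in sorted(set(chosen)))
    targets = TargetMap(pairs=tuple(pairs))

    rpkm_vals = rng.lognormal(mean=1.0, sigma=1.2, size=params.n_genes)
    n_low = max(1, int(round(params.frac_low_rpkm * params.n_genes)))
    low_idx = rng.choice(params.n_genes, size=n_low, replace=False)
    rpkm_vals[low_idx] = rng.uniform(0.0, params.rpkm_min, size=n_low)
    rpkm_vals = np.maximum(rpkm_vals, 0.0)
    if not (rpkm_vals > params.rpkm_min).any():
        rpkm_vals[int(rng.integers(params.n_genes))] = 10 * params.rpkm_min
    rpkm = RpkmTable(values=pd.Series(rpkm_vals, index=genes, name="rpkm"))
    return AnnotationResources(categories=categories, pathways=pathways,
                               targets=targets, rpkm=rpkm)
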