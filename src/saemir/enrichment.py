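"""Over-representation statistics for miRNA categories and target-gene
pathways.

For a query of m entities drawn from a universe of N, a set of size K with
k query hits gets:

    percent          = 100 * k / K
    fold_enrichment  = (k / m) / (K / N)
    p                = P[X >= k],  X ~ Hypergeometric(N, K, m)

The hypergeometric upper tail is identical to the one-sided Fisher exact
test on the 2x2 membership table, so a single implementation serves both
the miRNA-category analysis and the pathway analysis of persistent-miRNA
targets.  Predicted targets are restricted to genes actually expressed in
the tissue (RPKM strictly greater than a floor, 0.125 by default), and the
pathway universe defaults to that expression-filtered gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ThresholdConfig
from .exceptions import DesignError
from .io import GeneSetCollection, RpkmTable, TargetMap


def category_enrichment(query, collection: GeneSetCollection,
                        universe_members=None) -> pd.DataFrame:
    """Enrichment of every set in ``collection`` for the query entities.

    If ``universe_members`` is given, both the query and each set are
    intersected with it and N is its size; query members outside the
    universe are dropped with a warning.  Otherwise the collection's
    declared ``universe_size`` is used as N and the query is taken at face
    value.  Results are ranked by ascending p (ties broken by set name).
    """
    q = set(query)
    if universe_members is not None:
        universe = set(universe_members)
        outside = q - universe
        if outside:
            warnings.warn(
                f"{len(outside)} query member(s) outside the universe dropped",
                stacklevel=2)
            q &= universe
        n_universe = len(universe)
    else:
        universe = None
        n_universe = collection.universe_size
    if not q:
        raise DesignError("query is empty after universe intersection")
    m = len(q)

    rows = []
    for name, members in collection.sets.items():
        eff = members & universe if universe is not None else members
        big_k = len(eff)
        k = len(q & eff)
        percent = 100.0 * k / big_k if big_k else 0.0
        fold = (k / m) / (big_k / n_universe) if big_k else 0.0
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, m)) if big_k \
            else 1.0
        rows.append({"set_name": name, "count": k, "set_size": big_k,
                     "percent": percent, "fold_enrichment": fold,
                     "p_value": p})
    out = pd.DataFrame(rows).sort_values(["p_value", "set_name"],
                                         kind="stable")
    return out.reset_index(drop=True)


def filter_targets_by_expression(targets: TargetMap, rpkm: RpkmTable,
                                 cfg: ThresholdConfig) -> TargetMap:
    """Keep pairs whose gene has RPKM strictly above ``cfg.rpkm_min``.

    Genes absent from the RPKM table are dropped (not expressed as far as
    the reference profile knows).  Raising the floor can only remove pairs.
    """
    expressed = set(rpkm.values.index[rpkm.values.to_numpy() > cfg.rpkm_min])
    kept = tuple(p for p in targets.pairs if p[1] in expressed)
    return TargetMap(pairs=kept)


@dataclass(frozen=True)
class TargetSummary:
    """Pooled target-gene view of the persistent miRNAs."""

    per_mirna_counts: pd.Series  # expression-filtered target count per miRNA
    pooled_targets: frozenset[str]  # union, duplicates removed
    pathway_stats: pd.DataFrame  # pathway, size, overlap, coverage_ratio, p


def collect_persistent_targets(persistent_ids, targets: TargetMap,
                               pathways: GeneSetCollection,
                               universe_size: int | None = None,
                               ) -> TargetSummary:
    """Per-miRNA target counts, pooled deduplicated set, pathway coverage.

    ``targets`` should already be expression-filtered.  ``universe_size``
    defaults to the pathway collection's universe (normally the filtered
    expressed-gene list).  Coverage ratio is overlap / pathway size; p is
    the hypergeometric upper tail of the pooled set against the universe.
    Pathways are ranked by ascending p.
    """
    ids = list(persistent_ids)
    if not ids:
        raise DesignError("no persistent miRNAs supplied")
    by_mirna: dict[str, set[str]] = {m: set() for m in ids}
    for m, g in targets.pairs:
        if m in by_mirna:
            by_mirna[m].add(g)
    counts = pd.Series({m: len(gs) for m, gs in by_mirna.items()},
                       name="n_targets")
    empty = [m for m, c in counts.items() if c == 0]
    if empty:
        warnings.warn(
            f"persistent miRNA(s) with zero filtered targets: {empty[:5]}",
            stacklevel=2)
    pooled = frozenset().union(*by_mirna.values()) if by_mirna else frozenset()

    n_universe = universe_size if universe_size is not None \
        else pathways.universe_size
    m_query = len(pooled)
    rows = []
    for name, members in pathways.sets.items():
        k = len(pooled & members)
        big_k = len(members)
        rows.append({
            "pathway": name, "size": big_k, "overlap": k,
            "coverage_ratio": k / big_k,
            "p_value": float(stats.hypergeom.sf(k - 1, n_universe, big_k,
                                                m_query)),
        })
    stats_df = pd.DataFrame(rows).sort_values(["p_value", "pathway"],
                                              kind="stable")
    return TargetSummary(per_mirna_counts=counts, pooled_targets=pooled,
                         pathway_stats=stats_df.reset_index(drop=True))
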