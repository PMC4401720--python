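"""Readers, writers and validated containers for the pipeline's tabular formats.

Every external table is UTF-8 TSV with a header row; gene sets use the GMT
dialect (name, description, members, tab-separated).  Expression values are
assumed pre-normalized, log2-scale array intensities: no normalization is
performed here, and missing values are hard errors rather than imputed,
because downstream quartile thresholds and group means would silently shift.

Two fixture tables transcribed from the study this pipeline reproduces are
packaged under ``saemir/data``: the 34 smoking-dependent miRNAs
(``table2``: probe id, signed fold-change smoker vs nonsmoker, p) and the 12
cessation-persistent miRNAs (``table4``: quitter vs nonsmoker).  Probe ids
keep their ``_st`` suffixes verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import DesignError, FormatError

#: Allowed cohort group labels: never-smokers, smokers at baseline, and the
#: same smokers after three months of cessation.
GROUPS = ("nonsmoker", "smoker_baseline", "quitter")
GENDERS = ("M", "F")

_FIXTURES = ("table2", "table4")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """log2-scale miRNA x sample intensity matrix.

    ``values`` is a DataFrame indexed by miRNA id with one column per sample.
    Construction validates uniqueness of both id axes and finiteness of every
    cell; row/column order is preserved as given.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        for axis_name, labels in (("miRNA", idx), ("sample", cols)):
            dup = labels[labels.duplicated()]
            if len(dup):
                raise FormatError(f"duplicate {axis_name} id '{dup[0]}'")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            i, j = map(int, np.argwhere(~np.isfinite(arr))[0])
            raise FormatError(
                f"non-finite value at miRNA '{idx[i]}', sample '{cols[j]}'"
            )

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, mirna_ids: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given miRNAs (order as requested)."""
        wanted = list(mirna_ids)
        missing = [m for m in wanted if m not in self.values.index]
        if missing:
            raise FormatError(f"miRNA id(s) not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[wanted])

    def linear(self) -> pd.DataFrame:
        """Anti-logged (2**x) intensities, for absolute-scale statistics."""
        return np.power(2.0, self.values)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: sample id, subject id, group, gender.

    Validates group/gender vocabularies, sample-id uniqueness and the paired
    design: every quitter sample must share its subject id with exactly one
    smoker_baseline sample (quitters are re-sampled smokers).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "subject_id", "group", "gender"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing column(s): {missing}")
        t = self.table
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample id '{dup.iloc[0]}'")
        bad_group = sorted(set(t["group"]) - set(GROUPS))
        if bad_group:
            raise FormatError(
                f"unknown group label(s) {bad_group}; allowed: {list(GROUPS)}"
            )
        bad_gender = sorted(set(t["gender"]) - set(GENDERS))
        if bad_gender:
            raise FormatError(
                f"unknown gender label(s) {bad_gender}; allowed: {list(GENDERS)}"
            )
        baseline = t.loc[t["group"] == "smoker_baseline", "subject_id"]
        counts = baseline.value_counts()
        for subj in t.loc[t["group"] == "quitter", "subject_id"]:
            if counts.get(subj, 0) != 1:
                raise DesignError(
                    f"quitter subject '{subj}' has no unique smoker_baseline sample"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_of(self) -> pd.Series:
        """Series sample_id -> group."""
        return self.table.set_index("sample_id")["group"]

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise FormatError(f"unknown group '{group}'; allowed: {list(GROUPS)}")
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.table["group"] == g).sum()) for g in GROUPS
                if (self.table["group"] == g).any()}


@dataclass(frozen=True)
class GeneSetCollection:
    """Named sets over a universe of annotatable entities.

    ``universe_size`` is either supplied (preferred, e.g. the number of
    annotatable miRNAs) or derived as the union of all members, in which case
    ``universe_derived`` is True.
    """

    sets: dict[str, frozenset[str]]
    universe_size: int
    universe_derived: bool = False

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise FormatError("universe_size must be positive")
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set '{name}' is empty")
            if len(members) > self.universe_size:
                raise FormatError(
                    f"gene set '{name}' (size {len(members)}) exceeds universe "
                    f"size {self.universe_size}"
                )

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class TargetMap:
    """Deduplicated (miRNA, target gene) association pairs, order-preserving."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise FormatError("duplicate (miRNA, gene) pair in TargetMap")

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self, mirna_id: str) -> frozenset[str]:
        return frozenset(g for m, g in self.pairs if m == mirna_id)

    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.pairs)

    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)


@dataclass(frozen=True)
class RpkmTable:
    """Gene expression levels in RPKM; values must be finite and >= 0."""

    values: pd.Series

    def __post_init__(self) -> None:
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene id '{dup[0]}' in RPKM table")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            bad = self.values.index[~(np.isfinite(arr) & (arr >= 0))][0]
            raise FormatError(f"invalid RPKM value for gene '{bad}'")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a miRNA x sample TSV (first column miRNA ids, header sample ids).

    Raises :class:`FormatError` for duplicate ids or any non-numeric /
    missing cell, naming the offending row and column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate miRNA id '{dup[0]}' in {path}")
    dup = raw.columns[raw.columns.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample id '{dup[0]}' in {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"non-numeric cell '{raw.iat[i, j]}' at miRNA '{raw.index[i]}', "
            f"sample '{raw.columns[j]}' in {path}"
        )
    return ExpressionMatrix(numeric)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="mirna_id")


def read_sample_metadata(path: str | Path) -> SampleMeta:
    """Read and validate a sample metadata TSV."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMeta(table)


def write_sample_metadata(meta: SampleMeta, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path,
                   universe_size: int | None = None) -> GeneSetCollection:
    """Parse a GMT file (name, description, members...).

    If ``universe_size`` is None it is derived as the size of the union of
    all members and the collection is flagged ``universe_derived``.
    Duplicate members within a set are dropped with a warning.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name = fields[0]
            members = [f for f in fields[2:] if f]
            if len(fields) < 3 or not members:
                raise FormatError(f"{path}:{lineno}: gene set line has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name '{name}'")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: set '{name}' contains duplicate members; "
                    "deduplicated", stacklevel=2)
            sets[name] = frozenset(unique)
    derived = universe_size is None
    if derived:
        universe_size = len(frozenset().union(*sets.values())) if sets else 1
    return GeneSetCollection(sets=sets, universe_size=int(universe_size),
                             universe_derived=derived)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column, headerless (mirna_id, gene_id) TSV; deduplicates."""
    pairs: dict[tuple[str, str], None] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(fields):
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            pairs[(fields[0], fields[1])] = None
    return TargetMap(pairs=tuple(pairs))


def write_target_map(targets: TargetMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m, g in targets.pairs:
            fh.write(f"{m}\t{g}\n")


def read_rpkm_table(path: str | Path) -> RpkmTable:
    """Read a gene_id/rpkm TSV (header row) into an RpkmTable."""
    table = pd.read_csv(path, sep="\t")
    if list(table.columns[:2]) != ["gene_id", "rpkm"]:
        raise FormatError(
            f"{path}: expected columns 'gene_id', 'rpkm'; got {list(table.columns)}"
        )
    return RpkmTable(values=table.set_index("gene_id")["rpkm"].astype(float))


def write_rpkm_table(rpkm: RpkmTable, path: str | Path) -> None:
    rpkm.values.rename("rpkm").to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# result tables and fixtures
# ---------------------------------------------------------------------------

def write_results_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any result table (diffexp / cessation / index / enrichment)."""
    records.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load a packaged fixture transcribed from the study's printed tables.

    ``"table2"``: the 34 miRNAs differing between smokers and nonsmokers
    (25 up, 9 down).  ``"table4"``: the 12 miRNAs still dysregulated in
    quitters vs nonsmokers (7 up, 5 down).  Columns: probeset_id,
    fold_change (signed, printed precision), p_value, direction.
    """
    if name not in _FIXTURES:
        raise FormatError(
            f"unknown fixture '{name}'; valid names: {list(_FIXTURES)}"
        )
    ref = resources.files("saemir").joinpath(f"data/{name}.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
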