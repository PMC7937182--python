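"""Binary species-by-trait matrices: reading, validation and queries.

States are presence (1), absence (0) and missing ("?"). Missing means
unobserved, not absent: missing species never enter presence sets (so they
cannot pull a trait origin rootward) and carry the full state set {0, 1}
in parsimony calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .tree import RootedTree

MISSING = "?"
_VALID_TOKENS = {"0": 0, "1": 1, MISSING: None}


class TraitMatrixError(ValueError):
    """Raised on malformed or inconsistent trait tables."""


class UnknownTraitError(TraitMatrixError):
    pass


class TraitMatrix:
    """Species x traits presence/absence table.

    Backed by a pandas DataFrame with nullable integer dtype: 1 = present,
    0 = absent, NA = missing. Species labels index the rows, trait names the
    columns; both must be unique, and every trait needs at least one
    non-missing observation.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TraitMatrixError(f"duplicate species labels: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TraitMatrixError(f"duplicate trait names: {dups}")
        df = df.astype("Int8")
        bad = df.stack().pipe(lambda s: s[~s.isin([0, 1])])
        if len(bad):
            sp, tr = bad.index[0]
            raise TraitMatrixError(
                f"invalid state {bad.iloc[0]} for species {sp!r}, trait {tr!r}"
            )
        all_missing = [t for t in df.columns if df[t].isna().all()]
        if all_missing:
            raise TraitMatrixError(
                f"traits with no non-missing observation: {all_missing}"
            )
        self._df = df

    # ------------------------------------------------------------- queries

    @property
    def species(self) -> list[str]:
        return list(self._df.index)

    @property
    def traits(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_species(self) -> int:
        return len(self._df.index)

    @property
    def n_traits(self) -> int:
        return len(self._df.columns)

    def to_frame(self) -> pd.DataFrame:
        """Copy of the underlying table (Int8 with NA for missing)."""
        return self._df.copy()

    def _col(self, trait: str) -> pd.Series:
        if trait not in self._df.columns:
            raise UnknownTraitError(f"unknown trait: {trait!r}")
        return self._df[trait]

    def presence_set(self, trait: str) -> frozenset[str]:
        """Species observed with state 1; missing entries are excluded."""
        col = self._col(trait)
        return frozenset(col.index[col == 1])

    def absence_set(self, trait: str) -> frozenset[str]:
        col = self._col(trait)
        return frozenset(col.index[col == 0])

    def missing_set(self, trait: str) -> frozenset[str]:
        col = self._col(trait)
        return frozenset(col.index[col.isna()])

    def states(self, trait: str) -> dict[str, Optional[int]]:
        """Per-species state for one trait (None encodes missing)."""
        col = self._col(trait)
        return {sp: (None if pd.isna(v) else int(v)) for sp, v in col.items()}

    def restrict(self, species: Iterable[str]) -> "TraitMatrix":
        """Sub-matrix on the given species (order preserved from the matrix)."""
        keep = set(species)
        missing = keep - set(self._df.index)
        if missing:
            raise TraitMatrixError(
                f"species not in matrix: {sorted(missing)}"
            )
        return TraitMatrix(self._df.loc[[s for s in self._df.index if s in keep]])

    # ----------------------------------------------------------------- I/O

    def write_tsv(self, path: str | Path, sep: str = "\t") -> None:
        out = self._df.astype(object)
        out = out.where(out.notna(), MISSING)
        out.index.name = "species"
        out.to_csv(path, sep=sep)


def read_trait_matrix(path: str | Path, sep: str = "\t") -> TraitMatrix:
    """Read a trait table: header row of trait names, first column species.

    Cells must be ``0``, ``1`` or ``?``. Errors name the offending row and
    column.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0,
                      keep_default_na=False)
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype="object")
    for trait in raw.columns:
        for sp, tok in raw[trait].items():
            tok = tok.strip()
            if tok not in _VALID_TOKENS:
                raise TraitMatrixError(
                    f"invalid cell {tok!r} at species {sp!r}, trait {trait!r}"
                )
            parsed.at[sp, trait] = _VALID_TOKENS[tok]
    return TraitMatrix(parsed)


@dataclass
class ReconcileReport:
    """What reconcile dropped from each side."""

    dropped_from_tree: list[str] = field(default_factory=list)
    dropped_from_matrix: list[str] = field(default_factory=list)


def reconcile(
    matrix: TraitMatrix,
    tree: RootedTree,
    prune: bool = False,
) -> tuple[TraitMatrix, RootedTree, ReconcileReport]:
    """Align a trait matrix and a tree on a common species set.

    By default the species sets must be identical. With ``prune=True`` both
    are restricted to the intersection and the report lists what was dropped.
    An empty intersection is always an error.
    """
    tree_sp = set(tree.leaf_labels)
    mat_sp = set(matrix.species)
    common = tree_sp & mat_sp
    if not common:
        raise TraitMatrixError("tree and matrix share no species")
    report = ReconcileReport(
        dropped_from_tree=sorted(tree_sp - common),
        dropped_from_matrix=sorted(mat_sp - common),
    )
    if tree_sp == mat_sp:
        return matrix, tree, report
    if not prune:
        raise TraitMatrixError(
            "tree and matrix species differ "
            f"(tree-only: {report.dropped_from_tree[:5]}, "
            f"matrix-only: {report.dropped_from_matrix[:5]}); "
            "pass prune=True to restrict to the intersection"
        )
    return matrix.restrict(common), tree.prune_to(common), report
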