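"""Small parsimony for binary characters and the CI/RI homoplasy indices.

The observed step count ``s`` is the minimum number of 0<->1 changes needed
to explain the leaf states on a fixed tree (Fitch parsimony, computed with
Hartigan's generalization so that polytomies are scored exactly). Missing
leaves carry the full state set {0, 1} and never force a change.

For a binary character, the minimum conceivable steps ``m`` is 1 when the
character varies (0 otherwise), and the maximum conceivable steps ``g`` is
the step count on a star topology, min(#0s, #1s) over non-missing leaves.
The consistency index CI = m/s measures homoplasy (CI = 1 means a single
change suffices) and the retention index RI = (g-s)/(g-m) measures how much
of the potential synapomorphy the tree retains. CI is undefined for an
invariant character (s = 0); RI is undefined when g = m (e.g. a trait
present in exactly one species).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .traits import TraitMatrix
from .tree import RootedTree

StateMap = Mapping[str, Optional[int]]


def parsimony_steps(tree: RootedTree, states: StateMap) -> int:
    """Minimum number of state changes on the tree (Hartigan/Fitch count).

    ``states`` maps every leaf label to 0, 1 or None (missing). Steps are
    counted on the rooted topology; the count is invariant to the root
    position. At each internal node the children vote for the states in
    their optimal sets; with K children supporting the best state, the node
    contributes (#children - K) changes.
    """
    leaf_missing = tree.leaf_labels - set(states)
    if leaf_missing:
        raise ValueError(
            f"no state for leaves: {sorted(leaf_missing)[:5]}"
        )
    if all(states[l] is None for l in tree.leaf_labels):
        raise ValueError("all leaf states missing")
    cost = 0
    sets: dict[str, int] = {}  # bitmask: 1 -> {0}, 2 -> {1}, 3 -> {0,1}
    for nid in tree.postorder():
        kids = tree.children(nid)
        if not kids:
            s = states[nid]
            sets[nid] = 3 if s is None else (1 << s)
        else:
            c0 = sum(1 for k in kids if sets[k] & 1)
            c1 = sum(1 for k in kids if sets[k] & 2)
            best = max(c0, c1)
            sets[nid] = (1 if c0 == best else 0) | (2 if c1 == best else 0)
            cost += len(kids) - best
    return cost


def min_steps(states: StateMap) -> int:
    """Minimum conceivable steps: 0 if invariant among observed leaves, else 1."""
    seen = {v for v in states.values() if v is not None}
    return 1 if len(seen) > 1 else 0


def max_steps(states: StateMap) -> int:
    """Maximum conceivable steps: the star-topology count min(#0s, #1s)."""
    n0 = sum(1 for v in states.values() if v == 0)
    n1 = sum(1 for v in states.values() if v == 1)
    return min(n0, n1)


@dataclass
class ParsimonyIndices:
    """Per-trait parsimony summary (m, s, g, CI, RI) and the medians.

    ``table`` has one row per trait with columns m, s, g, CI, RI; CI/RI are
    NaN where undefined. Medians are taken over traits where the index is
    defined; the excluded traits are listed.
    """

    table: pd.DataFrame
    median_ci: float
    median_ri: float
    ci_undefined: list[str]
    ri_undefined: list[str]

    def to_dict(self) -> dict:
        def clean(v: float) -> Optional[float]:
            return None if (isinstance(v, float) and math.isnan(v)) else v

        return {
            "per_trait": {
                t: {k: clean(v) for k, v in row.items()}
                for t, row in self.table.to_dict(orient="index").items()
            },
            "median_ci": clean(self.median_ci),
            "median_ri": clean(self.median_ri),
            "ci_undefined": list(self.ci_undefined),
            "ri_undefined": list(self.ri_undefined),
        }

    def write_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "trait"
        out.to_csv(path)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")


def indices(tree: RootedTree, matrix: TraitMatrix) -> ParsimonyIndices:
    """Compute (m, s, g, CI, RI) for every trait on a reconciled tree/matrix."""
    rows = {}
    ci_undef: list[str] = []
    ri_undef: list[str] = []
    for trait in matrix.traits:
        states = {sp: st for sp, st in matrix.states(trait).items()
                  if sp in tree.leaf_labels}
        s = parsimony_steps(tree, states)
        m = min_steps(states)
        g = max_steps(states)
        ci = m / s if s > 0 else float("nan")
        ri = (g - s) / (g - m) if g > m else float("nan")
        if s == 0:
            ci_undef.append(trait)
        if g <= m:
            ri_undef.append(trait)
        rows[trait] = {"m": m, "s": s, "g": g, "CI": ci, "RI": ri}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.loc[matrix.traits]
    def _median(col: pd.Series) -> float:
        return float(col.median()) if col.notna().any() else float("nan")

    return ParsimonyIndices(
        table=table,
        median_ci=_median(table["CI"]),
        median_ri=_median(table["RI"]),
        ci_undefined=ci_undef,
        ri_undefined=ri_undef,
    )
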