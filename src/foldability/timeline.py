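"""Phylogenomic timelines: node distances and molecular-clock ages.

The age of a taxon (a SCOP Family or Superfamily) is read off a rooted
phylogenomic tree: count the internal nodes on the path from the root (the
most ancient taxon sits at the base) to each leaf, rescale the counts to a
relative 0-to-1 node distance (nd), and map nd to geological age in Gya with
a molecular clock.  nd = 0 is the most ancient taxon (origin of proteins,
~3.8 Gya by default) and nd = 1 the most derived (present day).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimelineEntry",
    "ClockModel",
    "TreeFormatError",
    "read_tree",
    "node_distances",
    "clock_transform",
    "timeline_frame",
]


class TreeFormatError(ValueError):
    """Raised for files that do not hold a single rooted Newick tree."""


@dataclass
class TimelineEntry:
    """One leaf taxon on the evolutionary timeline."""

    taxon: str
    node_count: int
    nd: float
    age: float | None = None


@dataclass(frozen=True)
class ClockModel:
    """Monotone mapping from node distance to geological age (Gya).

    ``linear`` maps nd 0 -> origin_age and nd 1 -> 0.  ``piecewise_anchors``
    interpolates monotonically through user-supplied ``(nd, age)`` anchors,
    allowing calibration against externally dated events.
    """

    kind: str = "linear"
    origin_age: float = 3.8
    anchors: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "piecewise_anchors"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.origin_age <= 0:
            raise ValueError("origin_age must be positive")
        if self.kind == "piecewise_anchors":
            if not self.anchors or len(self.anchors) < 2:
                raise ValueError("piecewise clock needs >= 2 anchors")
            nds = [a[0] for a in self.anchors]
            ages = [a[1] for a in self.anchors]
            if sorted(nds) != list(nds) or len(set(nds)) != len(nds):
                raise ValueError("anchor nd values must be strictly increasing")
            if any(a2 > a1 for a1, a2 in zip(ages, ages[1:])):
                raise ValueError("anchor ages must be non-increasing in nd")

    def age_at(self, nd: np.ndarray | float) -> np.ndarray | float:
        nd = np.asarray(nd, dtype=float)
        if np.any((nd < 0) | (nd > 1)):
            raise ValueError("nd must lie in [0, 1]")
        if self.kind == "linear":
            age = self.origin_age * (1.0 - nd)
        else:
            xs = np.array([a[0] for a in self.anchors])
            ys = np.array([a[1] for a in self.anchors])
            age = np.interp(nd, xs, ys)
        return float(age) if age.ndim == 0 else age

    def fingerprint(self) -> str:
        if self.kind == "linear":
            return f"linear;origin={self.origin_age:g}"
        pts = ",".join(f"({a:g},{b:g})" for a, b in self.anchors)
        return f"piecewise;anchors={pts}"


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a single rooted tree from a Newick file; polytomies allowed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeFormatError(f"{path.name}: not valid Newick ({exc})") from exc
    if len(trees) != 1:
        raise TreeFormatError(f"{path.name}: expected 1 tree, found {len(trees)}")
    tree = trees[0]
    tree.is_rooted = True
    if len(tree.seed_node.leaf_nodes()) < 1:
        raise TreeFormatError(f"{path.name}: empty tree")
    return tree


def node_distances(tree: dendropy.Tree) -> list[TimelineEntry]:
    """Per-leaf internal-node counts, normalised to nd in [0, 1].

    The count is the number of internal nodes on the root-to-leaf path, root
    inclusive and leaf exclusive (a leaf hanging off the root has count 1).
    nd rescales counts so the minimum maps to 0 (most ancient) and the
    maximum to 1 (most derived); if every leaf has the same count the tree
    carries no timeline signal, nd is set to 0 everywhere and a degeneracy
    warning is emitted.
    """
    leaves = tree.seed_node.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    entries = []
    for leaf in leaves:
        count = sum(1 for _ in leaf.ancestor_iter(inclusive=False))
        label = leaf.taxon.label if leaf.taxon is not None else ""
        entries.append(TimelineEntry(taxon=label, node_count=count, nd=0.0))
    counts = np.array([e.node_count for e in entries], dtype=float)
    cmin, cmax = counts.min(), counts.max()
    if cmax == cmin:
        warnings.warn(
            "all leaves have equal node counts; node distances are degenerate",
            stacklevel=2,
        )
        nd = np.zeros_like(counts)
    else:
        nd = (counts - cmin) / (cmax - cmin)
    for e, v in zip(entries, nd):
        e.nd = float(v)
    return entries


def clock_transform(
    entries: list[TimelineEntry], clock: ClockModel | None = None
) -> list[TimelineEntry]:
    """Fill geological ages from node distances using the clock model."""
    clock = clock or ClockModel()
    for e in entries:
        e.age = float(clock.age_at(e.nd))
    return entries


def timeline_frame(entries: list[TimelineEntry], clock: ClockModel | None = None) -> pd.DataFrame:
    """Tabulate entries as a (taxon, node_count, nd, age) DataFrame."""
    df = pd.DataFrame(
        {
            "taxon": [e.taxon for e in entries],
            "node_count": [e.node_count for e in entries],
            "nd": [e.nd for e in entries],
            "age": [e.age for e in entries],
        }
    )
    if clock is not None:
        df.attrs["clock"] = clock.fingerprint()
    return df
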