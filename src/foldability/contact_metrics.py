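"""Contact maps, contact order and contact-network tightness.

The folding-speed proxy used throughout this package is the size-modified
contact order (SMCO)::

    relCO = (1 / (L * N_c)) * sum_{(i,j)} (j - i)
    SMCO  = relCO * L**alpha

where ``L`` is the chain length in residues, ``N_c`` the number of native
contacts, and ``j - i`` the sequence separation of contact ``(i, j)``.
Higher SMCO means more non-local contacts per residue and, empirically,
slower folding.  Tightness is the mean shortest-path length in the residue
contact network (backbone adjacency included), a complementary measure of
native-state connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Structure

__all__ = [
    "ContactParams",
    "ContactMap",
    "UndefinedMetricError",
    "build_contact_map",
    "relative_contact_order",
    "smco",
    "tightness",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the input (e.g. no contacts)."""


@dataclass(frozen=True)
class ContactParams:
    """Parameters of the residue contact definition.

    cutoff
        Maximum inter-residue atom distance in Å for a native contact.
    min_separation
        Minimum sequence separation ``|i - j|`` counted as a contact;
        backbone neighbours are never contacts with the default of 2.
    atom_mode
        ``heavy_atoms`` measures the minimum distance over all non-hydrogen
        atom pairs; ``c_alpha`` uses Cα positions only.
    alpha
        Size-correction exponent of the SMCO; 0 recovers the plain relative
        contact order, 1 the mean contact separation.
    """

    cutoff: float = 6.0
    min_separation: int = 2
    atom_mode: str = "heavy_atoms"
    alpha: float = 0.7

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        if self.atom_mode not in ("heavy_atoms", "c_alpha"):
            raise ValueError(f"unknown atom_mode: {self.atom_mode!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    def fingerprint(self) -> str:
        return (
            f"cutoff={self.cutoff:g};min_sep={self.min_separation};"
            f"atoms={self.atom_mode};alpha={self.alpha:g}"
        )


@dataclass(frozen=True)
class ContactMap:
    """A set of native contacts ``(i, j)`` with ``1 <= i < j <= L``."""

    L: int
    contacts: frozenset = field(default_factory=frozenset)
    params: ContactParams = ContactParams()

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        for i, j in self.contacts:
            if not (1 <= i < j <= self.L):
                raise ValueError(f"contact ({i},{j}) out of range for L={self.L}")
            if j - i < self.params.min_separation:
                raise ValueError(
                    f"contact ({i},{j}) violates min_separation="
                    f"{self.params.min_separation}"
                )

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def separations(self) -> np.ndarray:
        """Sequence separations ``j - i`` of all contacts (unordered)."""
        return np.array([j - i for i, j in self.contacts], dtype=int)


def _residue_coords(s: Structure, atom_mode: str) -> list[np.ndarray]:
    coords = []
    for res in s.residues:
        if atom_mode == "c_alpha":
            ca = [a.position for a in res.atoms if a.name == "CA"]
            if not ca:
                raise UndefinedMetricError(
                    f"residue {res.index} of {s.domain_id} has no CA atom"
                )
            coords.append(np.asarray(ca[:1], dtype=float))
        else:
            heavy = [a.position for a in res.atoms if a.element not in ("H", "D")]
            if not heavy:
                raise UndefinedMetricError(
                    f"residue {res.index} of {s.domain_id} has no heavy atoms"
                )
            coords.append(np.asarray(heavy, dtype=float))
    return coords


def build_contact_map(s: Structure, params: ContactParams | None = None) -> ContactMap:
    """Compute the native contact map of a domain structure.

    A pair ``(i, j)`` is a contact iff ``j - i >= min_separation`` and the
    minimum inter-residue atom distance (per ``atom_mode``) is at most
    ``cutoff`` Å.
    """
    params = params or ContactParams()
    L = len(s.residues)
    if L < 1:
        raise UndefinedMetricError("empty structure")
    coords = _residue_coords(s, params.atom_mode)

    # flat atom array + residue labels; single cdist, then min-reduce per pair
    flat = np.concatenate(coords)
    labels = np.concatenate(
        [np.full(len(c), i + 1, dtype=int) for i, c in enumerate(coords)]
    )
    dmat = cdist(flat, flat)
    contacts = set()
    for i in range(1, L + 1):
        rows = labels == i
        for j in range(i + params.min_separation, L + 1):
            if dmat[np.ix_(rows, labels == j)].min() <= params.cutoff:
                contacts.add((i, j))
    return ContactMap(L=L, contacts=frozenset(contacts), params=params)


def relative_contact_order(cm: ContactMap) -> float:
    """Mean sequence separation of contacts, normalised by chain length."""
    if cm.n_contacts == 0:
        raise UndefinedMetricError("contact map has no contacts; relCO undefined")
    return float(cm.separations.sum()) / (cm.L * cm.n_contacts)


def smco(cm: ContactMap) -> float:
    """Size-modified contact order: ``relCO * L**alpha``."""
    return relative_contact_order(cm) * cm.L ** cm.params.alpha


def contact_graph(cm: ContactMap) -> nx.Graph:
    """Residue network: backbone edges ``(i, i+1)`` plus contact edges."""
    g = nx.path_graph(range(1, cm.L + 1))
    g.add_edges_from(cm.contacts)
    return g


def tightness(cm: ContactMap) -> float:
    """Mean unweighted shortest-path length over all residue pairs.

    Backbone edges guarantee connectivity, so the mean is always defined
    for ``L >= 2``.
    """
    if cm.L < 2:
        raise UndefinedMetricError("tightness undefined for a single residue")
    return nx.average_shortest_path_length(contact_graph(cm))
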