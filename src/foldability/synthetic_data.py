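"""Synthetic structures, contact maps, trees and domain catalogs.

Every pipeline stage can be exercised without downloading a single real
structure: this module fabricates inputs with *known* ground truth.

* :func:`gen_catalog` plants a piecewise-linear SMCO trend over evolutionary
  time at the family level — a decline from the origin of proteins to the
  "big bang" of domain rearrangements ~1.5 Gya, then a rise — together with
  epoch-dependent chain-length distributions (older domains peak near 150
  aa, younger near 100 aa) and optional per-class slope overrides.
* :func:`gen_ideal_structure` builds idealised Cα traces (α-helix, β-hairpin,
  random coil) whose contact geometry embodies the all-α vs all-β contrast:
  helices only make short-range contacts, hairpins pair sequence-distant
  residues.
* :func:`gen_contact_map` samples abstract contact maps under controllable
  separation laws.
* :func:`gen_tree` emits rooted Newick trees with controllable leaf-depth
  spread for timeline tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_metrics import ContactMap, ContactParams
from .structure_io import Atom, DomainCatalog, Residue, Structure

__all__ = [
    "SyntheticSpec",
    "gen_catalog",
    "gen_ideal_structure",
    "gen_contact_map",
    "gen_tree",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of a synthetic domain catalog.

    Slopes are SMCO per Gya of *forward* time (time elapsed since
    ``origin_age``), so a negative ``slope_early`` means SMCO falls from the
    origin towards the breakpoint — folding speeds up — and a positive
    ``slope_late`` means it rises again afterwards.  Defaults plant the
    bimodal pattern with a breakpoint at 1.5 Gya, family noise of 0.5 SMCO
    units, and chain lengths peaking near 150 aa before the breakpoint and
    near 100 aa after it.
    """

    n_families: int = 3000
    origin_age: float = 3.8
    breakpoint: float = 1.5
    slope_early: float = -0.5
    slope_late: float = 0.3
    smco_at_origin: float = 3.5
    noise_sd: float = 0.5
    class_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    class_slopes: dict = field(default_factory=dict)  # letter -> (early, late)
    domains_per_family: int = 1
    within_family_sd: float = 0.0
    length_pre_mode: float = 150.0
    length_pre_sd: float = 40.0
    length_post_mode: float = 100.0
    length_post_sd: float = 30.0
    length_smco_coupling: float = 0.0  # SMCO units per 100 aa above 125
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0 < self.breakpoint < self.origin_age:
            raise ValueError("breakpoint must lie in (0, origin_age)")
        if self.noise_sd < 0 or self.within_family_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or min(self.class_mix) < 0:
            raise ValueError("class_mix must be a probability vector over a,b,c,d")
        if self.domains_per_family < 1:
            raise ValueError("domains_per_family must be >= 1")


_SMCO_FLOOR = 0.1
_MIN_LENGTH = 40


def _planted_mean(age: np.ndarray, spec: SyntheticSpec, letter: str) -> np.ndarray:
    """Family mean SMCO on the planted piecewise line at the given ages."""
    early, late = spec.class_slopes.get(letter, (spec.slope_early, spec.slope_late))
    t = spec.origin_age - np.asarray(age, dtype=float)  # forward time
    t_break = spec.origin_age - spec.breakpoint
    return (
        spec.smco_at_origin
        + early * np.minimum(t, t_break)
        + late * np.maximum(t - t_break, 0.0)
    )


def gen_catalog(spec: SyntheticSpec | None = None) -> tuple[DomainCatalog, dict]:
    """Generate a domain catalog with a planted age-SMCO trend.

    Family ages are uniform on (0, origin_age); each family's mean SMCO is
    the planted piecewise line at its age plus Gaussian noise, floored at
    0.1.  Chain lengths are drawn from the epoch-appropriate normal mode
    (older epoch ~150 aa, younger ~100 aa) truncated at 40 aa.  Tightness is
    generated as an affine companion of SMCO so that its trend parallels the
    planted one.  Returns the catalog and a planted-truth record for
    parameter-recovery tests.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    letters = rng.choice(list("abcd"), size=spec.n_families, p=list(spec.class_mix))
    ages = rng.uniform(0.0, spec.origin_age, size=spec.n_families)

    rows = []
    for i in range(spec.n_families):
        letter = str(letters[i])
        age = float(ages[i])
        mu = float(_planted_mean(age, spec, letter))
        fam_smco = max(mu + rng.normal(0.0, spec.noise_sd), _SMCO_FLOOR)
        family = f"{letter}.{i + 1}.1.1"
        if age >= spec.breakpoint:
            mode, sd = spec.length_pre_mode, spec.length_pre_sd
        else:
            mode, sd = spec.length_post_mode, spec.length_post_sd
        for k in range(spec.domains_per_family):
            length = int(max(round(rng.normal(mode, sd)), _MIN_LENGTH))
            smco = fam_smco
            if spec.domains_per_family > 1 or spec.within_family_sd > 0:
                smco = max(fam_smco + rng.normal(0.0, spec.within_family_sd), _SMCO_FLOOR)
            smco = max(
                smco + spec.length_smco_coupling * (length - 125.0) / 100.0, _SMCO_FLOOR
            )
            tightness = max(1.5 + 0.4 * smco + rng.normal(0.0, 0.1), 1.0)
            rows.append(
                {
                    "domain_id": f"d{i + 1:05d}{chr(ord('a') + k)}",
                    "sccs": family,
                    "class_letter": letter,
                    "family": family,
                    "superfamily": f"{letter}.{i + 1}.1",
                    "length": length,
                    "smco": smco,
                    "tightness": tightness,
                    "age": age,
                }
            )
    catalog = DomainCatalog.from_frame(pd.DataFrame(rows))
    truth = {
        "slope_early": spec.slope_early,
        "slope_late": spec.slope_late,
        "class_slopes": dict(spec.class_slopes),
        "breakpoint": spec.breakpoint,
        "origin_age": spec.origin_age,
        "smco_at_origin": spec.smco_at_origin,
        "noise_sd": spec.noise_sd,
        "slope_axis": "forward_time",  # SMCO per Gya elapsed since origin
        "seed": spec.seed,
    }
    return catalog, truth


# ---------------------------------------------------------------------------
# Ideal structures


def _ca_structure(domain_id: str, coords: np.ndarray) -> Structure:
    residues = tuple(
        Residue(
            index=i + 1,
            name="ALA",
            atoms=(Atom(name="CA", element="C", position=tuple(map(float, xyz))),),
        )
        for i, xyz in enumerate(coords)
    )
    return Structure(domain_id=domain_id, residues=residues)


def _helix_coords(n: int) -> np.ndarray:
    # ideal alpha-helix: radius 2.3 A, rise 1.5 A/residue, 100 deg/residue;
    # consecutive Calpha chord ~3.8 A by construction
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _hairpin_coords(n: int) -> np.ndarray:
    # two antiparallel strands (3.5 A/residue rise, 4.8 A apart) joined by a
    # 2-residue turn; a +-0.74 A zigzag keeps consecutive Calpha ~3.8 A
    m = (n - 2) // 2  # strand 1 length; strand 2 takes the remainder
    zig = 0.74
    coords = []
    for i in range(m):
        coords.append((3.5 * i, 0.0, zig * (-1) ** i))
    # turn apex 3.70 A beyond the strand ends keeps all three turn gaps at
    # ~3.8 A for either zigzag phase
    xe = 3.5 * (m - 1)
    coords.append((xe + 3.70, 0.5, 0.0))
    coords.append((xe + 3.70, 4.3, 0.0))
    for k in range(n - 2 - m):
        coords.append((xe - 3.5 * k, 4.8, zig * (-1) ** k))
    return np.asarray(coords)


def _coil_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    # self-avoiding random walk, 3.8 A steps, 3.5 A exclusion
    coords = [np.zeros(3)]
    attempts = 0
    while len(coords) < n:
        v = rng.normal(size=3)
        step = coords[-1] + 3.8 * v / np.linalg.norm(v)
        prior = np.asarray(coords[:-1])
        if prior.size and np.min(np.linalg.norm(prior - step, axis=1)) < 3.5:
            attempts += 1
            if attempts > 1000:  # back out of a dead end
                coords.pop()
                attempts = 0
            continue
        coords.append(step)
        attempts = 0
    return np.asarray(coords)


def gen_ideal_structure(kind: str, n_residues: int, seed: int | None = None) -> Structure:
    """Build an idealised Cα-only structure of the requested kind.

    ``helix`` and ``hairpin`` are deterministic geometric constructions;
    ``coil`` is a seeded self-avoiding random walk with 3.8 Å steps.
    """
    if kind == "helix":
        if n_residues < 4:
            raise ValueError("helix needs >= 4 residues")
        coords = _helix_coords(n_residues)
    elif kind == "hairpin":
        if n_residues < 8:
            raise ValueError("hairpin needs >= 8 residues")
        coords = _hairpin_coords(n_residues)
    elif kind == "coil":
        if n_residues < 4:
            raise ValueError("coil needs >= 4 residues")
        coords = _coil_coords(n_residues, np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown structure kind {kind!r}")
    return _ca_structure(f"{kind}{n_residues}", coords)


# ---------------------------------------------------------------------------
# Abstract contact maps


def gen_contact_map(
    L: int,
    n_contacts: int,
    separation_law: str = "uniform",
    seed: int = 0,
    params: ContactParams | None = None,
) -> ContactMap:
    """Sample a contact map with a chosen sequence-separation bias.

    ``local`` favours short-range pairs (weight ΔL⁻²), ``antilocal``
    long-range ones (weight ΔL²), ``uniform`` neither.  Contacts are drawn
    without replacement among pairs with separation >= the params'
    ``min_separation``.
    """
    params = params or ContactParams()
    pairs = [
        (i, j)
        for i in range(1, L + 1)
        for j in range(i + params.min_separation, L + 1)
    ]
    if n_contacts > len(pairs):
        raise ValueError(f"requested {n_contacts} contacts, only {len(pairs)} eligible pairs")
    seps = np.array([j - i for i, j in pairs], dtype=float)
    if separation_law == "local":
        w = seps**-2.0
    elif separation_law == "antilocal":
        w = seps**2.0
    elif separation_law == "uniform":
        w = np.ones_like(seps)
    else:
        raise ValueError(f"unknown separation law {separation_law!r}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n_contacts, replace=False, p=w / w.sum())
    return ContactMap(L=L, contacts=frozenset(pairs[k] for k in idx), params=params)


# ---------------------------------------------------------------------------
# Trees


class _Tok:
    OPEN, CLOSE, COMMA = object(), object(), object()


def _newick(node) -> str:
    # iterative serialisation: deep caterpillars exceed the recursion limit
    parts: list[str] = []
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur is _Tok.OPEN:
            parts.append("(")
        elif cur is _Tok.CLOSE:
            parts.append(")")
        elif cur is _Tok.COMMA:
            parts.append(",")
        elif isinstance(cur, str):
            parts.append(cur)
        else:
            stack.append(_Tok.CLOSE)
            for i, child in enumerate(reversed(cur)):
                stack.append(child)
                if i < len(cur) - 1:
                    stack.append(_Tok.COMMA)
            stack.append(_Tok.OPEN)
    return "".join(parts)


def gen_tree(n_leaves: int, shape: str = "caterpillar", seed: int = 0) -> str:
    """Emit a rooted Newick tree with the requested leaf-depth profile.

    ``caterpillar`` gives the maximal spread of root-to-leaf node counts
    (1, 2, ..., n-1, n-1); ``balanced`` splits leaves as evenly as possible
    (all counts equal when n is a power of two — the degenerate timeline);
    ``yule`` grows the tree by splitting a uniformly chosen leaf.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    labels = [f"T{i + 1}" for i in range(n_leaves)]
    if shape == "caterpillar":
        node = [labels[-2], labels[-1]]
        for lab in reversed(labels[:-2]):
            node = [lab, node]
        tree = node
    elif shape == "balanced":

        def split(items):
            if len(items) == 1:
                return items[0]
            mid = len(items) // 2
            return [split(items[:mid]), split(items[mid:])]

        tree = split(labels)
        if isinstance(tree, str):  # pragma: no cover - n_leaves >= 2
            tree = [tree]
    elif shape == "yule":
        rng = np.random.default_rng(seed)
        tree = [labels[0], labels[1]]
        # registry of (parent list, index) per leaf
        leaves = [(tree, 0), (tree, 1)]
        for lab in labels[2:]:
            k = int(rng.integers(len(leaves)))
            parent, idx = leaves.pop(k)
            old = parent[idx]
            new_node = [old, lab]
            parent[idx] = new_node
            leaves.append((new_node, 0))
            leaves.append((new_node, 1))
        # tree already rooted at the initial split
    else:
        raise ValueError(f"unknown tree shape {shape!r}")
    return _newick(tree) + ";"


def write_tree(newick: str, path) -> None:
    """Write Newick text to a file (with trailing newline)."""
    with io.open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")
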