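# foldability

Tools for asking whether evolution optimised how fast proteins fold.

Protein domains differ enormously in folding time — from microseconds to
hours — and a large part of that spread is explained by the topology of the
native state: structures dominated by short-range contacts fold faster than
structures held together by sequence-distant contacts. This package computes
structure-based folding-speed proxies for protein domains, places domain
families on an evolutionary timeline derived from a rooted phylogenomic
tree, and tests how the proxies changed over ~3.8 billion years of protein
history. It is written for structural bioinformaticians and molecular
evolutionists who want a reproducible, fully testable version of this
analysis chain that also runs on synthetic data with known ground truth.

## The quantities

For a domain of `L` residues with native contact set `C` (`N_c = |C|`,
contacts are residue pairs `(i, j)` whose minimum heavy-atom distance is
≤ 6 Å and whose sequence separation `j − i` is ≥ 2):

* **Relative contact order**
  `relCO = (1 / (L · N_c)) · Σ_{(i,j)∈C} (j − i)` — the mean sequence
  separation of contacts, normalised by chain length.
* **Size-modified contact order** `SMCO = relCO · L^α` (default `α = 0.7`) —
  rescaling by a power of the length markedly improves the correlation with
  experimental folding rates; SMCO is the folding-time proxy used
  throughout (higher SMCO ⇒ slower folding).
* **Tightness** — the mean shortest-path length over all residue pairs in
  the contact network (backbone edges included), a complementary
  connectivity proxy.

The **timeline** comes from a rooted phylogenomic tree whose leaves are
SCOP families (or superfamilies): the number of internal nodes on each
root-to-leaf path is rescaled to a node distance `nd ∈ [0, 1]` (0 = most
ancient) and mapped to a geological age in Gya by a molecular clock
(linearly from 3.8 Gya by default, or through user-supplied anchors).

The **trend statistics** are LOESS (degree 2, span 0.7) with an F-test
against the flat model, two independent OLS segments split at the 1.5 Gya
"big bang" of domain rearrangements, per-chain-length endpoint-change
categories (positive / negative / insignificant) aggregated by domain
abundance with bootstrap SEMs, per-fold-class analyses with Wilcoxon
rank-sum comparisons, and a screen for families whose mean SMCO falls below
the range of known ultra-fast ("downhill") folders.

## Worked example

```python
from foldability import (gen_ideal_structure, build_contact_map, smco,
                         relative_contact_order, tightness,
                         SyntheticSpec, TrendConfig, RunConfig, run_pipeline)

for kind in ("helix", "hairpin"):
    cm = build_contact_map(gen_ideal_structure(kind, 20))
    print(kind, cm.L, cm.n_contacts, relative_contact_order(cm), smco(cm))

cfg = RunConfig(synthetic=SyntheticSpec(n_families=3000, seed=1),
                trend=TrendConfig(seed=1), out_dir="out")
report = run_pipeline(cfg)
```

prints (abbreviated):

```
helix    L=20 N_c=35 relCO=0.124 SMCO=1.012 tightness=2.689
hairpin  L=20 N_c=11 relCO=0.468 SMCO=3.812 tightness=3.905
early slope -0.546 SMCO/Gyr (p=6.0e-178)
late  slope +0.281 SMCO/Gyr (p=8.2e-16)
LOESS endpoint change: early -1.327, late +0.535
early-epoch category shares: {positive: 0.7, negative: 35.3, insignificant: 64.0}
```

The ideal α-helix only forms short-range contacts (relCO 0.124) while the
β-hairpin pairs sequence-distant residues (relCO 0.468), reproducing the
all-α < all-β folding-speed ordering. The synthetic catalog plants a
piecewise-linear SMCO trend (slopes −0.5 and +0.3 SMCO per Gyr of elapsed
time, breakpoint 1.5 Gya, family noise 0.5); the pipeline recovers both
slopes, the sign flip of the LOESS endpoint change at the breakpoint, and a
negative-dominated early epoch in the binned length analysis. `out/`
contains the catalog, family means, timeline, per-bin tables, the
fast-folder screen and `report.json` with a config fingerprint, so a rerun
with the same configuration is byte-identical.

The same analyses are available from the shell:

```sh
foldability smco structures/ --out metrics.tsv
foldability timeline tree.nwk --origin-age 3.8
foldability simulate --n-families 3000 --seed 1 --out-dir sim
foldability trends sim/catalog.tsv --seed 1 --out report.json
foldability run --synthetic --n-families 3000 --seed 1 --out-dir out
```

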