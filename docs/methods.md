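# Methods

## Contact definition and folding-speed proxies

A native contact is a residue pair `(i, j)` with sequence separation
`j − i ≥ min_separation` whose minimum inter-residue atom distance is at
most `cutoff`. Defaults: 6.0 Å over heavy atoms (hydrogens excluded) with
`min_separation = 2`, following the contact-order literature; both are
configurable (`ContactParams`) and every output table carries a parameter
fingerprint, because published analyses of this kind rarely state these
choices and conclusions can depend on them. A Cα-only mode exists for
reduced models. The sequence separation `ΔL_ij` is defined as `j − i`
(residues strictly between the pair plus one); the alternative "residues
between" convention differs by a constant 1 and does not change any
ordering, but the choice is fixed and recorded here.

Relative contact order is `Σ ΔL_ij / (L · N_c)`; the size-modified contact
order multiplies it by `L^α`. The exponent defaults to `α = 0.7`, the value
for which the size correction was reported to maximise the correlation with
experimental folding rates (r ≈ 0.74); `α = 0` recovers plain relative
contact order and `α = 1` the mean contact separation. SMCO is a folding
*time* proxy: larger values mean slower folding.

Tightness is the mean unweighted shortest-path length over all residue
pairs in the graph whose nodes are residues and whose edges are the
contacts plus the backbone adjacencies `(i, i+1)`. Backbone edges are
included because chain neighbours are in physical contact and they keep the
graph connected, so the mean path length is always defined. Computed with
networkx.

Structures are read from PDB files (first model, HETATM ignored,
highest-occupancy altloc, hydrogens kept but flagged). Residues are
renumbered 1..L in file order and chains are compacted across missing
residues: the contact-order sum counts residues along the chain, so author
numbering and numbering gaps are irrelevant to it, and only resolved
residues can contribute contacts. Chain filtering keeps X-ray chains with
exactly one SCOP family, at most one CATH domain, and no unassigned segment
of 30+ residues; resolution (≤ 3.0 Å) and length (40–10,000) bounds are
applied as annotation-level pre-filters. Sequence-identity culling is out
of scope (it requires an external clustering service) and is assumed done
upstream.

## Timeline construction

Domain ages come from a rooted phylogenomic tree whose leaves are SCOP
families or superfamilies. For each leaf the number of internal nodes on
the root-to-leaf path is counted, root inclusive and leaf exclusive;
polytomies count one node like binary splits. Counts are normalised to
`nd = (c − c_min) / (c_max − c_min)`, so the most ancient taxon has nd 0
and the most derived nd 1. Endpoint inclusion and the exact normalisation
only shift and rescale nd — leaf *ranking*, which carries the signal, is
invariant — so the simplest convention is used and stated. If every leaf
has the same count (perfectly balanced trees) the timeline is degenerate;
nd is set to 0 everywhere and a warning is raised.

The molecular clock maps nd to geological age. The default is linear:
`age = origin_age · (1 − nd)` with `origin_age = 3.8` Gya, the approximate
age of the oldest proteins. Real clock calibrations are piecewise;
`ClockModel(kind="piecewise_anchors")` interpolates monotonically through
user-supplied `(nd, age)` anchors for that purpose. Any monotone clock
preserves the order statistics all downstream analyses rely on.

## Trend statistics

**LOESS.** Cleveland's locally weighted polynomial regression, degree 2 and
span 0.7 by default. At each evaluation point the `q = floor(span · n)`
nearest x-values are tricube-weighted by distance scaled to the q-th
nearest distance, and a weighted polynomial is fitted; ties in x share
neighbourhoods, and ≥ q exact replicates receive uniform weights. The
smoother is linear in y, so its hat matrix gives pointwise standard errors
(`sigma² · ‖l_i‖²` with `sigma² = RSS / tr[(I−L)ᵀ(I−L)]`) for the 95% band.
The implementation was validated to < 1e-6 against an independent reference
implementation of the same algorithm on a frozen dataset
(`tests/data/loess_reference.tsv`).

**Trend F-test.** The fitted trend is tested against the intercept-only
model with an approximate F-test using trace-based effective degrees of
freedom (the two-delta form; above n = 3200, where the required matrix
products become expensive, the one-delta approximation is used — the two
agree to first order at such sizes). Simulated type-I error at n = 100 is
0.05 within Monte-Carlo noise (asserted in the test suite). For the
`linear` method the classical OLS slope test is used, and F equals the
squared slope t-statistic exactly.

**Segmented regression.** Two *independent* OLS lines on either side of a
fixed breakpoint, no continuity constraint. The breakpoint defaults to
1.5 Gya, the "big bang" of domain-combination rearrangements where the
trend reverses. Segments are fitted on the forward-time axis
`t = origin_age − age`, so slopes read as SMCO per Gyr elapsed: negative =
folding speeding up. A side with fewer than 3 points is reported absent.

**Endpoint change (ΔSMCO).** For any fitted trend over an epoch,
`delta = fitted(youngest age) − fitted(oldest age)`. Negative delta means
the trait fell over the epoch.

**Binned length analysis.** Chain length and SMCO are intrinsically
correlated, so trends are also tested within exact chain-length bins to
remove the size effect. Sparse lengths are pooled with ascending
neighbours until each bin holds at least `min_bin_n = 10` domains (a
pooling rule of this package, recorded in the bin labels). Each bin's
SMCO-vs-age trend (LOESS by default; a global quadratic via
`bin_method="poly"`) yields a delta and a p-value; bins significant at
`alpha_sig = 0.05` are categorised by the sign of delta, the rest are
insignificant, and category shares are aggregated weighted by domain
abundance. P-values are raw per bin; a Benjamini–Hochberg option exists
but is off by default because the reported shares are defined on raw
significance.

**Resampling SEMs.** Reported percentages get standard errors from
resampling domains: bootstrap with replacement at full size by default
(subsampling selectable). The SEM is the standard deviation (ddof 1) of
the statistic across replicates — the spread of the replicate estimates
themselves, not divided again by √n_replicates. Replicates in which the
analysis fails are dropped and counted. All draws come from a single
seeded generator.

**Fold-class analysis.** The binned analysis is repeated per SCOP class
(all-α, all-β, α/β, α+β) and epoch; classes with fewer than 30 domains are
excluded and counted. Class SMCO distributions are compared pairwise with
two-sided Wilcoxon rank-sum tests (exact for small samples).

**Fast-folder screen.** Families whose mean SMCO is ≤ 1.5 — below the
values of the five SCOP families containing experimentally identified
downhill folders (a.35.1.2, a.4.1.1, a.8.1.2, b.72.1.1, d.100.1.1), which
are flagged in the output — are returned with their ages and their
fraction of all families.

## Synthetic data

The generator fabricates every input with known ground truth.

`gen_catalog` plants the trend at the family level (the unit the timeline
regressions use): family ages are uniform on (0, 3.8) Gya; family mean
SMCO follows a piecewise-linear function of *forward* time with slopes
−0.5 (origin → breakpoint) and +0.3 (breakpoint → present) SMCO/Gyr by
default, Gaussian noise of 0.5 SMCO units, and a floor at 0.1. Slopes are
defined on the forward-time axis so that "negative slope" always means
folding speeding up, matching how the endpoint deltas are read. Chain
lengths are drawn per epoch (normal modes 150 aa before and 100 aa after
the breakpoint, truncated at 40 aa), reproducing the size shift across the
big bang. Class-specific slope overrides create class divergence; an
optional positive length–SMCO coupling reproduces the size confound the
binned analysis is designed to remove. Tightness is generated as an affine
companion of SMCO so the two proxies trend in parallel.

`gen_ideal_structure` builds Cα traces: an ideal α-helix (radius 2.3 Å,
rise 1.5 Å, 100°/residue — chord ≈ 3.8 Å), a β-hairpin (two antiparallel
strands 4.8 Å apart, 3.5 Å/residue rise with a ±0.74 Å zigzag and a
2-residue turn, all consecutive gaps ≈ 3.8 Å) and a self-avoiding random
coil (3.8 Å steps, 3.5 Å exclusion). Helices make only local contacts,
hairpins pair residue i with ≈ n+1−i, so the all-α < all-β SMCO ordering
is built into the geometry and verified by tests, not assumed.

`gen_contact_map` samples abstract maps under local (ΔL⁻²), uniform or
antilocal (ΔL²) separation laws; `gen_tree` emits caterpillar (maximal
node-count spread), balanced (degenerate) and Yule trees. All generators
are bitwise reproducible given their seed.

What the synthetic data does **not** emulate: real contact-map geometry
beyond the ideal fixtures (no side chains, no packing), phylogenetic
autocorrelation between related families (ages are i.i.d.), measurement
error in structures, database redundancy, and the empirical SMCO
distribution of SCOP. Passing the recovery tests therefore demonstrates
that the statistical machinery detects the planted signal at realistic
sizes and noise — not that the historical trend in the real protein
catalog has any particular value.

## Problem sizes and numerical choices

The test suite and acceptance script use 3,000 families for trend/slope
recovery, 20,000 domains for the binned category shares and class
divergence (10,000 per class), 100 replicates for resampling and null
Wilcoxon calibration, and 400–1,000 simulations for F-test calibration —
sizes at which the planted effects are comfortably detectable and the
whole suite runs in well under a minute per analysis. Degenerate inputs
are handled explicitly: constant y gives p = 1 and delta 0; near-perfect
fits (RSS ≤ 1e-12 · TSS) give p = 0 rather than a 0/0; empty epochs and
all-identical x raise errors; contact-free maps raise an undefined-metric
error and are meant to be excluded and logged upstream.

## Known limitations

* The contact definition and the SMCO exponent are literature defaults,
  not fitted; sensitivity to them should be explored via `ContactParams`.
* The linear clock is a stand-in for real, nonlinear clock calibrations;
  use anchors for fidelity. Only rank-based conclusions are clock-robust.
* The LOESS F-test is approximate (trace-based degrees of freedom); its
  calibration is verified by simulation at the sizes used here.
* No folding-rate prediction in physical units, no multi-domain
  cooperative-folding model, no tree inference, and no mmCIF input.
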