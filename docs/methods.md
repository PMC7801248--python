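# Methods

This note documents the models implemented in `skullcap`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## 1. Sequence divergence model (simulator)

All planted divergence follows a Jukes–Cantor (JC) clock. A lineage
evolving for `t` years at synonymous rate `μ` (per site per year) yields a
per-site difference probability against its ancestor of
`p = ¾(1 − e^(−4μt/3))`; a *pair* split `t` years ago therefore differs
with `p = ¾(1 − e^(−8μt/3))`, the JC expectation for `K = 2μt`.
Nonsynonymous sites accrue changes at `ω·μ` (ω ∈ [0, 1] is the acceptance
ratio standing in for purifying selection; default 0.13, the genome-wide
Ka/Ks scale typical of conserved plant proteomes).

Substitutions are planted per *change*, not per site-class: at each codon
position, each of the three possible single-base changes occurs with
probability `p_class(change)/(3 − τ)`, where the class (synonymous /
nonsynonymous) is that of the specific change on the current codon and τ
counts changes that would create a stop codon (those never occur). Two
properties motivate this kernel:

* at a fully synonymous position it reduces exactly to the JC transition
  kernel, so branch draws compose additively (ancestor → WGD → speciation
  → present gives correct pairwise divergences for every pair on the tree);
* the NG86 estimator is consistent with it *by construction*:
  `E[Sd/S] = p_syn` and `E[Nd/N] = p_nonsyn` for any codon composition,
  because each position's expected synonymous difference count,
  `σ·p_syn/(3 − τ)`, is exactly `p_syn` times its NG86 site contribution
  `σ/(3 − τ)`. A majority-class per-position assignment (the obvious
  alternative) breaks this: NG86 counts fractional sites, so planted
  divergence would be recovered ~23% low on uniform sense codons.

A multi-hit codon can combine individually stop-free changes into a stop
(e.g. ACT → TAA via three changes); such draws are resolved by reverting
the offending change(s) right-to-left, a deterministic tie-break affecting
O(p²) of codons.

Known divergences from real sequence evolution: no indels, no
transition/transversion bias, no codon-usage bias, no rate heterogeneity
across sites or lineages, one mRNA per gene, genes laid out with fixed
5-kb intergenic spacing (so the 30-kb tandem and 500-kb cluster rules are
exercised deterministically). Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions, not
robustness to alignment error, GC bias or assembly artifacts.

### Scenario defaults

The default scenario mirrors the study conditions the package targets:
WGD at 33.46 MYA and speciation at 6.15 MYA — the ages whose planted
divergences `2μT` equal the headline Ks peaks 0.87 and 0.16 at
μ = 1.3 × 10⁻⁸ — with a shared WGD preceding the split. Post-WGD retention
is a free parameter (no published value): the default removes 40% of the
doubled gene set (duplicate copies first), i.e. a 0.2 retained-duplicate
fraction, and the retained count is exactly `⌈(1 − loss)·2n⌉`. A
lineage-specific WGD mode (`wgd_lineage='A'|'B'`, with `wgd_age` then
*after* the split) exists solely to exercise query-vs-reference syntenic
depth (2:1 pattern); the shared mode enforces `wgd_age > speciation_age`.

LTR elements are modelled as two equal-length terminal repeats only
(identical at insertion age 0); internal element sequence is not simulated.
The Hi-C generator produces one chromosome of `n` 100-kb bins with expected
counts `scale·(1+|i−j|)^(−decay)·(1 + s·c_i c_j)`, `c_i = ±1` the planted
compartment sign (A fraction 0.532 by default, `round(f·n)` bins A),
Poisson-sampled unless `noise=False` (which returns the expected matrix
itself — the noiseless limit used for exact-recovery tests). Gene and TE
densities are Poisson per bin with A gene-dense (12 vs 4 per 100 kb) and
B TE-rich (55 vs 20), matching the qualitative contrast the compartment
orientation rule relies on.

## 2. Ka/Ks estimation

NG86 counting with equal pathway weighting and JC correction. Choices:

* **Sites**: per position, `syn/(3 − to_stop)`; substitutions to stop
  codons are excluded from numerator and denominator (standard NG86
  practice).
* **Differences**: 2–3-hit codon pairs average over all orderings of the
  single-base steps, excluding orderings that pass through a stop codon;
  if *every* ordering does, all are averaged (steps through stops counted
  nonsynonymous) — deterministic, and exercised only by pathological pairs.
* **Alignment**: proteins globally aligned (Needleman–Wunsch, BLOSUM62,
  gap open 10, extend 0.5) and back-translated; columns with a gap,
  ambiguity code or stop in either sequence are dropped and counted;
  pairs with < 30 surviving codons are skipped.
* **Flags, not exceptions**: `pS ≥ 0.75` → `ks_saturated` (excluded from
  distributions, counted in run logs); `Sd = 0` → `ks_zero`.

NG86 was chosen over ML (GY94/YN00) because it is fully specifiable,
oracle-testable by exhaustive enumeration (all sense-codon pairs are
checked against an independent pathway enumerator), and the dating layer
only requires a *consistent* Ks scale. Known behaviour: at WGD-scale
divergence (Ks ≈ 0.87, pS ≈ 0.51) NG86 underestimates slightly (mean
within ~1–2%), and the convex JC transform places the *mode* of the
per-pair sampling distribution another ~1% below the mean; distribution
peaks at high Ks are therefore expected a few percent low, while
low-divergence peaks (Ks ≈ 0.16) are recovered within ±0.02.

## 3. Homology and colinearity

* Candidate homolog pairs must share a protein 5-mer; retained pairs need
  ≥ 40% identity over aligned columns and ≥ 50% mutual coverage. These
  thresholds re-express the conventional BLASTP E-value cutoff without an
  external binary and are config-exposed.
* Chaining: unit anchor score, per-gene gap penalty 0.05, gap cap 25
  genes, minimum 5 anchors per block (MCScanX-style conventions). Chains
  are extracted iteratively (best chain, remove anchors, repeat), each
  anchor in at most one block, both orientations considered. The DP is
  verified against exhaustive chain enumeration on small instances.
* Tandem arrays combine the physical rule (< 30 kb gap) with an
  intervening-gene cap (default 1) over connected components of the
  within-species homology graph; clusters are maximal sets of ≥ 5 family
  genes whose span fits a 500-kb window, overlapping windows merged.
* Syntenic depth counts distinct blocks overlapping fixed gene-rank
  windows (default 50 genes; 10 in the small simulated tests) on the
  reference side; the modal depth distinguishes 2:1 (WGD in query) from
  1:1.

## 4. Dating

* Ks peaks: Gaussian KDE with fixed bandwidth 0.05 on a 0.001 grid over
  (0, 3]; zeros excluded; local maxima sorted by height. KDE over all
  syntenic pair values (not block medians) is the default.
* Rate calibration `μ = Ks/(2T)` from one anchor; a multi-anchor wrapper
  averages per-anchor rates arithmetically. `date_event` is the exact
  inverse.
* Duplication timing: a pair is called after the split if its Ks is below
  `peak·(1 − margin)`, before if above `peak·(1 + margin)` (margin 0.25);
  the band between is ambiguous. On cohorts planted at 2 vs 20 MY around a
  6.15-MY split this yields ≥ 95% correct calls.
* LTR ages: p-distance over unambiguous positions, JC correction,
  `T = K/(2μ)`; saturated repeats get an undefined age and are excluded
  from (but counted in) summaries. Times are reported in MY; internal
  units are years.

## 5. Compartments

Per chromosome: O/E normalisation (mean observed count per diagonal
distance; zero-contact distances are neutral O/E = 1; zero-row bins and
zero-variance rows masked), Pearson correlation, leading eigenvector by
power iteration (deterministic start, tolerance 1e-10, ≤ 10 000
iterations, verified against a dense solver). Orientation: the positive
sign is assigned so positive-eigenvector bins have higher mean gene
density (A = open/gene-dense). `fraction_A` aggregates unmasked bins
genome-wide. A chromosome is flagged low-signal when the leading
eigenvalue carries < 5% of the correlation matrix trace (for a PSD
correlation matrix the trace equals the total absolute spectrum).
Contrasts use a two-sided permutation test,
`p = (1 + #{|Δperm| ≥ |Δobs|})/(1 + n_perm)`, default 10 000 shuffles.
Matrix balancing (ICE/KR) and TAD calling are out of scope.

## 6. Problem sizes and determinism

The shipped tests and drivers run cohorts of 100–2000 pairs of 100–400
codons, 100–1000 LTR elements of 2 kb, and Hi-C matrices of 120–500 bins —
sizes at which every planted quantity is recovered within the tolerances
stated in the tests while the full suite stays fast. All randomness flows
from a single seed through named spawned generators (sequences, events,
branches, matrix), so identical config + seed reproduces every output file
byte-for-byte; the echoed effective config omits only the output path.

## 7. Known limitations

* NG86/JC saturates above pS = 0.75; ancient WGDs (Ks ≫ 1.5) need an ML
  estimator, which is out of scope (a config hook marks where one would
  plug in).
* The simulator's truth tables define orthology by gene ancestry; on real
  data orthology must be inferred, and the recovery rates reported on
  simulations do not transfer.
* Single-anchor rate calibration propagates no uncertainty; bootstrap CIs
  on Ks peaks are a noted hook, not implemented.
* Absolute event windows depend linearly on μ; the package reports the
  `K/(2μ)` identity and leaves choices of calibration anchors to the user.
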