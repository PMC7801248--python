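# skullcap

Comparative genome-evolution analysis for a pair of related plant genomes
(the *Scutellaria* / skullcap setting: two species sharing an ancient
whole-genome duplication, WGD, followed by a speciation split): syntenic
ortholog/paralog identification, Ka/Ks estimation, Ks-peak dating of the
speciation and WGD events, LTR retrotransposon insertion-age estimation,
tandem-duplication and gene-cluster calling with timing relative to
speciation, and Hi-C A/B-compartment calling.

Genome-scale analyses of this kind are normally a patchwork of external
binaries (BLASTP, MCScanX/DAGchainer, CoGe, LTR pipelines, Hi-C stacks).
`skullcap` reimplements the analytical core as one tested Python library,
and ships a synthetic genome-evolution simulator with *planted, logged
events* so every stage can be validated against ground truth before it is
pointed at real assemblies.

## The models at the core

* **Ka/Ks (Nei–Gojobori 1986).** For a protein-guided codon alignment,
  each codon contributes synonymous sites `s = Σ_pos syn/(3 − to_stop)`;
  multi-hit codon pairs are resolved by averaging synonymous/nonsynonymous
  step counts over all stop-free mutational pathways. With `pS = Sd/S` and
  `pN = Nd/N`, multiple hits are corrected by Jukes–Cantor,
  `d = −¾ ln(1 − 4p/3)`, giving `Ks = d(pS)`, `Ka = d(pN)`. `Ka/Ks < 1`
  indicates purifying selection.
* **Molecular clock.** `K = 2 μ T`: a pair split `T` years ago at rate `μ`
  per site per year accumulates `K` substitutions per site. Peaks of the
  Ks distribution (Gaussian KDE, fixed bandwidth) date speciation and WGD;
  a known split age calibrates `μ = Ks/(2T)`.
* **LTR insertion ages.** The two terminal repeats of an LTR element are
  identical at insertion; their JC-corrected divergence `K` dates the
  insertion as `T = K/(2μ)`.
* **Colinearity.** Homolog pairs (global protein alignment, BLOSUM62, with
  identity/coverage thresholds) become gene-rank anchors; a
  DAGchainer-style dynamic programme chains them into strictly monotone
  (same or inverted) blocks with unit anchor score and per-gene gap
  penalties.
* **A/B compartments.** Per chromosome, the contact matrix is
  observed/expected-normalised, converted to a Pearson correlation matrix,
  and segmented by the sign of the leading eigenvector (power iteration);
  the sign is oriented so A is the gene-dense, TE-poor compartment, and
  density contrasts are tested by label permutation.

## Worked example

`skullcap run-all --outdir results/demo --seed 1` simulates the default
scenario — WGD at 33.46 MYA, speciation at 6.15 MYA, μ = 1.3 × 10⁻⁸/site/yr,
ω = 0.13, lineage-specific tandem duplications and an inversion, a 1.41-MY
LTR cohort, and a 100-kb plaid Hi-C matrix with 53.2% A bins — then runs
every stage and prints:

```
# skullcap run-all report
seed: 1

## Ortholog Ks
syntenic ortholog pairs: 186
true 1:1 orthologs recovered: 143/144
ortholog Ks peak: 0.159
calibrated mu (vs planted 1.3e-08): 1.293e-08

## WGD Ks
paralog Ks peak: 0.874

## LTR insertion ages
mean age: 1.407 MY (planted 1.41 MY)
median age: 1.399 MY

## A/B compartments
fraction A: 0.532 (planted 0.532)
truth agreement: 1.000
TE density contrast p: 9.999e-05
gene density contrast p: 9.999e-05
```

Reading: the ortholog Ks peak (0.159) recovers the planted speciation
divergence 2μT = 0.16 and calibrates the rate back to 1.3 × 10⁻⁸; the
within-genome paralog peak (0.874) recovers the planted WGD divergence
0.87; LTR terminal-repeat divergence dates the cohort at 1.41 MY; and the
eigenvector calls reproduce the planted compartments exactly, with both
density contrasts significant (permutation p < 0.001). Duplication-timing
classification (see `duplication_timing.tsv`) places WGD paralogs before,
and tandem copies after, the speciation split.

The same steps are available as numbered drivers under `analysis/`
(`01_simulate_genomes.py` … `05_ab_compartments.py`), each a thin narrative
wrapper over `skullcap.pipeline`.

## Layout

```
src/skullcap/      library: simulate, io, synteny, kaks, dating,
                   compartments, pipeline, cli
analysis/          numbered analysis drivers (simulate -> ... -> compartments)
scripts/           acceptance.py
tests/             pytest suite with brute-force oracles and property tests
docs/methods.md    models, parameter choices, numerical conventions, limits
```
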