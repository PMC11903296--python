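# Methods

## Entrapment FDR validation

**Shuffled-target construction.** Each protein's residues are permuted by a
uniform random permutation restricted to the positions *not* occupied by
lysine, arginine or proline; K/R/P stay where they are. Because trypsin
cleaves C-terminal of K/R (suppressed before P), this freezes the cleavage
pattern: the shuffled protein digests into peptides of exactly the same
lengths (hence the same length and mass distributions) as the original,
while the peptide *sequences* are destroyed. Per-record random streams are
derived from a global seed combined with a hash of the accession, so results
are reproducible and independent of record order. Shuffled accessions gain a
`SHUF_` prefix; entrapment entries from a foreign-species FASTA keep their
native accessions and carry `origin=entrapment` from their source file.

A valid entrapment database must share essentially no peptides with the
target. On a 2,000-protein synthetic proteome with UniProt-average residue
frequencies and log-normal protein lengths (median 380 aa), the shared
unique tryptic peptide fraction (length 7–30, no missed cleavages, union
denominator) is 0–0.004% across seeds — the tests assert the ≤ 0.01% bound.
Shuffling occasionally *increases* the unique-peptide count slightly: exact
repeat peptides in the target are split into distinct sequences, which makes
the entrapment side conservative. Real proteomes contain low-complexity and
repeat regions that raise chance collisions relative to random sequences;
the synthetic bound therefore demonstrates the mechanism, not a guarantee
for any particular organism's database.

**Estimator.** With $d$ decoy-origin protein hits, $t$ target hits and $r$
the decoy:target database size ratio,
$\widehat{\mathrm{FDR}} = d(1+1/r)/(t+d)$. The $1/r$ term scales the
observed decoy hits up for false hits that landed in the target portion of
the search space. $r$ defaults to the ratio of *entry counts* (databases of
"similar size" are compared by entries; a flag switches to unique-peptide
counts). The calibration harness draws a false-hit count $F$ with
$F/(n_{\text{true}}+F)$ equal to the requested FDR and scatters false hits
over the combined space in proportion to database sizes, so
$\mathbb{E}[d] = F\cdot r/(1+r)$ and the estimator is unbiased; tests verify
the mean over 200 simulations stays within 3 SE of truth at 1% and 5% for
$r \in \{0.5, 1, 1.33\}$.

**ID accumulation.** True hits recur across technical replicates while false
hits scatter, so the union of per-replicate hit sets has a higher FDR than
any single replicate (e.g. three replicates sharing 99 targets with one
unique decoy each: 2.0% per replicate but 5.9% for the pooled set). The
`accumulated_fdr` report makes this contrast explicit; mean per-replicate ID
counts are the honest summary statistic.

**Digestion.** Tryptic cleavage is implemented as the regex `[KR](?!P)`
(`[KR]` for trypsin/P), with up to 2 missed cleavages by joining adjacent
fragments and the length filter applied last. Default spec: trypsin with
proline suppression, 0 missed cleavages, length 7–30, I/L not equated —
common DIA practice; all config-exposed. The in-package implementation
returns peptides in positional order (needed by the partition property
test); pyteomics' `cleave` serves as an independent oracle in the test
suite, as does `pyteomics.fasta.shuffle(fix_aa="KRP")` for the shuffle
contract.

## Two-proteome-mix benchmarking

Per-protein fold change between conditions is the ratio of *means of raw
linear quantities over observed replicates*, then log₂ — not the mean of
per-replicate log ratios — which tolerates unbalanced replicate counts; a
protein must be observed at least once in both conditions with positive
means. The local CV orders proteins by log₂ average abundance (descending)
and slides a 100-protein window with step 1, windows fully inside the range
(a single window when fewer rows than the window); CV is the sample SD over
the mean, computed on the linear-scale ratios $2^{\log_2 FC}$ by default
(log₂-scale option exposed). All CVs use the $n-1$ standard deviation since
replicate counts are small ($n = 3$ typical). Expected fold changes come
from the mix design's mass ratios; the per-species bias is the median
observed linear FC divided by the expected FC. Proteins with zero or
negative means are excluded rather than clamped, avoiding fabricated ratios.

Local CV curves in a two-species mix must be read per species: with
different design ratios per species, a cross-species window has nonzero
spread even in noise-free data.

## Single-cell postanalysis

The pipeline order is enforced via a matrix `stage` field:
`filter_missing → impute_min → log2_normalize → embed / DE`; running a later
stage early raises `PipelineOrderError`. Filtering removes proteins missing
in *more than* `max_missing_cells` cells (strict inequality: exactly the
threshold is kept); blanks do not count toward the threshold but are carried
through embedding. Imputation substitutes the *global* dataset minimum; the
original missingness mask is preserved for audit. "Normalization to a normal
distribution" is interpreted as per-protein z-scoring after log₂ (default;
global z-score and none are alternatives) — the conventional pre-embedding
standardization. Constant rows become all-zero with a warning.

Differential expression runs a two-sided *pooled-variance* Student's
*t*-test (not Welch) on the log₂ values — the per-protein z-score is an
affine transform applied to both groups, so the *t*-statistic is unchanged —
with Benjamini–Hochberg correction over all tested proteins. The fold change
is the ratio of linear post-imputation group means (orientation B/A), since
the upregulation rule "FC > 1" is a linear-ratio statement; upregulated
requires both q < α and FC > 1. Proteins with zero within-group variance in
both groups get p = 1 and a `degenerate` flag. UMAP runs with 15 neighbors,
min-dist 0.1 and a pinned seed recorded in the run manifest; heat-map leaf
ordering uses Euclidean distance with average linkage (config-exposed).

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
defaults chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| base abundance | $10^{\mathcal{N}(4,\,0.8)}$ (a.u.) | log-normal; spans ≥ 4 orders of magnitude at proteome scale |
| technical CV | 0.05 → 0.35, decay rate 1.0 per log₁₀ | exponential CV drop with abundance; ~35% at the limit of quantification, ~5% for abundant proteins |
| noise form | log-normal, $\sigma=\sqrt{\ln(1+CV^2)}$, mean-preserving | standard multiplicative error; realized CV matches the model |
| dropout | logistic in log₂ abundance, midpoint 6.64 (= log₂ 100), steepness 1.0 | missing-not-at-random; midpoint coincides with the noise model's LOQ reference (log₁₀ a = 2) |
| mix multiplier | species mass / max species mass across conditions | base abundances condition-agnostic; design ratios exact |
| peptides per protein | 1 + Poisson, rate rising with log abundance | ≥ 2-peptide filter has realistic bite |
| cell size scaling | (diameter/20 µm)³ | protein content is volume-proportional |
| biological CV | 0.5 between cells | single-cell CVs (~55–65%) far above technical replicate CVs (~10–20%), as observed in real single-cell vs bulk comparisons |
| blank background | 2 × 10⁻⁴ of base abundance | blanks detect only a few percent of the per-cell protein count (reagent background) |

The logistic dropout form is a modeling assumption (no functional form is
canonical); its parameters are fully exposed and recoverable from the
generated data (midpoint to ±0.5 log₂ units at 2,000+ proteins, tested).
Determinism is byte-level under a fixed seed.

**What the generator does not model:** peptide-level quantification rollup
(protein quantities are drawn directly), chromatographic or spectral
artifacts, interference/ratio compression between co-eluting species,
shared peptides between species, batch effects, or cell-cycle structure.
Passing tests therefore show the *analysis layer* is correct and calibrated
under the stated generative assumptions, not that any instrument achieves
these numbers on real samples.

## Problem sizes and numerical choices

Fold-change recovery aggregates 100 simulated experiments of 1,500 human +
500 yeast proteins × 3 replicates per mix — enough for the Monte-Carlo mean
of median fold changes to stabilize well inside the ±10–15% bands. FDR
calibration uses 200 simulations of 10,000 true hits against 20,000-entry
databases. The shuffle contract and peptide overlap are checked exhaustively
on 2,000-protein proteomes. DE power/FDR uses 100 simulations of 1,000
proteins (50 true 4-fold effects, 10 cells per group); replicate-CV
parameter recovery compares binned mean CVs against the generating curve
corrected for the small-sample bias of the sample SD ($\mathbb{E}[s] = c_4
\sigma$).

One interaction worth knowing: with min-imputation, the dominant principal
component of a single-cell matrix tracks per-cell detection depth (how many
low-abundance proteins were imputed), not cell type — mirroring what
MNAR missingness does to real single-cell embeddings. The cluster-separation
oracle therefore restricts to completely observed proteins
(`filter_missing(matrix, 0)`) or uses effects large enough to dominate; with
2-fold effects on 50 of 600 proteins and complete cases, PCA separates cell
types with silhouette > 0.5.

## Known limitations

- The shared-peptide bound is demonstrated on synthetic proteomes; real
  databases with extensive low-complexity regions may share more peptides
  after shuffling (the overlap report quantifies it for any pair of FASTAs).
- The FDR estimator assumes false hits distribute over target and decoy
  space in proportion to database size — reasonable for shuffled targets of
  similar size, less so for phylogenetically close entrapment species.
- Min-imputation is the modeled study convention; it compresses
  low-abundance variance and drives the detection-depth effect above.
  The package deliberately does not substitute a different imputation.
- Protein grouping/inference and search-engine q-value machinery are out of
  scope; the toolkit consumes protein-group-level reports as given.
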