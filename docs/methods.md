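# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic cohort does and does not emulate, and
the package's known limitations.

## Synthetic cohort model

The generator produces the statistical structure the analysis assumes,
not a realistic transcriptome. A genome of `n_chromosomes` two-arm
chromosomes with `genes_per_arm` genes per arm (default 4 × 60 → 480
genes) carries:

- **Baseline expression.** Per-gene means μ_g ~ LogNormal(0,
  `baseline_logmean_sd`=1), normalised to sum to 1 so a cell's expected
  total equals its library size. Library sizes are LogNormal with mean
  `mean_library_size` (default 5,000 UMIs, log-SD 0.25).
- **Dosage coupling.** A cell of clone c expects
  λ_ig = L_i · μ_g · (cn_{g,c}/2)^α · b_{batch(i),g}, with α =
  `dosage_exponent` (default 1: linear dosage, the standard working
  assumption of expression-based CNV inference). α = 0 decouples
  expression from copy number entirely (used by the exchangeability
  tests).
- **Count noise.** Negative binomial via a Gamma–Poisson mixture with one
  shared dispersion θ = `nb_dispersion` (default 2; var = λ + λ²/θ). A
  single shared dispersion is the simplest NB model that still produces
  realistic overdispersion.
- **Batches.** Gene-wise multiplicative LogNormal(0, `effect_sd`) factors
  per batch (default two batches, effect_sd 0.15) — the simplest
  mechanism a neighbourhood-based mixing metric can detect.
- **Mitochondrial content.** A `mito_gene_fraction` (default 3%) of genes
  get an `MT-` symbol prefix; each cell's mitochondrial λ is rescaled so
  its expected mitochondrial fraction equals a uniform draw from
  `mito_pct_range` (default 1–8%, i.e. healthy cells; QC tests construct
  their own failures).
- **Activity.** Disjoint activity gene sets (default four sets of 40);
  per clone, round(n · active_fraction) cells multiply set genes by
  `activity_fold` (default 3).

The bundled default cohort has 400 diploid reference cells and three
clones (260/260/280 cells) planting 0, 1 and 3 arm events — a burden
gradient mirroring the low/medium/high degrees the analysis must
separate. All randomness flows from one seed through documented stream
order; fixed seed ⇒ bit-identical outputs.

**Not emulated:** gene length/GC effects, doublets, ambient RNA, UMI
collisions, cell-cycle covariance between genes, focal (sub-arm) events,
and biologically structured gene–gene correlation. Passing the recovery
tests therefore shows the pipeline extracts planted dosage signal from NB
noise and multiplicative batch structure — not that it is robust to every
artifact of real droplet data.

## QC and preprocessing

Cells pass QC with ≥ 300 UMIs, 200–7,500 expressed genes and ≤ 20%
mitochondrial counts (a cell at exactly 20% is retained; the bound is on
exceeding it). The UMI rule is deliberately a *minimum*: the filtering
convention this follows lists "more than 300 UMIs" among removal criteria,
which taken literally would discard essentially every droplet; all four
thresholds are exposed as parameters.

Normalisation is ln(1 + 10⁴·x/total) per cell. Variable genes are ranked
by a variance-stabilised dispersion: a mean/variance trend is fitted by
binned medians (quantile bins, at least 10 genes per bin so a few
genuinely variable genes cannot inflate their own trend), expression is
standardised against the trend, clipped at √n_cells, and genes are ranked
by the clipped variance. PCA runs on per-gene z-scores clipped at ±10
(the common scaling default); the spectrum is the percentage of the
scaled matrix's variance per component.

The significant-PC count joins two stopping criteria: c1 = first
component where cumulative contribution > 90% **and** individual
contribution < 5%; c2 = last component whose drop to its successor
exceeds 0.1 percentage points; k = min of the criteria that fire, clamped
to [1, len]. This is the widely used reading of the three-part rule;
thresholds are parameters.

## iLISI

Euclidean distances in the supplied embedding; k = 3·perplexity
neighbours (self excluded); bandwidth per cell by binary search (50
iterations, tolerance 1e-5) to entropy log(perplexity); batch
probabilities are kernel-weighted neighbourhood compositions; score =
inverse Simpson index, clipped to [1, B]. Degenerate cases: a single
batch scores exactly 1 with a warning; a fully collapsed kernel falls
back to the nearest neighbour. The metric is computed on whatever
embedding it is given (typically the significant PCs); the package
measures mixing and deliberately does not perform batch correction.

## CNV inference and scoring

Smoothing: drop genes with mean normalised expression < 0.1 over all
cells; subtract the per-gene reference mean; clamp at ±3 pooled reference
SDs; centred moving average of 101 genes along genomic rank within each
chromosome, the window shrinking at chromosome ends; re-centre every cell
at its median (so reference cells sit at 0 by construction). Window and
clamp follow the conventions of expression-based CNV tools and are
configurable. With the bundled 120-gene chromosomes the 101-gene window
visibly bleeds signal across the arm boundary; on real annotations
(hundreds to thousands of genes per chromosome) the bleed is local.

State calling replaces an HMM with a deterministic quantizer: with σ the
pooled SD of reference smoothed residuals, |r| < aσ is neutral, aσ ≤ |r|
< bσ a one-copy event, bσ ≤ r < cσ a two-copy gain, r ≥ cσ a multi-copy
gain, and losses at or below −bσ saturate at complete loss; boundaries
map to the higher-magnitude state. Because the smoothed null is
near-Gaussian, the neutral half-width *a* directly sets the false-call
rate (≈13% at 1.5σ, ≈5% at 2σ); the defaults (a, b, c) = (2.5, 4.0, 5.5)
put the per-gene null call rate near 1–2%, keeping the false-positive
control property (≤ 5% non-neutral calls on event-free data) satisfied
with margin while planted events — which sit many σ out after smoothing —
remain fully detectable. A consequence of smoothing is that magnitude
discrimination between the event states is coarse; direction (gain vs
loss) is the robust readout.

Scoring sums the printed event weights (gain 1/2/3 by magnitude, loss 1,
complete loss 2, neutral 0) over genes: diploid-like cells score near 0
and the score is additive over genes and arms (the arm landscape's
gain + loss scores decompose each cell's total exactly). A raw-state-sum
variant is available via a custom weight map.

Levels: baseline = 95th percentile of reference scores; tumor cells at or
below it are low; the medium/high boundaries are the tertiles of
(score − baseline) over **all** tumor cells, with labels applied only
above the baseline. Tertiles over all tumor cells (rather than only the
cells above baseline) keep the trisection meaningful when a large
near-diploid subpopulation is present — anchoring on positive excesses
alone would force the lowest-burden third of genuinely altered cells into
"low" regardless of cohort structure. Both anchors are parameters of the
analysis, not biology: the low/medium/high degrees are a relative
trisection, not absolute copy-number classes.

## Differential expression and DEG-with-CNV

Per-gene two-sided Wilcoxon rank-sum on normalised expression, with the
tie-corrected normal approximation; when both groups have ≤ 8
observations and the pooled sample is tie-free the exact null is used.
log2FC = log2((mean expm1(a) + ε)/(mean expm1(b) + ε)), ε = 1e-9 — fold
changes on de-logged means, the convention of the surrounding ecosystem.
BH adjustment is applied over all tested genes; reported genes satisfy
|log2FC| ≥ 0.25 and adjusted p < 0.05, both directions. The up/down
labels for the landscape use the strict |log2FC| > 1 rule.

A gene "has a CNV event" when its state is non-neutral in ≥ 30% of the
tumor cells under comparison; the dominant direction is the larger summed
event weight (ties → gain). The 30% fraction is a declared convention —
no principled threshold exists for converting per-cell states into a
per-gene event — and is a parameter.

## Signature scoring and activity states

The per-cell score of a gene set is the area under its recovery curve
within the top T = ⌈0.05·G⌉ expression ranks, normalised by the maximal
area (all member genes at the very top); expression ties are broken by a
seeded random permutation shared across cells, making scores
deterministic given the seed and invariant to monotone transforms of a
cell's expression vector. Scores of sets with no genes in the matrix are
0 with a warning.

Activity classification min–max scales the four activity signatures over
the classified cells (a constant column contributes 0.5 with a warning),
averages them into a composite, and splits 1-D two-means with centroids
initialised at the composite extremes; the larger-centroid cluster is
"active", and a constant composite yields all-inactive. A fixed-threshold
mode is provided for calibrated scores. The two-means rule is a declared
construction: no published boundary exists for the active/inactive
dichotomy, so the package makes its rule explicit and configurable.

## Pipeline

The orchestrator validates a strict YAML config (unknown keys are
errors), derives per-stage child seeds from the global seed by hashing
the stage name (all below 2³¹), writes every artifact as TSV/JSON, and
logs parameters and timings. Timings live only in the log so that
identical config + seed reproduce every output byte for byte.

## Problem sizes

The test and acceptance workloads use cohorts of ~1,200 cells × 480 genes
(three clones, two batches), two-group DE at 200 + 200 cells × 500 genes,
and iLISI oracles at ≤ 60 cells with production-scale checks at 400 —
sizes chosen so the full suite exercises every recovery property in well
under a minute while keeping planted effects at realistic magnitudes
(4-copy gains, one-copy losses, 3× activity folds, 0.15 log-SD batch
effects).

## Known limitations

- The six CNV states are quantised from smoothed residuals, so absolute
  copy-number magnitude is not identifiable; gains/losses directions and
  relative burden are.
- The reference population must be genuinely diploid and expression-
  matched; a contaminated reference shifts σ and the baseline percentile.
- iLISI depends on perplexity and embedding dimensionality; reported
  values should cite both (the pipeline records them in its summary).
- The DEG-with-CNV intersection inherits any cross-arm smoothing bleed as
  conservative mis-annotation of event direction near boundaries.
- The generator's independence across genes means multiple-testing
  behaviour on real, correlated transcriptomes will be less clean than
  the type-I property tests suggest.
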