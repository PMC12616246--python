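# Methods

This note documents the models and procedures implemented in `phenoscape`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Event tables and preprocessing

Cells are rows and channels are columns everywhere. Each channel carries a
role (`PTM`, `state`, `immunophenotype`, `lineage`, `DNA`, `viability`,
`barcode`, `other`); the transform state (raw vs arcsinh) is tracked on the
table and a transform is refused if already applied.

Ion counts are variance-stabilised as `asinh(x / c)` with cofactor
`c = 5` by default — the mass-cytometry convention; the cofactor is
configurable per call because no single value is canonical for all
panels. Batch centering subtracts each channel's per-batch mean on the
transformed scale, removing between-run intensity drift under the
assumption that batches are balanced with respect to biology (conditions
are spread across acquisition batches). Per-batch channel means of the
output are zero to 1e-9 by construction.

Population gates are explicit threshold sets (all positive channels
strictly above, all negative channels at or below their thresholds),
applied on the arcsinh scale before centering. Gates are configuration,
not inference: thresholds in real screens are set interactively per
dataset, so the package ships a density-valley helper but never applies it
implicitly.

## Combinatorial debarcoding

A k-of-n scheme assigns each pooled sample a unique subset of `k` hot
barcode channels out of `n` (126 codes for 9-choose-4). Debarcoding is a
single-pass rank assignment:

1. each barcode channel is rescaled to [0, 1] using its 1st–99th
   percentile window across all cells (robust to outlier ion counts);
2. the cell's top-k channels are its candidate code; the *separation* is
   the gap between the k-th and (k+1)-th ranked rescaled intensities;
3. the cell is assigned iff the candidate is a valid scheme code and
   separation ≥ threshold (default 0.3, exposed because published
   debarcoders do not agree on a cutoff). Exact ties across the rank
   boundary give separation 0 and are always rejected — conservative
   doublet handling. No Mahalanobis refinement pass is performed.

Per-channel percentile rescaling presumes every barcode channel is hot in
some fraction of the pool (true of real multiplexed runs). The
condition→code mapping therefore strides codes evenly through the
lexicographic enumeration, which balances channel usage even when far
fewer than 126 conditions are pooled.

## Signed EMD and x̄EMD

The per-marker shift statistic between a condition and its matched control
is the exact 1-D Wasserstein-1 distance between the two empirical
distributions — the integral of |CDF difference|, computed by the
empirical quantile-function integral so unequal sample sizes are handled
exactly and deterministically (no subsampling). The sign is the sign of
the median difference; the median was chosen over the mean for robustness
to ion-count outliers, and ties keep `+`. Distances are computed on the
arcsinh, batch-centered scale, matching the stated processing order, so a
planted arcsinh-scale translation δ is recovered as |EMD| = δ up to
sampling error.

x̄EMD is the arithmetic mean of |EMD| over the included markers — by
default every non-barcode, non-DNA, non-viability channel ("all measured
markers"), with a config override. It satisfies x̄EMD ≥ |mean signed EMD|
and equals 0 for a condition against itself.

Positivity-based metrics (apoptotic fraction, % S-phase, therapeutic
apoptosis = co-culture minus monoculture baseline in percentage points)
take explicit thresholds. Real gates are unpublished, so both
instrument-scale (uncentered arcsinh, the pipeline default of 1.5 sits
between the synthetic low/high modes) and centered-scale thresholds are
supported via config. Cell states follow a fixed priority hierarchy —
apoptotic (cPARP⁺), else S (IdU⁺), else G0 (pRB⁻), else other — giving
exactly one state per cell.

## kNN-DREMI and ΔDREMI

For an ordered pair (x → y), both samples are rescaled to [0, 1] after
clipping at the 0.1/99.9 percentiles (tames outliers), and a joint density
is evaluated on an `(n_bins · n_mesh)²` grid via the k-nearest-neighbour
estimator `ρ̂(g) = k / (N π r_k(g)²)`, with `r_k` the Euclidean distance
from the grid point to its k-th nearest data point. Mesh cells are summed
into `n_bins × n_bins` scoring bins, each x-column is renormalised to a
conditional p(y|xᵢ) (columns with no mass are dropped rather than imputed,
avoiding log 0 artifacts), and the score is the mutual information, in
bits, of the joint in which every occupied column carries equal weight.
The score is deterministic for fixed inputs, bounded by `log2(n_bins)`,
zero for a degenerate conditioner, and — the defining property of density
resampling — approximately invariant to the x marginal as long as the x
support covers the response. It cannot be invariant to *missing* support:
if no cells sample the transition region of a response, no estimator can
recover the information there, and the validation uses overlapping
bimodal/uniform marginals accordingly.

Defaults `k = 10`, `n_bins = 20`, `n_mesh = 3` follow the documented
defaults of the reference kNN-DREMI implementation and are recorded in
output metadata. DREMI is directional and both orderings are stored;
ΔDREMI subtracts the matched control per ordered pair, in fixed panel
order, yielding a p·(p−1)-long rewiring vector (110 for 11 PTMs). A
planted rewiring of one dependency shows up in both orderings of that
pair; which direction dominates depends on sampling.

## Condition embeddings

Per-condition feature vectors (signed EMD per marker, or ΔDREMI per pair)
are embedded in 2-D two ways:

- **PCA**, column-centered, with a deterministic sign convention (each
  component's largest-magnitude loading is positive).
- **Diffusion potential**: pairwise Euclidean distances; adaptive
  bandwidth σᵢ = distance to the k-th nearest row; α-decay kernel
  `exp(−(d/σᵢ)^α)` symmetrised and row-normalised to a Markov matrix;
  powered to `t`; potential coordinates `−log(P^t)` floored at 1e-7;
  metric MDS to 2-D. Defaults k = 5, α = 10, t = 10. This is a
  deliberately desk-scale embedding (hundreds of conditions, not millions
  of cells): no automatic diffusion-time selection and no landmarking.
  The MDS is initialised from classical (Torgerson) scaling rather than a
  random start, so the embedding is simultaneously seed-deterministic and
  row-permutation-equivariant; the seed parameter is retained in the
  interface and passed to the solver. The quality bar is structure
  preservation (cluster separation, distance rank correlation), not
  coordinate equality with any other tool.

Missing feature values are zero-filled before embedding, with a logged
count.

## scRNA-seq stem-cell index

QC removes cells strictly beyond any exclusion bound: UMIs > 32,500 or
< 1,000; detected genes > 7,000 or < 300; mitochondrial fraction > 20%
("MT-"-prefixed genes); UMI/read ratio > 0.4. Bounds are strict as
printed, so values exactly at a bound are kept. The high-ratio exclusion
is counterintuitive (it removes low-duplication cells) but is followed as
listed; the bound is configurable. The per-rule attribution in the QC
report uses a fixed precedence (UMI → genes → mito → ratio) for
accounting only — the kept set is order-independent. Genes detected in
fewer than 25 cells are then removed, after the cell filters, matching the
listing order.

Normalization is count-based to 10,000 per cell, excluding from the
size-factor base every gene whose count exceeds 5% of that cell's total
(strict inequality, evaluated per cell); all genes, including excluded
ones, are divided by the cell's size factor, and ln(1+x) is applied as a
separate recorded step. A consequence of the rule as stated: a cell whose
every gene exceeds the 5% bound has an empty base and is flagged and
dropped with a warning — in a toy two-gene cell like [10, 90] *both*
genes are "highly expressed", so the cell is degenerate; the smallest
self-consistent illustration is [10, 190], where gene 1 sits exactly at 5%
(kept) and the normalized row is [10,000, 190,000]. The rule is scale-free,
so multiplying a cell's counts by a constant leaves its log-normalized
profile unchanged exactly.

Program scoring bins genes into 25 equal-frequency bins by mean
expression, samples 50 control genes per program gene from the program
gene's bin (excluding all program genes, seeded, pooled as a set), and
scores each cell as mean program expression minus mean control expression
— the standard expression-matched control-gene scheme. The stem-cell
index is revCSC score − proCSC score per cell, summarised per sample by
median and quartiles. The proCSC/revCSC gene lists are user-supplied
configuration (literature signatures are not reprinted here); the
synthetic generator ships its own.

## Synthetic generators

The cytometry generator emulates the statistical structure of a pooled
screen, not its biology or chemistry:

- Raw intensities are `cofactor · sinh(z)` for Gaussian arcsinh-scale `z`
  (lognormal-like raw scale); condition effects are translations of `z`,
  so a planted δ is exactly the arcsinh-scale shift the EMD should
  recover — the ground truth is analytic. Baseline levels per role
  (e.g. PTMs at z ≈ 2.2 ± 0.35, lineage high/low at 3.2/0.3) were chosen
  once for clear separability; real per-channel intensity scales are
  panel-specific and are not modelled.
- PTM dependencies follow `y = s · sigmoid(a(x − x₀)) + (1 − s) · noise`
  with the noise drawn from y's own marginal (a permuted copy of the
  response), so `s` spans independent (0) to deterministic (1) with one
  knob and conditional variance decreases with `s`.
- Each singlet's barcode channels realise exactly one k-of-n code
  (hot/cold lognormal intensities); doublets are channel-wise *sums* of
  two independently drawn cells, matching the ion-count physics of
  coincident events, at a configurable rate.
- Apoptosis / S-phase fractions, population mixtures (epithelial vs γδ),
  per-batch channel offsets and the condition→code map are all planted
  and recorded per cell in the ground-truth sidecar.

Not modelled: acquisition drift within a run, ion-cloud spillover,
spillover compensation, bead normalization, spatial organoid structure.
Passing the planted-recovery suites therefore demonstrates the
*statistical machinery* is correct — it does not certify performance on
real instruments' artifacts.

The scRNA generator draws per-gene base rates (Gamma), per-cell library
sizes (lognormal, median 4,000 UMIs), mitochondrial fractions
(Beta(4, 45), mean ≈ 8%) and UMI/read ratios (Beta(5, 15), mean 0.25,
so a realistic minority of cells fail the 0.4 bound), and blends
proCSC/revCSC program intensities per cell by a planted `program_mix`
weight (revCSC rate factor 0.2 + 1.8w; proCSC 2.0 − 1.8w) before Poisson
sampling. Metadata (total UMIs, detected genes, mitochondrial fraction)
are recomputable from the matrix exactly.

Both generators are bit-identical under a fixed seed and config.

## Numerical choices and problem sizes

- EMD magnitude is delegated to the exact empirical Wasserstein routine;
  the test oracle (mean |sorted difference| for equal sizes) is computed
  independently.
- Kendall correlation is the tie-adjusted τ-b.
- kNN radii use Euclidean distance on the unit square; grid densities are
  floored to avoid division by zero at coincident points.
- Validation sizes were chosen as the smallest that make the planted
  effects statistically unambiguous: 5,000 cells/condition for shift and
  DREMI recovery, 50,000 cells for debarcoding fidelity, 2,000 cells for
  apoptosis and stem-index recovery, 250–500 cells/condition for the
  31-condition end-to-end demo.

## Known limitations

- FCS files are not read or written; event tables travel as CSV with a
  YAML channel manifest. The screening formats of record are supported
  via CSV export.
- The diffusion-potential embedding is a simplification for
  condition-level matrices; it is not intended to reproduce any specific
  published embedding's coordinates.
- Gate thresholds, positivity cutoffs and the debarcoder separation
  threshold are configuration, with defaults suitable for the synthetic
  scales; real datasets require per-dataset values.
- Statistical testing of condition summaries (ANOVA, multiple-comparison
  correction) is out of scope; summaries export as TSV for external
  stats tools.
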