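# Methods

## Signal model

All coordinates are 0-based, half-open. Strand-specific per-base coverage is
normalised to reads per million (RPM) and the per-position log-enrichment of
each phospho-mark over total RNAPII is

    e(p) = log2( (phospho_RPM(p) + c) / (total_RPM(p) + c) ),  c = 5,

computed per base and then averaged within consecutive 20-nt bins (trailing
partial bins are dropped). The pseudocount c = 5 RPM acts as a shrinkage
floor: where coverage is far below it, enrichment is pinned toward 0
regardless of the phospho signal. The five marks are always ordered
(Tyr1, Ser2, Thr4, Ser5, Ser7). Replicate tracks are averaged per base
before enrichment. PCR duplicates are collapsed on the key
(chromosome, strand, read start, barcode) — read length is deliberately not
part of the key — keeping the first occurrence. Read-to-base coverage counts
full read footprints. The spliced/unspliced measure from junction-spanning
reads is (2·ExEx)/(ExI + IEx). Biotype assignment is hierarchical: each read
is counted once, for the first class in a caller-supplied abundance-ordered
hierarchy whose strand-matched annotation it overlaps, falling back to
"intergenic"; the class counts always partition the table.

An alternative binning (re-computing enrichment from bin-summed counts
rather than averaging per-base enrichment) can be had by binning the raw
tracks before `log2_enrichment`; the per-base-then-average order is the
package default because it preserves the per-position definition above.

## Hidden Markov model

Observations are the per-bin 5-vectors x_n. Each (chromosome, strand) is an
independent Markov chain sharing one parameter set {π, A, μ_i, Σ_i} with
full symmetric 5×5 covariances; `concatenate=True` reproduces the literal
single-chain variant (one concatenated sequence). Fitting is scaled
forward–backward Baum–Welch; decoding is log-space Viterbi with ties broken
toward the lower state index. The per-K fit diagnostic is

    MSE = (1/(5·B)) Σ_n ||x_n − μ_{z_n}||²   over all B bins of all chains,

i.e. the mean squared residual per scalar dimension; for a genome with two
equal-length strands of N bins each this is exactly the (1/10N) two-strand
form. The Viterbi path (not posterior-weighted means) defines z_n in the
MSE.

Numerical choices, each of which matters in practice:

* **Initialisation.** Means come from K-means (k-means++, one run, seeded)
  on the pooled bins; covariances from the K-means clusters; the initial
  distribution is uniform. The transition matrix is seeded with
  self-transition 0.9 and random off-diagonal mass. Phosphorylation states
  persist over many consecutive bins, and seeding that persistence lets the
  dynamic likelihood separate parameter basins from the first iterations; a
  flat random transition matrix makes early EM behave like a static mixture,
  which systematically merges rare states under the dominant untranscribed
  cluster (`self_transition=0` restores the flat variant). An empty K-means
  cluster is re-seeded deterministically from the point farthest from its
  assigned centroid.
* **Restart selection.** `fit` launches 8 EM runs from independent K-means
  seeds (each capped at 100 iterations), keeps the run with the highest HMM
  log-likelihood and continues it to convergence. The static (mixture)
  likelihood cannot distinguish a merged-state optimum from the true one on
  these data, while the HMM likelihood separates them by hundreds of nats —
  but only near convergence, so selection happens at the end of each
  restart, not early.
* **Convergence.** Relative log-likelihood change < 1e-4, at most 300
  iterations.
* **Covariance guard.** M-step covariances have their eigenvalues floored at
  1e-4. The floor only engages for degenerate clusters; healthy covariances
  pass through unchanged, which keeps the EM update exact and the
  log-likelihood non-decreasing (an additive ridge measurably breaks
  monotonicity when a state is very tight, as the untranscribed state is on
  recovered data).
* **Model selection.** `select_n_states` fits each K with a fresh
  initialisation seeded `seed + K` and picks the elbow of the MSE curve as
  the K with the sharpest proportional collapse of marginal improvement:
  argmax of (d_in − d_out)/(d_in + d_out + ε) over successive improvements
  d. The raw second difference of any convex decreasing curve peaks at the
  smallest K and cannot locate a level-off; the normalised form targets the
  point where improvement collapses (on the synthetic study, by a factor
  ~50–100 after K = 8). Singleton sweeps return their only K; failed fits
  are skipped with a warning.
* **Cross-run state identity.** States of two fits are matched by the
  optimal assignment (Hungarian algorithm) on Euclidean distances between
  emission means; biological labels are assigned the same way against a
  reference signature set, leaving surplus reference labels unused when
  K < 8.

## Downstream analyses

Segmentations are run-length encodings of labelled Viterbi paths (BED6,
half-open, 20-nt multiples). State enrichment over a window set compares
observed state counts with expectation under the genome-wide state
frequencies; the expectation-weighted mean ratio is identically 1. Metagene
state profiles report per-offset state frequencies (summing to 1 wherever
any gene covers the offset) and fold-enrichments over the genome-wide
frequencies; the ten-bin mode assigns each gene's bins to ten equal-width
fractions. Metagene signal profiles average a track (or one mark of the
binned matrix) across single-nt anchors, flipping minus-strand anchors;
flanks running off a chromosome are truncated with count weighting. Two
normalisations are provided for signal profiles: scaling the track by its
maximum inside protein-coding genes longer than 500 nt (the default reading
of the per-experiment normalisation) or per-anchor-window maxima
(`per_gene_max`); per-experiment maximum normalisation can reasonably mean
either, so both are exposed.

Transition-position analysis takes, per gene, the initial TSS-anchored I1
run; its end is the I1-exit position and the first EE bin is the EE-entry.
Genes whose run reaches the annotated 3' end (or that never show EE) are
censored and excluded from medians, with the censoring fraction always
reported; genes with no I1 at the TSS are counted separately. Exon-1 splits
use < 100 nt vs >= 100 nt (the boundary value goes to the long group, which
a strict <100 / >100 pair of thresholds would leave unassigned), plus the
top expression quartile of intronless genes. Expression is the mean total-RNAPII density over the
transcript. Expression matching takes the top quartile of the reference
class and greedily pairs each reference gene (descending expression) with
its nearest unused candidate by log-expression. Class comparisons use the
two-sided tie-corrected normal-approximation rank-sum test per mark per
class pair with Bonferroni correction across all tests of one invocation
(factor = marks × pairs) at corrected P < 0.01; classes with fewer than two
genes are skipped with a warning.

Periodicity is measured on the boundary-anchored metagene with the per-lag
Pearson autocorrelation (both overlap segments re-centred per lag), which is
free of the finite-window taper bias of the raw estimate; the reported
period is the first local maximum beyond 40 nt, flagged unreliable below an
autocorrelation of 0.1, and flat profiles return no period.

## Reproducibility statistics

Per-state Jaccard indices J_i = |A_i ∩ B_i| / |A_i ∪ B_i| over the bin sets
assigned to state i, reported for the two strands separately and combined,
after optimal state matching when the paths come from independent fits.
Permutation P values use the add-one estimator over uniform permutations of
one path's bins, so the smallest attainable value with 1,000 permutations is
1/1001 ≈ 1e-3; states with zero exceedances are flagged as being at that
bound rather than given a smaller nominal value, since 1,000 permutations
cannot certify anything below it.
Multi-initialisation stability fits the model from n distinct seeds,
Viterbi-decodes each run, matches states pairwise and reports the mean ± sd
fraction of identically-assigned bins against the 1/K random baseline
(12.5% for K = 8).

## Synthetic data generator

The generator is the package's study system: a single ~110–580 kb
chromosome carrying mRNAs (log-normal lengths, median 1,500 nt), CUTs
(median 377 nt), SUTs (median 745 nt) and snoRNAs (median 600 nt), placed
with 500–1,000 nt intergenic gaps on random strands, all boundaries snapped
to the 20-nt bin grid so every bin has exactly one truth state. A quarter of
mRNAs carry one intron (exon 1 log-normal around 100 nt, intron around
300 nt). Expression is log-normal (median 10 crosslinked reads/nt), placing
per-base total RPM a few-fold above the pseudocount — the regime the
enrichment transform assumes.

**Reference emission model.** Eight states (I1, I2, EE, E1, E2, E3, L, N)
with means in [−1, +1] chosen to satisfy the qualitative orderings of the
learned emission matrix (I1/I2 carry the highest Ser5P with I2 also high in
Ser7P; EE has positive Tyr1/Ser2/Ser7 and negative Ser5/Thr4; E1 the highest
Thr4; L non-positive everywhere; N zero), with diagonal covariances 0.25·I
(N: 0.4·I, the broadest). Two constraints shaped the numbers: a minimum
pairwise mean distance of 1.36 (≈2.7σ), below which the states are not
reliably separable by any clustering of their own draws, and approximate
mass balance — the terminal L span is 8 bins and snoRNAs (state I2) get
appreciable genomic mass — because a state with ≪2% occupancy is nearly
free to merge away and the 8-state ground truth would not be identifiable
from its own data (the MSE curve acquires spurious elbows).

**State layout.** mRNA: I1 over bins [0, 8) (160 nt, ending at the
nucleosome-1 3' boundary), EE for 14 bins, the remaining interior split
evenly E1/E2/E3, L over the last 8 bins; intron-containing genes extend I1
to the 5' splice site. CUTs are all-I1, SUTs are I1 (15 bins) then EE,
snoRNAs all-I2, intergenic territory all-N. Spans tile every transcript
exactly for any length.

**Coverage.** Per-base sense counts are Poisson with rate
expression × depth × m(p), where m(p) multiplies a 5' boost (2.0 over the
first 150 nt decaying linearly to 1.0 at 500 nt — integrating to the
~46% density reduction between the +50..150 and +450..500 windows, inside
the 40–50% range typical of 5'-enriched polymerase maps), a nucleosome
modulation 1 + 0.3·cos(2π(p − centre)/150) with the first nucleosome at
[10, 160) from the TSS, and a 0.5 dip over the final
100 nt before the poly(A) site. A uniform Poisson background (2% of median
expression) covers both strands — the antisense floor.

**Phospho tracks.** One emission 5-vector e is drawn per bin when the truth
is generated, and all replicate tracks share it — replicates differ only in
Poisson count noise, which is what makes replicate enrichment correlations
exceed 0.9 as replicates of a single underlying phosphorylation landscape
should. Over transcribed bins the phospho RPM per base is
max(0, (total_RPM + 5)·2^e − 5), the exact inverse of the enrichment
transform, so the signal chain recovers e up to count noise and the zero
floor. Untranscribed territory carries only the nonspecific-IP background
floor: with no polymerase there is no phospho-specific signal to modulate,
and recovered intergenic enrichment concentrates tightly near 0, as real
pseudocount-shrunk data does. Consequently the drawn e of N bins is not
encoded in the tracks, and recovery statements (round-trip mean absolute
error < 0.15) apply to transcribed bins (total RPM ≥ 1).

**Read table.** Unique reads per gene are Poisson in expression × length;
exact duplicates (same start and barcode) are appended so duplicates form
the configured fraction of the final table; junction-spanning reads on
intron-containing genes are tagged ExEx/ExI/IEx in configured proportions.

**What the generator does not emulate.** Sequence content (no bases, no
mappability), crosslinking or antibody biases, transcription dynamics
(truth states are deterministic spans, not a Markov sample — the HMM's
transition structure is therefore mis-specified in a realistic direction),
overlapping or bidirectional transcription units, replicate batch effects,
and chromosome heterogeneity. Passing tests therefore demonstrate correct
computation and recoverability under a faithful noise model, not performance
on real libraries.

## Problem sizes

The test suite and the acceptance script run the model-selection study on
~64,000 bins (K = 3…12), the stability study on ~23,000 bins × 10
initialisations, the periodicity study on 500 genes, and the default
end-to-end pipeline on ~12,000 bins; all stochastic tests fix their seeds.

## Known limitations

The elbow criterion assumes the MSE curve levels off within the swept range;
a range ending before the true state count will pick an interior knee.
Permutation nulls permute bins independently, ignoring the segmentations'
autocorrelation, so they are anti-conservative for long-range structure.
The generator's truth switches I1 to EE at +160 nt; real libraries need not
match this, and the analysis code reports whatever the data contain. The CLI
`enrich` command normalises RPM by each track's own coverage sum when no
library size is supplied, which differs from read-count normalisation for
long reads.
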