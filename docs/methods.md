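# Methods

This note documents the models, defaults, and numerical choices behind
`coextime`, and what the synthetic-data validation does and does not
establish about real compendia.

## Normalization cascade

Input is a dense FPKM gene × sample matrix (missing entries are an
error, not imputed). The cascade is:

1. **Replicate averaging** — arithmetic mean of FPKM columns within each
   replicate group, producing one column per group (RNAseq1).
   Averaging precedes the log transform, so the mean is taken on the
   expression scale.
2. **log2 transform** — `log2(x + 1)` with a pseudo-count of one
   (RNAseq2). The pseudo-count bounds the transform at zero but
   flattens oscillation troughs for genes whose FPKM dips near zero; see
   the marker-selection floor below.
3. **Quantile normalization** — every column is forced onto the common
   distribution defined by the across-column mean of sorted values
   (RNAseq3). Within-column ties all receive the mean of the reference
   values their tied ranks span (mid-rank policy). This tie policy is a
   documented choice; rank order within a column is otherwise preserved
   exactly. A single-column matrix is a warning no-op.
4. **Mean-centering** — subtract each gene's mean across columns
   (RNAseq4), recording the per-gene mean `m_g` and standard deviation
   `s_g`. All-zero genes are carried through (they center to zero) and
   flagged.

**Abridged path.** An external FPKM dataset is centered as
`log2(x + 1) − m_g` using the reference statistics, skipping both
replicate structure and the quantile step. It tracks the full cascade
closely (correlation above 0.9 in the tests) but is not identical —
and it is deliberately free of one quantile-step artifact, discussed
under synchronization below.

Mean-centering removes per-gene baselines exactly but **cannot** remove
gene-by-experiment batch interactions; those remain in RNAseq4 and are
what makes within-experiment samples correlate after centering. The
pipeline does not attempt batch correction.

## Correlation and ordering

Pearson correlations are computed from standardized rows blockwise
(`block_size` rows of the left factor at a time), so genome-scale
matrices stream through bounded memory; the result is independent of the
block size to floating-point reduction order (~1e-15). Zero-variance
rows have undefined correlations; they are reported as 0 and flagged so
downstream rankings stay total.

Three display orderings are provided: complete-linkage hierarchical
clustering on `1 − r` (leaf order traverses each dendrogram node
lowest-original-index-first, which keeps clusters contiguous and makes
the order deterministic under ties), angular order of the two leading
eigenvectors (AOE; eigenvector signs are fixed so the largest-magnitude
component is positive, ties broken by original index), and first
principal-component loadings (FPC). When the off-diagonal is entirely
zero there is no structure to order by and the original order is
returned. On correlation matrices of the form
`r_ij = cos(2π(φ_i − φ_j)/24)` the two leading eigenvectors span the
cosine/sine pair, so the AOE order walks the phase circle — the basis
for the phase-versus-order analysis.

The association between a display ordering and diurnal phases is scored
with the Fisher–Lee circular–circular correlation, treating the order
rank as a position on a circle (`2π·rank/n`). A monotone phase-sorted
order scores 1 by construction; a permutation null (seeded) provides the
reference distribution for observed orderings.

## Mutual-rank networks

For each gene the other genes are ranked by correlation (rank 1 = the
strongest partner; mid-ranks for ties; the self-pair is excluded before
ranking so a reciprocal best pair attains MR = 1 — an `include_self`
flag reproduces the alternative convention in which every rank shifts by
one). The mutual rank `MR(a,b) = sqrt(rank_a→b · rank_b→a)` is computed
by elementwise multiplication of the rank matrix with its transpose and
is exactly symmetric. Edge weights `N_x = exp(−(MR−1)/x)` with decays
`x = 5, 10, 25, 50, 100` define levels N1–N5 after thresholding at
`N_x ≥ 0.01`, i.e. admitting `MR ≤ 1 + x·ln(100)`. Weights are monotone
in MR, so the level edge sets are nested (N1 ⊆ … ⊆ N5) and so are
per-gene cohorts, which are checked rather than assumed.

The *anti* direction ranks un-negated correlations (rank 1 = most
negative partner) and stops at cohort extraction: module detection on
anti-correlation weights is out of scope by design.

**Level choice.** The decay should match the gene count. A pair's MR can
only be small if both reciprocal ranks are; with G genes, the admission
cutoff `1 + x·ln(100)` must sit well below G for the level to be
selective. N3 (MR ≤ 116) suits genome-scale matrices; on a few hundred
genes it admits a large fraction of all pairs and the greedy module
search degenerates to one giant candidate, so N1–N2 are appropriate
there. Relatedly, a k-gene module's co-members necessarily occupy ranks
1..k−1, so at N1 (x = 5) even a perfectly recovered 20-gene module has a
mean edge weight near 0.28 — below the default density floor of 0.30.
Module detection for 20-gene modules in a 2,000-gene compendium is
therefore benchmarked at N3.

## Module detection

Cohesiveness of a node set V on a weighted graph is
`f(V) = w_in / (w_in + w_bound + p·|V|)` with penalty `p` accounting for
unobserved connections. Candidates grow greedily from seed nodes (the
unused node of highest weighted degree first, ties by node id): at each
step the single addition of a boundary node or removal of a member that
most increases f(V) is applied; growth stops when no step improves f by
more than 1e-12 (strict improvement guarantees termination). Incremental
bookkeeping of each node's edge weight into V makes a step O(degree).
Candidates with overlap score `ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8` are
merged (union) to a fixed point in a deterministic order (descending
cohesiveness, then insertion index).

Significance is a one-sided Mann–Whitney U test that internal edge
weights exceed boundary edge weights. The U statistic uses mid-ranks;
the null is the exact tie-free permutation distribution (full
enumeration) when both groups have ≤ 8 edges, the normal approximation
with continuity correction otherwise. Under this convention complete
3-vs-3 separation gives p = 1/C(6,3) = 0.05 and an all-tied comparison
gives p = 0.5 by symmetry. A module with no boundary edges is perfectly
separated; we report the exact p against a single zero-weight
pseudo-boundary edge, `1/(n_in + 1)`, so an isolated 5-clique
(p = 1/11) passes the 0.1 cutoff while an isolated triangle (p = 1/4)
does not. Retention requires size ≥ 3, weighted density ≥ 0.3, and
raw p ≤ 0.1 (no multiplicity correction) — the published defaults of the
algorithm family, all configurable.

## Molecular timetable

Markers are chosen per left-closed phase bin ([b, b+width), dawn = 0 h,
bins partitioning [0, 24)): the `per_bin` genes with the lowest
rhythmicity q-value, ties broken by gene id; short bins take all
available genes and are flagged. Both the 0.5-h × 20 (960 markers) and
1-h × 20 (480 markers) configurations are supported. An optional
expression floor (`min_mean`, log2 units) excludes lowly expressed
candidates, whose oscillation troughs the `log2(x+1)` pseudo-count
flattens; 5.0 (≈ 31 FPKM) is used in the validation runs.

For each sample, markers are averaged within bins on the centered scale;
the bin with maximal mean gives the internal time (bin midpoint; ties to
the earliest bin), the minimal bin the trough, `max − min` the
amplitude, and the circular distance between peak and trough midpoints
the separation. An optional `scale_sd` flag divides each marker by its
reference standard deviation first. Without it, bins dominated by
high-amplitude genes weigh more; with it every bin contributes
comparably, which matters because the cosine is flat near its extremes —
the mean bin-level readout difference between the peak bin and its
neighbor is only `Ā(1 − cos(2π·width/24)) ≈ 0.034·Ā` for 1-h bins, so
modest per-bin heterogeneity moves the argmax. The reference protocol
subtracts the mean only, hence `scale_sd` defaults to off.

Synchronization is reported as
`sync% = 100 · A_sample / mean(A_reference)`, capped at 100, with the
reference amplitudes taken from designated entrained (LD time-course)
samples; the cosine term scales linearly with the synchronized fraction,
making relative amplitude a direct estimator. Two systematic effects
matter here. First, quantile normalization forces all samples onto one
distribution, which compresses the dispersion of strongly oscillating
(entrained) samples and stretches weakly oscillating ones — inflating
sync estimates by roughly 5–8 points in the validation conditions. The
abridged centering path has no quantile step and is the recommended
input for synchronization readouts; the validation uses it. Second,
additive noise inflates `max − min` for both numerator and denominator,
biasing the ratio upward by a few points. The estimates at a true 50%
synchronization land at 54–58% under the validation conditions.

Cross-species transfer restricts a target FPKM matrix to genes with a
strict one-to-one ortholog whose reference gene is rhythmic, centers
them with the *reference* ortholog's mean, renames rows to the reference
ids so the reference marker set applies directly, and inherits phases.
Ortholog amplitudes in the target species are independent of the
reference (the generator redraws them), which is the dominant noise
source in transferred timetables.

## Synthetic data generator

On the log2 scale, gene g in sample s is

    x_gs = b_g + τ·u_{g,e(s)} + λ·Σ_m L_gm f_m(s)
           + A_g·σ_s·cos(2π(t_s − φ_g)/24) + ε·z_gs,

exponentiated to FPKM. Defaults (one choice, used throughout):
baselines `b_g ~ N(5, 2²)` log2 FPKM; batch offsets `u_{g,e} ~ N(0, 1)`
per gene and experiment with scale τ = 1 (batch offsets must vary by
gene — a gene-shared offset is invisible to gene-wise correlation);
5 planted 20-gene modules with unit loadings, factor `f_m ~ N(0,1)`
drawn per replicate group (so replicate averaging cannot destroy planted
structure) and strength λ = 2; rhythmic fraction 0.8 (entrained algal
transcriptomes are predominantly rhythmic) with amplitudes
`A_g ~ U(1, 3)` log2 units; module members share a module phase with 1-h
jitter, other rhythmic genes have uniform phases; noise ε = 0.5. The
default design is 12 experiments × 10 samples in replicate pairs. The
first experiment is an entrained LD time course (σ = 1, evenly spaced
times); the remaining constant-light experiments draw a per-experiment
synchronization fraction from U(0.21, 0.96) — the range reported for
real constant-light cultures — unless a scalar is given. All randomness
flows through a single seeded generator in a fixed draw order, so a seed
determines the output bit for bit.

Companion generators produce (a) two overlapping rhythmicity reference
tables whose study-B phases are stored on a dawn convention offset by
12 h, with exact category counts so merged sizes are deterministic, plus
the underlying dense time course; and (b) a second species with a
one-to-one ortholog subset, optional phase offset Δ, and Poisson counts
with gene lengths and a fixed library size, inverted by the counts→FPKM
conversion (`FPKM = counts·10⁹/(L·N)`, N = column sum).

**What the generator does not emulate:** read-level sampling,
isoform-level length effects, dispersion–mean relationships,
non-sinusoidal waveforms, drifting (non-24-h) periods, and correlated
batch effects across experiments from the same lab. Passing validation
therefore demonstrates correctness of the machinery under the stated
statistical structure, not performance on any particular real compendium.

## Validation configurations and observed behavior

The acceptance suite fixes seeds and uses these study conditions:

- **Module recovery:** 2,000 genes × 120 samples, 12 experiments, five
  planted 20-gene modules (phases 8, 2, 14, 20, 5 h); detection at N3
  recovers every planted module with Jaccard 1.0.
- **Anti-correlation cohort phase:** same design but fully entrained
  with evenly spaced collection times. With random collection times the
  empirical time distribution's harmonics bias the apparent antiphase
  direction by up to ~2 h (the most anti-correlated phase is then no
  longer exactly 12 h away in finite samples); the balanced design
  removes that bias, and the cohort's circular mean sits 12 ± 1 h from
  the module phase.
- **Timetable:** 100 fully synchronized samples; 1-h bins, 20 markers
  per bin, expression floor 5.0, sd-scaling on; the median circular
  error of internal time is ≈ 0.8 h (within one bin). Recovery degrades
  monotonically as σ drops (checked at 1, 0.5, 0.25).
- **Synchronization:** abridged centering; cultures at σ = 0.5 read out
  at 54–58%; fully asynchronous cultures fall below the 5th percentile
  of entrained amplitudes.
- **Peak–trough separation:** the 12 h ± 1 bin geometry is verified at
  τ = 0.1, ε = 0.2 with no planted modules among the markers. This is a
  deliberate isolation of the cosine geometry: gene-by-experiment batch
  offsets survive centering and contribute per-bin readout noise of
  about `0.55·τ/√per_bin` after sd-scaling, which at τ = 1 exceeds the
  0.034·Ā adjacent-bin deficit and caps the within-one-bin fraction near
  65–80%. Batch variance is thus a real limitation of peak/trough
  localization (less so of the peak itself, and the internal-time and
  synchronization checks above pass at τ = 1).

## Known limitations

- Quantile normalization homogenizes per-sample dispersion; amplitude
  ratios computed from RNAseq4 overestimate synchronization (use the
  abridged path for sync).
- Mean-centering leaves gene×experiment batch interactions in place;
  they dominate fine-grained timetable readout noise.
- The greedy module search is a local optimizer; on graphs whose decay
  level is too permissive for the gene count it can return one giant
  candidate (choose the level per the rule above).
- Module p-values are raw (no multiplicity correction), matching the
  retain-if-p ≤ 0.1 convention; interpret module counts accordingly.
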