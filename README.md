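# coextime

Mutual-rank co-expression networks and molecular-timetable phase
estimation for bulk RNA-seq compendia.

## The problem

Large collections of heterogeneous RNA-seq experiments — hundreds of
samples from dozens of labs, conditions, and light regimes — are a rich
substrate for *guilt-by-association* analysis: genes that rise and fall
together across many perturbations tend to work together. But such
compendia come with strong per-experiment batch structure, and in
photosynthetic microbes (the motivating system is the green alga
*Chlamydomonas reinhardtii* and its relatives) a second pervasive signal:
diurnal rhythmicity. Under light–dark entrainment most of the
transcriptome oscillates with gene-specific peak phases, and cultures
sampled in "constant light" often retain partial synchrony.

`coextime` packages the analysis chain for this setting:

1. **Normalization cascade.** From an FPKM gene × sample table:
   replicate averaging → `log2(x+1)` → quantile normalization across
   samples → per-gene mean-centering. All four stages are retained
   (RNAseq1–RNAseq4), and the per-gene means/SDs of the reference allow
   external datasets to be placed on the same centered scale without
   re-running the cascade.
2. **Mutual-rank networks.** All-pairs Pearson correlation *r*; per-gene
   neighbor ranks; the symmetric mutual rank
   `MR(a,b) = sqrt(rank_a→b · rank_b→a)`; and exponential-decay edge
   weights `N_x = exp(−(MR−1)/x)` for `x ∈ {5, 10, 25, 50, 100}`
   (network levels N1–N5), keeping edges with `N_x ≥ 0.01`. Ranking
   un-negated correlations instead gives *anti-correlation* cohorts.
3. **Module detection.** A from-scratch implementation of the greedy
   overlapping graph clustering popularised by ClusterONE: grow node sets
   that maximize the cohesiveness
   `f(V) = w_in / (w_in + w_bound + p·|V|)`, merge candidates with
   overlap `ω(A,B) = |A∩B|²/(|A||B|) ≥ 0.8`, and keep modules passing
   size, density, and one-sided Mann–Whitney significance (`p ≤ 0.1`)
   filters.
4. **Diurnal phase analysis and the molecular timetable.** Merge
   rhythmicity references onto a common dawn convention, summarize phase
   distributions with circular statistics, and estimate the *internal
   diurnal time* of a single transcriptome snapshot: average the centered
   expression of phase-binned marker genes and read off the peak bin.
   The peak-to-trough amplitude, relative to fully entrained reference
   samples, estimates the culture's synchronization percentage. A strict
   one-to-one ortholog map transfers phases and reference means to a
   second species, so the same timetable applies across algae.
5. **Synthetic compendia with ground truth.** A seeded generator plants
   batch offsets, co-expression modules, gene-specific cosine rhythms and
   per-sample synchronization fractions, so every stage above can be
   validated against known truth.

## Worked example

```python
import pandas as pd
import coextime as ct

cfg = ct.SimConfig(seed=42, n_genes=500, n_experiments=6,
                   samples_per_experiment=8, replicates_per_group=2,
                   n_modules=3, module_size=15,
                   module_phases=(8.0, 20.0, 2.0))
mat, meta, truth = ct.simulate_dataset(cfg)

cascade = ct.normalize_cascade(mat, meta)          # RNAseq1..4 + stats
corr = ct.pcc_matrix(cascade.rnaseq4, axis="gene")
net = ct.build_networks(ct.mutual_rank(ct.rank_matrix(corr, "co")))
modules = ct.find_modules(net.graph("N2"))

ptab = ct.PhaseTable(pd.DataFrame(
    {"phase": truth.phase[truth.rhythmic_genes()], "q": 0.0}), source="truth")
for m in modules[:3]:
    s = ct.module_phase_summary(m.sorted_members(), ptab)
    print(f"size={m.size}  cohesiveness={m.cohesiveness:.3f}  "
          f"p={m.pvalue:.2e}  mean_phase={s.mean_phase:.1f} h")
```

prints

```
size=15  cohesiveness=0.564  p=1.84e-47  mean_phase=7.9 h
size=15  cohesiveness=0.535  p=1.01e-51  mean_phase=20.6 h
size=15  cohesiveness=0.503  p=7.60e-47  mean_phase=1.5 h
```

The three retained modules are exactly the three planted 15-gene modules,
and their circular mean phases (7.9 h, 20.6 h, 1.5 h after dawn) recover
the planted phases (8, 20, 2). On the same dataset the sample-level
correlation summary shows the batch structure the simulation plants:
mean within-experiment PCC 0.41 versus −0.11 between experiments.

The network level should match the gene count: the decay `x` admits
pairs with `MR ≤ 1 + x·ln(100)`, so N3 (`MR ≤ 116`) suits genome-scale
matrices (thousands of genes), while N1–N2 are appropriate for small
gene sets.

## Command line

The same stages are scriptable through the `coextime` console command:

```bash
coextime simulate --out sim/ --seed 1 --genes 500
coextime run --expression sim/expression.tsv --metadata sim/metadata.tsv --out run/
coextime timetable --expression run/rnaseq4.tsv --phases phases.tsv \
    --stats run/normalization_stats.tsv --out tt/
```

`run` executes normalize → correlate → mutual-rank networks (co and
anti) → module detection, writing each stage's artifacts plus the
resolved configuration; identical inputs and seed reproduce every
artifact byte for byte.

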