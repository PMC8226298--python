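"""Synthetic expression compendia with known ground truth.

The generator emulates the statistical structure of a multi-experiment
bulk RNA-seq compendium: per-experiment batch offsets (samples of an
experiment resemble each other far more than samples of other
experiments), planted co-expression modules driven by shared latent
factors, gene-specific diurnal cosine signals (most nuclear genes are
rhythmic under entrainment), a per-sample synchronization fraction that
scales the rhythmic signal (bulk cultures in constant light retain
partial synchrony), replicate structure, and multiplicative noise.

On the log2 scale, gene g in sample s is

    x_gs = b_g + tau * u_g,e(s) + lambda * sum_m L_gm f_m(s)
           + A_g * sigma_s * cos(2*pi*(t_s - phi_g)/24) + eps * z_gs

exponentiated to FPKM (2**x), so every effect is multiplicative on the
expression scale, matching how the downstream normalization (log2 then
centering) operates.  Members of a replicate group share the module
factors f_m, collection time t_s and synchronization sigma_s, but draw
independent noise.  All randomness flows through a single seeded
generator with a fixed draw order, so a seed fully determines the output.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountsTable, ExpressionMatrix, SampleMetadata
from .rhythm import OrthologMap, wrap_phase


@dataclass
class SimConfig:
    """Study-design parameters of a simulated compendium.

    Defaults describe a desk-scale compendium: 2,000 genes in 120 samples
    from 12 experiments (replicate pairs), 5 planted modules of 20 genes,
    80% of genes rhythmic, and per-culture synchronization drawn from
    21–96% for constant-light experiments while the designated light–dark
    time-course experiment is fully entrained.
    """

    seed: int
    n_genes: int = 2000
    n_experiments: int = 12
    samples_per_experiment: int = 10
    replicates_per_group: int = 2
    n_modules: int = 5
    module_size: int = 20
    module_strength: float = 2.0       # lambda, log2 units per factor sd
    rhythmic_fraction: float = 0.8
    amplitude_range: tuple[float, float] = (1.0, 3.0)  # A_g, log2 units
    module_phases: tuple[float, ...] | None = None
    module_phase_jitter: float = 1.0   # h, sd of member phases around the module phase
    n_diurnal_experiments: int = 1     # LD experiments: sigma = 1, evenly spaced times
    sync_fraction: float | tuple[float, float] = (0.21, 0.96)
    batch_scale: float = 1.0           # tau
    noise_scale: float = 0.5           # eps
    baseline_mean: float = 5.0         # b_g ~ N(mean, sd), log2 FPKM
    baseline_sd: float = 2.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.module_size < 3:
            raise ValueError("module sizes must be >= 3")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit into the gene set")
        if not 0 <= self.rhythmic_fraction <= 1:
            raise ValueError("rhythmic fraction must lie in [0, 1]")
        if self.samples_per_experiment % self.replicates_per_group:
            raise ValueError("samples per experiment must divide into replicate groups")
        if isinstance(self.sync_fraction, tuple):
            lo, hi = self.sync_fraction
            ok = 0 <= lo <= hi <= 1
        else:
            ok = 0 <= self.sync_fraction <= 1
        if not ok:
            raise ValueError("synchronization fractions must lie in [0, 1]")
        if self.n_diurnal_experiments > self.n_experiments:
            raise ValueError("more diurnal experiments than experiments")
        if self.module_phases is not None and len(self.module_phases) != self.n_modules:
            raise ValueError("module_phases must list one phase per module")

    @property
    def groups_per_experiment(self) -> int:
        return self.samples_per_experiment // self.replicates_per_group

    @property
    def n_samples(self) -> int:
        return self.n_experiments * self.samples_per_experiment


@dataclass
class GroundTruth:
    """Everything the generator knows: planted modules, per-gene phase and
    amplitude, per-sample time and synchronization, batch offsets."""

    module_of: pd.Series          # gene -> module index, -1 outside modules
    module_phase: np.ndarray      # per-module mean phase (h)
    phase: pd.Series              # gene -> phi (h), NaN when non-rhythmic
    amplitude: pd.Series          # gene -> A_g (0 when non-rhythmic)
    baselines: pd.Series
    sample_time: pd.Series        # sample -> t (h)
    sample_sync: pd.Series        # sample -> sigma in [0, 1]
    batch_offsets: pd.DataFrame   # gene x experiment (log2 units, scaled)

    def module_members(self, m: int) -> list[str]:
        return list(self.module_of.index[self.module_of == m])

    def rhythmic_genes(self) -> pd.Index:
        return self.phase.index[self.phase.notna()]


def _gene_ids(n: int, prefix: str = "g") -> pd.Index:
    width = len(str(n - 1)) if n > 1 else 1
    return pd.Index([f"{prefix}{i:0{width}d}" for i in range(n)], name="gene")


def simulate_dataset(cfg: SimConfig) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Generate an FPKM compendium, its sample metadata and the ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G, E = cfg.n_genes, cfg.n_experiments
    gpe = cfg.groups_per_experiment
    reps = cfg.replicates_per_group
    genes = _gene_ids(G)

    # 1. baselines
    b = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=G)
    # 2. module membership: a random permutation carved into blocks
    perm = rng.permutation(G)
    module_of = np.full(G, -1, dtype=int)
    loadings = np.zeros((G, cfg.n_modules))
    for m in range(cfg.n_modules):
        idx = perm[m * cfg.module_size:(m + 1) * cfg.module_size]
        module_of[idx] = m
        loadings[idx, m] = 1.0
    # 3. module phases
    if cfg.module_phases is not None:
        module_phase = np.asarray(cfg.module_phases, dtype=float)
    else:
        module_phase = rng.uniform(0.0, 24.0, size=cfg.n_modules)
    # 4. rhythmic genes (exact count) and per-gene phases
    n_rhythmic = int(round(cfg.rhythmic_fraction * G))
    rhythmic = np.zeros(G, dtype=bool)
    rhythmic[rng.permutation(G)[:n_rhythmic]] = True
    phase = np.full(G, np.nan)
    uniform_phases = rng.uniform(0.0, 24.0, size=G)
    jitter = rng.normal(0.0, cfg.module_phase_jitter, size=G)
    for g in range(G):
        if not rhythmic[g]:
            continue
        m = module_of[g]
        phase[g] = wrap_phase(module_phase[m] + jitter[g]) if m >= 0 else uniform_phases[g]
    # 5. amplitudes
    amp = np.where(
        rhythmic, rng.uniform(*cfg.amplitude_range, size=G), 0.0
    )
    # 6. batch offsets
    batch = cfg.batch_scale * rng.normal(0.0, 1.0, size=(G, E))

    # 7. per-experiment design: replicate groups, times, synchronization
    exp_ids = [f"E{e + 1:02d}" for e in range(E)]
    group_ids: list[str] = []
    sample_ids: list[str] = []
    sample_group: list[int] = []
    sample_exp: list[int] = []
    group_time = np.empty(E * gpe)
    group_sync = np.empty(E * gpe)
    light = []
    for e in range(E):
        diurnal = e < cfg.n_diurnal_experiments
        if diurnal:
            sigma = 1.0
            times = 24.0 * np.arange(gpe) / gpe
        else:
            if isinstance(cfg.sync_fraction, tuple):
                sigma = rng.uniform(*cfg.sync_fraction)
            else:
                sigma = float(cfg.sync_fraction)
            times = rng.uniform(0.0, 24.0, size=gpe)
        for k in range(gpe):
            gidx = e * gpe + k
            gid = f"{exp_ids[e]}g{k + 1:02d}"
            group_ids.append(gid)
            group_time[gidx] = times[k]
            group_sync[gidx] = sigma
            for r in range(reps):
                sample_ids.append(f"{gid}r{r + 1}")
                sample_group.append(gidx)
                sample_exp.append(e)
        light.extend(["LD" if diurnal else "LL"] * cfg.samples_per_experiment)

    # 8. module factors per replicate group; 9. per-sample noise
    factors = rng.normal(0.0, 1.0, size=(cfg.n_modules, E * gpe))
    noise = rng.normal(0.0, 1.0, size=(G, len(sample_ids)))

    sample_group = np.asarray(sample_group)
    sample_exp = np.asarray(sample_exp)
    t_s = group_time[sample_group]
    sigma_s = group_sync[sample_group]
    phase_safe = np.where(np.isnan(phase), 0.0, phase)
    cosine = np.cos(2.0 * np.pi * (t_s[None, :] - phase_safe[:, None]) / 24.0)
    x = (
        b[:, None]
        + batch[:, sample_exp]
        + cfg.module_strength * (loadings @ factors[:, sample_group])
        + amp[:, None] * sigma_s[None, :] * cosine
        + cfg.noise_scale * noise
    )
    fpkm = np.exp2(x)

    mat = ExpressionMatrix(
        pd.DataFrame(fpkm, index=genes, columns=pd.Index(sample_ids, name="sample")),
        stage="FPKM",
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "experiment": [exp_ids[e] for e in sample_exp],
                "replicate_group": [group_ids[g] for g in sample_group],
                "light_regime": light,
                "time": t_s,
                "library": "polyA",
            },
            index=pd.Index(sample_ids, name="sample"),
        )
    )
    truth = GroundTruth(
        module_of=pd.Series(module_of, index=genes),
        module_phase=module_phase,
        phase=pd.Series(phase, index=genes),
        amplitude=pd.Series(amp, index=genes),
        baselines=pd.Series(b, index=genes),
        sample_time=pd.Series(t_s, index=mat.samples),
        sample_sync=pd.Series(sigma_s, index=mat.samples),
        batch_offsets=pd.DataFrame(batch, index=genes, columns=exp_ids),
    )
    return mat, meta, truth


# ---------------------------------------------------------------------------
# diurnal reference studies


@dataclass
class ReferenceConfig:
    """Two overlapping diurnal reference studies plus a dense time course.

    ``frac_both`` of the genes are rhythmic in both studies, ``frac_only_a``
    and ``frac_only_b`` in exactly one; study B stores its phases on a dawn
    convention offset by ``convention_offset`` hours (so downstream merging
    must shift them back).
    """

    seed: int
    n_genes: int = 1000
    frac_both: float = 0.6
    frac_only_a: float = 0.15
    frac_only_b: float = 0.15
    convention_offset: float = 12.0
    n_timepoints: int = 24
    n_replicates: int = 2
    amplitude_range: tuple[float, float] = (1.0, 3.0)
    noise_scale: float = 0.3
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0

    def validate(self) -> None:
        if self.frac_both + self.frac_only_a + self.frac_only_b > 1 + 1e-12:
            raise ValueError("rhythmic fractions must sum to <= 1")
        for f in (self.frac_both, self.frac_only_a, self.frac_only_b):
            if f < 0:
                raise ValueError("fractions must be >= 0")


@dataclass
class DiurnalReferences:
    """Output bundle of :func:`simulate_diurnal_references`."""

    ref_a: "PhaseTable"
    ref_b: "PhaseTable"
    timecourse: ExpressionMatrix
    metadata: SampleMetadata
    phase: pd.Series  # true phase per gene (NaN when never rhythmic)


def simulate_diurnal_references(cfg: ReferenceConfig) -> DiurnalReferences:
    """Two phase tables with q-values plus the underlying diurnal time course.

    Genes rhythmic in both studies carry equal wrapped phases once the
    study-B convention shift is undone.  Category sizes are exact (rounded
    counts over a seeded permutation), so the merged-table size is
    deterministic.
    """
    from .rhythm import PhaseTable  # local import to avoid cycle at module load

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    genes = _gene_ids(G)
    phase = rng.uniform(0.0, 24.0, size=G)
    b = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=G)
    amp = rng.uniform(*cfg.amplitude_range, size=G)
    n_both = int(round(cfg.frac_both * G))
    n_a = int(round(cfg.frac_only_a * G))
    n_b = int(round(cfg.frac_only_b * G))
    perm = rng.permutation(G)
    both = perm[:n_both]
    only_a = perm[n_both:n_both + n_a]
    only_b = perm[n_both + n_a:n_both + n_a + n_b]
    in_a = np.sort(np.concatenate([both, only_a]))
    in_b = np.sort(np.concatenate([both, only_b]))
    q_a = rng.uniform(0.0, 0.05, size=in_a.size)
    q_b = rng.uniform(0.0, 0.05, size=in_b.size)

    ref_a = PhaseTable(
        pd.DataFrame({"phase": phase[in_a], "q": q_a}, index=genes[in_a]),
        source="studyA",
    )
    ref_b = PhaseTable(
        pd.DataFrame(
            {"phase": wrap_phase(phase[in_b] - cfg.convention_offset), "q": q_b},
            index=genes[in_b],
        ),
        source="studyB",
    )

    rhythmic = np.zeros(G, dtype=bool)
    rhythmic[np.concatenate([both, only_a, only_b]).astype(int)] = True
    amp = np.where(rhythmic, amp, 0.0)
    times = np.repeat(24.0 * np.arange(cfg.n_timepoints) / cfg.n_timepoints,
                      cfg.n_replicates)
    noise = rng.normal(0.0, 1.0, size=(G, times.size))
    x = (
        b[:, None]
        + amp[:, None] * np.cos(2.0 * np.pi * (times[None, :] - phase[:, None]) / 24.0)
        + cfg.noise_scale * noise
    )
    sample_ids = [
        f"TC_t{int(round(t * 10)):03d}_r{r + 1}"
        for t in 24.0 * np.arange(cfg.n_timepoints) / cfg.n_timepoints
        for r in range(cfg.n_replicates)
    ]
    mat = ExpressionMatrix(
        pd.DataFrame(np.exp2(x), index=genes, columns=pd.Index(sample_ids, name="sample")),
        stage="FPKM",
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "experiment": "timecourse",
                "replicate_group": [s.rsplit("_r", 1)[0] for s in sample_ids],
                "light_regime": "LD",
                "time": times,
                "library": "polyA",
            },
            index=pd.Index(sample_ids, name="sample"),
        )
    )
    true_phase = pd.Series(np.where(rhythmic, phase, np.nan), index=genes)
    return DiurnalReferences(ref_a=ref_a, ref_b=ref_b, timecourse=mat,
                             metadata=meta, phase=true_phase)


# ---------------------------------------------------------------------------
# second species with one-to-one orthologs


@dataclass
class OrthologConfig:
    """A second species sampled at fixed times, with a fraction of genes
    mapped one-to-one to the reference and inheriting its phases (plus an
    optional phase offset)."""

    seed: int
    mapping_fraction: float = 0.8
    phase_offset: float = 0.0          # Delta, h
    sample_times: tuple[float, ...] = (8.0,)
    sync: float = 1.0
    library_size: int = 5_000_000
    length_range: tuple[int, int] = (500, 5000)
    amplitude_range: tuple[float, float] = (1.0, 3.0)
    noise_scale: float = 0.3

    def validate(self) -> None:
        if not 0 < self.mapping_fraction <= 1:
            raise ValueError("mapping fraction must lie in (0, 1]")
        if not 0 <= self.sync <= 1:
            raise ValueError("sync must lie in [0, 1]")


@dataclass
class OrthologSpecies:
    """Output bundle of :func:`simulate_ortholog_species`."""

    counts: CountsTable
    ortholog_map: OrthologMap
    sample_times: pd.Series


def simulate_ortholog_species(
    reference_phase: pd.Series,
    reference_baselines: pd.Series,
    cfg: OrthologConfig,
) -> OrthologSpecies:
    """Counts for a second species whose orthologs inherit reference phases.

    ``reference_phase`` is the per-gene true phase (NaN = non-rhythmic);
    mapped rhythmic genes oscillate at ``phase + phase_offset``.  Counts
    are Poisson draws around ``FPKM * L * N / 1e9`` with gene lengths and
    a fixed library size, so :func:`coextime.io.counts_to_fpkm` inverts
    the scaling up to count noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ref_genes = reference_phase.index
    G = len(ref_genes)
    n_map = int(round(cfg.mapping_fraction * G))
    mapped_idx = np.sort(rng.permutation(G)[:n_map])
    mapped_ref = ref_genes[mapped_idx]
    target_ids = pd.Index([f"T_{g}" for g in mapped_ref], name="gene")

    phase = reference_phase.to_numpy(dtype=float)[mapped_idx]
    rhythmic = np.isfinite(phase)
    phase_t = np.where(rhythmic, wrap_phase(np.where(rhythmic, phase, 0.0) + cfg.phase_offset), 0.0)
    amp = np.where(rhythmic, rng.uniform(*cfg.amplitude_range, size=n_map), 0.0)
    b = reference_baselines.to_numpy(dtype=float)[mapped_idx]
    lengths = rng.integers(cfg.length_range[0], cfg.length_range[1] + 1, size=n_map)
    times = np.asarray(cfg.sample_times, dtype=float)
    noise = rng.normal(0.0, 1.0, size=(n_map, times.size))
    x = (
        b[:, None]
        + cfg.sync * amp[:, None]
        * np.cos(2.0 * np.pi * (times[None, :] - phase_t[:, None]) / 24.0)
        + cfg.noise_scale * noise
    )
    fpkm = np.exp2(x)
    mu = fpkm * lengths[:, None] * cfg.library_size / 1e9
    counts = rng.poisson(mu)
    sample_ids = pd.Index([f"V{i + 1:02d}" for i in range(times.size)], name="sample")
    table = CountsTable(
        values=pd.DataFrame(counts, index=target_ids, columns=sample_ids),
        lengths=pd.Series(lengths, index=target_ids, dtype=float),
    )
    omap = OrthologMap(pd.DataFrame({"reference": mapped_ref, "target": target_ids}))
    return OrthologSpecies(
        counts=table,
        ortholog_map=omap,
        sample_times=pd.Series(times, index=sample_ids),
    )
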