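import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coextime as ct
from coextime.normalize import NormalizationStats
from conftest import truth_phase_table


def _phase_table(phases, q=None, source="t"):
    phases = pd.Series(phases)
    q = pd.Series(0.01, index=phases.index) if q is None else pd.Series(q)
    return ct.PhaseTable(pd.DataFrame({"phase": phases, "q": q}), source=source)


def _stats(genes, mean=6.0, sd=1.0):
    idx = pd.Index(list(genes))
    return NormalizationStats(
        mean=pd.Series(mean, index=idx), sd=pd.Series(sd, index=idx),
        all_zero=pd.Index([]),
    )


class TestWrapPhase:
    @pytest.mark.parametrize("raw, expected", [(26.0, 2.0), (24.0, 0.0), (-2.0, 22.0)])
    def test_examples(self, raw, expected):
        assert ct.wrap_phase(raw) == expected

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-1000, 1000))
    def test_idempotent_and_24_periodic(self, x):
        w = ct.wrap_phase(x)
        assert 0 <= w < 24
        assert ct.wrap_phase(w) == w
        assert ct.wrap_phase(x + 24) == pytest.approx(w, abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ct.wrap_phase(float("nan"))


class TestMergePhaseReferences:
    def test_one_sided_genes_dropped_and_shift_applied(self):
        ref_a = _phase_table({"g1": 4.0, "g2": 10.0}, source="A")
        ref_b = _phase_table({"g1": 16.0, "g3": 1.0}, source="B")
        merged = ct.merge_phase_references(ref_a, ref_b, shift=12.0)
        assert list(merged.genes) == ["g1"]
        assert merged.table.loc["g1", "phase"] == 4.0  # primary from A
        assert merged.table.loc["g1", "secondary_phase"] == 4.0  # 16+12 wrapped


class TestCircularSummary:
    def test_concentrated_antipodal_and_symmetric_inputs(self):
        c = ct.circular_summary([6.0, 6.0, 6.0])
        assert c.mean_phase == pytest.approx(6.0) and c.resultant_length == pytest.approx(1.0)
        c = ct.circular_summary([23.0, 1.0])
        assert c.mean_phase == pytest.approx(0.0, abs=1e-9)
        c = ct.circular_summary([0.0, 12.0])
        assert c.mean_phase is None and c.resultant_length == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            ct.circular_summary([])

    def test_module_phase_summary(self, rng):
        table = _phase_table({"g1": 11.0, "g2": 11.0})
        s = ct.module_phase_summary(["g1", "g2", "g3"], table)
        assert s.fraction_rhythmic == pytest.approx(2 / 3)
        assert s.mean_phase == pytest.approx(11.0)
        none = ct.module_phase_summary(["x", "y"], table)
        assert none.fraction_rhythmic == 0.0 and none.mean_phase is None
        # planted phases ~ N(8, 0.5 h)
        phases = ct.wrap_phase(rng.normal(8.0, 0.5, size=40))
        table = _phase_table({f"m{i}": p for i, p in enumerate(phases)})
        s = ct.module_phase_summary(list(table.genes), table)
        assert abs(s.mean_phase - 8.0) < 0.5
        assert s.resultant_length > 0.9


class TestPhaseVsOrder:
    def test_phase_sorted_order_scores_near_one(self, rng):
        phases = np.sort(rng.uniform(0, 24, size=80))
        genes = [f"g{i:02d}" for i in range(80)]
        table = _phase_table(dict(zip(genes, phases)))
        report = ct.phase_vs_order(genes, table)
        assert report.abs_correlation > 0.9

    def test_random_order_scores_near_zero(self, rng):
        n = 500
        genes = [f"g{i:03d}" for i in range(n)]
        table = _phase_table(dict(zip(genes, rng.uniform(0, 24, size=n))))
        report = ct.phase_vs_order(list(rng.permutation(genes)), table)
        assert report.abs_correlation < 0.1

    def test_aoe_order_beats_permutation_null_on_cosine_data(self, rng):
        phases = rng.uniform(0, 24, size=100)
        genes = [f"g{i:03d}" for i in range(100)]
        arr = np.cos(2 * np.pi * (phases[:, None] - phases[None, :]) / 24.0)
        np.fill_diagonal(arr, 1.0)
        corr = ct.CorrelationMatrix(
            pd.DataFrame(arr, index=genes, columns=genes), axis="gene"
        )
        perm = ct.order_matrix(corr, "AOE")
        ordered = [genes[i] for i in perm]
        table = _phase_table(dict(zip(genes, phases)))
        report = ct.phase_vs_order(ordered, table, n_null=200, seed=0)
        assert report.null_percentile >= 99.0

    def test_too_few_genes_rejected(self):
        table = _phase_table({"g1": 1.0})
        with pytest.raises(ValueError, match="at least 10"):
            ct.phase_vs_order(["g1"], table)


class TestSelectMarkers:
    @staticmethod
    def _saturated_table(per_bin_available=25, bin_width=0.5):
        rows = {}
        starts = np.arange(0, 24, bin_width)
        rng = np.random.default_rng(1)
        for s in starts:
            for k in range(per_bin_available):
                gene = f"g_{s:04.1f}_{k:02d}"
                rows[gene] = (s + (k + 0.5) * bin_width / (per_bin_available + 1),
                              rng.uniform(0, 0.05))
        return ct.PhaseTable(
            pd.DataFrame(
                {"phase": {g: v[0] for g, v in rows.items()},
                 "q": {g: v[1] for g, v in rows.items()}}
            ),
            source="sat",
        )

    def test_half_hour_bins_yield_960_markers(self):
        table = self._saturated_table(bin_width=0.5)
        markers = ct.select_markers(table, _stats(table.genes), per_bin=20,
                                    bin_width=0.5)
        assert markers.n_markers == 960
        assert markers.short_bins == ()

    def test_one_hour_bins_yield_480_markers(self):
        table = self._saturated_table(bin_width=0.5)
        markers = ct.select_markers(table, _stats(table.genes), per_bin=20,
                                    bin_width=1.0)
        assert markers.n_markers == 480

    def test_short_bin_takes_all_and_is_flagged(self):
        table = _phase_table(
            {f"g{i}": 0.2 + 0.01 * i for i in range(5)}  # all in bin [0, 1)
        )
        markers = ct.select_markers(table, _stats(table.genes), per_bin=20,
                                    bin_width=1.0)
        assert len(markers.bins[0.0]) == 5
        assert 0.0 in markers.short_bins

    def test_lowest_q_wins_with_gene_id_tiebreak(self):
        table = _phase_table({"b": 0.5, "a": 0.6, "c": 0.4},
                             q={"b": 0.01, "a": 0.01, "c": 0.5})
        markers = ct.select_markers(table, _stats(table.genes), per_bin=2,
                                    bin_width=1.0)
        assert markers.bins[0.0] == ("a", "b")

    def test_expression_floor_excludes_dim_genes(self):
        table = _phase_table({"hi": 0.5, "lo": 0.6})
        stats = NormalizationStats(
            mean=pd.Series({"hi": 8.0, "lo": 1.0}),
            sd=pd.Series({"hi": 1.0, "lo": 1.0}),
            all_zero=pd.Index([]),
        )
        markers = ct.select_markers(table, stats, per_bin=5, bin_width=1.0,
                                    min_mean=4.0)
        assert markers.bins[0.0] == ("hi",)

    def test_degenerate_inputs_rejected(self):
        empty = ct.PhaseTable(
            pd.DataFrame(columns=["phase", "q"], dtype=float), source="e"
        )
        with pytest.raises(ValueError, match="empty"):
            ct.select_markers(empty, _stats([]))
        with pytest.raises(ValueError, match="divide"):
            ct.select_markers(_phase_table({"g": 1.0}), _stats(["g"]), bin_width=7.0)


class TestTimetable:
    def test_constant_expression_has_zero_amplitude_and_earliest_peak(self):
        table = TestSelectMarkers._saturated_table(bin_width=1.0,
                                                   per_bin_available=3)
        markers = ct.select_markers(table, _stats(table.genes), per_bin=3,
                                    bin_width=1.0)
        expr = ct.ExpressionMatrix(
            pd.DataFrame(0.0, index=list(table.genes), columns=["s1"]),
            stage="centered",
        )
        res = ct.timetable_profile(expr, markers)
        assert res.amplitude["s1"] == 0.0
        assert res.per_sample.loc["s1", "peak_bin"] == 0.0
        assert res.internal_time["s1"] == 0.5

    def test_majority_missing_markers_rejected(self):
        table = _phase_table({f"g{i}": i % 24 + 0.5 for i in range(48)})
        markers = ct.select_markers(table, _stats(table.genes), per_bin=2,
                                    bin_width=1.0)
        expr = ct.ExpressionMatrix(
            pd.DataFrame(0.0, index=["g0"], columns=["s"]), stage="centered"
        )
        with pytest.raises(ValueError, match="missing"):
            ct.timetable_profile(expr, markers)
        with pytest.raises(ValueError, match="centered"):
            ct.timetable_profile(
                ct.ExpressionMatrix(pd.DataFrame(1.0, index=["g"], columns=["s"])),
                markers,
            )

    def test_internal_time_recovery_on_synchronized_samples(self):
        cfg = ct.SimConfig(seed=31, n_genes=1000, n_experiments=5,
                           samples_per_experiment=8, replicates_per_group=1,
                           n_modules=0, module_size=3, sync_fraction=1.0,
                           n_diurnal_experiments=1)
        mat, meta, truth = ct.simulate_dataset(cfg)
        cascade = ct.normalize_cascade(mat, meta)
        markers = ct.select_markers(truth_phase_table(truth), cascade.stats,
                                    per_bin=20, bin_width=1.0, min_mean=5.0)
        res = ct.timetable_profile(cascade.rnaseq4, markers, scale_sd=True)
        err = ct.circular_distance(res.internal_time.to_numpy(),
                                   truth.sample_time.to_numpy())
        assert np.median(err) <= 1.0

    def test_peak_trough_separation_near_half_cycle(self):
        # weak batch + low noise isolate the cosine geometry: the peak sits
        # half a cycle from the trough for nearly every entrained sample
        cfg = ct.SimConfig(seed=1, n_genes=1500, n_experiments=10,
                           samples_per_experiment=10, replicates_per_group=2,
                           n_modules=0, module_size=3, sync_fraction=1.0,
                           n_diurnal_experiments=1, noise_scale=0.2,
                           batch_scale=0.1)
        mat, meta, truth = ct.simulate_dataset(cfg)
        cascade = ct.normalize_cascade(mat, meta)
        markers = ct.select_markers(truth_phase_table(truth), cascade.stats,
                                    per_bin=20, bin_width=1.0, min_mean=5.0)
        res = ct.timetable_profile(cascade.rnaseq4, markers, scale_sd=True)
        sep = res.per_sample.peak_trough_separation
        assert np.mean((sep >= 11.0) & (sep <= 13.0)) >= 0.95

    def test_time_recovery_degrades_as_sync_drops(self):
        meds = []
        for sig in (1.0, 0.5, 0.25):
            cfg = ct.SimConfig(seed=32, n_genes=800, n_experiments=5,
                               samples_per_experiment=8, replicates_per_group=1,
                               n_modules=0, module_size=3, sync_fraction=sig,
                               n_diurnal_experiments=0)
            mat, meta, truth = ct.simulate_dataset(cfg)
            cascade = ct.normalize_cascade(mat, meta)
            markers = ct.select_markers(truth_phase_table(truth), cascade.stats,
                                        per_bin=15, bin_width=1.0, min_mean=5.0)
            res = ct.timetable_profile(cascade.rnaseq4, markers, scale_sd=True)
            err = ct.circular_distance(res.internal_time.to_numpy(),
                                       truth.sample_time.to_numpy())
            meds.append(float(np.median(err)))
        assert meds[0] < meds[1] < meds[2]


class TestEstimateSync:
    @staticmethod
    def _result(amplitudes):
        per_sample = pd.DataFrame({"amplitude": pd.Series(amplitudes)})
        return ct.TimetableResult(
            bin_means=pd.DataFrame(), per_sample=per_sample, bin_width=1.0,
            n_markers_used=0, n_markers_missing=0,
        )

    def test_reference_mean_scaling_and_cap(self):
        res = self._result({"a": 4.0, "b": 0.0, "c": 9.0})
        sync = ct.estimate_sync(res, [4.0, 4.0])
        assert sync["a"] == 100.0
        assert sync["b"] == 0.0
        assert sync["c"] == 100.0  # capped
        with pytest.raises(ValueError):
            ct.estimate_sync(res, [])


class TestTransferOrthologs:
    @staticmethod
    def _reference(seed=21):
        refs = ct.simulate_diurnal_references(
            ct.ReferenceConfig(seed=seed, n_genes=1600, frac_both=0.8,
                               frac_only_a=0.1, frac_only_b=0.1,
                               noise_scale=0.2)
        )
        cascade = ct.normalize_cascade(refs.timecourse, refs.metadata)
        merged = ct.merge_phase_references(refs.ref_a, refs.ref_b)
        markers = ct.select_markers(merged, cascade.stats, per_bin=30,
                                    bin_width=1.0, min_mean=4.0)
        return refs, cascade, merged, markers

    def test_mapping_bookkeeping(self):
        refs, cascade, merged, _ = self._reference()
        orth = ct.simulate_ortholog_species(
            refs.phase, cascade.stats.mean,
            ct.OrthologConfig(seed=1, mapping_fraction=1.0, noise_scale=0.1),
        )
        fpkm = ct.counts_to_fpkm(orth.counts)
        out = ct.transfer_orthologs(fpkm, orth.ortholog_map, cascade.stats, merged)
        # retained genes = mapped genes whose reference ortholog is rhythmic
        mapped_rhythmic = set(orth.ortholog_map.pairs["reference"]) & set(merged.genes)
        assert set(out.matrix.genes) == mapped_rhythmic
        assert out.n_nonrhythmic == 1600 - len(mapped_rhythmic)
        assert set(out.phases.genes) == mapped_rhythmic

    def test_internal_time_recovered_and_antiphase_shifts_it(self):
        refs, cascade, merged, markers = self._reference()
        times = np.arange(0.0, 24.0, 3.0)
        internal = {}
        for delta in (0.0, 12.0):
            orth = ct.simulate_ortholog_species(
                refs.phase, cascade.stats.mean,
                ct.OrthologConfig(seed=2, mapping_fraction=1.0,
                                  phase_offset=delta,
                                  sample_times=tuple(times),
                                  noise_scale=0.1),
            )
            fpkm = ct.counts_to_fpkm(orth.counts)
            out = ct.transfer_orthologs(fpkm, orth.ortholog_map, cascade.stats,
                                        merged)
            res = ct.timetable_profile(out.matrix, markers, scale_sd=True)
            internal[delta] = res.internal_time.to_numpy()
        err0 = ct.circular_distance(internal[0.0], times)
        assert np.median(err0) <= 1.5
        # an antiphase species reads out half a cycle away
        err12 = ct.circular_distance(internal[12.0], times + 12.0)
        assert np.median(err12) <= 1.5

    def test_zero_usable_genes_rejected(self):
        refs, cascade, merged, _ = self._reference()
        fpkm = ct.ExpressionMatrix(pd.DataFrame({"s": [1.0]}, index=["alien"]))
        omap = ct.OrthologMap(pd.DataFrame({"reference": ["gx"], "target": ["alien"]}))
        with pytest.raises(ValueError, match="no target gene"):
            ct.transfer_orthologs(fpkm, omap, cascade.stats, merged)

    def test_one_to_one_violations_rejected(self):
        with pytest.raises(ValueError, match="one-to-one"):
            ct.OrthologMap(pd.DataFrame({"reference": ["a", "a"],
                                         "target": ["x", "y"]}))
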