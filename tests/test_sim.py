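"""Fission--fusion simulator laws and the companion input generators."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from mitoshape import (
    ChannelSpec,
    IntensitySpec,
    PopulationSpec,
    SimParams,
    fusion_k_metric,
    metrics_table,
    simulate_cell,
    simulate_intensities,
    simulate_lda_wells,
    simulate_phase_table,
    simulate_population,
)


class TestSimParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"total_length": 0.0},
            {"k_fis": -1.0},
            {"k_fis": 0.0, "k_fus": 0.0},
            {"min_len": 0.0},
            {"min_len": 200.0},
            {"n_events": -1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**kwargs)


class TestSimulateCell:
    def test_mass_conservation(self):
        for seed in range(20):
            p = SimParams(total_length=100.0, k_fis=3.0, k_fus=1.0, seed=seed)
            c = simulate_cell(p)
            assert c.total_length == pytest.approx(100.0, rel=1e-9)
            assert np.all(c.lengths >= p.min_len)

    def test_pure_fusion_absorbs_to_single_component(self):
        c = simulate_cell(SimParams(k_fis=0.0, k_fus=1.0, n_events=2000, seed=3))
        assert c.n_components == 1
        assert fusion_k_metric(c, 1) == pytest.approx(100.0)

    def test_large_min_len_blocks_all_fission(self):
        # no breakpoint can leave both daughters above total_length/2
        c = simulate_cell(
            SimParams(total_length=10.0, k_fis=5.0, k_fus=0.0, min_len=6.0, seed=1)
        )
        assert c.n_components == 1
        assert c.lengths[0] == pytest.approx(10.0)

    def test_determinism(self):
        p = SimParams(k_fis=2.0, k_fus=1.0, seed=42)
        a, b = simulate_cell(p), simulate_cell(p)
        np.testing.assert_array_equal(a.lengths, b.lengths)

    def test_ratio_drives_fragmentation(self):
        """Mean component count is higher at rate ratio 10 than at 0.1."""
        counts = {}
        for ratio in (0.1, 10.0):
            cells = [
                simulate_cell(
                    SimParams(k_fis=ratio, k_fus=1.0, n_events=2000, seed=s)
                )
                for s in range(200)
            ]
            counts[ratio] = [c.n_components for c in cells]
        assert np.mean(counts[10.0]) > np.mean(counts[0.1])
        p = stats.mannwhitneyu(counts[10.0], counts[0.1], alternative="greater").pvalue
        assert p < 0.01


class TestSimulatePopulation:
    def test_single_archetype_distinct_streams(self):
        spec = PopulationSpec("p", 10, [(SimParams(n_events=500), 1.0)])
        cells = simulate_population(spec, seed=0)
        assert len(cells) == 10
        assert len({c.cell_id for c in cells}) == 10
        # distinct random streams: not all partitions identical
        sizes = {c.n_components for c in cells}
        assert len(sizes) > 1 or len(cells[0].lengths) == 1

    def test_mixture_labels_split_binomially(self):
        fast = SimParams(k_fis=5.0, k_fus=1.0, n_events=10)
        slow = SimParams(k_fis=0.0, k_fus=1.0, n_events=10)
        spec = PopulationSpec("mix", 1000, [(slow, 0.5), (fast, 0.5)])
        cells = simulate_population(spec, seed=3)
        n0 = sum(c.archetype == "arch0" for c in cells)
        # planted 0.5: binomial 99.9% band at n=1000 is about +/- 52
        assert abs(n0 - 500) < 55

    def test_rerun_identical(self):
        spec = PopulationSpec(
            "p", 5, [(SimParams(k_fis=2.0, n_events=300), 1.0)]
        )
        a = simulate_population(spec, seed=9)
        b = simulate_population(spec, seed=9)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.lengths, cb.lengths)
            assert ca.archetype == cb.archetype

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec("p", 5, [(SimParams(), 0.7), (SimParams(), 0.7)])


class TestSimulateIntensities:
    def test_zero_hi_fraction_all_lo(self):
        spec = IntensitySpec(ChannelSpec(hi_fraction=0.0), ChannelSpec(hi_fraction=0.0))
        df = simulate_intensities(spec, 200, seed=0)
        assert (df["truth_ch1"] == 0).all() and (df["truth_ch2"] == 0).all()
        assert (df["ch1"] > 0).all() and (df["ch2"] > 0).all()

    def test_correlated_hi_states_recover_double_hi(self):
        spec = IntensitySpec(
            ChannelSpec(hi_fraction=0.26),
            ChannelSpec(hi_fraction=0.26),
            hi_correlation=1.0,
        )
        df = simulate_intensities(spec, 5000, seed=1)
        double_hi = ((df["truth_ch1"] == 1) & (df["truth_ch2"] == 1)).mean()
        # planted 0.26 with perfect coupling; binomial sd ~ 0.006
        assert double_hi == pytest.approx(0.26, abs=0.02)
        assert (df["truth_ch1"] == df["truth_ch2"]).all()

    def test_tiny_logsd_collapses_to_point_masses(self):
        ch = ChannelSpec(lo_logmean=0.0, hi_logmean=2.0, lo_logsd=1e-9,
                         hi_logsd=1e-9, hi_fraction=0.5)
        df = simulate_intensities(IntensitySpec(ch, ch), 500, seed=2)
        uniq = np.unique(np.round(df["ch1"], 6))
        assert len(uniq) == 2
        np.testing.assert_allclose(uniq, [1.0, np.e**2], rtol=1e-5)


class TestSimulateLdaWells:
    def test_schema_and_bounds(self):
        df = simulate_lda_wells(1.0, seed=0)
        assert list(df.columns) == ["dose", "wells", "positive"]
        assert (df["positive"] <= df["wells"]).all()

    def test_high_frequency_saturates(self):
        df = simulate_lda_wells(1.0, doses=(5, 50), wells_per_dose=50, seed=1)
        # P(positive) = 1 - e^-5 = 0.993 at the lowest dose
        assert (df["positive"] >= 45).all()

    def test_mean_positive_fraction_matches_binomial_mean(self):
        """At f = 1/150, dose 1000: E[positive fraction] = 1 - e^(-1000/150)."""
        fracs = [
            simulate_lda_wells(1 / 150, seed=s)
            .set_index("dose")
            .loc[1000, "positive"]
            / 24
            for s in range(500)
        ]
        expected = 1 - np.exp(-1000 / 150)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.005)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            simulate_lda_wells(0.0)
        with pytest.raises(ValueError):
            simulate_lda_wells(1.5)


def test_phase_table_counts_sum_to_group_sizes():
    probs = {("P", "c3"): (0.6, 0.2, 0.2), ("P", "c5"): (0.2, 0.4, 0.4)}
    sizes = {("P", "c3"): 300, ("P", "c5"): 200}
    df = simulate_phase_table(probs, sizes, seed=0)
    totals = df.groupby(["population", "cluster"])["count"].sum()
    assert totals[("P", "c3")] == 300 and totals[("P", "c5")] == 200


def test_simulated_mixture_metrics_are_reproducible_tables():
    from mitoshape.sim import HYPERFUSED, INTERMEDIATE

    spec = PopulationSpec(
        "mix", 20, [(dataclasses.replace(HYPERFUSED, n_events=500), 0.5),
                    (dataclasses.replace(INTERMEDIATE, n_events=500), 0.5)]
    )
    tab = metrics_table(simulate_population(spec, seed=4))
    assert len(tab) == 20
    assert (tab["total_length"] > 0).all()
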