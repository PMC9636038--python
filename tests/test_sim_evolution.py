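import numpy as np
import pandas as pd
import pytest

from clonechron import ccf_engine
from clonechron.sim_evolution import (
    Clone,
    CloneSpecError,
    SimConfig,
    simulate_panel,
    simulate_tumor,
    truncal_only_spec,
)


def _counts_frame(sim):
    rows = []
    for v in sim.variants:
        for s, c in v.samples.items():
            rows.append({"mutation_id": v.mutation_id, "sample": s,
                         "depth": c.depth, "alt_reads": c.alt_reads})
    return pd.DataFrame(rows)


def test_identical_seeds_are_bit_identical():
    cfg = dict(seed=13, n_regions=2, purity_per_region=(0.8, 0.6),
               clone_spec=(
                   Clone("truncal", None, (1.0, 1.0), 60),
                   Clone("s1", "truncal", (0.5, 0.1), 40),
               ))
    a, b = simulate_tumor(SimConfig(**cfg)), simulate_tumor(SimConfig(**cfg))
    pd.testing.assert_frame_equal(_counts_frame(a), _counts_frame(b))
    pd.testing.assert_frame_equal(a.truth.mutation_truth, b.truth.mutation_truth)
    assert [v.context for v in a.variants] == [v.context for v in b.variants]


def test_cluster_sizes_match_variant_table():
    cfg = SimConfig(seed=1, n_regions=1, clone_spec=(
        Clone("truncal", None, (1.0,), 70),
        Clone("s1", "truncal", (0.4,), 30),
        Clone("s2", "s1", (0.2,), 25),
    ))
    sim = simulate_tumor(cfg)
    truth = sim.truth.mutation_truth
    assert len(sim.variants) == 125
    assert truth["cluster_id"].value_counts().to_dict() == {
        "truncal": 70, "s1": 30, "s2": 25}
    assert truth["mutation_id"].is_unique


def test_clonal_diploid_pure_tumor_vaf_converges_to_half():
    cfg = SimConfig(seed=2, purity_per_region=(1.0,), tumor_depth_mean=2000,
                    clone_spec=truncal_only_spec(400))
    sim = simulate_tumor(cfg)
    truth = sim.truth.mutation_truth.set_index("mutation_id")
    vafs = [
        v.samples["R1"].vaf
        for v in sim.variants
        if truth.loc[v.mutation_id, "segment_class"] == "diploid"
    ]
    assert np.mean(vafs) == pytest.approx(0.5, abs=0.01)


def test_cluster_mean_vaf_matches_expected_vaf():
    """Empirical VAF per cluster tracks CCF x expected clonal VAF."""
    purity = 0.7
    cfg = SimConfig(seed=6, purity_per_region=(purity,), tumor_depth_mean=500,
                    clone_spec=(
                        Clone("truncal", None, (1.0,), 200),
                        Clone("s1", "truncal", (0.3,), 200),
                    ))
    sim = simulate_tumor(cfg)
    truth = sim.truth.mutation_truth.set_index("mutation_id")
    for cluster, ccf in [("truncal", 1.0), ("s1", 0.3)]:
        vafs = [
            v.samples["R1"].vaf for v in sim.variants
            if truth.loc[v.mutation_id, "cluster_id"] == cluster
            and truth.loc[v.mutation_id, "segment_class"] == "diploid"
        ]
        expected = ccf * ccf_engine.expected_vaf(1, 2, purity)
        assert np.mean(vafs) == pytest.approx(expected, abs=0.015)


def test_duplicated_count_poisson_around_closed_form():
    """Pre-gain multiplicity-2 burden: mean (rate/2)*f*t over many seeds."""
    expected = 13 * 0.04 * 2  # = 1.04
    counts = []
    for seed in range(200):
        cfg = SimConfig(seed=seed, clone_spec=truncal_only_spec(60),
                        arm_fraction=0.04, gain_time_years=2.0)
        truth = simulate_tumor(cfg).truth.mutation_truth
        counts.append(int((truth["multiplicity"] == 2).sum()))
    mean = np.mean(counts)
    # Poisson mean-of-200 has sd ~0.072; allow 4 sigma
    assert mean == pytest.approx(expected, abs=4 * np.sqrt(expected / 200))


def test_poisson_burden_mode_consistent_with_rate_times_age():
    cfg = SimConfig(seed=3, donor_age_years=10.0, rate_per_year=26.0,
                    clone_spec=truncal_only_spec(260),
                    poisson_mutation_counts=True)
    sim = simulate_tumor(cfg)
    n = len(sim.variants)
    assert abs(n - 260) <= 4 * np.sqrt(260)
    assert sim.truth.event_truth["mrca_time_years"] == pytest.approx(n / 26.0)


@pytest.mark.parametrize(
    "spec, message",
    [
        ((Clone("r", None, (0.9,), 10),), "CCF 1.0"),
        ((Clone("r", None, (1.0,), 10), Clone("c", "r", (1.2,), 5)), "pigeonhole"),
        ((Clone("r", None, (1.0,), 10), Clone("c", "missing", (0.5,), 5)), "unknown parent"),
        ((Clone("r", None, (1.0,), 10), Clone("r2", None, (1.0,), 5)), "one root"),
    ],
)
def test_invalid_clone_specs_rejected(spec, message):
    with pytest.raises(CloneSpecError, match=message):
        simulate_tumor(SimConfig(seed=0, clone_spec=spec))


def test_gain_time_cannot_exceed_mrca_time():
    with pytest.raises(CloneSpecError, match="MRCA"):
        simulate_tumor(SimConfig(seed=0, clone_spec=truncal_only_spec(26),
                                 gain_time_years=2.0))  # MRCA at 1 year


class TestPanel:
    def test_zero_error_rate_gives_zero_counts(self):
        cfg = SimConfig(seed=0, panel_error_rate=0.0, gain_time_years=1.0,
                        clone_spec=truncal_only_spec(50))
        sim = simulate_tumor(cfg)
        panel = simulate_panel(cfg, sim.variants)
        assert (panel["alt_reads"] == 0).all()
        assert len(panel) == len(sim.variants)

    def test_empty_loci_give_empty_table(self):
        panel = simulate_panel(SimConfig(seed=0), [])
        assert panel.empty
        assert list(panel.columns) == ["chrom", "pos", "ref", "alt", "sample",
                                       "depth", "alt_reads"]

    def test_mean_alt_count_matches_binomial_mean(self):
        cfg0 = SimConfig(seed=0, clone_spec=truncal_only_spec(40),
                         gain_time_years=1.0, panel_error_rate=1e-3,
                         panel_depth=10000)
        sim = simulate_tumor(cfg0)
        means = []
        for seed in range(50):
            cfg = SimConfig(seed=seed, clone_spec=truncal_only_spec(40),
                            gain_time_years=1.0, panel_error_rate=1e-3,
                            panel_depth=10000)
            means.append(simulate_panel(cfg, sim.variants)["alt_reads"].mean())
        assert np.mean(means) == pytest.approx(10.0, abs=1.0)
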