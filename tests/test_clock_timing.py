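import numpy as np
import pandas as pd
import pytest

from clonechron import ccf_engine, clock_timing, sim_evolution
from clonechron.clock_timing import (
    STATUS_INSUFFICIENT,
    STATUS_OK,
    RateModel,
    arm_fraction_from_segments,
    classify_duplication,
    fit_rate_model,
    time_gain,
    time_mrca,
)

AGES = [24.0, 29.0, 30.0, 38.0, 44.0]


def test_noiseless_burdens_recover_rate_exactly():
    df = pd.DataFrame(
        {"donor": [f"D{i}" for i in range(5)], "age_years": AGES,
         "n_substitutions": [26.0 * a for a in AGES]}
    )
    model = fit_rate_model(df)
    assert model.rate_per_year == pytest.approx(26.0, abs=1e-9)
    assert model.sigma2 == 0.0 and model.tau2 == 0.0


def test_poisson_cohort_recovers_rate_within_two_se():
    rng = np.random.default_rng(0)
    rows = []
    for i, age in enumerate(AGES):
        for _ in range(5 if i == 1 else 1):  # one multi-region donor
            rows.append({"donor": f"D{i}", "age_years": age,
                         "n_substitutions": rng.poisson(26 * age)})
    model = fit_rate_model(pd.DataFrame(rows))
    assert abs(model.rate_per_year - 26.0) <= 2 * model.se_rate


def test_matches_statsmodels_mixed_lm():
    """Independent cross-check of the profiled-ML fit against MixedLM."""
    import statsmodels.api as sm

    rng = np.random.default_rng(42)
    rows = []
    for i, age in enumerate([20.0, 25.0, 33.0, 41.0, 52.0, 37.0]):
        slope_dev = rng.normal(0, 2.0)
        for _ in range(4):
            rows.append({"donor": f"P{i}", "age_years": age,
                         "n_substitutions": (26 + slope_dev) * age + rng.normal(0, 20)})
    df = pd.DataFrame(rows)
    ours = fit_rate_model(df)
    ref = sm.MixedLM(df["n_substitutions"], df[["age_years"]], groups=df["donor"],
                     exog_re=df[["age_years"]]).fit(reml=False)
    assert ours.rate_per_year == pytest.approx(ref.params["age_years"], rel=1e-3)
    assert ours.se_rate == pytest.approx(ref.bse["age_years"], rel=1e-2)


def test_single_donor_falls_back_to_poisson_origin(caplog):
    df = pd.DataFrame({"donor": ["X"] * 3, "age_years": [29.0] * 3,
                       "n_substitutions": [700, 750, 720]})
    with caplog.at_level("WARNING"):
        model = fit_rate_model(df)
    assert model.method == "poisson_origin"
    assert model.rate_per_year == pytest.approx(2170 / 87)
    assert "single donor" in caplog.text


def test_shared_donor_slope_for_repeated_samples():
    rng = np.random.default_rng(1)
    rows = []
    for d, age, dev in [("A", 30.0, 3.0), ("B", 40.0, -3.0)]:
        for _ in range(6):
            rows.append({"donor": d, "age_years": age,
                         "n_substitutions": (26 + dev) * age + rng.normal(0, 5)})
    model = fit_rate_model(pd.DataFrame(rows))
    assert model.donor_slopes["A"] > 0 > model.donor_slopes["B"]
    ra, _ = model.donor_rate("A")
    rb, _ = model.donor_rate("B")
    assert ra > rb


@pytest.fixture
def cohort_model():
    return RateModel(26.0, 2.4, float("nan"), float("nan"), method="fixed")


class TestTimeGain:
    def test_point_estimate_arithmetic(self, cohort_model):
        est = time_gain(2, cohort_model, arm_fraction=0.04, n_boot=200, seed=0)
        assert est.t_years == pytest.approx(2 / (13 * 0.04))
        assert est.status == STATUS_INSUFFICIENT  # below the default minimum of 3

    def test_zero_duplicated_mutations_flagged(self, cohort_model):
        est = time_gain(0, cohort_model, arm_fraction=0.04, n_boot=100, seed=0)
        assert est.t_years == 0.0
        assert est.status == STATUS_INSUFFICIENT

    def test_sufficient_count_is_ok(self, cohort_model):
        est = time_gain(8, cohort_model, arm_fraction=0.3, n_boot=500, seed=1)
        assert est.status == STATUS_OK
        assert est.ci_low <= est.t_years <= est.ci_high

    def test_timing_scales_inversely_with_rate(self, cohort_model):
        double = RateModel(52.0, 0.0, float("nan"), float("nan"))
        t1 = time_gain(8, cohort_model, 0.3, n_boot=0, seed=0).t_years
        t2 = time_gain(8, double, 0.3, n_boot=0, seed=0).t_years
        assert t2 == pytest.approx(t1 / 2)

    def test_invalid_arm_fraction(self, cohort_model):
        with pytest.raises(ValueError):
            time_gain(5, cohort_model, arm_fraction=0.0)


class TestTimeMrca:
    def test_point_estimate_arithmetic(self, cohort_model):
        est = time_mrca(80, cohort_model, n_boot=500, seed=0)
        assert est.t_years == pytest.approx(80 / 26)  # ~3.1 years: early childhood
        assert est.ci_low <= est.t_years <= est.ci_high

    def test_zero_clonal_burden(self, cohort_model):
        est = time_mrca(0, cohort_model, seed=0)
        assert (est.t_years, est.ci_low, est.ci_high) == (0.0, 0.0, 0.0)

    def test_donor_specific_rate_used_when_available(self):
        model = RateModel(26.0, 1.0, 1.0, 1.0, donor_slopes={"D1": 4.0}, n_donors=3)
        est = time_mrca(60, model, n_boot=0, seed=0, donor="D1")
        assert est.rate_per_year == pytest.approx(30.0)
        assert est.rate_source == "donor_blup"
        est2 = time_mrca(60, model, n_boot=0, seed=0, donor="unknown")
        assert est2.rate_source == "cohort"


def test_classify_duplication_on_simulator_truth():
    """Pure-tumor, high-depth reads separate the 1/3 and 2/3 VAF classes."""
    cfg = sim_evolution.SimConfig(
        seed=5, n_regions=1, purity_per_region=(1.0,), tumor_depth_mean=120,
        clone_spec=sim_evolution.truncal_only_spec(150),
        arm_fraction=0.3, gain_time_years=2.0,
    )
    sim = sim_evolution.simulate_tumor(cfg)
    ann = ccf_engine.annotate(sim.variants, sim.segments, sim.meta)
    n_dup, n_nondup = classify_duplication(ann)
    truth = sim.truth.mutation_truth
    true_dup = int((truth["multiplicity"] == 2).sum())
    true_single = int(((truth["segment_class"] == "gain_arm")
                       & (truth["multiplicity"] == 1)).sum())
    assert abs(n_dup - true_dup) <= 1
    assert abs(n_nondup - true_single) <= 1


def test_classify_duplication_empty_input():
    ann = pd.DataFrame(columns=["mutation_id", "cn_class"])
    assert classify_duplication(ann) == (0, 0)


def test_arm_fraction_from_segments():
    cfg = sim_evolution.SimConfig(seed=0, arm_fraction=0.04)
    sim = sim_evolution.simulate_tumor(cfg)
    f = arm_fraction_from_segments(sim.segments,
                                   callable_genome_bp=cfg.callable_genome_bp)
    assert f == pytest.approx(0.04, rel=1e-6)
    with pytest.raises(ValueError, match="gain"):
        arm_fraction_from_segments([])
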