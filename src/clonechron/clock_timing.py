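"""Molecular-clock timing of copy-number gains and of the MRCA.

Somatic substitutions accumulate at a near-constant rate through life, so
mutation counts convert to chronological time. The cohort rate (diploid
genome-wide substitutions per year) is estimated by a zero-intercept linear
mixed-effects model of per-sample burden on age, with a per-donor random
slope absorbing both donor-level rate variation and repeated sampling of
one tumor. Two events are then timed:

* a single-copy chromosomal gain — mutations present on two of the three
  copies of the gained arm predate the gain, and on one arm copy they
  accrue at (r/2)*f per year where f is the arm's share of the haploid
  callable genome, so t_gain = n_dup / ((r/2) * f);
* the most recent common ancestor — the clonal (truncal) burden divided by
  the genome-wide rate, t_mrca = n_clonal / r.

Confidence intervals come from a parametric bootstrap: counts are Poisson
resampled (mutation acquisition is a Poisson process) and the rate is drawn
from a truncated normal using its fitted standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

DEFAULT_CALLABLE_GENOME_BP = 2.9e9  # diploid-equivalent callable length
DEFAULT_MIN_DUP = 3

STATUS_OK = "ok"
STATUS_INSUFFICIENT = "insufficient_duplicated_mutations"


@dataclass
class RateModel:
    """Cohort mutation rate (substitutions/year) with per-donor deviations."""

    rate_per_year: float
    se_rate: float
    sigma2: float  # residual variance
    tau2: float  # random-slope variance
    donor_slopes: dict[str, float] = field(default_factory=dict)  # BLUP deviations
    n_donors: int = 0
    method: str = "mixed_ml"

    def donor_rate(self, donor: str | None) -> tuple[float, str]:
        """Rate for one donor (fixed effect + BLUP deviation if available)."""
        if donor is not None and donor in self.donor_slopes:
            return self.rate_per_year + self.donor_slopes[donor], "donor_blup"
        return self.rate_per_year, "cohort"


@dataclass
class TimingEstimate:
    """Timing of a gain or of the MRCA, in years since birth, with 95% CI."""

    event: str  # "gain" | "mrca"
    t_years: float
    ci_low: float
    ci_high: float
    n_mutations: int  # n_dup for gains, n_clonal for the MRCA
    rate_per_year: float
    se_rate: float
    arm_fraction: float | None = None
    n_boot: int = 0
    status: str = STATUS_OK
    rate_source: str = "cohort"


# ---------------------------------------------------------------------------
# rate model


def _profile_ml(ages_by_donor, y_by_donor, lam):
    """Profiled ML pieces for y_i = a_i*(r + b_i) + e, b ~ N(0, lam*sigma2).

    Returns (r_hat, sigma2_hat, neg2loglik, inv_info) for fixed variance
    ratio lam = tau2/sigma2. M_i = (I + lam a a')^{-1} has a rank-one
    closed form, so everything reduces to scalar accumulations.
    """
    xtmx = 0.0
    xtmy = 0.0
    for a, y in zip(ages_by_donor, y_by_donor):
        s = 1.0 + lam * float(a @ a)
        # a' M a = a'a - lam (a'a)^2 / s ; a' M y analogous
        aa = float(a @ a)
        ay = float(a @ y)
        xtmx += aa - lam * aa * aa / s
        xtmy += ay - lam * aa * ay / s
    r_hat = xtmy / xtmx
    n_total = sum(len(a) for a in ages_by_donor)
    rss = 0.0
    logdet = 0.0
    for a, y in zip(ages_by_donor, y_by_donor):
        resid = y - r_hat * a
        aa = float(a @ a)
        s = 1.0 + lam * aa
        ar = float(a @ resid)
        rss += float(resid @ resid) - lam * ar * ar / s
        logdet += np.log(s)
    sigma2 = rss / n_total
    if sigma2 <= 0:
        sigma2 = 0.0
        neg2ll = -np.inf  # degenerate perfect fit
    else:
        neg2ll = n_total * np.log(sigma2) + logdet + n_total * (1.0 + np.log(2.0 * np.pi))
    return r_hat, sigma2, neg2ll, 1.0 / xtmx


def fit_rate_model(burdens: pd.DataFrame) -> RateModel:
    """Fit the zero-intercept random-slope model to per-sample burdens.

    ``burdens`` has columns donor, age_years, n_substitutions (one row per
    sample). The model, fitted by profiled maximum likelihood, is

        y_ij = age_ij * (r + b_i) + e_ij,  b_i ~ N(0, tau2), e ~ N(0, sigma2)

    with the intercept fixed at zero (no somatic burden at birth). With a
    single donor the model is unidentifiable and a Poisson regression
    through the origin is used instead (a warning is logged).
    """
    required = {"donor", "age_years", "n_substitutions"}
    if missing := required - set(burdens.columns):
        raise ValueError(f"burden table missing columns {sorted(missing)}")
    donors = list(burdens["donor"].unique())
    ages_by_donor = []
    y_by_donor = []
    for d in donors:
        grp = burdens[burdens["donor"] == d]
        ages_by_donor.append(grp["age_years"].to_numpy(dtype=float))
        y_by_donor.append(grp["n_substitutions"].to_numpy(dtype=float))

    if len(donors) < 2:
        total_y = float(np.sum(y_by_donor[0]))
        total_a = float(np.sum(ages_by_donor[0]))
        r = total_y / total_a
        se = np.sqrt(total_y) / total_a if total_y > 0 else float("nan")
        logger.warning(
            "single donor: falling back to Poisson regression through the origin"
        )
        return RateModel(r, se, sigma2=float("nan"), tau2=float("nan"),
                         donor_slopes={donors[0]: 0.0}, n_donors=1,
                         method="poisson_origin")

    # degenerate perfect fit (noiseless burdens): OLS through the origin is exact
    r0, sigma2_0, _, inv_info0 = _profile_ml(ages_by_donor, y_by_donor, 0.0)
    y_scale = max(float(np.mean([float(y @ y) for y in y_by_donor])), 1.0)
    if sigma2_0 <= 1e-12 * y_scale:
        return RateModel(float(r0), 0.0, 0.0, 0.0,
                         donor_slopes={d: 0.0 for d in donors}, n_donors=len(donors))

    def objective(log_lam):
        lam = np.exp(log_lam)
        return _profile_ml(ages_by_donor, y_by_donor, lam)[2]

    # profile the variance ratio; include the lam -> 0 boundary
    res = optimize.minimize_scalar(objective, bounds=(-20.0, 10.0), method="bounded")
    candidates = [0.0, float(np.exp(res.x))]
    best = min(candidates, key=lambda lam: _profile_ml(ages_by_donor, y_by_donor, lam)[2])
    r_hat, sigma2, _, inv_info = _profile_ml(ages_by_donor, y_by_donor, best)
    tau2 = best * sigma2
    se = float(np.sqrt(sigma2 * inv_info)) if sigma2 > 0 else 0.0

    slopes = {}
    for d, a, y in zip(donors, ages_by_donor, y_by_donor):
        if sigma2 > 0 and best > 0:
            aa = float(a @ a)
            s = 1.0 + best * aa
            resid = y - r_hat * a
            ar = float(a @ resid)
            slopes[d] = best * (ar - best * aa * ar / s)
        else:
            slopes[d] = 0.0
    return RateModel(float(r_hat), se, float(sigma2), float(tau2),
                     donor_slopes=slopes, n_donors=len(donors))


# ---------------------------------------------------------------------------
# duplicated / non-duplicated classification


def classify_duplication(
    annotations: pd.DataFrame,
    truncal_ids: set[str] | None = None,
) -> tuple[int, int]:
    """Count clonal mutations on the gained arm by allele class.

    Returns (n_dup, n_nondup): mutations assigned to the duplicated allele
    (multiplicity 2, acquired before the gain) versus a single copy
    (acquired after). ``annotations`` is the ccf_engine table; rows are
    restricted to the truncal cluster when ``truncal_ids`` is given. An
    empty gain-region table yields (0, 0).
    """
    gain = annotations[annotations["cn_class"].isin(["gain_single", "gain_duplicated"])]
    if truncal_ids is not None:
        gain = gain[gain["mutation_id"].isin(truncal_ids)]
    per_mut = gain.drop_duplicates("mutation_id")
    n_dup = int((per_mut["cn_class"] == "gain_duplicated").sum())
    n_nondup = int((per_mut["cn_class"] == "gain_single").sum())
    return n_dup, n_nondup


def arm_fraction_from_segments(segments, sample: str | None = None,
                               callable_genome_bp: float = DEFAULT_CALLABLE_GENOME_BP) -> float:
    """Gained-arm length as a fraction of the haploid callable genome."""
    gain_len = 0
    seen = sample
    for seg in segments:
        if (seg.major_cn, seg.minor_cn) != (2, 1):
            continue
        if seen is None:
            seen = seg.sample
        if seg.sample == seen:
            gain_len += seg.length
    if gain_len == 0:
        raise ValueError("no single-copy-gain segment found")
    return gain_len / (callable_genome_bp / 2.0)


# ---------------------------------------------------------------------------
# timing


def _bootstrap_times(n: int, rate: float, se_rate: float, scale: float,
                     n_boot: int, rng: np.random.Generator) -> np.ndarray:
    n_star = rng.poisson(n, size=n_boot)
    if se_rate > 0 and np.isfinite(se_rate):
        a = (0.0 - rate) / se_rate
        r_star = stats.truncnorm.rvs(a, np.inf, loc=rate, scale=se_rate,
                                     size=n_boot, random_state=rng)
    else:
        r_star = np.full(n_boot, rate)
    return n_star / (r_star * scale)


def time_gain(
    n_dup: int,
    rate_model: RateModel,
    arm_fraction: float,
    n_boot: int = 1000,
    seed: int = 0,
    min_dup: int = DEFAULT_MIN_DUP,
    donor: str | None = None,
) -> TimingEstimate:
    """Time a single-copy gain from its duplicated-mutation count.

    Pre-gain mutations accrued on one chromosome copy at (r/2)*arm_fraction
    per year, so t = n_dup / ((r/2) * arm_fraction). When ``n_dup`` falls
    below ``min_dup`` the estimate is still computed but flagged
    insufficient (too few duplicated mutations to time the gain reliably).
    """
    if arm_fraction <= 0:
        raise ValueError(f"arm_fraction must be positive, got {arm_fraction}")
    if n_dup < 0:
        raise ValueError("n_dup must be non-negative")
    rate, source = rate_model.donor_rate(donor)
    scale = 0.5 * arm_fraction
    t = n_dup / (rate * scale)
    rng = np.random.default_rng(seed)
    ts = _bootstrap_times(n_dup, rate, rate_model.se_rate, scale, n_boot, rng)
    lo, hi = (np.percentile(ts, [2.5, 97.5]) if n_boot > 0 else (t, t))
    status = STATUS_OK if n_dup >= min_dup else STATUS_INSUFFICIENT
    if status == STATUS_INSUFFICIENT:
        logger.warning("only %d duplicated mutation(s): gain timing flagged unreliable", n_dup)
    return TimingEstimate("gain", float(t), float(lo), float(hi), n_dup,
                          rate, rate_model.se_rate, arm_fraction=arm_fraction,
                          n_boot=n_boot, status=status, rate_source=source)


def time_mrca(
    n_clonal: int,
    rate_model: RateModel,
    n_boot: int = 1000,
    seed: int = 0,
    donor: str | None = None,
) -> TimingEstimate:
    """Time the most recent common ancestor from the clonal burden.

    The clonal (truncal) mutation count, on the diploid-equivalent callable
    genome, divided by the rate: t = n_clonal / r.
    """
    if n_clonal < 0:
        raise ValueError("n_clonal must be non-negative")
    rate, source = rate_model.donor_rate(donor)
    t = n_clonal / rate
    if n_clonal == 0:
        return TimingEstimate("mrca", 0.0, 0.0, 0.0, 0, rate, rate_model.se_rate,
                              n_boot=0, rate_source=source)
    rng = np.random.default_rng(seed)
    if n_boot > 0:
        ts = _bootstrap_times(n_clonal, rate, rate_model.se_rate, 1.0, n_boot, rng)
        lo, hi = np.percentile(ts, [2.5, 97.5])
    else:
        lo, hi = t, t
    return TimingEstimate("mrca", float(t), float(lo), float(hi), n_clonal,
                          rate, rate_model.se_rate, n_boot=n_boot, rate_source=source)
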