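"""Presence/absence testing of called variants against a panel of normals.

Unrelated non-tumor samples provide a locus-specific sequencing error rate;
each (variant, sample) observation is then tested with a one-sided exact
binomial test against that error rate, and calls are accepted when the
multiple-testing corrected p-value falls below a stringent threshold
(default 0.001), minimizing false positives when deciding which regions of
a tumor truly share a mutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class LocusErrorModel:
    """Pooled panel counts and the resulting error-rate estimate at one locus."""

    mutation_id: str
    panel_alt: int
    panel_depth: int
    pseudocount: float
    error_rate: float


@dataclass
class PresenceCall:
    mutation_id: str
    sample: str
    alt_reads: int
    depth: int
    error_rate: float
    p_value: float
    q_value: float
    present: bool


def estimate_error_rates(
    panel: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> dict[str, LocusErrorModel]:
    """Estimate per-locus error rates from panel-of-normals read counts.

    ``panel`` has columns chrom,pos,ref,alt,depth,alt_reads (one or more rows
    per locus; counts are pooled). The estimate is regularized with a
    symmetric pseudocount and capped at 0.5:

        eps = (alt + c) / (depth + 2c)
    """
    required = {"chrom", "pos", "ref", "alt", "depth", "alt_reads"}
    if missing := required - set(panel.columns):
        raise ValueError(f"panel table missing columns {sorted(missing)}")
    models: dict[str, LocusErrorModel] = {}
    grouped = panel.groupby(["chrom", "pos", "ref", "alt"], sort=False)
    for (chrom, pos, ref, alt), grp in grouped:
        depth = int(grp["depth"].sum())
        alt_n = int(grp["alt_reads"].sum())
        if depth <= 0:
            raise ValueError(f"zero panel depth at {chrom}:{pos}")
        eps = (alt_n + pseudocount) / (depth + 2.0 * pseudocount)
        eps = min(eps, 0.5)
        mid = f"{chrom}:{pos}:{ref}>{alt}"
        models[mid] = LocusErrorModel(mid, alt_n, depth, pseudocount, eps)
    return models


def presence_p_value(alt_reads: int, depth: int, error_rate: float) -> float:
    """One-sided exact binomial tail P(X >= alt_reads | depth, error_rate)."""
    if alt_reads <= 0:
        return 1.0
    return float(stats.binom.sf(alt_reads - 1, depth, error_rate))


def test_presence(
    variant: VariantRecord, sample: str, model: LocusErrorModel
) -> tuple[float, LocusErrorModel]:
    """p-value for the variant's counts in one sample under the locus error model."""
    counts = variant.samples[sample]
    return presence_p_value(counts.alt_reads, counts.depth, model.error_rate), model


def call_presence(
    variants: list[VariantRecord],
    models: dict[str, LocusErrorModel],
    alpha: float = DEFAULT_ALPHA,
    method: str = "bh",
) -> pd.DataFrame:
    """Test every (variant, sample) pair and correct across the whole run.

    ``method`` is "bh" (Benjamini-Hochberg, default) or "bonferroni". A
    variant is called present in a sample when its corrected p-value is
    below ``alpha``.
    """
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown correction method {method!r}")
    rows = []
    for variant in variants:
        model = models.get(variant.mutation_id)
        if model is None:
            raise ValueError(f"no panel error model for {variant.mutation_id}")
        for sample, counts in variant.samples.items():
            rows.append(
                {
                    "mutation_id": variant.mutation_id,
                    "sample": sample,
                    "alt_reads": counts.alt_reads,
                    "depth": counts.depth,
                    "error_rate": model.error_rate,
                    "p_value": presence_p_value(counts.alt_reads, counts.depth, model.error_rate),
                }
            )
    calls = pd.DataFrame(rows)
    if calls.empty:
        calls["q_value"] = []
        calls["present"] = []
        return calls
    _, q, _, _ = multipletests(calls["p_value"].to_numpy(), method=sm_method)
    calls["q_value"] = q
    calls["present"] = (q < alpha) & (calls["alt_reads"] > 0)
    logger.info(
        "presence filter: %d/%d (mutation, sample) pairs accepted at alpha=%g (%s)",
        int(calls["present"].sum()), len(calls), alpha, method,
    )
    return calls
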