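"""Cancer cell fraction (CCF) computation from read counts, purity and copy number.

The CCF of a somatic substitution — the fraction of cancer cells carrying
it — is obtained from the variant allele fraction (VAF) in three steps:

1. adjust the VAF for non-tumor contamination by dividing by the sample
   purity;
2. classify the locus by its allele-specific copy-number state, and for
   single-copy gains decide by binomial likelihood whether the mutation sits
   on the duplicated allele (two of three copies) or on a single copy;
3. scale the adjusted VAF by the state-specific factor: x2 for diploid
   loci, x1 for loci with loss of heterozygosity, x3 for a mutation on a
   single copy of a 2+1 gain, and x1.5 for a mutation on the duplicated
   allele.

CCFs are reported raw (not capped at 1); loci in any other copy-number
state are excluded from downstream analysis with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .variant_io import CopyNumberSegment, SampleMeta, VariantRecord, lookup_segment

logger = logging.getLogger(__name__)

# copy-number classes
DIPLOID = "diploid"
LOH = "loh"
GAIN = "gain"  # 2+1 gain before allele assignment
GAIN_SINGLE = "gain_single"
GAIN_DUPLICATED = "gain_duplicated"
OTHER = "other"

_CCF_MULTIPLIER = {DIPLOID: 2.0, LOH: 1.0, GAIN_SINGLE: 3.0, GAIN_DUPLICATED: 1.5}


@dataclass
class MutationAnnotation:
    """Per-sample annotation of one mutation: VAF, CN class, multiplicity, CCF."""

    mutation_id: str
    sample: str
    vaf: float
    adjusted_vaf: float
    cn_class: str
    multiplicity: int
    total_cn: int
    purity: float
    ccf: float
    p_duplicated: float | None = None
    excluded: bool = False
    reason: str | None = None


def expected_vaf(multiplicity: int, total_cn: int, purity: float) -> float:
    """Expected VAF of a fully clonal mutation on ``multiplicity`` of
    ``total_cn`` tumor copies in a sample of the given purity, assuming
    diploid contaminating normal cells:

        xi = m * p / (2 * (1 - p) + n_t * p)
    """
    if not 1 <= multiplicity <= total_cn:
        raise ValueError(f"multiplicity {multiplicity} outside [1, total_cn={total_cn}]")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    return multiplicity * purity / (2.0 * (1.0 - purity) + total_cn * purity)


def classify_cn(segment: CopyNumberSegment) -> str:
    """Map an allele-specific copy-number state to its CCF rule class.

    (1,1) is diploid; minor=0 with major>=1 is LOH; (2,1) is a single-copy
    gain (allele assignment still needed); anything else is excluded.
    """
    major, minor = segment.major_cn, segment.minor_cn
    if (major, minor) == (1, 1):
        return DIPLOID
    if minor == 0 and major >= 1:
        return LOH
    if (major, minor) == (2, 1):
        return GAIN
    return OTHER


def assign_allele(
    variant: VariantRecord, sample: str, segment: CopyNumberSegment, purity: float
) -> tuple[str, float]:
    """Decide whether a mutation on a 2+1 gain lies on the duplicated allele.

    Compares binomial likelihoods of the observed alt count under the
    expected VAFs for multiplicity 1 and 2 (equal priors); ties break to the
    single-copy class. Returns (class, posterior probability of duplicated).
    """
    counts = variant.samples[sample]
    if counts.depth == 0:
        raise ValueError(f"zero depth for {variant.mutation_id} in {sample}")
    xi1 = expected_vaf(1, 3, purity)
    xi2 = expected_vaf(2, 3, purity)
    ll1 = stats.binom.logpmf(counts.alt_reads, counts.depth, xi1)
    ll2 = stats.binom.logpmf(counts.alt_reads, counts.depth, xi2)
    post2 = float(special.expit(ll2 - ll1))
    cls = GAIN_DUPLICATED if ll2 > ll1 else GAIN_SINGLE
    return cls, float(post2)


def _multiplicity_for(cn_class: str, segment: CopyNumberSegment) -> int:
    if cn_class == DIPLOID:
        return 1
    if cn_class == LOH:
        return max(segment.major_cn, 1)
    if cn_class == GAIN_SINGLE:
        return 1
    if cn_class == GAIN_DUPLICATED:
        return 2
    return 1


def compute_ccf(
    variant: VariantRecord,
    sample: str,
    segment: CopyNumberSegment | None,
    purity: float,
    gain_class: str | None = None,
) -> MutationAnnotation:
    """Annotate one mutation in one sample with its CCF.

    ``gain_class`` optionally forces the allele assignment on gain segments
    (used to share the truncal assignment across regions); otherwise the
    assignment is made from this sample's counts.
    """
    counts = variant.samples[sample]
    vaf = counts.vaf
    adjusted = vaf / purity
    if segment is None:
        return MutationAnnotation(
            variant.mutation_id, sample, vaf, adjusted, OTHER, 1, 0, purity,
            float("nan"), excluded=True, reason="no copy-number segment",
        )
    cn_class = classify_cn(segment)
    p_dup = None
    if cn_class == GAIN:
        if gain_class in (GAIN_SINGLE, GAIN_DUPLICATED):
            cn_class = gain_class
        else:
            cn_class, p_dup = assign_allele(variant, sample, segment, purity)
    if cn_class == OTHER:
        return MutationAnnotation(
            variant.mutation_id, sample, vaf, adjusted, OTHER, 1, segment.total_cn,
            purity, float("nan"), excluded=True, reason="unsupported copy-number state",
        )
    mult = _multiplicity_for(cn_class, segment)
    ccf = _CCF_MULTIPLIER[cn_class] * adjusted
    return MutationAnnotation(
        variant.mutation_id, sample, vaf, adjusted, cn_class, mult, segment.total_cn,
        purity, ccf, p_duplicated=p_dup,
    )


def annotate(
    variants: list[VariantRecord],
    segments: list[CopyNumberSegment],
    meta: list[SampleMeta],
) -> pd.DataFrame:
    """Annotate every (mutation, sample) pair with VAF, CN class and CCF.

    For gain-region mutations in multi-region tumors, the allele assignment
    is made once in the sample with the highest purity (where the expected
    VAFs of the two classes are farthest apart) and shared across regions.
    """
    purity = {m.sample: m.purity for m in meta}
    seg_by_sample: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        seg_by_sample.setdefault(seg.sample, []).append(seg)

    rows = []
    n_excluded = 0
    for variant in variants:
        sample_names = [s for s in variant.samples if s in purity]
        # shared truncal allele assignment: decided in the highest-purity
        # sample whose locus is a gain and has nonzero depth
        gain_class = None
        for s in sorted(sample_names, key=lambda s: -purity[s]):
            seg = lookup_segment(seg_by_sample.get(s, []), variant.chrom, variant.pos)
            if seg is not None and classify_cn(seg) == GAIN and variant.samples[s].depth > 0:
                gain_class, _ = assign_allele(variant, s, seg, purity[s])
                break
        for s in sample_names:
            seg = lookup_segment(seg_by_sample.get(s, []), variant.chrom, variant.pos)
            ann = compute_ccf(variant, s, seg, purity[s], gain_class=gain_class)
            if ann.excluded:
                n_excluded += 1
            rows.append(
                {
                    "mutation_id": ann.mutation_id,
                    "chrom": variant.chrom,
                    "pos": variant.pos,
                    "ref": variant.ref,
                    "alt": variant.alt,
                    "context": variant.context,
                    "sample": ann.sample,
                    "depth": variant.samples[s].depth,
                    "alt_reads": variant.samples[s].alt_reads,
                    "purity": ann.purity,
                    "vaf": ann.vaf,
                    "adjusted_vaf": ann.adjusted_vaf,
                    "cn_class": ann.cn_class,
                    "multiplicity": ann.multiplicity,
                    "total_cn": ann.total_cn,
                    "ccf": ann.ccf,
                    "p_duplicated": ann.p_duplicated,
                    "excluded": ann.excluded,
                }
            )
    if n_excluded:
        logger.info("excluded %d (mutation, sample) annotations", n_excluded)
    return pd.DataFrame(rows)
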