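import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonechron import ccf_engine
from clonechron.ccf_engine import (
    DIPLOID,
    GAIN_DUPLICATED,
    GAIN_SINGLE,
    LOH,
    OTHER,
    assign_allele,
    classify_cn,
    compute_ccf,
    expected_vaf,
)
from clonechron.variant_io import CopyNumberSegment
from tests.conftest import make_variant


@pytest.mark.parametrize(
    "m, nt, p, expected",
    [
        (1, 2, 1.0, 0.5),  # pure-tumor heterozygous diploid
        (2, 3, 1.0, 2 / 3),  # duplicated allele of a 2+1 gain, pure tumor
        (1, 3, 0.8, 0.8 / (0.4 + 2.4)),  # direct arithmetic
        (2, 2, 1.0, 1.0),  # both copies mutated
    ],
)
def test_expected_vaf_values(m, nt, p, expected):
    assert expected_vaf(m, nt, p) == pytest.approx(expected, abs=1e-12)


def test_expected_vaf_rejects_multiplicity_above_total_cn():
    with pytest.raises(ValueError):
        expected_vaf(3, 2, 1.0)
    with pytest.raises(ValueError):
        expected_vaf(1, 2, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    m=st.integers(1, 4),
    extra=st.integers(0, 3),
    p=st.floats(0.05, 1.0),
)
def test_expected_vaf_bounded(m, extra, p):
    assert 0 < expected_vaf(m, m + extra, p) <= 1


@pytest.mark.parametrize(
    "major, minor, expected",
    [
        (1, 1, DIPLOID),
        (2, 0, LOH),  # e.g. the lost arm after an isochromosome event
        (1, 0, LOH),
        (2, 1, "gain"),
        (3, 2, OTHER),  # higher amplification: excluded
        (2, 2, OTHER),
    ],
)
def test_classify_cn(major, minor, expected):
    seg = CopyNumberSegment("S1", "chr1", 1, 100, major, minor)
    assert classify_cn(seg) == expected


def test_assign_allele_by_binomial_likelihood(gain_segment):
    # oracle: expected VAFs at purity 1 are 1/3 and 2/3
    dup = make_variant(chrom="chr1", alt_reads=65)
    single = make_variant(chrom="chr1", alt_reads=33)
    assert assign_allele(dup, "S1", gain_segment, 1.0)[0] == GAIN_DUPLICATED
    assert assign_allele(single, "S1", gain_segment, 1.0)[0] == GAIN_SINGLE


def test_assign_allele_tie_breaks_to_single_copy(gain_segment):
    # alt/depth exactly midway between 1/3 and 2/3: equal likelihoods
    mid = make_variant(chrom="chr1", alt_reads=50)
    cls, post = assign_allele(mid, "S1", gain_segment, 1.0)
    assert cls == GAIN_SINGLE
    assert post == pytest.approx(0.5)


def test_assign_allele_requires_depth(gain_segment):
    v = make_variant(chrom="chr1", depth=0, alt_reads=0)
    with pytest.raises(ValueError):
        assign_allele(v, "S1", gain_segment, 1.0)


class TestCcfRules:
    def test_diploid_doubles_adjusted_vaf(self, diploid_segment):
        v = make_variant(depth=100, alt_reads=40)
        ann = compute_ccf(v, "S1", diploid_segment, purity=0.8)
        assert ann.adjusted_vaf == pytest.approx(0.5)
        assert ann.ccf == pytest.approx(1.0)
        assert ann.multiplicity == 1

    def test_loh_ccf_equals_adjusted_vaf(self, loh_segment):
        v = make_variant(chrom="chr1", pos=15_000_000, depth=100, alt_reads=25)
        ann = compute_ccf(v, "S1", loh_segment, purity=0.5)
        assert ann.cn_class == LOH
        assert ann.ccf == pytest.approx(0.5)

    def test_duplicated_allele_times_1_5(self, gain_segment):
        v = make_variant(chrom="chr1", depth=99, alt_reads=66)
        ann = compute_ccf(v, "S1", gain_segment, purity=1.0)
        assert ann.cn_class == GAIN_DUPLICATED
        assert ann.multiplicity == 2
        assert ann.ccf == pytest.approx(1.0)

    def test_single_copy_times_3(self, gain_segment):
        v = make_variant(chrom="chr1", depth=99, alt_reads=33)
        ann = compute_ccf(v, "S1", gain_segment, purity=1.0)
        assert ann.cn_class == GAIN_SINGLE
        assert ann.ccf == pytest.approx(1.0)

    def test_missing_segment_and_other_states_excluded(self):
        v = make_variant()
        assert compute_ccf(v, "S1", None, purity=0.8).excluded
        amp = CopyNumberSegment("S1", "chr2", 1, 10_000_000, 3, 2)
        ann = compute_ccf(v, "S1", amp, purity=0.8)
        assert ann.excluded and ann.cn_class == OTHER

    def test_ccf_not_capped_at_one(self, diploid_segment):
        v = make_variant(depth=100, alt_reads=80)
        ann = compute_ccf(v, "S1", diploid_segment, purity=0.9)
        assert ann.ccf > 1.5  # raw value retained


@pytest.mark.parametrize("purity", [0.13, 0.5, 0.81, 1.0])
@pytest.mark.parametrize(
    "cn, m",
    [((1, 1), 1), ((2, 0), 2)],
)
def test_closed_loop_identity_diploid_and_loh(purity, cn, m):
    """A noiseless clonal VAF maps back to CCF exactly 1 for diploid and
    total-CN-2 LOH loci at any purity."""
    seg = CopyNumberSegment("S1", "chr1", 1, 1000, *cn)
    xi = expected_vaf(m, sum(cn), purity)
    depth = 10_000_000
    v = make_variant(chrom="chr1", depth=depth, alt_reads=round(xi * depth))
    ann = compute_ccf(v, "S1", seg, purity)
    assert ann.ccf == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("m, alt_frac", [(1, 1 / 3), (2, 2 / 3)])
def test_closed_loop_identity_gain_pure_tumor(gain_segment, m, alt_frac):
    """In the pure-tumor limit the x3 / x1.5 gain rules are exact."""
    depth = 3_000_000
    v = make_variant(chrom="chr1", depth=depth, alt_reads=round(alt_frac * depth))
    ann = compute_ccf(v, "S1", gain_segment, purity=1.0)
    assert ann.multiplicity == m
    assert ann.ccf == pytest.approx(1.0, abs=1e-6)


def test_ccf_strictly_increasing_in_alt_reads(diploid_segment):
    ccfs = [
        compute_ccf(make_variant(alt_reads=a), "S1", diploid_segment, 0.8).ccf
        for a in range(0, 101, 10)
    ]
    assert all(b > a for a, b in zip(ccfs, ccfs[1:]))


def test_annotate_shares_truncal_gain_assignment_across_regions():
    """The allele call made in the highest-purity region is applied to all."""
    from clonechron.variant_io import SampleCounts, SampleMeta, VariantRecord

    v = VariantRecord(
        "chr1", 500, "A", "T",
        {
            # high purity: clearly duplicated (2/3); low purity: ambiguous
            "R1": SampleCounts(depth=120, alt_reads=80),
            "R2": SampleCounts(depth=100, alt_reads=20),
        },
    )
    segs = [CopyNumberSegment(s, "chr1", 1, 1000, 2, 1) for s in ("R1", "R2")]
    meta = [SampleMeta("R1", "D", 1.0, 30.0), SampleMeta("R2", "D", 0.3, 30.0)]
    ann = ccf_engine.annotate([v], segs, meta)
    assert set(ann["cn_class"]) == {GAIN_DUPLICATED}
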