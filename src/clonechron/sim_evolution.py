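"""Truth-annotated simulator of multi-region tumor sequencing data.

The generator emulates the statistical structure the downstream analysis
assumes: a truncal clone carrying all shared mutations, nested subclones
whose cancer cell fractions obey the pigeonhole constraint in every
region, an isochromosome-style event (loss of one arm, single-copy gain of
the other) placed at a known time on the molecular clock, binomial read
sampling at configurable depth, and a panel of normals with a configurable
per-base error rate.

The genome is two synthetic chromosomes. chr1 carries the event: its first
arm is lost (copy number 1+0) and its second arm gained (2+1); chr2 is
diploid. Mutation positions are drawn uniformly within arms — only the
copy-number class of a locus matters downstream, so no reference sequence
is needed. Trinucleotide contexts are sampled from a configurable
96-category distribution (uniform by default) and written directly into
the variant table.

Truncal mutations on the gained arm are split into a multiplicity-2 class
(acquired before the gain on the copy that was later duplicated; expected
count (rate/2) * arm_fraction * gain_time) and a multiplicity-1 class.
Read depths are Poisson around the configured means (floored at 1), and
alt counts are binomial at the expected VAF implied by cluster CCF,
purity, total copy number and multiplicity. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import spectra as _spectra
from .ccf_engine import expected_vaf
from .variant_io import CopyNumberSegment, SampleCounts, SampleMeta, VariantRecord

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


class CloneSpecError(ValueError):
    """The clone specification violates a structural constraint."""


@dataclass(frozen=True)
class Clone:
    """One cluster of the simulated clone tree."""

    cluster_id: str
    parent_id: str | None
    ccf_per_region: tuple[float, ...]
    n_mutations: int


def truncal_only_spec(n_mutations: int, n_regions: int = 1) -> tuple[Clone, ...]:
    return (Clone("truncal", None, (1.0,) * n_regions, n_mutations),)


def default_clone_spec(n_regions: int = 1) -> tuple[Clone, ...]:
    """Truncal clone plus one broad low-CCF subclone.

    Sized to the cohort's observed scale: ~80 truncal mutations (an MRCA in
    the first few years of life at 26 substitutions/year) and a subclonal
    set at mean CCF 0.25 bringing the per-sample burden near the observed
    median of ~730.
    """
    return (
        Clone("truncal", None, (1.0,) * n_regions, 80),
        Clone("sub1", "truncal", (0.25,) * n_regions, 648),
    )


def five_region_spec() -> tuple[Clone, ...]:
    """A five-region clone tree: short trunk, three intermediate nodes (two
    of which split into private leaves, one itself terminal), five terminal
    branches in all — one per sampled region."""
    return (
        Clone("truncal", None, (1.0, 1.0, 1.0, 1.0, 1.0), 80),
        Clone("intA", "truncal", (0.80, 0.70, 0.0, 0.0, 0.0), 60),
        Clone("intB", "truncal", (0.0, 0.0, 0.75, 0.70, 0.0), 60),
        Clone("intC", "truncal", (0.0, 0.0, 0.0, 0.0, 0.80), 70),
        Clone("leafA1", "intA", (0.45, 0.0, 0.0, 0.0, 0.0), 55),
        Clone("leafA2", "intA", (0.30, 0.55, 0.0, 0.0, 0.0), 55),
        Clone("leafB1", "intB", (0.0, 0.0, 0.50, 0.10, 0.0), 55),
        Clone("leafB2", "intB", (0.0, 0.0, 0.15, 0.50, 0.0), 55),
    )


@dataclass
class SimConfig:
    """Study-design parameters of one simulated tumor.

    Defaults reflect the sequencing design and cohort-level estimates the
    analysis was built for: 82x tumor / 43x normal coverage, purity 0.81,
    26 diploid genome-wide substitutions per year, a donor in their late
    twenties, and an arm-level gain acquired at age two.
    """

    seed: int = 0
    n_regions: int = 1
    donor_age_years: float = 29.0
    rate_per_year: float = 26.0
    purity_per_region: tuple[float, ...] = ()
    tumor_depth_mean: float = 82.0
    normal_depth_mean: float = 43.0
    clone_spec: tuple[Clone, ...] = ()
    gain_time_years: float = 2.0
    arm_fraction: float = 0.04
    callable_genome_bp: float = 2.9e9
    panel_error_rate: float = 1e-3
    panel_depth: int = 10000
    poisson_mutation_counts: bool = False
    context_distribution: tuple[float, ...] | None = None  # 96 probs; None = uniform
    donor_id: str = "donor1"

    def __post_init__(self):
        if not self.clone_spec:
            self.clone_spec = default_clone_spec(self.n_regions)
        if not self.purity_per_region:
            self.purity_per_region = (0.81,) * self.n_regions

    def validate(self) -> None:
        if self.n_regions < 1:
            raise CloneSpecError("n_regions must be >= 1")
        if len(self.purity_per_region) != self.n_regions:
            raise CloneSpecError("purity_per_region length must equal n_regions")
        if any(not 0 < p <= 1 for p in self.purity_per_region):
            raise CloneSpecError("purities must be in (0, 1]")
        if self.donor_age_years <= 0 or self.rate_per_year <= 0:
            raise CloneSpecError("age and rate must be positive")
        if not 0 < self.arm_fraction < 1:
            raise CloneSpecError("arm_fraction must be in (0, 1)")
        if not 0 <= self.panel_error_rate <= 1e-2:
            raise CloneSpecError("panel_error_rate must be in [0, 1e-2]")
        clones = {c.cluster_id: c for c in self.clone_spec}
        roots = [c for c in self.clone_spec if c.parent_id is None]
        if len(roots) != 1:
            raise CloneSpecError(f"need exactly one root clone, found {len(roots)}")
        root = roots[0]
        if any(abs(c - 1.0) > 1e-9 for c in root.ccf_per_region):
            raise CloneSpecError(f"root clone {root.cluster_id} must have CCF 1.0 in all regions")
        for c in self.clone_spec:
            if len(c.ccf_per_region) != self.n_regions:
                raise CloneSpecError(f"clone {c.cluster_id} has wrong CCF dimension")
            if c.parent_id is not None:
                parent = clones.get(c.parent_id)
                if parent is None:
                    raise CloneSpecError(f"clone {c.cluster_id} has unknown parent {c.parent_id}")
                for r, (cc, pc) in enumerate(zip(c.ccf_per_region, parent.ccf_per_region)):
                    if cc > pc + 1e-9:
                        raise CloneSpecError(
                            f"pigeonhole violation: clone {c.cluster_id} CCF {cc} exceeds "
                            f"parent {c.parent_id} CCF {pc} in region {r + 1}"
                        )
        mrca_time = root.n_mutations / self.rate_per_year
        if self.gain_time_years < 0 or self.gain_time_years > mrca_time + 1e-9:
            raise CloneSpecError(
                f"gain_time_years {self.gain_time_years} must lie in [0, implied MRCA "
                f"time {mrca_time:.3g}]"
            )


@dataclass
class TruthTables:
    """Ground truth emitted alongside the simulated tables."""

    mutation_truth: pd.DataFrame  # mutation_id, cluster_id, multiplicity, segment_class
    cluster_truth: pd.DataFrame  # cluster_id, region/sample, ccf, n_mutations
    event_truth: dict  # gain_time_years, mrca_time_years


@dataclass
class SimResult:
    variants: list[VariantRecord]
    segments: list[CopyNumberSegment]
    meta: list[SampleMeta]
    truth: TruthTables
    config: SimConfig

    @property
    def sample_names(self) -> list[str]:
        return [m.sample for m in self.meta]


# segment classes
SEG_LOSS = "loss_arm"  # chr1 first arm, 1+0
SEG_GAIN = "gain_arm"  # chr1 second arm, 2+1
SEG_DIPLOID = "diploid"  # chr2, 1+1

_SEG_CN = {SEG_LOSS: (1, 0), SEG_GAIN: (2, 1), SEG_DIPLOID: (1, 1)}


def _genome_layout(config: SimConfig):
    """(chrom, start, end) per segment class; gained-arm length is
    arm_fraction of the haploid callable genome, the lost arm matches it,
    and chr2 takes the remainder."""
    half = config.callable_genome_bp / 2.0
    l_gain = int(round(config.arm_fraction * half))
    l_loss = l_gain
    l_dip = int(round(half)) - l_gain - l_loss
    return {
        SEG_LOSS: ("chr1", 1, l_loss),
        SEG_GAIN: ("chr1", l_loss + 1, l_loss + l_gain),
        SEG_DIPLOID: ("chr2", 1, l_dip),
    }


def _draw_context(rng: np.random.Generator, probs: np.ndarray):
    """Sample a 96-channel, return (context, ref, alt), random strand."""
    ch = int(rng.choice(96, p=probs))
    name = _spectra.CHANNELS[ch]
    five, ref, alt, three = name[0], name[2], name[4], name[6]
    context = five + ref + three
    if rng.random() < 0.5:  # emit the purine strand half the time
        context = context[::-1].translate(_COMP)
        ref = ref.translate(_COMP)
        alt = alt.translate(_COMP)
    return context, ref, alt


def simulate_tumor(config: SimConfig) -> SimResult:
    """Generate variant, segment and metadata tables plus ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = _genome_layout(config)
    regions = [f"R{i + 1}" for i in range(config.n_regions)]
    probs = (
        np.full(96, 1.0 / 96.0)
        if config.context_distribution is None
        else np.asarray(config.context_distribution, dtype=float)
    )
    if probs.shape != (96,) or abs(probs.sum() - 1.0) > 1e-6:
        raise CloneSpecError("context_distribution must be 96 probabilities summing to 1")

    clones = list(config.clone_spec)
    root = next(c for c in clones if c.parent_id is None)

    # per-copy placement weights: copy number times haploid arm length
    seg_names = [SEG_LOSS, SEG_GAIN, SEG_DIPLOID]
    cn_totals = {s: sum(_SEG_CN[s]) for s in seg_names}
    lengths = {s: layout[s][2] - layout[s][1] + 1 for s in seg_names}
    weights = np.array([cn_totals[s] * lengths[s] for s in seg_names], dtype=float)
    weights /= weights.sum()

    used_positions: set[tuple[str, int]] = set()

    def draw_position(seg_name: str) -> tuple[str, int]:
        chrom, start, end = layout[seg_name]
        while True:
            pos = int(rng.integers(start, end + 1))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                return chrom, pos

    variants: list[VariantRecord] = []
    truth_rows = []
    cluster_sizes: dict[str, int] = {}

    for clone in clones:
        n = clone.n_mutations
        if config.poisson_mutation_counts:
            n = int(rng.poisson(n))
        # truncal mutations acquired before the gain on the to-be-duplicated
        # copy: multiplicity 2 on the gained arm
        n_dup = 0
        if clone is root:
            expected_dup = (config.rate_per_year / 2.0) * config.arm_fraction * config.gain_time_years
            n_dup = min(int(rng.poisson(expected_dup)), n)
        seg_assign = [SEG_GAIN] * n_dup + [
            seg_names[i] for i in rng.choice(len(seg_names), size=n - n_dup, p=weights)
        ]
        mults = [2] * n_dup + [1] * (n - n_dup)
        cluster_sizes[clone.cluster_id] = n

        for seg_name, mult in zip(seg_assign, mults):
            chrom, pos = draw_position(seg_name)
            context, ref, alt = _draw_context(rng, probs)
            major, minor = _SEG_CN[seg_name]
            total_cn = major + minor
            samples = {}
            for r, region in enumerate(regions):
                purity = config.purity_per_region[r]
                ccf = clone.ccf_per_region[r]
                xi = ccf * expected_vaf(mult, total_cn, purity) if ccf > 0 else 0.0
                xi = min(xi, 1.0)
                depth = max(int(rng.poisson(config.tumor_depth_mean)), 1)
                alt_reads = int(rng.binomial(depth, xi))
                samples[region] = SampleCounts(depth=depth, alt_reads=alt_reads)
            rec = VariantRecord(chrom, pos, ref, alt, samples, context)
            variants.append(rec)
            truth_rows.append(
                {
                    "mutation_id": rec.mutation_id,
                    "cluster_id": clone.cluster_id,
                    "multiplicity": mult,
                    "segment_class": seg_name,
                }
            )

    segments = [
        CopyNumberSegment(region, chrom, start, end, *(_SEG_CN[s]))
        for region in regions
        for s, (chrom, start, end) in ((s, layout[s]) for s in seg_names)
    ]
    meta = [
        SampleMeta(region, config.donor_id, config.purity_per_region[r], config.donor_age_years)
        for r, region in enumerate(regions)
    ]

    cluster_truth = pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "sample": region,
                "ccf": c.ccf_per_region[r],
                "n_mutations": cluster_sizes[c.cluster_id],
            }
            for c in clones
            for r, region in enumerate(regions)
        ]
    )
    truth = TruthTables(
        mutation_truth=pd.DataFrame(truth_rows),
        cluster_truth=cluster_truth,
        event_truth={
            "gain_time_years": config.gain_time_years,
            "mrca_time_years": cluster_sizes[root.cluster_id] / config.rate_per_year,
        },
    )
    return SimResult(variants, segments, meta, truth, config)


def simulate_panel(config: SimConfig, loci: list[VariantRecord]) -> pd.DataFrame:
    """Panel-of-normals alt counts at the given loci.

    One pooled pseudo-sample: alt ~ Binomial(panel_depth, panel_error_rate)
    per locus, on an independent substream of the configured seed.
    """
    rng = np.random.default_rng([config.seed, 7])
    rows = []
    for rec in loci:
        alt = int(rng.binomial(config.panel_depth, config.panel_error_rate))
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "sample": "panel",
                "depth": config.panel_depth,
                "alt_reads": alt,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample", "depth", "alt_reads"]
    )


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (YAML-friendly)."""
    d = dict(d)
    spec = d.pop("clone_spec", None)
    if isinstance(spec, str):
        named = {"default": None, "truncal_only": None, "five_region": five_region_spec()}
        if spec == "five_region":
            d["clone_spec"] = five_region_spec()
            d.setdefault("n_regions", 5)
        elif spec == "truncal_only":
            d["clone_spec"] = truncal_only_spec(
                d.pop("n_truncal", 80), d.get("n_regions", 1)
            )
        elif spec != "default":
            raise CloneSpecError(f"unknown clone_spec name {spec!r}; choose from {sorted(named)}")
    elif spec is not None:
        d["clone_spec"] = tuple(
            Clone(c["cluster_id"], c.get("parent_id"), tuple(c["ccf_per_region"]), int(c["n_mutations"]))
            for c in spec
        )
    if "purity_per_region" in d and d["purity_per_region"] is not None:
        d["purity_per_region"] = tuple(d["purity_per_region"])
    return SimConfig(**d)
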