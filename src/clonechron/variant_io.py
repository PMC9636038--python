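"""Readers and writers for the tabular artifacts of subclonal reconstruction.

The on-disk formats are deliberately plain: tab-separated tables for somatic
variants, allele-specific copy-number segments (Battenberg-style output),
and per-sample metadata; a restricted VCF 4.2 reader for SNV calls carrying
per-sample AD/DP fields; and Newick/JSON writers for clone trees.

All genomic coordinates are 1-based and inclusive, matching the conventions
of the upstream variant callers and of Battenberg segment tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "depth", "alt_reads", "context"]
SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]
META_COLUMNS = ["sample", "donor", "purity", "age_years"]

MISSING = "."


class ParseError(ValueError):
    """A malformed row in an input file; carries the 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class ValidationError(ValueError):
    """Input violated a structural invariant (e.g. alt_reads > depth)."""


@dataclass(frozen=True)
class SampleCounts:
    """Read support for one variant in one sample."""

    depth: int
    alt_reads: int

    def __post_init__(self):
        if self.depth < 0 or self.alt_reads < 0:
            raise ValidationError(f"negative counts: depth={self.depth}, alt_reads={self.alt_reads}")
        if self.alt_reads > self.depth:
            raise ValidationError(f"alt_reads {self.alt_reads} exceeds depth {self.depth}")

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0


@dataclass
class VariantRecord:
    """One somatic single-base substitution with per-sample read counts.

    ``context`` is the reference trinucleotide around the site (central base
    equal to ``ref``) and may be absent (None).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    samples: dict[str, SampleCounts] = field(default_factory=dict)
    context: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(f"ref/alt must be single bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.context is not None:
            if len(self.context) != 3 or any(b not in _BASES for b in self.context):
                raise ValidationError(f"bad trinucleotide context {self.context!r}")
            if self.context[1] != self.ref:
                raise ValidationError(
                    f"context {self.context} center does not match ref {self.ref} at {self.chrom}:{self.pos}"
                )

    @property
    def mutation_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class CopyNumberSegment:
    """Allele-specific copy-number interval for one sample (1-based, inclusive)."""

    sample: str
    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValidationError(
                f"require major_cn >= minor_cn >= 0, got ({self.major_cn},{self.minor_cn})"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class SampleMeta:
    """Per-sample purity and donor/age bookkeeping."""

    sample: str
    donor: str
    purity: float
    age_years: float

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValidationError(f"purity must be in (0,1], got {self.purity}")
        if self.age_years <= 0:
            raise ValidationError(f"age_years must be positive, got {self.age_years}")


# ---------------------------------------------------------------------------
# variants


def read_variants(path, format: str = "tsv") -> list[VariantRecord]:
    """Read somatic SNVs from a TSV table or a restricted VCF 4.2 file.

    TSV rows are one (variant, sample) pair; rows sharing chrom/pos/ref/alt
    are merged into a single :class:`VariantRecord`. VCF input is limited to
    SNVs with per-sample AD/DP; multiallelic rows are split and non-SNV
    alleles skipped (a count is logged).
    """
    if format == "tsv":
        return _read_variants_tsv(path)
    if format == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown variant format {format!r}")


def _read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns and c != "context"]
    if missing:
        raise ParseError(f"missing columns {missing}", path=path, line=1)
    records: dict[tuple, VariantRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            chrom = str(row.chrom)
            pos = int(row.pos)
            ref, alt = str(row.ref), str(row.alt)
            sample = str(row.sample)
            counts = SampleCounts(depth=int(row.depth), alt_reads=int(row.alt_reads))
            context = getattr(row, "context", MISSING)
            context = None if (pd.isna(context) or context == MISSING) else str(context)
            key = (chrom, pos, ref, alt)
            if key in records:
                rec = records[key]
                if sample in rec.samples:
                    raise ValidationError(f"duplicate sample {sample} for {chrom}:{pos}")
                rec.samples[sample] = counts
                if rec.context is None:
                    rec.context = context
                    VariantRecord(chrom, pos, ref, alt, {}, context)  # re-validate context
            else:
                records[key] = VariantRecord(chrom, pos, ref, alt, {sample: counts}, context)
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), path=path, line=line) from exc
    return list(records.values())


def _read_variants_vcf(path) -> list[VariantRecord]:
    import pysam

    records: dict[tuple, VariantRecord] = {}
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            for ai, alt in enumerate(rec.alts or ()):
                if len(rec.ref) != 1 or alt is None or len(alt) != 1 or rec.ref not in _BASES or alt not in _BASES:
                    n_skipped += 1
                    continue
                samples = {}
                for name in sample_names:
                    fmt = rec.samples[name]
                    ad = fmt.get("AD")
                    if ad is None or ad[ai + 1] is None:
                        continue
                    alt_reads = int(ad[ai + 1])
                    depth = fmt.get("DP")
                    depth = int(depth) if depth is not None else int(sum(x or 0 for x in ad))
                    if alt_reads > depth:
                        raise ValidationError(
                            f"alt_reads {alt_reads} > depth {depth} for {name} at {rec.chrom}:{rec.pos}"
                        )
                    samples[name] = SampleCounts(depth=depth, alt_reads=alt_reads)
                key = (rec.chrom, rec.pos, rec.ref, alt)
                records[key] = VariantRecord(rec.chrom, rec.pos, rec.ref, alt, samples)
    if n_skipped:
        logger.info("skipped %d non-SNV VCF allele(s)", n_skipped)
    return list(records.values())


def write_variants(records: list[VariantRecord], path) -> None:
    rows = []
    for rec in records:
        for sample, counts in rec.samples.items():
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "sample": sample,
                    "depth": counts.depth,
                    "alt_reads": counts.alt_reads,
                    "context": rec.context if rec.context is not None else MISSING,
                }
            )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segments and metadata


def read_segments(path) -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep="\t")
    segments = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            segments.append(
                CopyNumberSegment(
                    sample=str(row.sample),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    major_cn=int(row.major_cn),
                    minor_cn=int(row.minor_cn),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), path=path, line=i + 2) from exc
    validate_segments(segments)
    return segments


def validate_segments(segments: list[CopyNumberSegment]) -> None:
    """Reject overlapping segments within one (sample, chrom)."""
    by_key: dict[tuple, list[CopyNumberSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample, seg.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping segments for sample {sample} on {chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def write_segments(segments: list[CopyNumberSegment], path) -> None:
    rows = [
        {
            "sample": s.sample,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "major_cn": s.major_cn,
            "minor_cn": s.minor_cn,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    metas = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            metas.append(
                SampleMeta(
                    sample=str(row.sample),
                    donor=str(row.donor),
                    purity=float(row.purity),
                    age_years=float(row.age_years),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), path=path, line=i + 2) from exc
    return metas


def write_sample_meta(metas: list[SampleMeta], path) -> None:
    rows = [
        {"sample": m.sample, "donor": m.donor, "purity": m.purity, "age_years": m.age_years}
        for m in metas
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


def lookup_segment(
    segments: list[CopyNumberSegment], chrom: str, pos: int, sample: str | None = None
) -> CopyNumberSegment | None:
    """Return the segment containing (chrom, pos), 1-based inclusive, or None.

    If ``sample`` is given, only that sample's segments are searched.
    """
    for seg in segments:
        if sample is not None and seg.sample != sample:
            continue
        if seg.contains(chrom, pos):
            return seg
    return None


# ---------------------------------------------------------------------------
# trees

# write_tree accepts any object exposing the CloneTree surface of
# phylogeny_builder: .root (node id), .parent (dict id->id|None) and
# .clusters (dict id -> cluster with .n_mutations).


def _children_map(tree) -> dict:
    children: dict = {nid: [] for nid in tree.clusters}
    for nid, parent in tree.parent.items():
        if parent is not None:
            children[parent].append(nid)
    for kids in children.values():
        kids.sort()
    return children


def tree_to_newick(tree) -> str:
    children = _children_map(tree)

    def render(nid: str) -> str:
        kids = children[nid]
        inner = "(" + ",".join(render(k) for k in kids) + ")" if kids else ""
        return f"{inner}{nid}:{tree.clusters[nid].n_mutations}"

    return render(tree.root) + ";"


def write_tree(tree, path, format: str = "newick") -> None:
    """Serialize a clone tree. Newick branch lengths are the cluster mutation
    counts; node labels are cluster ids. JSON additionally carries CCF centers.
    """
    if format == "newick":
        with open(path, "w") as fh:
            fh.write(tree_to_newick(tree) + "\n")
    elif format == "json":
        payload = {
            "root": tree.root,
            "nodes": {
                nid: {
                    "parent": tree.parent.get(nid),
                    "n_mutations": tree.clusters[nid].n_mutations,
                    "ccf_center": dict(getattr(tree.clusters[nid], "ccf_center", {}) or {}),
                }
                for nid in tree.clusters
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown tree format {format!r}")
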