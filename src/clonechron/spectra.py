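"""96-channel trinucleotide mutation spectra and their comparison.

Substitutions are collapsed to the pyrimidine strand (a G>T mutation in an
A_C context is counted as its reverse complement) and binned into the
standard 96 classes: six pyrimidine-centred substitution types (C>A, C>G,
C>T, T>A, T>C, T>G) times sixteen flanking-base combinations in
alphabetical order. Spectra of mutation subsets (e.g. clonal versus
subclonal) are compared by cosine similarity, with an optional bootstrap
null obtained by resampling the pooled set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUB_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in SUB_CLASSES
    for five in _BASES
    for three in _BASES
]
_CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


@dataclass
class Spectrum96:
    counts: np.ndarray  # shape (96,), ints
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CHANNELS, name="count")


def channel_of(context: str, ref: str, alt: str) -> str | None:
    """Map one substitution to its pyrimidine-strand channel name.

    Returns None for invalid input (non-ACGT bases, context not centred on
    ref, ref == alt).
    """
    if (
        len(context) != 3
        or any(b not in _BASES for b in context)
        or ref not in _BASES
        or alt not in _BASES
        or context[1] != ref
        or ref == alt
    ):
        return None
    if ref in "AG":  # purine-centred: flip to the pyrimidine strand
        context = context[::-1].translate(_COMP)
        ref = ref.translate(_COMP)
        alt = alt.translate(_COMP)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_spectrum(mutations, subset_ids=None) -> Spectrum96:
    """Count substitutions into the 96 channels.

    ``mutations`` is either a DataFrame with columns mutation_id, context,
    ref, alt (one row per mutation; extra rows per sample are deduplicated)
    or an iterable of VariantRecord. ``subset_ids`` optionally restricts to
    a set of mutation ids. Records with missing or invalid context are
    skipped and counted in ``n_skipped``.
    """
    if isinstance(mutations, pd.DataFrame):
        df = mutations.drop_duplicates("mutation_id")
        triples = [
            (row.mutation_id, row.context, row.ref, row.alt)
            for row in df.itertuples(index=False)
        ]
    else:
        triples = [(v.mutation_id, v.context, v.ref, v.alt) for v in mutations]
    counts = np.zeros(96, dtype=int)
    n_skipped = 0
    for mid, context, ref, alt in triples:
        if subset_ids is not None and mid not in subset_ids:
            continue
        if context is None or (isinstance(context, float) and np.isnan(context)):
            n_skipped += 1
            continue
        ch = channel_of(str(context), str(ref), str(alt))
        if ch is None:
            n_skipped += 1
            continue
        counts[_CHANNEL_INDEX[ch]] += 1
    if n_skipped:
        logger.info("spectrum: skipped %d record(s) with missing/invalid context", n_skipped)
    return Spectrum96(counts, n_skipped=n_skipped)


def compare_spectra(a: Spectrum96, b: Spectrum96) -> float:
    """Cosine similarity of two spectra's normalized count vectors, in [0, 1]."""
    if a.total == 0 or b.total == 0:
        raise ValueError("cannot compare a zero-total spectrum")
    va = a.counts / np.linalg.norm(a.counts)
    vb = b.counts / np.linalg.norm(b.counts)
    return float(np.clip(va @ vb, 0.0, 1.0))


def bootstrap_cosine_pvalue(
    a: Spectrum96, b: Spectrum96, n_boot: int = 1000, seed: int = 0
) -> float:
    """p-value for the observed cosine under a shared-process null.

    The pooled counts define a common multinomial; pairs of spectra of the
    original sizes are resampled from it and the fraction of null cosines
    at or below the observed one is returned (small p = the two sets look
    more different than sampling noise allows).
    """
    observed = compare_spectra(a, b)
    pooled = a.counts + b.counts
    probs = pooled / pooled.sum()
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.multinomial(a.total, probs)
        rb = rng.multinomial(b.total, probs)
        na = ra / np.linalg.norm(ra) if ra.any() else ra
        nb = rb / np.linalg.norm(rb) if rb.any() else rb
        null[i] = na @ nb
    return float((np.sum(null <= observed) + 1) / (n_boot + 1))
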