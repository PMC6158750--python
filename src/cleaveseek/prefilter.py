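"""Optional input-cleaning filters applied to read libraries before analysis.

All filters return new :class:`~cleaveseek.seqio.ReadLibrary` objects; the
inputs are never mutated.  Except for the joint conservation filter, every
filter is idempotent and order-independent, and no filter can increase a
library's total abundance.
"""

from __future__ import annotations

import logging
from collections import Counter

from .seqio import ReadLibrary, Transcript

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = set("ACGT")

# discard thresholds for mono-, di- and tri-nucleotide composition; a read is
# discarded when its most frequent k-mer exceeds the fraction (strict >)
LOW_COMPLEXITY_THRESHOLDS = {1: 0.75, 2: 0.375, 3: 0.25}


def _rebuild(lib: ReadLibrary, keep) -> ReadLibrary:
    return ReadLibrary(
        name=lib.name,
        records={s: a for s, a in lib.records.items() if keep(s, a)},
    )


def filter_ambiguous(lib: ReadLibrary) -> ReadLibrary:
    """Drop reads containing any base outside {A, C, G, T}."""
    return _rebuild(lib, lambda s, a: set(s) <= _UNAMBIGUOUS)


def max_kmer_fraction(sequence: str, k: int) -> float:
    """Fraction of overlapping k-mer windows occupied by the most frequent k-mer."""
    n_windows = len(sequence) - k + 1
    if n_windows < 1:
        return 0.0
    counts = Counter(sequence[i : i + k] for i in range(n_windows))
    return max(counts.values()) / n_windows


def exceeds_composition(sequence: str, k: int) -> bool:
    """Does the k-nucleotide composition rule alone discard this sequence?

    The boundary is strict: a sequence exactly at the threshold passes.
    """
    return max_kmer_fraction(sequence, k) > LOW_COMPLEXITY_THRESHOLDS[k]


def is_low_complexity(sequence: str) -> bool:
    """True when mono/di/tri-nucleotide composition exceeds 75% / 37.5% / 25%.

    Fractions use overlapping k-mer counts over the L-k+1 windows.  Note
    that under overlapping counting a sequence past the mono boundary always
    carries enough homo-dimers to trip the di rule as well.
    """
    return any(exceeds_composition(sequence, k) for k in LOW_COMPLEXITY_THRESHOLDS)


def filter_low_complexity(lib: ReadLibrary) -> ReadLibrary:
    """Drop reads dominated by a single mono-, di- or tri-nucleotide."""
    return _rebuild(lib, lambda s, a: not is_low_complexity(s))


def filter_conservation(libs: list[ReadLibrary]) -> list[ReadLibrary]:
    """Keep only sequences present in *every* replicate library.

    With a single library this is a no-op (a warning is logged): conservation
    is only meaningful across replicates.
    """
    if len(libs) < 2:
        logger.warning("conservation filter needs >= 2 libraries; skipped")
        return list(libs)
    shared = set(libs[0].records)
    for lib in libs[1:]:
        shared &= set(lib.records)
    return [_rebuild(lib, lambda s, a: s in shared) for lib in libs]


def filter_genome_match(lib: ReadLibrary, genome: list[Transcript]) -> ReadLibrary:
    """Keep reads with >= 1 exact full-length match on either genome strand.

    Exact matching only (0 mismatches), done internally with a per-length
    substring index over both strands of every chromosome record.
    """
    from .encoding import reverse_complement

    if not genome:
        raise ValueError("genome is empty")
    lengths = sorted({len(s) for s in lib.records})
    present: dict[int, set[str]] = {n: set() for n in lengths}
    for chrom in genome:
        for strand_seq in (chrom.sequence, reverse_complement(chrom.sequence)):
            for n in lengths:
                bucket = present[n]
                for i in range(len(strand_seq) - n + 1):
                    bucket.add(strand_seq[i : i + n])
    return _rebuild(lib, lambda s, a: s in present[len(s)])


def filter_size_abundance(
    lib: ReadLibrary,
    min_len: int,
    max_len: int,
    min_abundance: int = 1,
) -> ReadLibrary:
    """Keep reads with min_len <= length <= max_len and abundance >= min_abundance."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return _rebuild(
        lib, lambda s, a: min_len <= len(s) <= max_len and a >= min_abundance
    )
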