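"""Degradome-tag alignment, degradation profiles, peak categories, candidates.

Degradome tags are exact-matched to the sense strand of each transcript by
encoding every transcript window of each accepted tag length as an integer
(see :mod:`cleaveseek.encoding`) and binary-searching it in per-length sorted
lists of encoded tags.  A hit's window start marks a putative cleavage
position: the tag's 5' end is the uncapped 5' end of the 3' cleavage
fragment.

Each profile position is then ranked with the five-category peak scheme
(unique maximum, tied maximum, above average, at/below average, singleton),
where the average deliberately ignores abundance-1 positions so that
background degradation does not drag it down.  Finally a 32-nt candidate
window is cut around each qualifying peak and candidates are grouped by the
integer code of their TR2 7-mer.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .encoding import EncodedSeq, encode_window, _SRNA_CODE
from .seqio import ReadLibrary, Transcript

# --- duplex geometry -------------------------------------------------------
# The degradome tag 5' end at transcript position p (1-based) pairs with sRNA
# position 10 (RISC cleaves between the bases opposite sRNA positions 10 and
# 11).  The 32-nt candidate window spans transcript positions p-16 .. p+15,
# so p sits at window position 17 (1-based) and, gap-free, sRNA position i
# pairs with window position 27 - i.
WINDOW_FLANK_5P = 16  # nt upstream of the cleavage position
WINDOW_FLANK_3P = 15  # nt downstream (window length 32)
WINDOW_LEN = 32
ANCHOR_SRNA_POS = 10
ANCHOR_WINDOW_POS = 17  # 1-based window position paired with sRNA position 10


def window_pos_for_srna_pos(i: int) -> int:
    """1-based window position that pairs with sRNA position ``i`` gap-free."""
    return ANCHOR_WINDOW_POS + ANCHOR_SRNA_POS - i


def target_region_value(window: str, srna_start: int, srna_end: int) -> int:
    """mRNA-mode integer of the window bases opposite sRNA positions
    ``srna_start..srna_end``, read 3'->5' along the transcript so that index i
    of the region pairs with sRNA position ``srna_start + i``."""
    bases = [
        window[window_pos_for_srna_pos(i) - 1]
        for i in range(srna_start, srna_end + 1)
    ]
    return encode_window("".join(bases), "mRNA")


@dataclass
class Signal:
    """One degradome peak on a transcript."""

    abundance: int
    weighted_abundance: float = 0.0
    category: int = -1  # unset until assign_categories


@dataclass
class DegradationProfile:
    """Per-transcript map of cleavage position -> degradome signal."""

    transcript_id: str
    signals: dict[int, Signal] = field(default_factory=dict)


@dataclass(frozen=True)
class TargetCandidate:
    """A 32-nt window around an inferred cleavage position."""

    transcript_id: str
    cleavage_pos: int
    window: str
    abundance: int
    weighted_abundance: float
    category: int
    tr1_code: EncodedSeq
    tr2_code: EncodedSeq

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LEN:
            raise ValueError("candidate window must be exactly 32 nt")


class FragmentIndex:
    """Per-length sorted lists of encoded degradome tags.

    For each accepted tag length the unique tags are encoded (sRNA code,
    matching the code used for transcript windows) and sorted ascending, so
    membership is a binary search.  A parallel slot per tag accumulates its
    transcriptome-wide exact-match count, used for weighted abundances.
    """

    def __init__(self) -> None:
        self.by_length: dict[int, list[int]] = {}      # sorted encoded values
        self._abundance: dict[int, list[int]] = {}     # parallel to by_length
        self._match_count: dict[int, list[int]] = {}   # transcriptome hits

    def lookup(self, length: int, value: int) -> int | None:
        """Slot index of an encoded window value, or None if absent."""
        values = self.by_length.get(length)
        if values is None:
            return None
        i = bisect.bisect_left(values, value)
        if i < len(values) and values[i] == value:
            return i
        return None

    def abundance(self, length: int, slot: int) -> int:
        return self._abundance[length][slot]

    def match_count(self, length: int, slot: int) -> int:
        return self._match_count[length][slot]


def build_fragment_index(
    deg: ReadLibrary, min_len: int = 19, max_len: int = 21
) -> FragmentIndex:
    """Encode and sort the in-range degradome tags into a FragmentIndex."""
    per_length: dict[int, list[tuple[int, int]]] = {}
    for seq, abundance in deg.records.items():
        if min_len <= len(seq) <= max_len:
            per_length.setdefault(len(seq), []).append(
                (encode_window(seq, "sRNA"), abundance)
            )
    if not per_length:
        raise ValueError(
            f"no degradome reads within the accepted size range "
            f"[{min_len}, {max_len}]"
        )
    index = FragmentIndex()
    for length, pairs in per_length.items():
        pairs.sort()
        index.by_length[length] = [v for v, _ in pairs]
        index._abundance[length] = [a for _, a in pairs]
        index._match_count[length] = [0] * len(pairs)
    return index


def align_degradome(
    transcripts: list[Transcript], index: FragmentIndex
) -> dict[str, DegradationProfile]:
    """Exact-match all indexed tags against every transcript window.

    Every length-l window of each transcript (sense strand only) is encoded
    with the same code as the tags and binary-searched.  A hit contributes the
    tag's abundance at the window start; after all transcripts are scanned,
    each position's weighted abundance divides every contributing tag's
    abundance by its total number of transcriptome matches.
    """
    hits: list[tuple[str, int, int, int]] = []  # (tid, pos, length, slot)
    for transcript in transcripts:
        codes = [_SRNA_CODE[b] for b in transcript.sequence]
        L = len(codes)
        for length, values in index.by_length.items():
            if L < length:
                continue
            mask = (1 << (2 * length)) - 1
            value = 0
            for i in range(length):
                value = (value << 2) | codes[i]
            for start in range(L - length + 1):
                if start:
                    value = ((value << 2) | codes[start + length - 1]) & mask
                j = bisect.bisect_left(values, value)
                if j < len(values) and values[j] == value:
                    hits.append((transcript.id, start + 1, length, j))
                    index._match_count[length][j] += 1
    profiles: dict[str, DegradationProfile] = {}
    for tid, pos, length, slot in hits:
        profile = profiles.setdefault(tid, DegradationProfile(transcript_id=tid))
        signal = profile.signals.setdefault(pos, Signal(abundance=0))
        abundance = index.abundance(length, slot)
        signal.abundance += abundance
        signal.weighted_abundance += abundance / index.match_count(length, slot)
    return profiles


def assign_categories(profile: DegradationProfile) -> DegradationProfile:
    """Assign the five-way peak category to every signal position.

    With M the maximum abundance on the transcript and avg the mean over
    positions with abundance > 1 (abundance-1 positions are background and
    excluded):  abundance 1 -> category 4;  == M, unique -> 0;  == M, tied
    -> 1;  > avg -> 2;  <= avg -> 3.
    """
    abundances = [s.abundance for s in profile.signals.values()]
    if not abundances:
        return profile
    peak = max(abundances)
    n_at_peak = abundances.count(peak)
    informative = [a for a in abundances if a > 1]
    avg = sum(informative) / len(informative) if informative else 0.0
    for signal in profile.signals.values():
        a = signal.abundance
        if a == 1:
            signal.category = 4
        elif a == peak:
            signal.category = 0 if n_at_peak == 1 else 1
        elif a > avg:
            signal.category = 2
        else:
            signal.category = 3
    return profile


def extract_candidates(
    transcript: Transcript,
    profile: DegradationProfile,
    allowed_categories: set[int] = frozenset({0, 1, 2, 3}),
    min_fragment_abundance: int = 1,
) -> list[TargetCandidate]:
    """Cut a 32-nt candidate window around each qualifying peak.

    Peaks within 16 nt of the 5' end or 15 nt of the 3' end cannot host a
    full window and are skipped.  TR1/TR2 region codes are precomputed here;
    TR3 depends on the query sRNA length and is computed at filter time.
    """
    seq = transcript.sequence
    L = len(seq)
    candidates: list[TargetCandidate] = []
    for pos in sorted(profile.signals):
        signal = profile.signals[pos]
        if signal.category not in allowed_categories:
            continue
        if signal.abundance < min_fragment_abundance:
            continue
        if pos < WINDOW_FLANK_5P + 1 or pos > L - WINDOW_FLANK_3P:
            continue
        window = seq[pos - WINDOW_FLANK_5P - 1 : pos + WINDOW_FLANK_3P]
        candidates.append(
            TargetCandidate(
                transcript_id=transcript.id,
                cleavage_pos=pos,
                window=window,
                abundance=signal.abundance,
                weighted_abundance=signal.weighted_abundance,
                category=signal.category,
                tr1_code=EncodedSeq(target_region_value(window, 1, 7), 7, "mRNA"),
                tr2_code=EncodedSeq(target_region_value(window, 8, 14), 7, "mRNA"),
            )
        )
    return candidates


def group_by_tr2(
    candidates: list[TargetCandidate],
) -> dict[int, list[TargetCandidate]]:
    """Partition candidates by the integer code of their TR2 7-mer."""
    groups: dict[int, list[TargetCandidate]] = {}
    for cand in candidates:
        groups.setdefault(cand.tr2_code.value, []).append(cand)
    return groups
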