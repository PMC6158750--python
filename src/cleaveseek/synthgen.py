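"""Deterministic synthetic fixtures with planted sRNA-target-degradome truth.

The generator emulates the structure of a plant degradome experiment: random
transcripts; sRNAs written as (optionally edited) reverse complements of
chosen target sites; degradome tags whose 5' ends sit exactly at the
cleavage position opposite sRNA positions 10/11, at controlled abundances;
plus Poisson background degradation tags of abundance 1 (category 4 by
construction, hence separable under stringent settings).

Everything is driven by one integer seed, and the truth table records, for
every planted site, the expected peak category and the expected duplex
alignment score under a named rule preset — computed here from the edit
spec alone, independently of the prediction modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .prefilter import is_low_complexity
from .seqio import ReadLibrary, Transcript

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_PARTNER = {"G": "T", "T": "G"}  # sRNA base -> target base forming G:U


def make_transcriptome(
    n: int,
    length_range: tuple[int, int] = (500, 1500),
    seed: int = 0,
) -> list[Transcript]:
    """Uniform-random transcripts, reproducible from the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    transcripts = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, size=length))
        transcripts.append(Transcript(id=f"T{i:04d}", sequence=seq, source="fasta"))
    return transcripts


@dataclass(frozen=True)
class EditSpec:
    """Which imperfections to plant at each site, by sRNA position.

    ``gap_positions`` lists positions g meaning one bulged target base
    between sRNA positions g and g+1 (an sRNA-strand gap in the duplex).
    """

    mismatch_positions: tuple[int, ...] = ()
    wobble_positions: tuple[int, ...] = ()
    gap_positions: tuple[int, ...] = ()


@dataclass
class PlantedSite:
    srna_name: str
    srna_sequence: str
    transcript_id: str
    cleavage_position: int
    expected_category: int
    expected_score: float


@dataclass
class PlantResult:
    srna_lib: ReadLibrary
    deg_lib: ReadLibrary
    srna_names: dict[str, str]
    truth: pd.DataFrame
    transcripts: list[Transcript] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)


def _expected_score(edits: EditSpec, srna_len: int, rules) -> float:
    score = 0.0
    for i in edits.mismatch_positions:
        if not rules.mismatch_allowed_at(i):
            raise ValueError(f"edit spec plants a forbidden mismatch at position {i}")
        score += rules.mismatch_penalty(i)
    for i in edits.wobble_positions:
        if not rules.wobble_allowed_at(i):
            raise ValueError(f"edit spec plants a forbidden wobble at position {i}")
        score += rules.gu_wobble_score * rules.multiplier(i)
    for g in edits.gap_positions:
        # the aligner charges a bulge at the sRNA position it is traversing
        pos = g if g < 10 else g + 1
        score += rules.gap_score * rules.multiplier(pos)
    return score


def _check_feasible(edits: EditSpec, srna_len: int, rules) -> float:
    n_mm = len(edits.mismatch_positions)
    n_gap = len(edits.gap_positions)
    if n_mm > rules.max_mismatches:
        raise ValueError("edit spec exceeds max_mismatches")
    if len(edits.wobble_positions) > rules.max_gu_wobbles:
        raise ValueError("edit spec exceeds max_gu_wobbles")
    if n_gap > rules.max_gaps:
        raise ValueError("edit spec exceeds max_gaps")
    for i in (*edits.mismatch_positions, *edits.wobble_positions):
        if not 1 <= i <= srna_len:
            raise ValueError(f"edit position {i} outside sRNA")
    for g in edits.gap_positions:
        if not 1 <= g < srna_len:
            raise ValueError(f"gap position {g} outside sRNA")
    score = _expected_score(edits, srna_len, rules)
    if score > rules.max_score:
        raise ValueError(
            f"edit spec score {score} exceeds max_score {rules.max_score}"
        )
    return score


def _mismatch_base(rng, srna_base: str) -> str:
    """A target base that is neither the complement nor a wobble partner."""
    bad = {_COMP[srna_base], _WOBBLE_PARTNER.get(srna_base, "")}
    choices = [b for b in "ACGT" if b not in bad]
    return choices[int(rng.integers(len(choices)))]


def _site_target_bases(
    rng, srna: str, edits: EditSpec
) -> dict[int, str]:
    """Planned target base per window position (1-based, cleavage at 17).

    Gap-free, sRNA position i pairs window position 27 - i; positions beyond
    a planted bulge shift one base away from the anchor.
    """
    n = len(srna)
    mism, wob, gaps = (
        set(edits.mismatch_positions),
        set(edits.wobble_positions),
        set(edits.gap_positions),
    )
    bases: dict[int, str] = {}
    for i in range(1, n + 1):
        w = 27 - i
        # shift for bulges between this position and the anchor (position 10)
        for g in gaps:
            if g >= 10 and i > g:
                w -= 1
            elif g < 10 and i <= g:
                w += 1
        s = srna[i - 1]
        if i in mism:
            bases[w] = _mismatch_base(rng, s)
        elif i in wob:
            bases[w] = _WOBBLE_PARTNER[s]
        else:
            bases[w] = _COMP[s]
    for g in gaps:
        w_b = 27 - g if g < 10 else 26 - g
        s_left, s_right = srna[g - 1], srna[g]
        bad = {
            _COMP[s_left], _WOBBLE_PARTNER.get(s_left, ""),
            _COMP[s_right], _WOBBLE_PARTNER.get(s_right, ""),
        }
        choices = [b for b in "ACGT" if b not in bad]
        if not choices:
            raise ValueError(
                "cannot plant a bulge between a G and a T/U (any base would "
                "pair with a neighbour)"
            )
        bases[w_b] = choices[int(rng.integers(len(choices)))]
    return bases


def _expected_categories(
    planted: dict[str, dict[int, int]]
) -> dict[tuple[str, int], int]:
    """Category each planted site will receive, from the generator's own
    abundance bookkeeping (background tags are abundance 1 -> category 4 and
    excluded from the average)."""
    out: dict[tuple[str, int], int] = {}
    for tid, positions in planted.items():
        informative = [a for a in positions.values() if a > 1]
        peak = max(positions.values())
        n_at_peak = sum(1 for a in positions.values() if a == peak)
        avg = sum(informative) / len(informative) if informative else 0.0
        for pos, a in positions.items():
            if a == 1:
                cat = 4
            elif a == peak and a > 1:
                cat = 0 if n_at_peak == 1 else 1
            elif a > avg:
                cat = 2
            else:
                cat = 3
            out[(tid, pos)] = cat
    return out


def plant_interactions(
    transcripts: list[Transcript],
    n_sites: int,
    srna_len_range: tuple[int, int] = (19, 24),
    edits: EditSpec = EditSpec(),
    peak_abundance: int = 10,
    background_rate: float = 0.0,
    seed: int = 0,
    preset_name: str = "allen",
    tag_len: int = 20,
) -> PlantResult:
    """Plant ``n_sites`` sRNA-target interactions and their degradome tags.

    Each site picks a transcript, cleavage position and sRNA length at
    random, rewrites the transcript so the (edited) site is complementary to
    a freshly drawn sRNA, and emits a degradome tag of ``peak_abundance``
    copies whose 5' end sits at the cleavage position.  ``background_rate``
    is the expected number of abundance-1 background tags per transcript.
    """
    from .rules import preset as load_preset

    rules = load_preset(preset_name)
    rng = np.random.default_rng(seed)
    expected_score = _check_feasible(edits, srna_len_range[0], rules)

    sequences = {t.id: list(t.sequence) for t in transcripts}
    used: dict[str, list[tuple[int, int]]] = {t.id: [] for t in transcripts}
    planted_abund: dict[str, dict[int, int]] = {}
    srna_lib = ReadLibrary(name="srna_planted")
    deg_lib = ReadLibrary(name="degradome_planted")
    srna_names: dict[str, str] = {}
    sites: list[PlantedSite] = []

    # cleavage position must leave a full 32-nt window and a full tag
    max_margin = max(15, tag_len - 1)
    eligible = [t for t in transcripts if len(t) >= 17 + max_margin + 10]
    if not eligible:
        raise ValueError("no transcript long enough to host a planted site")

    for k in range(n_sites):
        for _ in range(1000):
            t = eligible[int(rng.integers(len(eligible)))]
            L = len(sequences[t.id])
            n = int(rng.integers(srna_len_range[0], srna_len_range[1] + 1))
            p = int(rng.integers(17, L - max_margin + 1))
            lo, hi = p - 16, p + 15  # window span, 1-based
            if any(not (hi < a or lo > b) for a, b in used[t.id]):
                continue
            srna = "".join(rng.choice(_BASES, size=n))
            if srna in srna_names or is_low_complexity(srna):
                continue
            # wobbles need a sRNA G or U at the planted position
            srna_list = list(srna)
            for i in edits.wobble_positions:
                if srna_list[i - 1] not in "GT":
                    srna_list[i - 1] = "GT"[int(rng.integers(2))]
            srna = "".join(srna_list)
            if srna in srna_names:
                continue
            # a bulge flanked by G and T has no base that avoids pairing with
            # both neighbours (their complements + wobble partners cover all
            # four bases); resample so the planted gap cannot be absorbed
            if any(
                {srna[g - 1], srna[g]} == {"G", "T"}
                for g in edits.gap_positions
            ):
                continue
            for w, base in _site_target_bases(rng, srna, edits).items():
                sequences[t.id][p + w - 17 - 1] = base
            tag = "".join(sequences[t.id][p - 1 : p - 1 + tag_len])
            if tag in deg_lib.records or is_low_complexity(tag):
                continue
            used[t.id].append((lo, hi))
            planted_abund.setdefault(t.id, {})[p] = peak_abundance
            name = f"srna{k:04d}"
            srna_names[srna] = name
            srna_lib.add(srna, 10)
            deg_lib.add(tag, peak_abundance)
            sites.append(
                PlantedSite(name, srna, t.id, p, -1, expected_score)
            )
            break
        else:
            raise RuntimeError("could not place a site; transcriptome too small")

    # background degradation: abundance-1 tags at fresh positions
    if background_rate > 0:
        for t in transcripts:
            L = len(sequences[t.id])
            if L < tag_len + 1:
                continue
            k = int(rng.poisson(background_rate))
            for _ in range(k):
                pos = int(rng.integers(1, L - tag_len + 2))
                if pos in planted_abund.get(t.id, {}):
                    continue
                tag = "".join(sequences[t.id][pos - 1 : pos - 1 + tag_len])
                if tag in deg_lib.records:
                    continue
                deg_lib.add(tag, 1)
                planted_abund.setdefault(t.id, {})[pos] = 1

    categories = _expected_categories(planted_abund)
    for site in sites:
        site.expected_category = categories[(site.transcript_id,
                                             site.cleavage_position)]

    # rebuild transcripts with the edited sequences
    edited = [
        Transcript(id=t.id, sequence="".join(sequences[t.id]), source=t.source)
        for t in transcripts
    ]
    truth = pd.DataFrame(
        [
            {
                "srna_name": s.srna_name,
                "srna_sequence": s.srna_sequence,
                "transcript_id": s.transcript_id,
                "cleavage_position": s.cleavage_position,
                "expected_category": s.expected_category,
                "expected_score": s.expected_score,
                "preset": preset_name,
            }
            for s in sites
        ]
    )
    return PlantResult(
        srna_lib=srna_lib,
        deg_lib=deg_lib,
        srna_names=srna_names,
        truth=truth,
        transcripts=edited,
        sites=sites,
    )


def write_library_fasta(lib: ReadLibrary, path: str | Path) -> None:
    """Write a collapsed library in the count-bearing header dialect."""
    with open(path, "w") as fh:
        for i, (seq, abundance) in enumerate(sorted(lib.records.items())):
            fh.write(f">r{i:06d}-{abundance}\n{seq}\n")


def write_transcripts_fasta(transcripts: list[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n{t.sequence}\n")
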