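"""Configurable targeting rules, region extraction and the three-stage filter.

A :class:`TargetingRuleSet` holds every tunable feature of the sRNA-mRNA
duplex alignment (penalty scores, count maxima, core-region multiplier,
position-10/11 permissions, gap budget).  Two presets are bundled: the
classic Allen et al. plant-miRNA scoring scheme (mismatch 1, G:U wobble 0.5,
positions 2-13 doubled, cutoff 4, no mismatch or wobble at position 10/11)
and the Fahlgren-Carrington variant, which is identical except that it
permits a mismatch or G:U wobble at sRNA position 10 or 11.

Candidate pruning works on 7-nt regions.  From the sRNA: R1 = positions 1-7,
R2 = 8-14, R3 = the last seven bases.  From each candidate window the
opposite target regions TR1/TR2/TR3 are read 3'->5' along the transcript so
index i of a region pairs with index i of its counterpart, and encoded in
mRNA mode — a perfectly complementary region pair therefore shares one
integer.  Conceptually each region has a 16384 x 16384 boolean matrix of
region pairs that can ever appear inside a rule-compliant duplex; rows are
computed lazily and memoized instead of materializing ~0.8 GB of tables.

The filter is deliberately *conservative*: a region pair is declared valid
whenever any small-gap region alignment fits inside the full global budgets,
with bases that a gap elsewhere in the duplex could shift out of the region
treated as free.  Pruning therefore never discards a candidate that the full
duplex aligner would accept — the prediction set with filtering on is
identical to the set with filtering bypassed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

from .degradome import TargetCandidate, target_region_value
from .encoding import EncodedSeq

REGION_LEN = 7
N_REGION_CODES = 4**REGION_LEN  # 16384 rows/columns per region matrix

# pair classification in 2-bit code space: sRNA code s vs mRNA-mode code m.
# match iff m == s (the inverse-code property); G:U wobble iff sRNA G pairs
# target U or sRNA U pairs target G.
_WOBBLE = {(0b10, 0b00), (0b11, 0b01)}  # (sRNA code, mRNA code)

MATCH, WOBBLE, MISMATCH = 0, 1, 2


def classify_pair(srna_code: int, mrna_code: int) -> int:
    if srna_code == mrna_code:
        return MATCH
    if (srna_code, mrna_code) in _WOBBLE:
        return WOBBLE
    return MISMATCH


@dataclass(frozen=True)
class TargetingRuleSet:
    """All configurable features of the duplex alignment search."""

    max_score: float = 4.0
    max_mismatches: int = 4
    max_adjacent_mismatches: int = 2
    max_gu_wobbles: int = 8
    mismatch_score: float = 1.0
    gu_wobble_score: float = 0.5
    gap_score: float = 1.0
    max_gaps: int = 1
    core_start: int = 2
    core_end: int = 13
    core_multiplier: float = 2.0
    max_mismatches_core: int = 4
    max_adjacent_mismatches_core: int = 2
    allow_mismatch_pos10: bool = False
    pos10_mismatch_score: float = 1.0
    allow_mismatch_pos11: bool = False
    pos11_mismatch_score: float = 1.0
    permissible_mismatch_positions: frozenset[int] = frozenset()
    non_permissible_mismatch_positions: frozenset[int] = frozenset()
    gu_counts_as_mismatch: bool = False

    def __post_init__(self) -> None:
        if self.core_start > self.core_end:
            raise ValueError("core_start must be <= core_end")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")
        for name in ("max_score", "mismatch_score", "gu_wobble_score", "gap_score"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # frozenset-ify if plain iterables were passed
        for name in (
            "permissible_mismatch_positions",
            "non_permissible_mismatch_positions",
        ):
            value = getattr(self, name)
            if not isinstance(value, frozenset):
                object.__setattr__(self, name, frozenset(value))

    # -- positional helpers -------------------------------------------------
    def multiplier(self, srna_pos: int) -> float:
        return (
            self.core_multiplier
            if self.core_start <= srna_pos <= self.core_end
            else 1.0
        )

    def mismatch_penalty(self, srna_pos: int) -> float:
        if srna_pos == 10:
            base = self.pos10_mismatch_score
        elif srna_pos == 11:
            base = self.pos11_mismatch_score
        else:
            base = self.mismatch_score
        return base * self.multiplier(srna_pos)

    def mismatch_allowed_at(self, srna_pos: int) -> bool:
        """Positional permission for a mismatch OR wobble pair."""
        if srna_pos == 10 and not self.allow_mismatch_pos10:
            return False
        if srna_pos == 11 and not self.allow_mismatch_pos11:
            return False
        if srna_pos in self.non_permissible_mismatch_positions:
            return False
        if (
            self.permissible_mismatch_positions
            and srna_pos not in self.permissible_mismatch_positions
        ):
            return False
        return True

    def wobble_allowed_at(self, srna_pos: int) -> bool:
        # position 10/11 prohibitions cover wobbles as well as mismatches
        if srna_pos == 10 and not self.allow_mismatch_pos10:
            return False
        if srna_pos == 11 and not self.allow_mismatch_pos11:
            return False
        return True

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for name in (
            "permissible_mismatch_positions",
            "non_permissible_mismatch_positions",
        ):
            d[name] = sorted(d[name])
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "TargetingRuleSet":
        d = dict(d)
        for name in (
            "permissible_mismatch_positions",
            "non_permissible_mismatch_positions",
        ):
            if name in d:
                d[name] = frozenset(d[name])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "TargetingRuleSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def preset(name: str) -> TargetingRuleSet:
    """Bundled rule sets: ``allen`` or ``fahlgren_carrington`` (alias ``fc``)."""
    if name == "allen":
        return TargetingRuleSet()
    if name in ("fahlgren_carrington", "fc"):
        return replace(
            TargetingRuleSet(),
            allow_mismatch_pos10=True,
            pos10_mismatch_score=1.0,
            allow_mismatch_pos11=True,
            pos11_mismatch_score=1.0,
        )
    raise ValueError(f"unknown preset {name!r}")


@dataclass(frozen=True)
class RegionCodes:
    """The three encoded 7-mer regions of one sRNA."""

    r1: EncodedSeq
    r2: EncodedSeq
    r3: EncodedSeq
    srna_length: int


def region_start(region: str, srna_length: int) -> int:
    """Absolute 1-based sRNA position where a region begins."""
    if region == "R1":
        return 1
    if region == "R2":
        return 8
    if region == "R3":
        # the final seven bases; overlaps R2 for sRNAs shorter than 21 nt
        return srna_length - REGION_LEN + 1
    raise ValueError(f"unknown region {region!r}")


def extract_regions(srna: str) -> RegionCodes:
    """Encode R1 (1-7), R2 (8-14) and R3 (last 7 nt) of a sRNA.

    For sRNAs shorter than 21 nt, R3 is the final seven bases and overlaps
    R2.
    """
    from .encoding import encode

    n = len(srna)
    if n < 2 * REGION_LEN:
        raise ValueError(f"sRNA of length {n} is too short for region extraction")
    r3_start = region_start("R3", n)
    return RegionCodes(
        r1=encode(srna[0:7], "sRNA"),
        r2=encode(srna[7:14], "sRNA"),
        r3=encode(srna[r3_start - 1 : r3_start + 6], "sRNA"),
        srna_length=n,
    )


# ---------------------------------------------------------------------------
# region pair validity
# ---------------------------------------------------------------------------

_pair_cache: dict[tuple, bool] = {}


def _codes_of(value: int) -> tuple[int, ...]:
    return tuple(
        (value >> (2 * (REGION_LEN - 1 - k))) & 0b11 for k in range(REGION_LEN)
    )


def region_pair_valid(
    region: str,
    srna_region_value: int,
    target_region_value_: int,
    srna_length: int,
    rules: TargetingRuleSet,
) -> bool:
    """Can this (sRNA region, target region) 7-mer pair sit inside any
    rule-compliant duplex?

    Existential search over gap-free and small-gap region alignments.  The
    start offset (|offset| <= max_gaps) models gaps elsewhere in the duplex
    shifting the frame; out-of-range target columns and gap columns are free
    (a gap's cost may fall outside the region).  Budgets are the full global
    budgets, never a partition of them — weaker pruning, guaranteed
    conservative.
    """
    key = (region, srna_region_value, target_region_value_, srna_length, rules)
    cached = _pair_cache.get(key)
    if cached is not None:
        return cached

    start = region_start(region, srna_length)
    s_codes = _codes_of(srna_region_value)
    # target 7-mer in mRNA code space; index k pairs sRNA position start + k
    t_codes = _codes_of(target_region_value_)
    g = rules.max_gaps
    counts_wobble_adjacent = rules.gu_counts_as_mismatch

    def search(i, j, gaps, score, n_mm, n_wob, run, core_mm, core_run) -> bool:
        if score > rules.max_score or n_mm > rules.max_mismatches:
            return False
        if n_wob > rules.max_gu_wobbles:
            return False
        if run > rules.max_adjacent_mismatches:
            return False
        if core_mm > rules.max_mismatches_core:
            return False
        if core_run > rules.max_adjacent_mismatches_core:
            return False
        if i == REGION_LEN:
            return True
        pos = start + i
        in_core = rules.core_start <= pos <= rules.core_end
        # option 1: pair sRNA i with target j (free when j out of range)
        if 0 <= j < REGION_LEN:
            kind = classify_pair(s_codes[i], t_codes[j])
        else:
            kind = MATCH  # unknown base outside the region: free
        ok = True
        d_score = 0.0
        d_mm = d_wob = 0
        mm_like = False
        if kind == WOBBLE:
            if not rules.wobble_allowed_at(pos):
                ok = False
            d_score = rules.gu_wobble_score * rules.multiplier(pos)
            d_wob = 1
            if rules.gu_counts_as_mismatch:
                d_mm = 1
            mm_like = counts_wobble_adjacent
        elif kind == MISMATCH:
            if not rules.mismatch_allowed_at(pos):
                ok = False
            d_score = rules.mismatch_penalty(pos)
            d_mm = 1
            mm_like = True
        if ok and search(
            i + 1,
            j + 1,
            gaps,
            score + d_score,
            n_mm + d_mm,
            n_wob + d_wob,
            run + 1 if mm_like else 0,
            core_mm + (d_mm if in_core else 0),
            (core_run + 1 if mm_like else 0) if in_core else 0,
        ):
            return True
        # option 2/3: gap moves, free of charge (cost may fall outside region)
        if gaps < g:
            if search(i + 1, j, gaps + 1, score, n_mm, n_wob, 0, core_mm, 0):
                return True
            if search(i, j + 1, gaps + 1, score, n_mm, n_wob, 0, core_mm, 0):
                return True
        return False

    valid = any(
        search(0, offset, 0, 0.0, 0, 0, 0, 0, 0) for offset in range(-g, g + 1)
    )
    _pair_cache[key] = valid
    return valid


_row_cache: dict[tuple, frozenset[int]] = {}


def region_row(
    region: str,
    srna_region_code: EncodedSeq,
    srna_length: int,
    rules: TargetingRuleSet,
) -> frozenset[int]:
    """One lazily computed row of a region's 16384 x 16384 validity matrix:
    every mRNA 7-mer value that can pair with this sRNA region 7-mer."""
    if not 0 <= srna_region_code.value < N_REGION_CODES:
        raise ValueError("region code out of 7-mer range")
    key = (region, srna_region_code.value, srna_length, rules)
    row = _row_cache.get(key)
    if row is None:
        row = frozenset(
            m
            for m in range(N_REGION_CODES)
            if region_pair_valid(region, srna_region_code.value, m, srna_length, rules)
        )
        _row_cache[key] = row
    return row


def three_stage_filter(
    regions: RegionCodes,
    groups: dict[int, list[TargetCandidate]],
    rules: TargetingRuleSet,
) -> list[TargetCandidate]:
    """Prune candidate groups through the R2 -> R1 -> R3 region cascade.

    Stage 1 keeps only TR2 groups whose key can pair with the sRNA's R2;
    stage 2 drops candidates whose TR1 cannot pair with R1; stage 3 derives
    TR3 (which depends on this sRNA's length) from the candidate window and
    drops candidates whose TR3 cannot pair with R3.  Membership tests are
    memoized cells of the conceptual matrices.
    """
    n = regions.srna_length
    r3_start = region_start("R3", n)
    survivors: list[TargetCandidate] = []
    for tr2_value, candidates in groups.items():
        if not region_pair_valid("R2", regions.r2.value, tr2_value, n, rules):
            continue
        for cand in candidates:
            if not region_pair_valid(
                "R1", regions.r1.value, cand.tr1_code.value, n, rules
            ):
                continue
            tr3 = target_region_value(cand.window, r3_start, r3_start + 6)
            if not region_pair_valid("R3", regions.r3.value, tr3, n, rules):
                continue
            survivors.append(cand)
    return survivors
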