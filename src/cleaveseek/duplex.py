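"""Cleavage-anchored sRNA-mRNA duplex alignment.

The aligner pairs a sRNA against the 32-nt candidate window around an
inferred cleavage position.  The anchor is fixed: sRNA position 10 sits
opposite window position 17 (the cleavage position) and is never gapped —
RISC cleaves between the target bases opposite sRNA positions 10 and 11.
From the anchor, the search first walks toward the 5' end of the sRNA
(window positions increasing) and, if that arm survives, toward the 3' end.
At each step the pair is classified (Watson-Crick match, G:U wobble —
sRNA G : target T/U or sRNA U : target G — or mismatch) and, up to the gap
budget, single-base bulges on either strand are branched on.  Branches die
the moment any rule in the :class:`~cleaveseek.rules.TargetingRuleSet` is
broken; every surviving complete alignment is collected and the best is
chosen by (score, gaps, mismatches + wobbles), remaining ties broken by the
5'-most first difference in column states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .degradome import (
    ANCHOR_SRNA_POS,
    ANCHOR_WINDOW_POS,
    WINDOW_LEN,
    TargetCandidate,
    window_pos_for_srna_pos,
)
from .encoding import _SRNA_CODE
from .rules import MATCH, MISMATCH, WOBBLE, TargetingRuleSet, classify_pair

# column states
STATE_MATCH = "match"
STATE_WOBBLE = "gu_wobble"
STATE_MISMATCH = "mismatch"
STATE_SRNA_GAP = "srna_gap"      # gap in the sRNA strand: window base bulged
STATE_TARGET_GAP = "target_gap"  # gap in the target strand: sRNA base bulged

_PAIR_STATE = {MATCH: STATE_MATCH, WOBBLE: STATE_WOBBLE, MISMATCH: STATE_MISMATCH}
_STATE_RANK = {
    STATE_MATCH: 0,
    STATE_WOBBLE: 1,
    STATE_MISMATCH: 2,
    STATE_SRNA_GAP: 3,
    STATE_TARGET_GAP: 4,
}


@dataclass(frozen=True)
class Column:
    """One aligned column: a pair or a single-strand bulge."""

    state: str
    srna_pos: Optional[int]    # 1-based sRNA position, None for srna_gap
    window_pos: Optional[int]  # 1-based window position, None for target_gap


@dataclass(frozen=True)
class DuplexAlignment:
    """A complete, rule-compliant sRNA-mRNA duplex."""

    srna: str
    target_window: str
    columns: tuple[Column, ...]  # 5'->3' of the sRNA
    score: float
    n_mismatches: int
    n_wobbles: int
    n_gaps: int

    @property
    def pairs(self) -> dict[int, str]:
        """Per-sRNA-position state (bulged window bases carry no position)."""
        return {
            c.srna_pos: c.state for c in self.columns if c.srna_pos is not None
        }

    def sort_key(self) -> tuple:
        """Lexicographic selection key: score, gaps, edits, then column states."""
        return (
            self.score,
            self.n_gaps,
            self.n_mismatches + self.n_wobbles,
            tuple(_STATE_RANK[c.state] for c in self.columns),
        )


def _classify(srna: str, window: str, i: int, w: int) -> int:
    return classify_pair(_SRNA_CODE[srna[i - 1]], _SRNA_CODE[window[w - 1]] ^ 0b11)


def _max_run(flags: Iterable[bool]) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def enumerate_alignments(
    srna: str, window: str, rules: TargetingRuleSet
) -> list[DuplexAlignment]:
    """All complete duplex alignments that satisfy every targeting rule.

    Gap columns cost ``gap_score`` (with the core multiplier of the sRNA
    position being traversed) and always count as mismatch-like for the
    adjacency rule; wobbles count as mismatches only when the rule set says
    so.  Score/count budgets prune branches in flight; adjacency and
    core-region counts are verified on each completed alignment.
    """
    n = len(srna)
    if len(window) != WINDOW_LEN:
        raise ValueError("target window must be exactly 32 nt")
    if window_pos_for_srna_pos(n) - rules.max_gaps < 1:
        raise ValueError(
            f"sRNA of length {n} would overrun the 3' edge of the target window"
        )
    if window_pos_for_srna_pos(1) + rules.max_gaps > WINDOW_LEN:
        raise ValueError("gap budget would overrun the 5' edge of the target window")

    results: list[DuplexAlignment] = []

    def try_pair(i: int, w: int):
        kind = _classify(srna, window, i, w)
        if kind == WOBBLE:
            if not rules.wobble_allowed_at(i):
                return None
            d_mm = 1 if rules.gu_counts_as_mismatch else 0
            return (
                STATE_WOBBLE,
                rules.gu_wobble_score * rules.multiplier(i),
                d_mm,
                1,
            )
        if kind == MISMATCH:
            if not rules.mismatch_allowed_at(i):
                return None
            return (STATE_MISMATCH, rules.mismatch_penalty(i), 1, 0)
        return (STATE_MATCH, 0.0, 0, 0)

    def finish(cols5: list[Column], anchor: Column, cols3: list[Column],
               score: float, n_mm: int, n_wob: int, n_gap: int) -> None:
        # cols5 were built anchor-outward; reverse into 5'->3' order
        columns = tuple(reversed(cols5)) + (anchor,) + tuple(cols3)
        mm_like = [
            c.state == STATE_MISMATCH
            or c.state in (STATE_SRNA_GAP, STATE_TARGET_GAP)
            or (c.state == STATE_WOBBLE and rules.gu_counts_as_mismatch)
            for c in columns
        ]
        if _max_run(mm_like) > rules.max_adjacent_mismatches:
            return
        in_core = [
            c.srna_pos is not None
            and rules.core_start <= c.srna_pos <= rules.core_end
            for c in columns
        ]
        core_mm = sum(
            1
            for c, core in zip(columns, in_core)
            if core
            and (
                c.state == STATE_MISMATCH
                or (c.state == STATE_WOBBLE and rules.gu_counts_as_mismatch)
            )
        )
        if core_mm > rules.max_mismatches_core:
            return
        if (
            _max_run(f and core for f, core in zip(mm_like, in_core))
            > rules.max_adjacent_mismatches_core
        ):
            return
        results.append(
            DuplexAlignment(
                srna=srna,
                target_window=window,
                columns=columns,
                score=score,
                n_mismatches=n_mm,
                n_wobbles=n_wob,
                n_gaps=n_gap,
            )
        )

    def within_budget(score: float, n_mm: int, n_wob: int) -> bool:
        return (
            score <= rules.max_score
            and n_mm <= rules.max_mismatches
            and n_wob <= rules.max_gu_wobbles
        )

    def walk3(i: int, w: int, cols3: list[Column], cols5: list[Column],
              anchor: Column, score: float, n_mm: int, n_wob: int, n_gap: int):
        if i > n:
            finish(cols5, anchor, cols3, score, n_mm, n_wob, n_gap)
            return
        if w < 1:
            return
        pr = try_pair(i, w)
        if pr is not None:
            state, d_s, d_mm, d_wob = pr
            if within_budget(score + d_s, n_mm + d_mm, n_wob + d_wob):
                cols3.append(Column(state, i, w))
                walk3(i + 1, w - 1, cols3, cols5, anchor,
                      score + d_s, n_mm + d_mm, n_wob + d_wob, n_gap)
                cols3.pop()
        if n_gap < rules.max_gaps:
            g_s = rules.gap_score * rules.multiplier(i)
            if within_budget(score + g_s, n_mm, n_wob):
                cols3.append(Column(STATE_TARGET_GAP, i, None))
                walk3(i + 1, w, cols3, cols5, anchor,
                      score + g_s, n_mm, n_wob, n_gap + 1)
                cols3.pop()
                cols3.append(Column(STATE_SRNA_GAP, None, w))
                walk3(i, w - 1, cols3, cols5, anchor,
                      score + g_s, n_mm, n_wob, n_gap + 1)
                cols3.pop()

    def walk5(i: int, w: int, cols5: list[Column], anchor: Column,
              score: float, n_mm: int, n_wob: int, n_gap: int):
        if i < 1:
            # 5' arm complete; start the 3' arm from the anchor outward
            walk3(ANCHOR_SRNA_POS + 1, ANCHOR_WINDOW_POS - 1, [], list(cols5),
                  anchor, score, n_mm, n_wob, n_gap)
            return
        if w > WINDOW_LEN:
            return
        pr = try_pair(i, w)
        if pr is not None:
            state, d_s, d_mm, d_wob = pr
            if within_budget(score + d_s, n_mm + d_mm, n_wob + d_wob):
                cols5.append(Column(state, i, w))
                walk5(i - 1, w + 1, cols5, anchor,
                      score + d_s, n_mm + d_mm, n_wob + d_wob, n_gap)
                cols5.pop()
        if n_gap < rules.max_gaps:
            g_s = rules.gap_score * rules.multiplier(i)
            if within_budget(score + g_s, n_mm, n_wob):
                cols5.append(Column(STATE_TARGET_GAP, i, None))
                walk5(i - 1, w, cols5, anchor,
                      score + g_s, n_mm, n_wob, n_gap + 1)
                cols5.pop()
                cols5.append(Column(STATE_SRNA_GAP, None, w))
                walk5(i, w + 1, cols5, anchor,
                      score + g_s, n_mm, n_wob, n_gap + 1)
                cols5.pop()

    # the anchor pair itself (never gapped)
    pr = try_pair(ANCHOR_SRNA_POS, ANCHOR_WINDOW_POS)
    if pr is not None:
        state, d_s, d_mm, d_wob = pr
        if within_budget(d_s, d_mm, d_wob):
            anchor = Column(state, ANCHOR_SRNA_POS, ANCHOR_WINDOW_POS)
            walk5(ANCHOR_SRNA_POS - 1, ANCHOR_WINDOW_POS + 1, [], anchor,
                  d_s, d_mm, d_wob, 0)
    return results


def select_best(alignments: list[DuplexAlignment]) -> DuplexAlignment:
    """Lowest score, then fewest gaps, then fewest mismatches + wobbles;
    remaining ties broken by the 5'-most first difference in column states."""
    if not alignments:
        raise ValueError("cannot select from an empty alignment list")
    return min(alignments, key=DuplexAlignment.sort_key)


def align_duplex(
    srna: str, cand: TargetCandidate, rules: TargetingRuleSet
) -> Optional[DuplexAlignment]:
    """Best rule-compliant duplex of a sRNA against a candidate window, or
    None when no alignment satisfies the rules."""
    alignments = enumerate_alignments(srna, cand.window, rules)
    if not alignments:
        return None
    return select_best(alignments)


def render_duplex(a: DuplexAlignment) -> str:
    """Fixed-width 3-line duplex: target 5'->3', pair symbols, sRNA 3'->5'.

    Symbols: ``|`` match, ``o`` G:U wobble, space mismatch, ``-`` gap.  The
    sRNA line is rendered as RNA (U for T).
    """
    symbols = {
        STATE_MATCH: "|",
        STATE_WOBBLE: "o",
        STATE_MISMATCH: " ",
        STATE_SRNA_GAP: "-",
        STATE_TARGET_GAP: "-",
    }
    top, mid, bot = [], [], []
    # reversed columns put the target 5' end on the left
    for c in reversed(a.columns):
        top.append("-" if c.window_pos is None else a.target_window[c.window_pos - 1])
        mid.append(symbols[c.state])
        bot.append(
            "-" if c.srna_pos is None else a.srna[c.srna_pos - 1].replace("T", "U")
        )
    return "\n".join(
        (
            "5' " + "".join(top) + " 3' target",
            "   " + "".join(mid) + "   ",
            "3' " + "".join(bot) + " 5' sRNA",
        )
    )
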