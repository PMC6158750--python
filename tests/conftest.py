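"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from cleaveseek.rules import TargetingRuleSet

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {("G", "T"), ("T", "G")}  # (sRNA base, target base)


def pair_kind(s: str, t: str) -> str:
    """Direct string-level pair classification (independent of the 2-bit codes)."""
    if _COMP[s] == t:
        return "match"
    if (s, t) in _WOBBLE:
        return "wobble"
    return "mismatch"


def oracle_enumerate(srna: str, window: str, rules: TargetingRuleSet):
    """Brute-force enumeration of every anchored gapped duplex alignment.

    Walks the sRNA left-to-right (5'->3') over all start offsets and gap
    placements, with no in-flight pruning; each complete layout is then
    validated against every rule by direct recomputation.  Returns the list
    of (score, n_gaps, n_mm, n_wob, states) tuples of valid alignments.
    """
    n = len(srna)
    g = rules.max_gaps
    layouts = []

    def walk(i, w, gaps, cols):
        if i > n:
            layouts.append(list(cols))
            return
        if w < 1 or w > 32:
            return
        # the anchor (sRNA position 10 <-> window position 17) is never gapped
        if i == 10:
            if w == 17:
                cols.append(("pair", i, w))
                walk(i + 1, w - 1, gaps, cols)
                cols.pop()
            return
        cols.append(("pair", i, w))
        walk(i + 1, w - 1, gaps, cols)
        cols.pop()
        if gaps < g:
            cols.append(("srna_bulge", i, None))  # target-strand gap
            walk(i + 1, w, gaps + 1, cols)
            cols.pop()
            if cols:  # the aligner never bulges window bases beyond the sRNA ends
                cols.append(("window_bulge", None, w))  # sRNA-strand gap
                walk(i, w - 1, gaps + 1, cols)
                cols.pop()

    for start in range(26 - g, 26 + g + 1):
        walk(1, start, 0, [])

    valid = []
    for cols in layouts:
        score = n_mm = n_wob = n_gap = 0
        # states: (label, charge_pos, core_pos_or_None) in 5'->3' order
        states = []
        ok = True
        for idx, (kind, i, w) in enumerate(cols):
            if kind == "pair":
                pk = pair_kind(srna[i - 1], window[w - 1])
                if pk == "mismatch":
                    if not rules.mismatch_allowed_at(i):
                        ok = False
                        break
                    score += rules.mismatch_penalty(i)
                    n_mm += 1
                elif pk == "wobble":
                    if not rules.wobble_allowed_at(i):
                        ok = False
                        break
                    score += rules.gu_wobble_score * rules.multiplier(i)
                    n_wob += 1
                    if rules.gu_counts_as_mismatch:
                        n_mm += 1
                states.append((pk, i, i))
            elif kind == "srna_bulge":
                # bulged sRNA base: charged and core-flagged at its position
                score += rules.gap_score * rules.multiplier(i)
                n_gap += 1
                states.append(("gap", i, i))
            else:
                # bulged window base between consumed sRNA positions j, j+1:
                # the aligner charges the position it is traversing — j in
                # the 5' arm, j+1 in the 3' arm — and treats the column as
                # outside the core region
                nxt = next(
                    ii for k2, ii, _ in cols[idx + 1 :]
                    if k2 in ("pair", "srna_bulge")
                )
                prev = next(
                    ii for k2, ii, _ in reversed(cols[:idx])
                    if k2 in ("pair", "srna_bulge")
                )
                charge = prev if nxt <= 10 else nxt
                score += rules.gap_score * rules.multiplier(charge)
                n_gap += 1
                states.append(("gap", charge, None))
        if not ok:
            continue
        if score > rules.max_score or n_mm > rules.max_mismatches:
            continue
        if n_wob > rules.max_gu_wobbles or n_gap > rules.max_gaps:
            continue
        mm_like = [
            st == "mismatch" or st == "gap"
            or (st == "wobble" and rules.gu_counts_as_mismatch)
            for st, _, _ in states
        ]
        run = best = 0
        for f in mm_like:
            run = run + 1 if f else 0
            best = max(best, run)
        if best > rules.max_adjacent_mismatches:
            continue
        core = [
            cp is not None and rules.core_start <= cp <= rules.core_end
            for _, _, cp in states
        ]
        core_mm = sum(
            1 for (st, _, _), c in zip(states, core)
            if c and (st == "mismatch"
                      or (st == "wobble" and rules.gu_counts_as_mismatch))
        )
        if core_mm > rules.max_mismatches_core:
            continue
        run = best = 0
        for f, c in zip(mm_like, core):
            run = run + 1 if (f and c) else 0
            best = max(best, run)
        if best > rules.max_adjacent_mismatches_core:
            continue
        valid.append((round(score, 6), n_gap, n_mm, n_wob, tuple(states)))
    return valid


def oracle_best_triple(srna: str, window: str, rules: TargetingRuleSet):
    """Best (score, gaps, mismatches + wobbles) the oracle can find, or None."""
    valid = oracle_enumerate(srna, window, rules)
    if not valid:
        return None
    return min((s, gp, mm + wb) for s, gp, mm, wb, _ in valid)


def random_window_for(srna: str, rng: random.Random, n_mm=0, n_wob=0) -> str:
    """A 32-nt window whose site is the (edited) complement of the sRNA."""
    n = len(srna)
    window = [rng.choice("ACGT") for _ in range(32)]
    edit_pos = rng.sample(range(1, n + 1), k=min(n_mm + n_wob, n))
    mm_pos, wob_pos = set(edit_pos[:n_mm]), set(edit_pos[n_mm:])
    for i in range(1, n + 1):
        w = 27 - i
        s = srna[i - 1]
        if i in mm_pos:
            window[w - 1] = rng.choice(
                [b for b in "ACGT" if b != _COMP[s] and (s, b) not in _WOBBLE]
            )
        elif i in wob_pos and s in "GT":
            window[w - 1] = {"G": "T", "T": "G"}[s]
        else:
            window[w - 1] = _COMP[s]
    return "".join(window)


@pytest.fixture(scope="session")
def planted_fixture():
    """A small deterministic planted-truth dataset shared across tests."""
    from cleaveseek.synthgen import make_transcriptome, plant_interactions

    transcripts = make_transcriptome(10, (400, 800), seed=7)
    planted = plant_interactions(
        transcripts, 15, peak_abundance=10, background_rate=2.0, seed=8
    )
    return planted
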