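"""Targeting rules, presets, region extraction and the three-stage filter."""

import dataclasses
import random

import pytest

from cleaveseek.encoding import EncodedSeq, complement, encode
from cleaveseek.rules import (
    N_REGION_CODES,
    TargetingRuleSet,
    extract_regions,
    preset,
    region_pair_valid,
    region_row,
    region_start,
    three_stage_filter,
)

from conftest import pair_kind


class TestPresets:
    def test_allen_rejects_position10_mismatch(self):
        r = preset("allen")
        assert not r.mismatch_allowed_at(10)
        assert not r.wobble_allowed_at(11)

    def test_presets_differ_only_in_pos10_11_fields(self):
        a, fc = preset("allen"), preset("fahlgren_carrington")
        diff = {
            f.name
            for f in dataclasses.fields(TargetingRuleSet)
            if getattr(a, f.name) != getattr(fc, f.name)
        }
        assert diff == {"allow_mismatch_pos10", "allow_mismatch_pos11"}
        assert fc.mismatch_allowed_at(10) and fc.wobble_allowed_at(11)

    def test_allen_scoring_scheme(self):
        r = preset("allen")
        assert (r.mismatch_score, r.gu_wobble_score, r.gap_score) == (1.0, 0.5, 1.0)
        assert (r.core_start, r.core_end, r.core_multiplier) == (2, 13, 2.0)
        assert r.max_score == 4.0

    def test_config_file_roundtrip(self, tmp_path):
        for name in ("allen", "fc"):
            p = tmp_path / f"{name}.json"
            preset(name).to_json(p)
            assert TargetingRuleSet.from_json(p) == preset(name)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            preset("no-such-preset")


class TestRegionExtraction:
    @pytest.mark.parametrize(
        "length,r3_start", [(19, 13), (20, 14), (21, 15), (24, 18)]
    )
    def test_r3_start_positions(self, length, r3_start):
        assert region_start("R3", length) == r3_start
        srna = "".join("ACGT"[i % 4] for i in range(length))
        regions = extract_regions(srna)
        assert regions.r3.value == encode(srna[r3_start - 1 : r3_start + 6]).value

    def test_regions_are_7nt(self):
        for length in range(19, 25):
            srna = "".join("AGCT"[i % 4] for i in range(length))
            regions = extract_regions(srna)
            assert regions.r1.length == regions.r2.length == regions.r3.length == 7

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            extract_regions("ACGTACGTACGTA")  # 13 nt

    def test_perfect_site_region_identity(self):
        """On a perfectly complementary site, each TR code equals the
        corresponding R code (complement-identity property)."""
        srna = "TGACAGAAGAGAGTGAGCACA"
        regions = extract_regions(srna)
        for r, (a, b) in ((regions.r1, (1, 7)), (regions.r2, (8, 14)),
                          (regions.r3, (15, 21))):
            tr = encode(complement(srna[a - 1 : b]), "mRNA")
            assert tr.value == r.value


def row_oracle_gapfree(region, srna_value, srna_len, rules):
    """Independent brute-force row enumeration for gap-free rule sets:
    positionwise classification and direct budget checks."""
    from cleaveseek.encoding import decode

    srna7 = decode(EncodedSeq(srna_value, 7, "sRNA"))
    start = region_start(region, srna_len)
    out = set()
    for m in range(N_REGION_CODES):
        target7 = decode(EncodedSeq(m, 7, "mRNA"))
        score = n_mm = n_wob = run = max_run = core_mm = 0
        core_run = max_core_run = 0
        ok = True
        for k in range(7):
            pos = start + k
            kind = pair_kind(srna7[k], target7[k])
            mult = rules.multiplier(pos)
            in_core = rules.core_start <= pos <= rules.core_end
            mm_like = False
            if kind == "mismatch":
                if not rules.mismatch_allowed_at(pos):
                    ok = False
                    break
                score += rules.mismatch_penalty(pos)
                n_mm += 1
                mm_like = True
            elif kind == "wobble":
                if not rules.wobble_allowed_at(pos):
                    ok = False
                    break
                score += rules.gu_wobble_score * mult
                n_wob += 1
                if rules.gu_counts_as_mismatch:
                    n_mm += 1
                    mm_like = True
            run = run + 1 if mm_like else 0
            max_run = max(max_run, run)
            if in_core:
                core_mm += 1 if (kind == "mismatch" or (kind == "wobble" and rules.gu_counts_as_mismatch)) else 0
                core_run = core_run + 1 if mm_like else 0
                max_core_run = max(max_core_run, core_run)
            else:
                core_run = 0
        if (
            ok
            and score <= rules.max_score
            and n_mm <= rules.max_mismatches
            and n_wob <= rules.max_gu_wobbles
            and max_run <= rules.max_adjacent_mismatches
            and core_mm <= rules.max_mismatches_core
            and max_core_run <= rules.max_adjacent_mismatches_core
        ):
            out.add(m)
    return out


class TestRegionRows:
    def test_row_contains_perfect_complement(self):
        rules = preset("allen")
        for value in (0, 16383, 10922, 27):
            row = region_row("R1", EncodedSeq(value, 7, "sRNA"), 21, rules)
            assert value in row

    def test_strict_rules_give_singleton_row(self):
        strict = TargetingRuleSet(
            max_score=0.0, max_mismatches=0, max_gu_wobbles=0, max_gaps=0
        )
        row = region_row("R2", EncodedSeq(1234, 7, "sRNA"), 21, strict)
        assert row == {1234}

    @pytest.mark.parametrize("region", ["R1", "R2", "R3"])
    def test_rows_match_bruteforce_oracle_gapfree(self, region):
        rules = dataclasses.replace(preset("allen"), max_gaps=0)
        rng = random.Random(10)
        for value in rng.sample(range(N_REGION_CODES), 3):
            got = region_row(region, EncodedSeq(value, 7, "sRNA"), 21, rules)
            assert got == row_oracle_gapfree(region, value, 21, rules)

    def test_row_monotone_in_budgets(self):
        base = dataclasses.replace(preset("allen"), max_gaps=0)
        code = EncodedSeq(777, 7, "sRNA")
        row0 = region_row("R1", code, 21, base)
        for relax in (
            {"max_score": 5.0},
            {"max_mismatches": 5},
            {"max_gu_wobbles": 9},
            {"max_gaps": 1},
        ):
            bigger = region_row("R1", code, 21, dataclasses.replace(base, **relax))
            assert row0 <= bigger

    def test_matrix_dimension(self):
        assert N_REGION_CODES == 16384


class TestThreeStageFilter:
    def build_candidates(self, srna, edits, rng):
        """One candidate built from a window complementary up to edits."""
        from conftest import random_window_for
        from cleaveseek.degradome import TargetCandidate, target_region_value

        window = random_window_for(srna, rng, n_mm=edits)
        return TargetCandidate(
            transcript_id="t",
            cleavage_pos=50,
            window=window,
            abundance=5,
            weighted_abundance=5.0,
            category=0,
            tr1_code=EncodedSeq(target_region_value(window, 1, 7), 7, "mRNA"),
            tr2_code=EncodedSeq(target_region_value(window, 8, 14), 7, "mRNA"),
        )

    def test_perfect_site_survives_all_stages(self):
        rng = random.Random(11)
        srna = "".join(rng.choice("ACGT") for _ in range(21))
        cand = self.build_candidates(srna, 0, rng)
        out = three_stage_filter(
            extract_regions(srna), {cand.tr2_code.value: [cand]}, preset("allen")
        )
        assert out == [cand]

    def test_overloaded_tr2_eliminated_at_stage_one(self):
        """Five mismatches confined to the R2/TR2 region break every budget,
        so the whole group is dropped before stages two and three."""
        rng = random.Random(12)
        srna = "".join(rng.choice("ACGT") for _ in range(21))
        cand = self.build_candidates(srna, 0, rng)
        regions = extract_regions(srna)
        # verify against exhaustive row: pick a TR2 value outside the R2 row
        rules = preset("allen")
        row = region_row("R2", regions.r2, 21, rules)
        bad_tr2 = next(m for m in range(N_REGION_CODES) if m not in row)
        groups = {bad_tr2: [cand]}
        assert three_stage_filter(regions, groups, rules) == []

    def test_conservative_never_drops_aligner_accepted_candidate(self):
        """Core contract: any candidate the duplex aligner accepts passes
        all three region stages, under gap budgets 0 and 1."""
        from cleaveseek.degradome import target_region_value
        from cleaveseek.duplex import align_duplex

        rng = random.Random(13)
        for max_gaps in (0, 1):
            rules = dataclasses.replace(preset("fc"), max_gaps=max_gaps)
            for _ in range(150):
                n = rng.randint(19, 24)
                srna = "".join(rng.choice("ACGT") for _ in range(n))
                cand = self.build_candidates(srna, rng.randint(0, 4), rng)
                if align_duplex(srna, cand, rules) is None:
                    continue
                regions = extract_regions(srna)
                groups = {cand.tr2_code.value: [cand]}
                assert three_stage_filter(regions, groups, rules) == [cand]


def test_region_pair_reflexive_under_any_rules():
    rng = random.Random(14)
    for _ in range(50):
        value = rng.randrange(N_REGION_CODES)
        assert region_pair_valid("R2", value, value, 21, preset("allen"))
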