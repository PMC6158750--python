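"""Degradome alignment, profiles, categories and candidate extraction."""

import random

import pytest

from cleaveseek import degradome
from cleaveseek.degradome import DegradationProfile, Signal
from cleaveseek.encoding import complement, encode
from cleaveseek.seqio import ReadLibrary, Transcript


def make_lib(records):
    return ReadLibrary(name="deg", records=dict(records))


def naive_scan(transcripts, records):
    """Brute-force oracle: all-window substring scan, sense strand only."""
    hits = {}  # (tid, pos) -> abundance
    match_count = {seq: 0 for seq in records}
    for t in transcripts:
        for seq in records:
            start = 0
            while True:
                i = t.sequence.find(seq, start)
                if i < 0:
                    break
                match_count[seq] += 1
                start = i + 1
    for t in transcripts:
        for seq, abundance in records.items():
            start = 0
            while True:
                i = t.sequence.find(seq, start)
                if i < 0:
                    break
                key = (t.id, i + 1)
                a, w = hits.get(key, (0, 0.0))
                hits[key] = (a + abundance, w + abundance / match_count[seq])
                start = i + 1
    return hits


class TestAlignment:
    def test_planted_tag_found_at_position(self):
        rng = random.Random(3)
        seq = "".join(rng.choice("ACGT") for _ in range(100))
        tag = seq[30:50]  # 5' end at position 31
        lib = make_lib({tag: 7})
        index = degradome.build_fragment_index(lib, 19, 21)
        profiles = degradome.align_degradome(
            [Transcript(id="t", sequence=seq)], index
        )
        assert profiles["t"].signals[31].abundance == 7

    def test_multimapping_splits_weighted_abundance(self):
        rng = random.Random(4)
        core = "".join(rng.choice("ACGT") for _ in range(20))
        t1 = "".join(rng.choice("ACGT") for _ in range(40)) + core
        t2 = core + "".join(rng.choice("ACGT") for _ in range(40))
        lib = make_lib({core: 10})
        index = degradome.build_fragment_index(lib, 19, 21)
        profiles = degradome.align_degradome(
            [Transcript(id="a", sequence=t1), Transcript(id="b", sequence=t2)],
            index,
        )
        assert profiles["a"].signals[41].weighted_abundance == pytest.approx(5.0)
        assert profiles["b"].signals[1].weighted_abundance == pytest.approx(5.0)

    def test_agrees_with_naive_scan_oracle(self):
        rng = random.Random(5)
        transcripts = [
            Transcript(
                id=f"t{i}",
                sequence="".join(rng.choice("ACGT") for _ in range(rng.randint(150, 300))),
            )
            for i in range(50)
        ]
        records = {}
        for _ in range(400):  # embedded tags: guaranteed hits
            t = rng.choice(transcripts)
            n = rng.choice([19, 20, 21])
            start = rng.randint(0, len(t.sequence) - n)
            records[t.sequence[start : start + n]] = rng.randint(1, 20)
        for _ in range(100):  # random tags: mostly misses
            records["".join(rng.choice("ACGT") for _ in range(20))] = 1
        lib = make_lib(records)
        index = degradome.build_fragment_index(lib, 19, 21)
        profiles = degradome.align_degradome(transcripts, index)
        got = {
            (tid, pos): (s.abundance, round(s.weighted_abundance, 9))
            for tid, p in profiles.items()
            for pos, s in p.signals.items()
        }
        want = {
            k: (a, round(w, 9)) for k, (a, w) in naive_scan(transcripts, records).items()
        }
        assert got == want

    def test_weighted_abundance_conserved_per_read(self):
        """Summed over the transcriptome, one read's weighted abundance
        equals its raw abundance, however many places it maps."""
        rng = random.Random(6)
        core = "".join(rng.choice("ACGT") for _ in range(20))
        transcripts = [
            Transcript(id=f"t{i}", sequence=core + "".join(rng.choice("ACGT") for _ in range(30)) + core)
            for i in range(3)
        ]
        lib = make_lib({core: 12})
        index = degradome.build_fragment_index(lib, 19, 21)
        profiles = degradome.align_degradome(transcripts, index)
        total = sum(
            s.weighted_abundance for p in profiles.values() for s in p.signals.values()
        )
        assert total == pytest.approx(12)

    def test_out_of_range_lengths_not_indexed(self):
        lib = make_lib({"ACGT" * 5: 1, "ACGT" * 7: 1})
        index = degradome.build_fragment_index(lib, 19, 21)
        assert set(index.by_length) == {20}
        with pytest.raises(ValueError):
            degradome.build_fragment_index(make_lib({"ACGT" * 7: 1}), 19, 21)


def profile_from(abundances):
    p = DegradationProfile(transcript_id="t")
    for i, a in enumerate(abundances, start=1):
        p.signals[i * 25] = Signal(abundance=a)
    return degradome.assign_categories(p)


class TestCategories:
    @pytest.mark.parametrize(
        "abundances,expected",
        [
            # tied maxima; avg over >1 positions = (5+5+2)/3 = 4
            ([5, 5, 2, 1], [1, 1, 3, 4]),
            # unique maximum; avg = (9+2)/2 = 5.5
            ([9, 2, 1], [0, 3, 4]),
            ([1], [4]),
            # above-average peak: avg = (8+3+3)/3 = 14/3
            ([8, 3, 3, 1, 1], [0, 3, 3, 4, 4]),
        ],
    )
    def test_worked_profiles(self, abundances, expected):
        p = profile_from(abundances)
        assert [s.category for s in p.signals.values()] == expected

    def test_partition_exhaustive_and_exclusive(self):
        """Every position gets exactly one category in 0..4 over an
        exhaustive family of small profiles; all five categories occur."""
        import itertools

        seen = set()
        for n in (1, 2, 3, 4):
            for abundances in itertools.product((1, 2, 8, 9), repeat=n):
                p = profile_from(abundances)
                cats = [s.category for s in p.signals.values()]
                assert len(cats) == n
                assert all(c in range(5) for c in cats)
                seen.update(cats)
        assert seen == {0, 1, 2, 3, 4}


class TestCandidates:
    def make_transcript_with_peak(self, pos, length=200, seed=7):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        tag = seq[pos - 1 : pos + 19]
        lib = make_lib({tag: 8})
        t = Transcript(id="t", sequence=seq)
        index = degradome.build_fragment_index(lib, 19, 21)
        profiles = degradome.align_degradome([t], index)
        degradome.assign_categories(profiles["t"])
        return t, profiles["t"]

    def test_window_is_32nt_centered_on_cleavage(self):
        t, profile = self.make_transcript_with_peak(60)
        (cand,) = degradome.extract_candidates(t, profile)
        assert len(cand.window) == 32
        assert cand.window == t.sequence[60 - 17 : 60 + 15]
        assert cand.window[16] == t.sequence[59]  # position p at window index 17

    @pytest.mark.parametrize("pos", [10, 16])
    def test_5prime_boundary_produces_no_candidate(self, pos):
        t, profile = self.make_transcript_with_peak(pos)
        assert pos in profile.signals
        assert degradome.extract_candidates(t, profile) == []

    @pytest.mark.parametrize("pos,expected", [(186, False), (185, True)])
    def test_3prime_boundary(self, pos, expected):
        # window needs p <= L - 15; build the profile by hand since a real
        # >= 19-nt tag can never start closer than 18 nt to the 3' end
        rng = random.Random(9)
        t = Transcript(id="t", sequence="".join(rng.choice("ACGT") for _ in range(200)))
        profile = DegradationProfile(transcript_id="t")
        profile.signals[pos] = Signal(abundance=5)
        degradome.assign_categories(profile)
        cands = degradome.extract_candidates(t, profile)
        assert bool(cands) == expected

    def test_category_filter_and_abundance_floor(self):
        t, profile = self.make_transcript_with_peak(60)
        assert degradome.extract_candidates(t, profile, frozenset({1, 2})) == []
        assert (
            degradome.extract_candidates(t, profile, min_fragment_abundance=9) == []
        )

    def test_tr2_matches_planted_srna_r2(self):
        """For a perfectly complementary planted site, the TR2 code equals
        the sRNA's R2 code (complement-identity property)."""
        rng = random.Random(8)
        seq = list("".join(rng.choice("ACGT") for _ in range(120)))
        srna = "".join(rng.choice("ACGT") for _ in range(21))
        p = 50
        for i in range(1, 22):  # sRNA position i pairs transcript p + 10 - i
            seq[p + 10 - i - 1] = complement(srna[i - 1])
        seq = "".join(seq)
        tag = seq[p - 1 : p + 19]
        t = Transcript(id="t", sequence=seq)
        index = degradome.build_fragment_index(make_lib({tag: 5}), 19, 21)
        profiles = degradome.align_degradome([t], index)
        degradome.assign_categories(profiles["t"])
        cands = degradome.extract_candidates(t, profiles["t"])
        cand = next(c for c in cands if c.cleavage_pos == p)
        assert cand.tr2_code.value == encode(srna[7:14], "sRNA").value
        assert cand.tr1_code.value == encode(srna[0:7], "sRNA").value


class TestGrouping:
    def test_groups_partition_candidates(self, planted_fixture):
        from cleaveseek.degradome import (
            align_degradome,
            assign_categories,
            build_fragment_index,
            extract_candidates,
            group_by_tr2,
        )

        index = build_fragment_index(planted_fixture.deg_lib, 19, 21)
        profiles = align_degradome(planted_fixture.transcripts, index)
        by_id = {t.id: t for t in planted_fixture.transcripts}
        cands = []
        for tid, p in profiles.items():
            assign_categories(p)
            cands.extend(extract_candidates(by_id[tid], p))
        groups = group_by_tr2(cands)
        assert sum(len(v) for v in groups.values()) == len(cands)
        for key, members in groups.items():
            assert all(c.tr2_code.value == key for c in members)

    def test_empty_input(self):
        assert degradome.group_by_tr2([]) == {}
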