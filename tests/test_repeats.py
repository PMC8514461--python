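import pytest

from plantmeth.calling import SiteFrequency
from plantmeth.io_formats import RepeatPair
from plantmeth.motif import reverse_complement, site_context
from plantmeth.repeats import classify_pair, filter_pairs, match_cytosines


def _pair(start_a=0, start_b=300, length=200, identity=0.995, chrom="c1", reverse=False):
    return RepeatPair(
        region_a=(chrom, start_a, start_a + length),
        region_b=(chrom, start_b, start_b + length),
        length=length,
        identity=identity,
        reverse=reverse,
    )


def _freq_table(reference, frequencies):
    """frequencies: (chrom, pos, strand) -> (freq, cov)."""
    table = {}
    for (chrom, pos, strand), (freq, cov) in frequencies.items():
        table[(chrom, pos, strand)] = SiteFrequency(
            chrom, pos, strand, "CpG", cov, round(freq * cov)
        )
    return table


@pytest.fixture
def duplicated_reference(rng):
    """A contig whose [0, 200) block recurs exactly at [300, 500)."""
    block = "".join(rng.choice(list("ACGT"), size=200))
    spacer = "".join(rng.choice(list("ACGT"), size=100))
    tail = "".join(rng.choice(list("ACGT"), size=60))
    return {"c1": block + spacer + block + tail}


class TestFilterPairs:
    @pytest.mark.parametrize(
        "length, identity, kept",
        [(100, 0.99, True), (99, 0.999, False), (150, 0.98, False), (300, 1.0, True)],
    )
    def test_thresholds_inclusive(self, length, identity, kept):
        pairs = filter_pairs([_pair(length=length, identity=identity, start_b=400)])
        assert bool(pairs) is kept

    def test_pairs_without_cytosines_dropped(self):
        reference = {"c1": "AT" * 300}
        assert filter_pairs([_pair()], reference=reference) == []
        reference_with_c = {"c1": "AT" * 75 + "ACG" + "AT" * 300}  # C inside member A
        assert filter_pairs([_pair()], reference=reference_with_c) != []


class TestMatchCytosines:
    def test_identical_members_fully_matched(self, duplicated_reference):
        ref = duplicated_reference
        pair = _pair()
        freqs = {}
        for offset in range(200):
            for pos in (offset, 300 + offset):
                for strand in "+-":
                    if site_context(ref["c1"], pos, strand) is not None:
                        freqs[("c1", pos, strand)] = (0.8, 10)
        profile = match_cytosines(pair, _freq_table(ref, freqs), ref)
        expected = sum(
            1
            for offset in range(200)
            for strand in "+-"
            if site_context(ref["c1"], offset, strand) is not None
            and site_context(ref["c1"], 300 + offset, strand) is not None
        )
        assert len(profile.matched) == expected
        profile = classify_pair(profile)
        assert profile.n_differential["allC"] == 0
        assert profile.differential["allC"] is False

    def test_missing_coverage_excludes_offset(self, duplicated_reference):
        ref = duplicated_reference
        pair = _pair()
        freqs = {}
        for offset in range(200):
            for strand in "+-":
                if site_context(ref["c1"], offset, strand) is None:
                    continue
                freqs[("c1", offset, strand)] = (0.8, 10)
                # member B: first matchable offset gets coverage 2 (below cutoff)
                cov = 2 if not freqs.get("marked") and offset > 0 else 10
                if cov == 2:
                    freqs["marked"] = True
                freqs[("c1", 300 + offset, strand)] = (0.8, cov)
        freqs.pop("marked", None)
        full = match_cytosines(pair, _freq_table(ref, {k: (0.8, 10) for k in freqs}), ref)
        reduced = match_cytosines(pair, _freq_table(ref, freqs), ref)
        assert len(reduced.matched) == len(full.matched) - 1

    def test_matched_count_equals_brute_force_intersection(self, duplicated_reference, rng):
        ref = duplicated_reference
        pair = _pair()
        freqs = {}
        for pos in range(len(ref["c1"])):
            for strand in "+-":
                if site_context(ref["c1"], pos, strand) is None:
                    continue
                if rng.random() < 0.7:
                    freqs[("c1", pos, strand)] = (float(rng.random()), int(rng.integers(3, 15)))
        table = _freq_table(ref, freqs)
        profile = match_cytosines(pair, table, ref)
        expected = 0
        for offset in range(200):
            for strand in "+-":
                fa = table.get(("c1", offset, strand))
                fb = table.get(("c1", 300 + offset, strand))
                if (
                    site_context(ref["c1"], offset, strand) is not None
                    and site_context(ref["c1"], 300 + offset, strand) is not None
                    and fa is not None
                    and fb is not None
                    and fa.coverage >= 5
                    and fb.coverage >= 5
                ):
                    expected += 1
        assert len(profile.matched) == expected

    def test_reverse_orientation_strand_flip(self, rng):
        """An inverted copy pairs + strand cytosines with - strand positions."""
        block = "".join(rng.choice(list("ACGT"), size=80))
        ref = {"c1": block + "TTTT" + reverse_complement(block)}
        start_b = len(block) + 4
        pair = RepeatPair(
            region_a=("c1", 0, 80),
            region_b=("c1", start_b, start_b + 80),
            length=80,
            identity=1.0,
            reverse=True,
        )
        freqs = {}
        for pos in range(len(ref["c1"])):
            for strand in "+-":
                if site_context(ref["c1"], pos, strand) is not None:
                    freqs[("c1", pos, strand)] = (0.9, 10)
        profile = match_cytosines(pair, _freq_table(ref, freqs), ref)
        assert profile.matched, "inverted repeat must still match cytosines"
        for m in profile.matched:
            pos_b = start_b + 80 - 1 - m.offset
            strand_b = "-" if m.strand_a == "+" else "+"
            assert site_context(ref["c1"], pos_b, strand_b) is not None


class TestClassifyPair:
    def _profile_with(self, deltas, contexts=None):
        from plantmeth.repeats import MatchedCytosine, PairMethylationProfile

        contexts = contexts or ["CpG"] * len(deltas)
        profile = PairMethylationProfile(pair=_pair())
        for i, (d, ctx) in enumerate(zip(deltas, contexts)):
            profile.matched.append(MatchedCytosine(i, "+", 0.5, 0.5 + d, ctx))
        return profile

    def test_ten_percent_with_delta_half_is_differential(self):
        profile = classify_pair(self._profile_with([0.5] + [0.0] * 9))
        assert profile.differential["allC"] is True

    def test_delta_just_below_threshold_not_differential(self):
        profile = classify_pair(self._profile_with([0.49] * 10))
        assert profile.n_differential["allC"] == 0
        assert profile.differential["allC"] is False

    def test_empty_class_flag_undefined(self):
        profile = classify_pair(self._profile_with([0.5], contexts=["CpG"]))
        assert profile.differential["CHH"] is None

    def test_context_counts_partition_all_cytosines(self, rng):
        deltas = rng.uniform(-1, 1, size=60).tolist()
        contexts = [str(rng.choice(["CpG", "CHG", "CHH"])) for _ in deltas]
        profile = classify_pair(self._profile_with(deltas, contexts))
        assert profile.n_matched["allC"] == sum(
            profile.n_matched[c] for c in ("CpG", "CHG", "CHH")
        )
        assert profile.n_differential["allC"] == sum(
            profile.n_differential[c] for c in ("CpG", "CHG", "CHH")
        )

    def test_flags_match_brute_force_recount(self, rng):
        deltas = rng.uniform(-1, 1, size=40).tolist()
        contexts = [str(rng.choice(["CpG", "CHG", "CHH"])) for _ in deltas]
        profile = classify_pair(self._profile_with(deltas, contexts))
        for cls in ("allC", "CpG", "CHG", "CHH"):
            members = [
                (d, c) for d, c in zip(deltas, contexts) if cls == "allC" or c == cls
            ]
            n_diff = sum(1 for d, _ in members if abs(d) >= 0.5)
            if not members:
                assert profile.differential[cls] is None
            else:
                assert profile.n_differential[cls] == n_diff
                assert profile.differential[cls] == (n_diff / len(members) >= 0.10)

    def test_symmetric_in_member_order(self, duplicated_reference, rng):
        ref = duplicated_reference
        freqs = {}
        for pos in range(len(ref["c1"])):
            for strand in "+-":
                if site_context(ref["c1"], pos, strand) is not None:
                    freqs[("c1", pos, strand)] = (float(rng.random()), 10)
        table = _freq_table(ref, freqs)
        fwd = classify_pair(match_cytosines(_pair(), table, ref))
        swapped = RepeatPair(("c1", 300, 500), ("c1", 0, 200), 200, 0.995)
        rev = classify_pair(match_cytosines(swapped, table, ref))
        assert fwd.n_matched == rev.n_matched
        assert fwd.n_differential == rev.n_differential
        assert fwd.differential == rev.differential
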