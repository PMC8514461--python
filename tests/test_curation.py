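from dataclasses import dataclass, field
from itertools import count

import numpy as np
import pytest

from plantmeth.curation import (
    CurationConfig,
    balance_negative_samples,
    denoise_samples,
    select_high_confidence_sites,
    subsample_training_set,
)
from plantmeth.io_formats import BisulfiteSiteRecord

from _oracles import balance_counts_oracle, select_sites_oracle

_uid = count()


@dataclass
class FakeSample:
    """Carries only what curation needs: a k-mer, a label, and an identity."""

    kmer: str
    label: int | None = None
    truth: int | None = None
    uid: int = field(default_factory=lambda: next(_uid))


def _multiset(samples):
    counts = {}
    for s in samples:
        counts[s.kmer] = counts.get(s.kmer, 0) + 1
    return counts


def _record(chrom, pos, strand, n_meth, n_unmeth, context="CHH"):
    return BisulfiteSiteRecord(chrom, pos, strand, n_meth, n_unmeth, context)


class TestSelectHighConfidenceSites:
    def test_single_replicate_thresholds(self):
        report = [
            _record("c1", 10, "+", 19, 1),  # cov 20, freq 0.95 -> methylated
            _record("c1", 20, "+", 4, 0),  # cov 4 -> fails coverage
            _record("c1", 30, "+", 0, 8),  # cov 8, freq 0 -> unmethylated
            _record("c1", 40, "+", 4, 4),  # freq 0.5 -> neither
        ]
        sets = select_high_confidence_sites([report], "CHH", CurationConfig())
        assert sets.methylated == {("c1", 10, "+")}
        assert sets.unmethylated == {("c1", 30, "+")}

    def test_union_rule_accepts_single_replicate_positive(self):
        reports = [
            [_record("c1", 10, "+", 10, 0)],
            [_record("c1", 10, "+", 3, 4)],  # freq < 0.9 here
        ]
        sets = select_high_confidence_sites(reports, "CHH", CurationConfig())
        assert ("c1", 10, "+") in sets.methylated

    def test_unmethylated_requires_zero_in_all_replicates(self):
        reports = [
            [_record("c1", 10, "+", 0, 9)],
            [_record("c1", 10, "+", 1, 9)],  # one methylated read elsewhere
        ]
        sets = select_high_confidence_sites(reports, "CHH", CurationConfig())
        assert ("c1", 10, "+") not in sets.unmethylated

    def test_intersection_rule_for_cpg(self):
        reports = [
            [_record("c1", 10, "+", 10, 0, "CpG"), _record("c1", 20, "+", 10, 0, "CpG")],
            [_record("c1", 10, "+", 9, 1, "CpG"), _record("c1", 20, "+", 5, 5, "CpG")],
        ]
        sets = select_high_confidence_sites(reports, "CpG", CurationConfig())
        assert sets.methylated == {("c1", 10, "+")}

    @pytest.mark.parametrize("context,rule", [("CpG", "intersection"), ("CHH", "union")])
    def test_matches_set_algebra_oracle_on_random_replicates(self, rng, context, rule):
        reports = []
        for _ in range(3):
            report = []
            for pos in range(500):
                cov = int(rng.integers(0, 15))
                n_meth = int(rng.binomial(cov, rng.random())) if cov else 0
                report.append(_record("c1", pos, "+", n_meth, cov - n_meth, context))
            reports.append(report)
        sets = select_high_confidence_sites(reports, context, CurationConfig())
        exp_meth, exp_unmeth = select_sites_oracle(reports, context, rule=rule)
        assert sets.methylated == exp_meth
        assert sets.unmethylated == exp_unmeth


class TestBalanceNegativeSamples:
    def test_worked_example(self):
        pos = [FakeSample("A")] * 3 + [FakeSample("B")] * 2
        neg = [FakeSample("A") for _ in range(10)]
        neg += [FakeSample("B")] + [FakeSample("C") for _ in range(4)]
        out = balance_negative_samples(pos, neg, 0)
        assert _multiset(out) == {"A": 3, "B": 1, "C": 1}
        assert len(out) == len(pos)

    def test_identical_multisets_kept_whole(self):
        pos = [FakeSample(k) for k in "AABBC"]
        neg = [FakeSample(k) for k in "AABBC"]
        out = balance_negative_samples(pos, neg, 0)
        assert _multiset(out) == _multiset(neg)

    def test_empty_positive_set(self):
        assert balance_negative_samples([], [FakeSample("A")], 0) == []

    def test_random_multiset_property(self, rng):
        """Per-common-kmer negative count never exceeds the positive count."""
        kmers = [f"K{i}" for i in range(12)]
        for trial in range(1000):
            pos = [FakeSample(k) for k in rng.choice(kmers, size=int(rng.integers(0, 25)))]
            neg = [FakeSample(k) for k in rng.choice(kmers, size=int(rng.integers(0, 25)))]
            out = balance_negative_samples(pos, neg, int(rng.integers(2**31)))
            out_counts = _multiset(out)
            bounds = balance_counts_oracle([s.kmer for s in pos], [s.kmer for s in neg])
            for kmer, (cap, _avail) in bounds.items():
                assert out_counts.get(kmer, 0) <= cap
            assert len(out) <= max(len(pos), 0) or len(out) <= len(neg)
            assert set(map(id, out)) <= set(map(id, neg))


class TestSubsample:
    def test_even_split(self):
        pos = [FakeSample("A") for _ in range(100)]
        neg = [FakeSample("B") for _ in range(100)]
        p, n = subsample_training_set(pos, neg, 50, 0)
        assert (len(p), len(n)) == (25, 25)

    def test_exhausted_class_not_backfilled(self):
        pos = [FakeSample("A") for _ in range(10)]
        neg = [FakeSample("B") for _ in range(100)]
        p, n = subsample_training_set(pos, neg, 50, 0)
        assert (len(p), len(n)) == (10, 25)

    def test_seed_reproducible(self):
        pos = [FakeSample("A") for _ in range(100)]
        neg = [FakeSample("B") for _ in range(100)]
        first = subsample_training_set(pos, neg, 60, 7)
        second = subsample_training_set(pos, neg, 60, 7)
        assert [s.uid for s in first[0]] == [s.uid for s in second[0]]
        assert [s.uid for s in first[1]] == [s.uid for s in second[1]]


def _oracle_fit_score(train, to_score, epochs, seed):
    """A perfect scorer: probability reflects each sample's hidden truth."""
    return np.array([0.95 if s.truth == 1 else 0.05 for s in to_score])


class TestDenoise:
    def _dataset(self, n=200, mislabel=0):
        pos = [FakeSample("A", label=1, truth=1) for _ in range(n)]
        neg = [FakeSample("A", label=0, truth=0) for _ in range(n)]
        injected = [FakeSample("A", label=1, truth=0) for _ in range(mislabel)]
        return pos, neg, injected

    def test_clean_data_stops_after_first_iteration(self):
        pos, neg, _ = self._dataset()
        denoised, history = denoise_samples(pos + neg, _oracle_fit_score, CurationConfig(), 0)
        assert len(history) == 1
        assert history[0]["retention"] >= 0.99

    def test_injected_false_positives_removed(self):
        pos, neg, injected = self._dataset(n=200, mislabel=40)
        denoised, history = denoise_samples(
            pos + injected + neg, _oracle_fit_score, CurationConfig(), 0
        )
        kept_pos_ids = {id(s) for s in denoised if s.label == 1}
        assert kept_pos_ids.isdisjoint({id(s) for s in injected})
        assert kept_pos_ids == {id(s) for s in pos}

    def test_set_containment_invariants(self):
        pos, neg, injected = self._dataset(n=150, mislabel=30)
        samples = pos + injected + neg
        denoised, _ = denoise_samples(samples, _oracle_fit_score, CurationConfig(), 0)
        out_pos = {id(s) for s in denoised if s.label == 1}
        out_neg = {id(s) for s in denoised if s.label == 0}
        assert out_pos <= {id(s) for s in samples if s.label == 1}
        assert out_neg <= {id(s) for s in neg}

    def test_positive_set_shrinks_weakly(self):
        pos, neg, injected = self._dataset(n=100, mislabel=50)

        retained = []

        def noisy_fit_score(train, to_score, epochs, seed):
            rng = np.random.default_rng(seed)
            return np.clip(
                [0.8 * s.truth + 0.1 + rng.normal(0, 0.15) for s in to_score], 0, 1
            )

        _, history = denoise_samples(
            pos + injected + neg, noisy_fit_score, CurationConfig(), 0
        )
        counts = [h["retained"] for h in history]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_requires_both_classes(self):
        pos, _, _ = self._dataset(n=5)
        with pytest.raises(ValueError):
            denoise_samples(pos, _oracle_fit_score, CurationConfig(), 0)
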