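import io as _io
import json

import numpy as np
import pytest

from plantmeth.motif import scan_cytosines
from plantmeth.synthetic import (
    SyntheticConfig,
    TRAINING_FREQ_MIX,
    generate_bisulfite_table,
    generate_event_reads,
    generate_reference,
    generate_training_samples,
    generate_truth,
    inject_mislabels,
)


class TestGenerateReference:
    def test_fixed_seed_reproducible(self):
        cfg = SyntheticConfig(genome_length=5_000, seed=9)
        assert generate_reference(cfg) == generate_reference(cfg)

    def test_gc_fraction_within_binomial_bound(self):
        n = 100_000
        cfg = SyntheticConfig(genome_length=n, gc_fraction=0.5, seed=1)
        (seq,) = generate_reference(cfg).values()
        gc = seq.count("G") + seq.count("C")
        sd = np.sqrt(n * 0.5 * 0.5)
        assert abs(gc - n * 0.5) < 3 * sd

    def test_contig_count(self):
        cfg = SyntheticConfig(genome_length=2_000, n_contigs=2, seed=1)
        assert len(generate_reference(cfg)) == 2


class TestGenerateTruth:
    def test_truth_sites_match_motif_scan(self):
        cfg = SyntheticConfig(genome_length=2_000, seed=4)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        scanned = {s.key: s.context for s in scan_cytosines(ref, cfg.k)}
        assert set(truth) == set(scanned)
        assert all(truth[k].context == scanned[k] for k in truth)

    def test_molecule_states_follow_frequency(self):
        cfg = SyntheticConfig(
            genome_length=800, coverage=100, read_length=400, seed=4,
            freq_mix=dict(TRAINING_FREQ_MIX),
        )
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        _, states = generate_event_reads(ref, truth, cfg)
        per_site: dict = {}
        for (_, chrom, pos, strand), state in states.items():
            per_site.setdefault((chrom, pos, strand), []).append(state)
        for key, observed in per_site.items():
            freq = truth[key].frequency
            if freq == 0.0:
                assert sum(observed) == 0
            elif freq == 1.0:
                assert sum(observed) == len(observed)

    def test_intermediate_frequency_recovered_within_binomial_error(self):
        cfg = SyntheticConfig(genome_length=600, coverage=120, read_length=300, seed=8)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        _, states = generate_event_reads(ref, truth, cfg)
        per_site: dict = {}
        for (_, chrom, pos, strand), state in states.items():
            per_site.setdefault((chrom, pos, strand), []).append(state)
        checked = 0
        for key, observed in per_site.items():
            freq = truth[key].frequency
            n = len(observed)
            if 0.0 < freq < 1.0 and n >= 30:
                sd = np.sqrt(freq * (1 - freq) / n)
                assert abs(np.mean(observed) - freq) < 4 * sd + 1e-9
                checked += 1
        assert checked > 0


class TestGenerateEventReads:
    def test_fixed_seed_byte_identical_serialization(self):
        cfg = SyntheticConfig(genome_length=1_000, coverage=4, read_length=500, seed=3)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        outputs = []
        for _ in range(2):
            reads, _ = generate_event_reads(ref, truth, cfg)
            buf = _io.StringIO()
            for r in reads:
                buf.write(json.dumps({"id": r.read_id, "s": r.signals}))
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_reads_tile_both_strands_at_coverage(self):
        cfg = SyntheticConfig(genome_length=2_000, coverage=10, read_length=500, seed=3)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        reads, _ = generate_event_reads(ref, truth, cfg)
        total_bases = sum(len(r.bases) for r in reads)
        assert total_bases >= cfg.coverage * cfg.genome_length
        assert {r.strand for r in reads} == {"+", "-"}
        for read in reads:
            assert read.bases == ref[read.chrom][read.start : read.end]


class TestGenerateBisulfiteTable:
    def test_no_error_full_methylation_all_reads_methylated(self):
        cfg = SyntheticConfig(
            genome_length=600, conversion_error=0.0, seed=5,
            freq_mix={c: (0.0, 1.0, 1, 1) for c in ("CpG", "CHG", "CHH")},
        )
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        records = generate_bisulfite_table(truth, ref, cfg)
        assert records
        assert all(r.count_unmethylated == 0 for r in records)

    def test_observed_frequency_tracks_truth(self):
        cfg = SyntheticConfig(genome_length=2_000, bisulfite_coverage=60.0, seed=5)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        records = generate_bisulfite_table(truth, ref, cfg)
        diffs = [
            r.frequency - truth[(r.chrom, r.pos, r.strand)].frequency
            for r in records
            if r.coverage >= 30
        ]
        assert abs(float(np.mean(diffs))) < 0.02

    def test_zero_coverage_rows_emitted(self):
        cfg = SyntheticConfig(genome_length=3_000, bisulfite_coverage=1.0, seed=5)
        ref = generate_reference(cfg)
        truth = generate_truth(ref, cfg)
        records = generate_bisulfite_table(truth, ref, cfg)
        assert any(r.coverage == 0 for r in records)
        assert len(records) == len(truth)


@pytest.fixture(scope="module")
def samples():
    return generate_training_samples(SyntheticConfig(seed=21), 2_000)


class TestInjectMislabels:

    def test_zero_ratio_is_identity(self, samples):
        out, injected = inject_mislabels(samples, 0.0, seed=1)
        assert injected == set()
        assert [s.uid for s in out] == [s.uid for s in samples]

    def test_ten_percent_of_thousand_positives(self, samples):
        out, injected = inject_mislabels(samples, 0.10, seed=1)
        assert len(injected) == 100  # 10% of 1000 positives
        assert sum(1 for s in out if s.label == 1) == 1000  # positive count preserved

    def test_injected_are_relabelled_negatives(self, samples):
        genuine_pos = {s.uid for s in samples if s.label == 1}
        out, injected = inject_mislabels(samples, 0.15, seed=2)
        assert injected.isdisjoint(genuine_pos)
        negatives_left = {s.uid for s in out if s.label == 0}
        assert injected.isdisjoint(negatives_left)
        for s in out:
            if s.uid in injected:
                assert s.label == 1


class TestGenerateTrainingSamples:
    def test_balanced_shapes_and_determinism(self):
        cfg = SyntheticConfig(seed=13)
        samples = generate_training_samples(cfg, 50)
        assert len(samples) == 50
        assert sum(s.label for s in samples) == 25
        for s in samples:
            assert s.seq_features.shape == (13, 4)
            assert s.signal_features.shape == (13, 16)
            assert s.kmer[6] == "C"
        again = generate_training_samples(cfg, 50)
        np.testing.assert_array_equal(
            np.stack([s.signal_features for s in samples]),
            np.stack([s.signal_features for s in again]),
        )

    def test_class_separation_visible_in_center_rows(self):
        cfg = SyntheticConfig(seed=13)
        samples = generate_training_samples(cfg, 400)
        center_mean = lambda s: s.seq_features[4:9, 1].mean()
        pos = np.mean([center_mean(s) for s in samples if s.label == 1])
        neg = np.mean([center_mean(s) for s in samples if s.label == 0])
        assert pos - neg > 2.0  # configured shift is 3 sigma
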