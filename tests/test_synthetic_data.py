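import collections
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kmerlm.synthetic_data import (
    BackgroundModel, GenerationError, LabeledSequenceSet, PWMotif,
    dinucleotide_counts, dinucleotide_shuffle, generate_background,
    make_motif_discovery_dataset, make_motif_occupancy_dataset,
    make_promoter_dataset, markov_background, one_hot_pwm,
    sample_pwm_instance, split_dataset, tata_box_pwm,
    uniform_background, read_fasta, write_fasta,
)


class TestBackground:
    def test_uniform_frequencies(self):
        seq = generate_background(uniform_background(0), 100_000)
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(0.25,
                                                               abs=0.01)

    def test_degenerate_chain(self):
        m = BackgroundModel(order=1,
                            composition=np.tile([1, 0, 0, 0], (4, 1)),
                            initial=[1, 0, 0, 0], seed=0)
        assert generate_background(m, 50) == "A" * 50

    def test_determinism(self):
        bg = markov_background(np.full((4, 4), 0.25), seed=7)
        assert generate_background(bg, 500) == generate_background(bg, 500)

    def test_validation(self):
        with pytest.raises(ValueError):
            BackgroundModel(order=0, composition=[0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            BackgroundModel(order=2)

    def test_order1_empirical_transition(self):
        t = np.array([[0.7, 0.1, 0.1, 0.1],
                      [0.1, 0.7, 0.1, 0.1],
                      [0.1, 0.1, 0.7, 0.1],
                      [0.1, 0.1, 0.1, 0.7]])
        seq = generate_background(markov_background(t, seed=3), 100_000)
        idx = {b: i for i, b in enumerate("ACGT")}
        counts = np.zeros((4, 4))
        for a, b in zip(seq, seq[1:]):
            counts[idx[a], idx[b]] += 1
        emp = counts / counts.sum(axis=1, keepdims=True)
        assert np.max(np.abs(emp - t)) < 0.02


class TestPWM:
    def test_one_hot_always_consensus(self, rng):
        pwm = one_hot_pwm("T6", "TTTTTT")
        for _ in range(20):
            assert sample_pwm_instance(pwm, rng) == "TTTTTT"

    def test_tata_mode_is_consensus(self, rng):
        pwm = tata_box_pwm()
        draws = collections.Counter(sample_pwm_instance(pwm, rng)
                                    for _ in range(2000))
        assert draws.most_common(1)[0][0] == "TATAAA"

    def test_uniform_pwm_chi_square(self, rng):
        from scipy.stats import chisquare
        pwm = PWMotif("U4", np.full((4, 4), 0.25))
        draws = collections.Counter(sample_pwm_instance(pwm, rng)
                                    for _ in range(25_600))
        counts = [draws.get("".join(p), 0)
                  for p in itertools.product("ACGT", repeat=4)]
        assert chisquare(counts).pvalue > 1e-4

    def test_validation(self):
        with pytest.raises(ValueError):
            PWMotif("bad", np.full((4, 4), 0.3))
        with pytest.raises(ValueError, match=">= 4"):
            PWMotif("short", np.full((4, 3), 0.25))

    def test_log_likelihood(self):
        pwm = PWMotif("U4", np.full((4, 4), 0.25))
        assert pwm.log_likelihood("ACGT") == pytest.approx(4 * np.log(0.25))


class TestDinucleotideShuffle:
    def test_aatt(self, rng):
        out = dinucleotide_shuffle("AATT", rng)
        assert dinucleotide_counts(out) == {"AA": 1, "AT": 1, "TT": 1}
        assert out[0] == "A" and out[-1] == "T"

    def test_acacac(self, rng):
        # brute-force oracle: the only strings with dinucleotide counts
        # {AC:3, CA:2} and endpoints A..C are permutations = "ACACAC"
        valid = {"".join(p) for p in itertools.permutations("ACACAC")
                 if dinucleotide_counts("".join(p)) == {"AC": 3, "CA": 2}
                 and p[0] == "A" and p[-1] == "C"}
        assert valid == {"ACACAC"}
        assert dinucleotide_shuffle("ACACAC", rng) == "ACACAC"

    @settings(max_examples=200, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=2, max_size=80),
           seed=st.integers(0, 2 ** 16))
    def test_counts_preserved_property(self, seq, seed):
        out = dinucleotide_shuffle(seq, np.random.default_rng(seed))
        assert dinucleotide_counts(out) == dinucleotide_counts(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_actually_shuffles(self):
        seq = "ACGTACGTAAGGTTCCACGT" * 3
        outs = {dinucleotide_shuffle(seq, np.random.default_rng(s))
                for s in range(10)}
        assert len(outs) > 1


class TestMotifDiscovery:
    def test_positives_contain_consensus(self):
        pwm = one_hot_pwm("T6", "TTTTTT")
        ds = make_motif_discovery_dataset(pwm, uniform_background(0),
                                          n=200, L=101, seed=0)
        positives = [r for r in ds.records if r.label == 1]
        assert len(positives) == 100
        assert all("TTTTTT" in r.sequence for r in positives)

    def test_negatives_paired_dinucleotide_counts(self):
        pwm = one_hot_pwm("T6", "TTTTTT")
        ds = make_motif_discovery_dataset(pwm, uniform_background(0),
                                          n=60, L=101, seed=1)
        pos = {r.id[3:]: r for r in ds.records if r.label == 1}
        neg = {r.id[3:]: r for r in ds.records if r.label == 0}
        for key in pos:
            assert (dinucleotide_counts(pos[key].sequence)
                    == dinucleotide_counts(neg[key].sequence))

    def test_split_80_10_10(self):
        pwm = one_hot_pwm("T6", "TTTTTT")
        ds = make_motif_discovery_dataset(pwm, uniform_background(0),
                                          n=200, L=101, seed=0)
        sizes = {s: len(ds.subset(s)) for s in ("train", "dev", "test")}
        assert sizes == {"train": 160, "dev": 20, "test": 20}

    def test_L_too_small(self):
        pwm = one_hot_pwm("T6", "TTTTTT")
        with pytest.raises(ValueError):
            make_motif_discovery_dataset(pwm, uniform_background(0),
                                         n=10, L=6)


class TestMotifOccupancy:
    def test_gc_matching_and_centering(self):
        pwm = tata_box_pwm()
        ds = make_motif_occupancy_dataset(pwm, uniform_background(0),
                                          n=100, L=101, seed=0)
        pos = {r.id[3:]: r for r in ds.records if r.label == 1}
        neg = {r.id[3:]: r for r in ds.records if r.label == 0}
        assert len(pos) == len(neg) == 50
        start = (101 - pwm.width) // 2
        for key in pos:
            gc = lambda s: (s.count("G") + s.count("C")) / len(s)
            assert abs(gc(pos[key].sequence)
                       - gc(neg[key].sequence)) <= 0.02 + 1e-12

    def test_centered_consensus_for_onehot(self):
        pwm = one_hot_pwm("T6", "TTTTTT")
        ds = make_motif_occupancy_dataset(pwm, uniform_background(0),
                                          n=40, L=101, seed=2)
        start = (101 - 6) // 2
        for r in ds.records:
            assert r.sequence[start:start + 6] == "TTTTTT"

    def test_matching_failure_raises(self):
        # impossibly tight GC tolerance on an extreme-composition bg
        skew = BackgroundModel(order=0,
                               composition=[0.97, 0.01, 0.01, 0.01])
        pwm = tata_box_pwm()
        with pytest.raises(GenerationError):
            make_motif_occupancy_dataset(pwm, skew, n=4, L=101, seed=0,
                                         gc_tol=0.0, score_tol=0.0,
                                         max_attempts=3)


class TestPromoter:
    def test_tata_variant_motif_everywhere(self):
        pwm = one_hot_pwm("TATA", "TATAAA")
        ds = make_promoter_dataset(pwm, uniform_background(0), n=100,
                                   variant="tata", seed=0)
        assert ds.length == 300
        for r in ds.records:
            assert "TATAAA" in r.sequence
        for r in ds.records:
            if r.label == 1:
                assert r.sequence[219:225] == "TATAAA"

    def test_nontata_segment_substitution(self):
        ds = make_promoter_dataset(tata_box_pwm(), uniform_background(0),
                                   n=40, variant="nontata", seed=1)
        pos = {r.id[3:]: r for r in ds.records if r.label == 1}
        neg = {r.id[3:]: r for r in ds.records if r.label == 0}
        seg = 300 // 20
        for key in pos:
            diff_segments = sum(
                pos[key].sequence[s * seg:(s + 1) * seg]
                != neg[key].sequence[s * seg:(s + 1) * seg]
                for s in range(20))
            assert diff_segments <= 12

    def test_bad_variant(self):
        with pytest.raises(ValueError):
            make_promoter_dataset(tata_box_pwm(), uniform_background(0),
                                  n=10, variant="cpg")


class TestSplitDataset:
    def _ds(self, n):
        recs = [type("R", (), {})() for _ in range(n)]
        from kmerlm.synthetic_data import SequenceRecord
        records = [SequenceRecord(f"r{i}", "ACGT", i % 2)
                   for i in range(n)]
        return LabeledSequenceSet(task="motif_discovery",
                                  records=records, length=4)

    def test_100_records(self):
        out = split_dataset(self._ds(100), (0.8, 0.1, 0.1), seed=0)
        assert [len(out.subset(s)) for s in ("train", "dev", "test")] \
            == [80, 10, 10]

    def test_stratified_balance(self):
        out = split_dataset(self._ds(10), (0.8, 0.1, 0.1), seed=0,
                            stratified=True)
        for split in ("train", "dev", "test"):
            labels = [r.label for r in out.subset(split)]
            if labels:
                assert abs(sum(labels) - len(labels) / 2) <= 0.5

    def test_determinism(self):
        a = split_dataset(self._ds(50), seed=9)
        b = split_dataset(self._ds(50), seed=9)
        assert [r.split for r in a.records] == [r.split for r in b.records]

    def test_bad_ratio(self):
        with pytest.raises(ValueError):
            split_dataset(self._ds(10), (0.5, 0.4, 0.2))


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        ds = make_motif_discovery_dataset(one_hot_pwm("T6", "TTTTTT"),
                                          uniform_background(0),
                                          n=20, L=50, seed=0)
        path = tmp_path / "ds.tsv"
        ds.to_tsv(path)
        loaded = LabeledSequenceSet.from_tsv(path, task=ds.task)
        assert [(r.id, r.sequence, r.label, r.split)
                for r in loaded.records] \
            == [(r.id, r.sequence, r.label, r.split)
                for r in ds.records]

    def test_fasta_roundtrip(self, tmp_path):
        seqs = {"a": "ACGTACGT", "b": "TTTT"}
        path = tmp_path / "x.fasta"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs
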