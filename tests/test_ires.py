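"""Sliding-window splitting, kmer featurization, classifier training
protocol, fragment prediction and IRES-to-ORF assignment."""

import itertools

import numpy as np
import pytest

from circtrans.circseq import CircularSequence
from circtrans.fixtures import make_ires_training_fixture
from circtrans.ires import (
    IresCall,
    IresClassifier,
    KmerFeaturizer,
    TrainParams,
    assign_ires_to_orf,
    kmer_features,
    predict_ires,
    split_windows,
    train_ires_model,
)
from circtrans.orf import find_orfs
from tests.conftest import random_dna


class TestSplitWindows:
    def test_default_consecutive_overlap_is_154(self, rng):
        circ = CircularSequence("c", random_dna(rng, 500))
        frags = split_windows(circ)
        assert all(f.length == 174 for f in frags)
        for a, b in zip(frags, frags[1:]):
            assert b.start - a.start == 20
            assert a.length - (b.start - a.start) == 154

    def test_whole_sequence_when_shorter_than_window(self, rng):
        circ = CircularSequence("c", random_dna(rng, 174))
        (frag,) = split_windows(circ)
        assert frag.length == 174 and not frag.spans_junction

    def test_wrap_fragment_count_and_junction_flags(self, rng):
        circ = CircularSequence("c", random_dna(rng, 500))
        frags = split_windows(circ)
        assert [f.start for f in frags] == list(range(0, 500, 20))
        assert len(frags) == 25
        for f in frags:
            assert f.spans_junction == (f.start + 174 > 500)
            assert f.sequence == circ.subseq(f.start, 174)

    def test_no_wrap_tail_fragment_covers_end(self, rng):
        circ = CircularSequence("c", random_dna(rng, 500))
        frags = split_windows(circ, wrap=False)
        assert not any(f.spans_junction for f in frags)
        assert frags[-1].start + frags[-1].length == 500

    def test_full_circle_coverage_when_window_ge_step(self, rng):
        circ = CircularSequence("c", random_dna(rng, 333))
        covered = set()
        for f in split_windows(circ):
            covered.update((f.start + i) % 333 for i in range(f.length))
        assert covered == set(range(333))

    def test_invalid_geometry_rejected(self, rng):
        circ = CircularSequence("c", random_dna(rng, 50))
        with pytest.raises(ValueError):
            split_windows(circ, window=0)
        with pytest.raises(ValueError):
            split_windows(circ, step=0)


class TestKmerFeatures:
    def test_homopolymer_mononucleotide_frequencies(self):
        vec = kmer_features("AAAA", 1, 1)
        assert vec.as_dict() == {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}

    def test_count_over_length_normalization(self):
        # 3 dimers in a 4-mer, each counted once, divided by length 4
        d = kmer_features("ACGT", 2, 2).as_dict()
        assert d["AC"] == d["CG"] == d["GT"] == 0.25
        assert sum(v > 0 for v in d.values()) == 3

    def test_matches_dictionary_count_oracle(self, rng):
        seq = random_dna(rng, 174)
        vec = kmer_features(seq, 1, 4)
        got = vec.as_dict()
        for k in range(1, 5):
            counts = {}
            for i in range(len(seq) - k + 1):
                counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
            for kmer in map("".join, itertools.product("ACGT", repeat=k)):
                assert got[kmer] == pytest.approx(counts.get(kmer, 0) / 174)

    def test_feature_vector_length_and_denormalization(self, rng):
        seq = random_dna(rng, 80)
        vec = kmer_features(seq, 1, 4)
        assert len(vec.values) == 4 + 16 + 64 + 256
        offset = 0
        for k in range(1, 5):
            counts = vec.values[offset : offset + 4**k] * 80
            assert np.allclose(counts, np.round(counts))
            assert int(round(counts.sum())) == 80 - k + 1
            offset += 4**k

    def test_error_cases(self):
        with pytest.raises(ValueError):
            kmer_features("ACG", 1, 4)  # shorter than k_max
        with pytest.raises(ValueError):
            kmer_features("ACGN", 1, 2)  # non-ACGT


class TestTrainingProtocol:
    def test_training_is_seed_deterministic(self):
        pos, neg = make_ires_training_fixture(30, 30, frag_len=100, seed=4)
        params = TrainParams(n_rounds=30, seed=4)
        _, m1 = train_ires_model(pos, neg, params=params, cv_folds=3, seed=4)
        _, m2 = train_ires_model(pos, neg, params=params, cv_folds=3, seed=4)
        assert m1 == m2

    def test_small_class_rejected_naming_it(self):
        pos, neg = make_ires_training_fixture(5, 30, frag_len=100, seed=0)
        with pytest.raises(ValueError, match="positives"):
            train_ires_model(pos, neg, cv_folds=10)

    def test_metrics_match_contingency_definition(self):
        pos, neg = make_ires_training_fixture(40, 40, frag_len=100, seed=2)
        model, metrics = train_ires_model(
            pos, neg, params=TrainParams(n_rounds=30, seed=2), cv_folds=4,
            seed=2,
        )
        assert 0.0 <= metrics.accuracy <= 1.0
        assert len(metrics.fold_accuracy) == 4
        # accuracy must lie between min and max of sens/spec-weighted rates
        assert 0.0 <= metrics.sensitivity <= 1.0
        assert 0.0 <= metrics.specificity <= 1.0

    def test_model_save_load_roundtrip(self, tmp_path, rng):
        pos, neg = make_ires_training_fixture(30, 30, frag_len=100, seed=1)
        model, _ = train_ires_model(
            pos, neg, params=TrainParams(n_rounds=20, seed=1), cv_folds=3,
            seed=1,
        )
        path = tmp_path / "model.json"
        model.save(path)
        reloaded = IresClassifier.load(path)
        probe = [random_dna(rng, 174) for _ in range(10)]
        assert np.array_equal(
            model.score_sequences(probe), reloaded.score_sequences(probe)
        )

    def test_sklearn_param_interface(self):
        clf = IresClassifier(max_depth=3)
        assert clf.get_params()["max_depth"] == 3
        clf.set_params(eta=0.1)
        assert clf.eta == 0.1


class _ConstantModel:
    """Stub scorer with a fixed probability for every fragment."""

    def __init__(self, score):
        self.score = score
        self.threshold = 0.5

    def score_sequences(self, seqs):
        return np.full(len(seqs), self.score)


class TestPredictAndAssign:
    def test_threshold_filters_all_when_score_below(self, rng):
        circ = CircularSequence("c", random_dna(rng, 400))
        assert predict_ires(circ, _ConstantModel(0.4), threshold=0.5) == []

    def test_zero_threshold_returns_every_fragment(self, rng):
        circ = CircularSequence("c", random_dna(rng, 400))
        calls = predict_ires(circ, _ConstantModel(0.4), threshold=0.0)
        assert len(calls) == len(split_windows(circ))

    def test_shorter_fragment_mode(self, rng):
        circ = CircularSequence("c", random_dna(rng, 400))
        calls = predict_ires(
            circ, _ConstantModel(0.9), window=100, step=10, threshold=0.5
        )
        assert all(c.fragment.length == 100 for c in calls)
        assert [c.fragment.start for c in calls] == list(range(0, 400, 10))

    def test_trained_model_localizes_planted_window(self):
        # plant one positive-composition window in a long random circle and
        # check the calls concentrate there
        pos, neg = make_ires_training_fixture(150, 150, seed=0)
        model, _ = train_ires_model(
            pos, neg, params=TrainParams(n_rounds=200, seed=0), seed=0
        )
        extra_pos, _ = make_ires_training_fixture(1, 0, seed=99)
        rng = np.random.default_rng(5)
        backdrop = "".join(rng.choice(list("ACGT"), size=800))
        planted_at = 300
        seq = backdrop[:planted_at] + extra_pos[0] + backdrop[planted_at + 174 :]
        circ = CircularSequence("c", seq)
        calls = predict_ires(circ, model, threshold=0.0)
        best = max(calls, key=lambda c: c.score)
        # the top-scoring fragment overlaps the planted window
        assert best.fragment.start < planted_at + 174
        assert best.fragment.start + 174 > planted_at
        # and planted-region fragments outscore distant background ones
        overlapping = [
            c.score for c in calls
            if c.fragment.start < planted_at + 174
            and c.fragment.start + 174 > planted_at
        ]
        distant = [
            c.score for c in calls
            if c.fragment.start + 174 < planted_at
            or c.fragment.start > planted_at + 174
        ]
        assert max(overlapping) > np.median(distant)

    def test_no_calls_means_none_for_every_orf(self, rng):
        circ = CircularSequence("c", "ATG" + random_dna(rng, 120) + "TAA")
        orfs = find_orfs(circ, min_nt_length=6)
        assert orfs
        assignment = assign_ires_to_orf(orfs, [], circ.L)
        assert all(v is None for v in assignment.values())

    def test_single_call_assigned_to_all_orfs(self, rng):
        circ = CircularSequence("c", "ATGGGT" + random_dna(rng, 120) + "TAA")
        orfs = find_orfs(circ, min_nt_length=6)
        frags = split_windows(circ)
        call = IresCall(frags[0], 0.9, frags[0].spans_junction)
        assignment = assign_ires_to_orf(orfs, [call], circ.L)
        assert all(v is call for v in assignment.values())

    def test_nearest_upstream_fragment_wins(self):
        # ORF starts at 500 on an L=800 circle; one fragment ends at 470
        # (upstream distance 30), the other at 100 (upstream distance 400)
        from circtrans.ires import Fragment
        from circtrans.orf import OrfCall

        L = 800
        orf = OrfCall(
            orf_id="ORF1", start_pos=500, stop_pos=600, nt_length=103 * 3,
            is_infinite=False, repeat_nt_length=None, laps=0,
            spans_junction=False, inner_starts=(), peptide="M", orbit_id=0,
        )
        near = IresCall(Fragment(297, 174, "A" * 174, False), 0.6, False)
        far = IresCall(Fragment(727, 174, "A" * 174, True), 0.99, True)
        assignment = assign_ires_to_orf([orf], [far, near], L)
        assert assignment["ORF1"] is near
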