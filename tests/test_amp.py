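"""AMP screen: curation, windows, training, scanning, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glandscreen as gs
from glandscreen.amp import Corpus, window_count
from glandscreen.features import AMINO_ACIDS


def naive_identity(a: str, b: str) -> float:
    """Character-by-character oracle for the best-offset ungapped identity."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    ns, nl = len(short), len(long_)
    best = 0
    for off in range(-(ns - 1), nl):
        matches = sum(
            1 for i in range(ns)
            if 0 <= i + off < nl and short[i] == long_[i + off]
        )
        best = max(best, matches)
    return best / ns


class TestIdentity:
    def test_identical_sequences(self):
        assert gs.ungapped_identity("MKVLW", "MKVLW") == 1.0

    def test_contained_subsequence(self):
        # the shorter sequence matches fully inside the longer one
        assert gs.ungapped_identity("KVL", "MKVLW") == 1.0

    def test_shifted_overlap(self):
        assert gs.ungapped_identity("AAK", "KAA") == pytest.approx(2 / 3)

    @given(a=st.text(alphabet="ACDK", min_size=1, max_size=12),
           b=st.text(alphabet="ACDK", min_size=1, max_size=12))
    @settings(max_examples=80, deadline=None)
    def test_matches_naive_oracle(self, a, b):
        assert gs.ungapped_identity(a, b) == pytest.approx(
            naive_identity(a, b))


class TestCuration:
    def test_duplicate_20mers_collapse_to_one(self):
        s = "MKVLWAALLVTFLAGCQAKV"
        corpus = gs.curate_corpus([("a", s, 1), ("b", s, 1),
                                   ("n", "PQRSTVWYA", 0)])
        assert corpus.sequences.count(s) == 1

    def test_length_window_enforced(self):
        corpus = gs.curate_corpus([
            ("short", "MKVL", 1),            # 4-mer: dropped
            ("long", "A" * 101, 1),          # 101-mer: dropped
            ("ok", "MKVLW", 1),
            ("neg", "PQRST", 0),
        ])
        assert set(corpus.ids) == {"ok", "neg"}

    def test_empty_class_is_hard_error(self):
        with pytest.raises(ValueError, match="label 0"):
            gs.curate_corpus([("a", "MKVLW", 1)])

    def test_deterministic_under_input_shuffling(self):
        rng = np.random.default_rng(0)
        triples = [(f"s{i}",
                    "".join(rng.choice(list(AMINO_ACIDS), size=30)),
                    i % 2) for i in range(30)]
        a = gs.curate_corpus(triples)
        shuffled = list(triples)
        np.random.default_rng(1).shuffle(shuffled)
        b = gs.curate_corpus(shuffled)
        assert a.sequences == b.sequences


class TestWindowDigest:
    @pytest.mark.parametrize("length,expected", [
        (7, 0),    # below the minimum window size
        (8, 1),
        (20, 76),  # sum over k=8..15 of 20-k+1
    ])
    def test_window_counts(self, length, expected):
        rec = gs.ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY"[:length]
                               if length <= 20 else "A" * length)
        windows = gs.window_digest([rec])
        assert sum(len(w.occurrences) for w in windows) == expected

    def test_duplicates_collapsed_with_occurrences_recorded(self):
        rec = gs.ProteinRecord("p", "A" * 10)
        windows = gs.window_digest([rec])
        # 8-, 9- and 10-mers of a homopolymer: three distinct sequences
        assert len(windows) == 3
        w8 = next(w for w in windows if w.length == 8)
        assert len(w8.occurrences) == 3  # starts 0, 1, 2

    def test_bad_window_bounds_rejected(self):
        with pytest.raises(ValueError, match="window_min"):
            gs.window_digest([gs.ProteinRecord("p", "A" * 30)], 15, 8)

    @given(lengths=st.lists(st.integers(1, 60), min_size=1, max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_closed_form_count_matches_enumeration(self, lengths):
        rng = np.random.default_rng(0)
        proteome = [
            gs.ProteinRecord(f"p{i}",
                             "".join(rng.choice(list(AMINO_ACIDS), size=L)))
            for i, L in enumerate(lengths)
        ]
        windows = gs.window_digest(proteome)
        pre_dedup = sum(len(w.occurrences) for w in windows)
        assert pre_dedup == window_count(lengths)
        # independent brute-force enumeration
        brute = sum(
            1 for rec in proteome
            for k in range(8, 16)
            for _ in range(max(0, len(rec) - k + 1))
        )
        assert pre_dedup == brute


class TestTraining:
    def test_separable_corpus_learned_accurately(self, trained_classifier):
        assert trained_classifier.cv_accuracy >= 0.95
        assert trained_classifier.auc >= 0.95

    def test_all_four_kernels_reported(self, trained_classifier):
        assert {r.kernel for r in trained_classifier.per_kernel} == \
               {"rbf", "linear", "polynomial", "sigmoid"}

    def test_same_seed_reproduces_choice(self, strong_corpus):
        a = gs.train_classifiers(strong_corpus, seed=3)
        b = gs.train_classifiers(strong_corpus, seed=3)
        assert (a.kernel, a.hyperparameters) == (b.kernel, b.hyperparameters)
        assert a.cv_accuracy == b.cv_accuracy

    def test_single_class_rejected(self):
        corpus = Corpus(sequences=("MKVLWAAL", "PQRSTVWY"),
                        labels=np.array([1, 1]))
        with pytest.raises(ValueError, match="both classes"):
            gs.train_classifiers(corpus)


@pytest.fixture(scope="module")
def windows(strong_spec):
    proteome = gs.simulate_proteome(
        gs.SimulationSpec(n_proteins=10, mean_length=60, sd_length=10,
                          planted_enriched=2, seed=strong_spec.seed))
    return gs.window_digest(proteome)


class TestScan:
    def test_threshold_zero_keeps_all(self, windows, trained_classifier):
        cands = gs.scan_proteome(windows, trained_classifier, threshold=0.0)
        assert len(cands) == len(windows)

    def test_threshold_above_one_keeps_none(self, windows,
                                            trained_classifier):
        assert gs.scan_proteome(windows, trained_classifier,
                                threshold=1.0001) == []

    def test_candidate_count_monotone_in_threshold(self, windows,
                                                   trained_classifier):
        counts = [len(gs.scan_proteome(windows, trained_classifier, t))
                  for t in (0.0, 0.25, 0.5, 0.75, 0.9, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_planted_motifs_recovered(self, strong_spec, trained_classifier):
        proteome = gs.simulate_proteome(
            gs.SimulationSpec(n_proteins=40, mean_length=120, sd_length=30,
                              seed=21))
        planted, loci = gs.plant_amp_motifs(proteome, strong_spec,
                                            n_motifs=10)
        windows = gs.window_digest(planted)
        cands = gs.scan_proteome(windows, trained_classifier, threshold=0.8)
        recovered = 0
        for (pid, lo, hi) in loci:
            for c in cands:
                if any(p == pid and s < hi and lo < s + c.window.length
                       for p, s in c.window.occurrences):
                    recovered += 1
                    break
        assert recovered >= 0.8 * len(loci)


class TestFilterCandidates:
    def test_tryptophan_homopolymer_rejected_as_insoluble(self):
        soluble, _ = gs.amp.assess_peptide("WWWWWWWWWW")
        assert not soluble

    def test_printed_peptide_is_soluble_but_fails_instability(self):
        # KKLYISKGCMSKSLC: cationic and under the hydrophobic-fraction cap,
        # but its instability index (49.0) exceeds the classic 40 threshold
        soluble, stable = gs.amp.assess_peptide("KKLYISKGCMSKSLC")
        assert soluble
        assert not stable

    def test_asp_pro_bond_fails_stability(self):
        _, stable = gs.amp.assess_peptide("KKKDPKKKRR")
        assert not stable

    def test_selection_requires_both_flags(self, trained_classifier):
        windows = gs.window_digest(
            [gs.ProteinRecord("p", "KKWWWWWWWWLLLLAA")])
        cands = gs.scan_proteome(windows, trained_classifier, threshold=0.0)
        flagged = gs.filter_candidates(cands)
        for c in flagged:
            assert c.selected == (c.soluble and c.stable)


class TestModelSerialisation:
    def test_round_trip_reproduces_decisions(self, trained_classifier,
                                             tmp_path):
        path = tmp_path / "model.json"
        gs.save_model(trained_classifier, path)
        loaded = gs.load_model(path)
        seqs = ["KKLYISKGCMSKSLC", "AAAAGGGGSSSS", "RRRKKKWWIRRK",
                "LLLLLPPPPGGGG"]
        from glandscreen.features import feature_matrix
        X = feature_matrix(seqs, lam=trained_classifier.lam,
                           weight=trained_classifier.weight)
        assert np.allclose(trained_classifier.decision_values(X),
                           loaded.decision_values(X), atol=1e-12)
        assert np.allclose(trained_classifier.probabilities(X),
                           loaded.probabilities(X), atol=1e-12)

    def test_unrecognised_file_rejected(self, tmp_path):
        path = tmp_path / "bogus.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="not a recognised"):
            gs.load_model(path)
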