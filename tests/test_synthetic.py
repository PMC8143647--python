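"""Generator contracts: determinism, planted structure, closed forms."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import glandscreen as gs


class TestProteome:
    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        spec = gs.SimulationSpec(n_proteins=10, planted_enriched=2, seed=1)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        gs.write_fasta(gs.simulate_proteome(spec), p1)
        gs.write_fasta(gs.simulate_proteome(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_proteins_rejected(self):
        with pytest.raises(ValueError, match="n_proteins"):
            gs.SimulationSpec(n_proteins=0)

    def test_mean_length_close_to_target(self):
        spec = gs.SimulationSpec(n_proteins=1000, mean_length=350.0,
                                 sd_length=150.0, seed=2)
        lengths = np.array([len(r) for r in gs.simulate_proteome(spec)])
        se = 150.0 / np.sqrt(1000)
        # truncation at 30 residues shifts the mean up slightly; 3 standard
        # errors of the untruncated target still covers it
        assert abs(lengths.mean() - 350.0) < 3 * se + 7
        assert lengths.min() >= 30


class TestIntensityMatrix:
    def test_zero_missing_rate_gives_complete_matrix(self):
        spec = gs.SimulationSpec(n_proteins=50, mean_length=40, sd_length=5,
                                 planted_enriched=5, missing_rate=0.0, seed=3)
        m, _ = gs.simulate_intensity_matrix(spec, gs.simulate_proteome(spec))
        assert not m.data.isna().any().any()

    def test_overall_missing_rate_calibrated(self):
        spec = gs.SimulationSpec(n_proteins=400, mean_length=40, sd_length=5,
                                 planted_enriched=20, missing_rate=0.2, seed=4)
        m, _ = gs.simulate_intensity_matrix(spec, gs.simulate_proteome(spec))
        assert m.data.isna().mean().mean() == pytest.approx(0.2, abs=0.03)

    def test_too_many_planted_rejected(self):
        spec = gs.SimulationSpec(n_proteins=5, mean_length=40, sd_length=5,
                                 planted_enriched=10, seed=5)
        proteome = gs.simulate_proteome(spec)
        with pytest.raises(ValueError, match="planted_enriched"):
            gs.simulate_intensity_matrix(spec, proteome)

    def test_planted_fg_zscores_dominate_background(self):
        spec = gs.SimulationSpec(n_proteins=500, mean_length=40, sd_length=5,
                                 planted_enriched=40, enrichment_fold=100,
                                 missing_rate=0.1, seed=7)
        m, truth = gs.simulate_intensity_matrix(spec,
                                                gs.simulate_proteome(spec))
        logv = np.log10(m.data)
        z = logv.sub(logv.mean(axis=1), axis=0).div(logv.std(axis=1, ddof=0),
                                                    axis=0)
        fg_z = z[m.samples_with_role("FG")].mean(axis=1)
        background_median = fg_z[~fg_z.index.isin(truth)].median()
        planted = fg_z[fg_z.index.isin(truth)]
        assert (planted > background_median).mean() >= 0.95


class TestAmpCorpus:
    def test_positive_charge_exceeds_negative(self):
        spec = gs.SimulationSpec(n_amp=150, n_background=150, seed=8)
        corpus = gs.simulate_amp_corpus(spec)
        pos = [gs.net_charge(s) for _, s, y in corpus if y == 1]
        neg = [gs.net_charge(s) for _, s, y in corpus if y == 0]
        assert np.mean(pos) > np.mean(neg)

    def test_zero_bias_classes_indistinguishable(self):
        spec = gs.SimulationSpec(n_amp=200, n_background=200,
                                 amp_charge_bias=0.0,
                                 amp_hydropathy_bias=0.0, seed=9)
        corpus = gs.simulate_amp_corpus(spec)
        pos = [gs.net_charge(s) / len(s) for _, s, y in corpus if y == 1]
        neg = [gs.net_charge(s) / len(s) for _, s, y in corpus if y == 0]
        assert ks_2samp(pos, neg).pvalue > 0.01

    def test_lengths_within_5_to_100(self):
        spec = gs.SimulationSpec(n_amp=100, n_background=100, seed=10)
        assert all(5 <= len(s) <= 100
                   for _, s, _ in gs.simulate_amp_corpus(spec))


class TestHitTable:
    def test_fraction_one_annotates_every_protein(self):
        spec = gs.SimulationSpec(n_proteins=60, mean_length=40, sd_length=5,
                                 seed=11)
        proteome = gs.simulate_proteome(spec)
        hits, truth = gs.simulate_hit_table(proteome, spec, fraction=1.0)
        results = gs.annotate_all(hits, query_ids=[p.id for p in proteome])
        assert all(r.transferred_annotation is not None for r in results)
        # the transferred labels match the planted orthology
        assert all(r.transferred_annotation == truth[r.query_id]
                   for r in results)

    def test_fraction_zero_annotates_nothing(self):
        spec = gs.SimulationSpec(n_proteins=60, mean_length=40, sd_length=5,
                                 seed=12)
        proteome = gs.simulate_proteome(spec)
        hits, _ = gs.simulate_hit_table(proteome, spec, fraction=0.0)
        results = gs.annotate_all(hits, query_ids=[p.id for p in proteome])
        assert gs.annotation_summary(results).annotated == 0

    def test_efficiency_matches_requested_fraction(self):
        spec = gs.SimulationSpec(n_proteins=400, mean_length=40, sd_length=5,
                                 seed=13)
        proteome = gs.simulate_proteome(spec)
        hits, _ = gs.simulate_hit_table(proteome, spec, fraction=0.965)
        results = gs.annotate_all(hits, query_ids=[p.id for p in proteome])
        s = gs.annotation_summary(results)
        assert s.annotated == round(0.965 * 400)


class TestPlate:
    def test_saturating_dose_reaches_full_inhibition(self):
        spec = gs.SimulationSpec(dose_ec50=1.0, dose_hill=2.0,
                                 od_noise_sd=0.0, seed=14)
        plate = gs.simulate_plate(spec, [1e9], emax=1.0)
        curve = gs.analyze_plate(plate)
        assert curve.inhibition_percent[0] == pytest.approx(100.0)

    def test_ec50_dose_gives_half_inhibition(self):
        spec = gs.SimulationSpec(dose_ec50=125.0, dose_hill=2.0,
                                 od_noise_sd=0.0, seed=15)
        plate = gs.simulate_plate(spec, [125.0], emax=1.0)
        assert gs.analyze_plate(plate).inhibition_percent[0] == \
            pytest.approx(50.0)

    def test_partial_emax_plateaus_at_emax(self):
        spec = gs.SimulationSpec(dose_ec50=1.0, dose_hill=2.0,
                                 od_noise_sd=0.0, seed=16)
        plate = gs.simulate_plate(spec, [1e9, 1e8, 1e7], emax=0.75)
        assert gs.analyze_plate(plate).max_inhibition == pytest.approx(75.0)

    def test_duplicates_generated_independently(self):
        spec = gs.SimulationSpec(od_noise_sd=0.05, seed=17)
        plate = gs.simulate_plate(spec, [100.0, 50.0], replicates=2)
        assert plate.od_test[0][0] != plate.od_test[0][1]


def test_planted_truth_not_embedded_in_files(tmp_path):
    spec = gs.SimulationSpec(n_proteins=30, mean_length=40, sd_length=5,
                             planted_enriched=3, seed=18)
    proteome = gs.simulate_proteome(spec)
    matrix, truth = gs.simulate_intensity_matrix(spec, proteome)
    path = tmp_path / "m.tsv"
    gs.write_intensity_matrix(matrix, path)
    text = path.read_text()
    header = text.splitlines()[0]
    assert "planted" not in text.lower()
    assert "truth" not in header.lower()


def test_generators_are_pure_functions_of_seed():
    spec = gs.SimulationSpec(n_proteins=25, mean_length=40, sd_length=5,
                             planted_enriched=3, seed=19)
    p1 = gs.simulate_proteome(spec)
    m1, t1 = gs.simulate_intensity_matrix(spec, p1)
    h1, o1 = gs.simulate_hit_table(p1, spec)
    p2 = gs.simulate_proteome(spec)
    m2, t2 = gs.simulate_intensity_matrix(spec, p2)
    h2, o2 = gs.simulate_hit_table(p2, spec)
    assert [r.sequence for r in p1] == [r.sequence for r in p2]
    assert m1.data.equals(m2.data) and t1 == t2
    assert h1 == h2 and o1 == o2
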