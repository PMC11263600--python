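"""Partitioned fragmentation learning: reliability, direction, intensity."""

import itertools
import math

import numpy as np
import pytest

from glycosearch.chem import residue_mass
from glycosearch.fragmodel import (
    CHARGE_TOP,
    FragmentationModel,
    FragmentRecord,
    IntensityModel,
    LEN_EDGES,
    MOBILITY_ORDER,
    PartitionKey,
    ReliabilityModel,
    TrainingRecord,
    backbone_feature_dim,
    backbone_fragment_features,
    extract_pair_features,
    fit_intensity,
    fit_reliability,
    ladder_direction,
    partition_key,
    predict_intensity,
    predict_reliability,
    records_from_annotated,
    y_fragment_features,
)
from glycosearch.glycans import GlycanComposition
from glycosearch.simulate import (
    SimulationConfig,
    default_theta_backbone,
    simulate_spectra,
)
from glycosearch.peptides import Peptide, digest
from glycosearch.simulate import example_glycans, example_proteins


class TestPartitionKey:
    def test_bin_lookup_example(self):
        key = partition_key(12, 10, 3, "mobile")
        assert (key.peptide_len_bin, key.glycan_size_bin, key.charge_bin) == (2, 2, 3)
        assert key.mobility == "mobile"

    def test_grid_cardinality_is_150(self):
        keys = {
            partition_key(length, size, z, mob)
            for length in (5, 12, 18, 25, 40)
            for size in (5, 15)
            for z in (1, 2, 3, 4, 7)
            for mob in MOBILITY_ORDER
        }
        assert len(keys) == 150

    def test_top_charge_bin_clamp(self):
        assert partition_key(10, 5, 7, "mobile").charge_bin == 5

    def test_manhattan_distance(self):
        a = partition_key(12, 10, 3, "mobile")
        b = partition_key(12, 5, 4, "immobile")
        assert a.manhattan(b) == 1 + 1 + 2


class TestPairFeatures:
    def test_hexnac_offset_fires_on_both_peaks(self):
        m = residue_mass("HexNAc")
        masses = np.array([500.0, 500.0 + m])
        f1 = extract_pair_features(masses, 500.0, "b", peptide_mass=0.0)
        f2 = extract_pair_features(masses, 500.0 + m, "b", peptide_mass=0.0)
        assert "offset:HexNAc" in f1 and "offset:HexNAc" in f2

    def test_singleton_spectrum_empty(self):
        assert extract_pair_features(np.array([500.0]), 500.0, "b", 1000.0) == frozenset()

    def test_partner_outside_tolerance_absent(self):
        m = residue_mass("HexNAc")
        tol = 20e-6
        masses = np.array([500.0, 500.0 + m + 3 * tol * (500.0 + m)])
        feats = extract_pair_features(masses, 500.0, "b", 0.0, tol=tol)
        assert "offset:HexNAc" not in feats

    def test_complement_feature(self):
        pep_mass = 1500.0
        masses = np.array([600.0, 900.0])
        feats = extract_pair_features(masses, 600.0, "y", pep_mass)
        assert "complement" in feats

    def test_y_series_monosaccharide_offsets(self):
        m = residue_mass("Hex")
        masses = np.array([2000.0, 2000.0 + m])
        feats = extract_pair_features(masses, 2000.0, "Y", 0.0)
        assert "offset:Hex" in feats
        assert "offset:dHex" not in feats


class TestReliability:
    def test_posterior_closed_forms(self):
        model = ReliabilityModel(likelihood_ratios={"a": 5.0, "b": 0.2}, prior=0.5)
        assert predict_reliability(model, {"a"}) == pytest.approx(5 / 6, abs=1e-4)
        assert predict_reliability(model, set()) == pytest.approx(0.5)
        assert predict_reliability(model, {"a", "b"}) == pytest.approx(0.5)

    def test_discriminative_feature_gets_lr_above_one(self):
        recs = [
            TrainingRecord(
                peptide="ANDTK",
                glycan=GlycanComposition.from_dict({"Hex": 5, "HexNAc": 2}),
                charge=2,
                fragments=[
                    FragmentRecord(series="b", index=1, intensity=10.0,
                                   features=frozenset({"complement"}))
                ],
                unannotated_features=[frozenset(), frozenset()],
            )
            for _ in range(10)
        ]
        model = fit_reliability(recs)
        assert model.likelihood_ratios["complement"] > 1.0

    def test_reliability_separates_true_from_noise_peaks(self):
        """On simulated spectra, φ ranks annotated fragment peaks above noise
        peaks (AUROC > 0.8)."""
        config = SimulationConfig(seed=11, noise_sigma=0.2, n_noise_peaks=40.0)
        pairs = _example_pairs(120)
        spectra, _ = simulate_spectra(pairs, config)
        records = records_from_annotated(spectra)
        model = fit_reliability(records)
        pos_scores, neg_scores = [], []
        for rec in records:
            pos_scores.extend(model.predict(f.features) for f in rec.fragments)
            neg_scores.extend(model.predict(fs) for fs in rec.unannotated_features)
        pos = np.array(pos_scores)
        neg = np.array(neg_scores)
        # AUROC by rank statistic
        from scipy.stats import mannwhitneyu

        auroc = mannwhitneyu(pos, neg).statistic / (pos.size * neg.size)
        assert auroc > 0.8


class TestLadderDirection:
    def _frags(self, intensities):
        return [
            FragmentRecord(series="Y", glycan_size=i, intensity=v)
            for i, v in enumerate(intensities)
        ]

    def test_monotone_increasing(self):
        assert ladder_direction(self._frags([1, 2, 3, 4])) == "ascending"

    def test_monotone_decreasing(self):
        assert ladder_direction(self._frags([4, 3, 2, 1])) == "descending"

    def test_flat_ties_default_descending(self):
        assert ladder_direction(self._frags([2, 2, 2, 2])) == "descending"

    def test_too_few_matches_default(self):
        assert ladder_direction(self._frags([5.0])) == "descending"


def _example_pairs(n, seed=3):
    db_proteins = example_proteins(seed=seed)
    glycans = example_glycans()
    peptides = [
        p
        for name, seq in db_proteins
        for p in digest(seq, max_missed=1)
        if 6 <= len(p.sequence) <= 25
    ]
    rng = np.random.default_rng(seed)
    return [
        (peptides[int(rng.integers(len(peptides)))], glycans[int(rng.integers(len(glycans)))])
        for _ in range(n)
    ]


class TestIntensityModel:
    def test_predictions_sum_to_one(self):
        config = SimulationConfig(seed=5)
        spectra, _ = simulate_spectra(_example_pairs(30), config)
        records = records_from_annotated(spectra)
        model = fit_intensity(records, "backbone")
        for rec in records[:10]:
            frags, pred = predict_intensity(model, rec)
            if frags:
                assert pred.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_theta_is_uniform(self):
        model = IntensityModel(theta=np.zeros(backbone_feature_dim()), series_group="backbone")
        rec = records_from_annotated(
            simulate_spectra(_example_pairs(1), SimulationConfig(seed=2))[0]
        )[0]
        frags, pred = predict_intensity(model, rec)
        assert np.allclose(pred, 1.0 / len(frags))

    def test_objective_non_decreasing(self):
        config = SimulationConfig(seed=8, noise_sigma=0.3)
        spectra, _ = simulate_spectra(_example_pairs(40), config)
        records = records_from_annotated(spectra)
        model = fit_intensity(records, "backbone")
        trace = np.array(model.loglik_trace)
        assert trace.size >= 2
        assert np.all(np.diff(trace) >= -1e-9)

    def test_parameter_recovery_small(self):
        """Fitting spectra simulated from a known θ recovers a θ that
        correlates strongly with the truth (small-n smoke; the full-size
        recovery check lives in the acceptance suite)."""
        theta_true = default_theta_backbone()
        config = SimulationConfig(seed=21, noise_sigma=0.15, n_noise_peaks=5.0)
        spectra, _ = simulate_spectra(_example_pairs(150, seed=4), config,
                                      theta_backbone=theta_true)
        records = records_from_annotated(spectra)
        model = fit_intensity(records, "backbone", use_reliability_weights=False)
        mask = theta_true != 0
        r = np.corrcoef(model.theta, theta_true)[0, 1]
        assert r > 0.8

    def test_degenerate_single_fragment_spectra_fall_back(self):
        recs = [
            TrainingRecord(
                peptide="ANDTK",
                glycan=GlycanComposition.from_dict({"Hex": 5, "HexNAc": 2}),
                charge=2,
                fragments=[FragmentRecord(series="b", index=1, intensity=5.0)],
            )
            for _ in range(5)
        ]
        model = fit_intensity(recs, "backbone")
        assert np.allclose(model.theta, 0.0)


class TestFragmentationModelAssembly:
    def test_fit_resolve_and_roundtrip(self, tmp_path):
        config = SimulationConfig(seed=13)
        spectra, _ = simulate_spectra(_example_pairs(60), config)
        records = records_from_annotated(spectra)
        model = FragmentationModel.fit(records)
        assert model.partitions
        # every conceivable key resolves somewhere
        for length, size, z, mob in itertools.product((5, 18, 40), (5, 15), (1, 3, 7),
                                                      MOBILITY_ORDER):
            pm = model.resolve(partition_key(length, size, z, mob))
            assert pm is not None
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = FragmentationModel.from_json(path)
        assert set(loaded.partitions) == set(model.partitions)
        k = next(iter(model.partitions))
        assert np.allclose(loaded.partitions[k].backbone.theta,
                           model.partitions[k].backbone.theta)
        assert loaded.partitions[k].reliability.prior == pytest.approx(
            model.partitions[k].reliability.prior
        )
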