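"""Closed-form score layers and their reduction identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycosearch.scoring import (
    GPSM,
    MatchedFragment,
    ScoringParams,
    apply_smoothing,
    cor_terms,
    mass_accuracy_bias,
    peptide_coverage_gate,
    score_glycan_base,
    score_glycan_model,
    score_peptide_base,
    score_peptide_model,
    score_total_base,
    score_total_model,
    sigfrag,
    signature_ion_term,
)

PARAMS = ScoringParams()


def frag(intensity, ppm=0.0, series="b", phi=0.0, size=0, pred=0.0, index=1):
    return MatchedFragment(
        target_mass=500.0, intensity=intensity, ppm=ppm, series=series,
        reliability=phi, glycan_size=size, predicted=pred, index=index,
    )


def random_gpsm(rng, n_p=None, n_g=None):
    n_p = n_p if n_p is not None else int(rng.integers(1, 12))
    n_g = n_g if n_g is not None else int(rng.integers(1, 8))
    gpsm = GPSM(
        matched_P=[
            frag(float(rng.uniform(10, 1e5)), float(rng.uniform(-15e-6, 15e-6)),
                 series=rng.choice(["b", "y"]), index=i + 1)
            for i in range(n_p)
        ],
        matched_G=[
            frag(float(rng.uniform(10, 1e5)), float(rng.uniform(-15e-6, 15e-6)),
                 series="Y", size=int(rng.integers(0, 6)))
            for i in range(n_g)
        ],
        coverage_P=float(rng.uniform(0.1, 1.0)),
        coverage_G=float(rng.uniform(0.1, 1.0)),
        coverage_G_core=float(rng.uniform(0.1, 1.0)),
        ppm_pre=float(rng.uniform(-4e-6, 4e-6)),
    )
    return gpsm


class TestPeptideBase:
    def test_no_matches_is_zero(self):
        assert score_peptide_base(GPSM(coverage_P=0.5), PARAMS) == 0.0

    def test_two_peak_example(self):
        gpsm = GPSM(matched_P=[frag(1000.0), frag(1000.0)], coverage_P=0.5)
        assert score_peptide_base(gpsm, PARAMS) == pytest.approx(3.0, abs=1e-9)

    def test_peak_at_tolerance_contributes_nothing(self):
        gpsm = GPSM(matched_P=[frag(1000.0, ppm=PARAMS.tol)], coverage_P=1.0)
        assert score_peptide_base(gpsm, PARAMS) == pytest.approx(0.0, abs=1e-12)


class TestGlycanBase:
    def test_zero_coverage_zero_score(self):
        gpsm = GPSM(matched_G=[frag(100.0, series="Y")], coverage_G=0.0, coverage_G_core=1.0)
        assert score_glycan_base(gpsm, PARAMS) == 0.0

    def test_five_match_example(self):
        gpsm = GPSM(
            matched_G=[frag(100.0, series="Y") for _ in range(5)],
            coverage_G=5 / 7, coverage_G_core=1.0,
        )
        assert score_glycan_base(gpsm, PARAMS) == pytest.approx(10 * (5 / 7) ** 0.5, abs=1e-3)

    def test_doubling_intensities_adds_log2_per_match(self):
        rng = np.random.default_rng(0)
        gpsm = random_gpsm(rng)
        s1 = score_glycan_base(gpsm, PARAMS)
        doubled = GPSM(
            matched_G=[frag(m.intensity * 2, m.ppm, "Y", size=m.glycan_size)
                       for m in gpsm.matched_G],
            coverage_G=gpsm.coverage_G, coverage_G_core=gpsm.coverage_G_core,
        )
        base_only = GPSM(
            matched_G=gpsm.matched_G, coverage_G=gpsm.coverage_G,
            coverage_G_core=gpsm.coverage_G_core,
        )
        s0 = score_glycan_base(base_only, PARAMS)
        expected_delta = sum(
            math.log10(2) * (1 - abs(m.ppm / PARAMS.tol) ** 4) for m in gpsm.matched_G
        ) * gpsm.coverage_G**0.5 * gpsm.coverage_G_core**0.4
        assert score_glycan_base(doubled, PARAMS) - s0 == pytest.approx(expected_delta, rel=1e-9)


class TestMassAccuracyBias:
    def test_far_off_peak_tends_to_zero(self):
        assert mass_accuracy_bias(1e-3) == pytest.approx(0.0, abs=1e-6)

    def test_at_one_sigma(self):
        val = mass_accuracy_bias(5e-6, 0.0, 5e-6)
        assert val == pytest.approx(-10 * math.log10(1 - math.exp(-0.5)), abs=1e-3)

    def test_perfect_match_capped(self):
        assert mass_accuracy_bias(0.0) == pytest.approx(30.0)


class TestSignatureIons:
    def test_unexpected_oxonium_penalty(self):
        gpsm = GPSM(sialic_counts={"NeuAc": 0}, oxonium_rel={"NeuAc": 0.5})
        assert signature_ion_term(gpsm) == pytest.approx(10 * math.log10(0.5), abs=1e-4)

    def test_missing_expected_oxonium(self):
        gpsm = GPSM(sialic_counts={"NeuAc": 1}, oxonium_rel={"NeuAc": 0.0})
        assert signature_ion_term(gpsm) == pytest.approx(10 * math.log10(0.5), abs=1e-4)

    def test_two_expected_missing_hits_floor(self):
        gpsm = GPSM(sialic_counts={"NeuAc": 2}, oxonium_rel={"NeuAc": 0.0})
        assert signature_ion_term(gpsm) == pytest.approx(-20.0, abs=1e-6)

    def test_observed_and_expected_no_penalty(self):
        gpsm = GPSM(sialic_counts={"NeuAc": 1}, oxonium_rel={"NeuAc": 0.3})
        assert signature_ion_term(gpsm) == 0.0


class TestTotalBase:
    def test_linear_mixture(self):
        rng = np.random.default_rng(3)
        gpsm = random_gpsm(rng)
        gpsm.ppm_pre = 0.0
        sp = score_peptide_base(gpsm, PARAMS)
        sg = score_glycan_base(gpsm, PARAMS)
        total = score_total_base(gpsm, PARAMS)
        assert total == pytest.approx(
            0.65 * sp + 0.35 * sg + signature_ion_term(gpsm) + 30.0, abs=1e-9
        )

    def test_bias_separability(self):
        rng = np.random.default_rng(4)
        gpsm = random_gpsm(rng)
        gpsm.ppm_pre = 0.0
        t0 = score_total_base(gpsm, PARAMS)
        gpsm.ppm_pre = 5e-6
        t1 = score_total_base(gpsm, PARAMS)
        expected = mass_accuracy_bias(5e-6) - mass_accuracy_bias(0.0)
        assert t1 - t0 == pytest.approx(expected, abs=1e-9)


class TestCorTerms:
    def test_perfect_correlation_example(self):
        gpsm = GPSM(
            matched_P=[frag(float(i + 1) * 10, pred=float(i + 1), index=i + 1)
                       for i in range(10)],
            coverage_P=1.0,
        )
        cor_p, cor_p_prime, _, _ = cor_terms(gpsm)
        assert cor_p == pytest.approx(2.0, abs=1e-9)  # (1+1)*log10(10)
        assert cor_p_prime == pytest.approx(20.0, abs=1e-9)

    def test_anticorrelation_endpoint(self):
        gpsm = GPSM(
            matched_P=[frag(float(10 - i), pred=float(i), index=i + 1) for i in range(5)],
            matched_G=[frag(float(10 - i), series="Y", pred=float(i), size=i)
                       for i in range(5)],
            coverage_P=1.0,
        )
        cor_p, _, cor_g, _ = cor_terms(gpsm)
        assert cor_p == pytest.approx(0.0, abs=1e-9)
        assert cor_g == pytest.approx(0.0, abs=1e-9)

    def test_rel_g_floor_and_pad(self):
        # two Y matches with φ = 1 and ρ_G = -0.5 -> Rel_G = 2 * 0.25 = 0.5
        gpsm = GPSM(
            matched_P=[frag(1.0, index=1), frag(2.0, index=2), frag(3.0, index=3)],
            matched_G=[
                frag(10.0, series="Y", phi=1.0, pred=3.0, size=1),
                frag(20.0, series="Y", phi=1.0, pred=2.9, size=2),
                frag(15.0, series="Y", phi=1.0, pred=1.0, size=3),
            ],
            coverage_P=1.0,
        )
        _, _, _, rel_g = cor_terms(gpsm)
        phis = [1.0, 1.0, 1.0]
        from glycosearch.scoring import shifted_pearson

        rho = shifted_pearson([10, 20, 15], [3.0, 2.9, 1.0])
        expected = sum(0.5 * p + 0.5 for p in phis) * max(rho, 0.25)
        assert rel_g == pytest.approx(expected, abs=1e-9)

    def test_no_peptide_matches_all_zero(self):
        gpsm = GPSM(matched_G=[frag(5.0, series="Y", size=2)])
        assert cor_terms(gpsm) == (0.0, 0.0, 0.0, 0.0)


class TestModelScores:
    def test_single_peak_example(self):
        gpsm = GPSM(matched_P=[frag(1000.0, phi=1.0, index=1)], coverage_P=1.0)
        # 3*2 + 1, Cor_P = 0 for a single match (degenerate correlation)
        assert score_peptide_model(gpsm, PARAMS) == pytest.approx(7.0, abs=1e-9)

    def test_gate_function_values(self):
        assert peptide_coverage_gate(1 / 3) == pytest.approx(1.0, abs=1e-12)
        assert peptide_coverage_gate(0.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_sigfrag_counts_sizes_above_one(self):
        gpsm = GPSM(
            matched_G=[frag(1.0, series="Y", size=s) for s in (0, 1, 2, 5)]
        )
        assert sigfrag(gpsm) == 2

    def test_phi_increase_never_decreases_peptide_score(self):
        rng = np.random.default_rng(5)
        gpsm = random_gpsm(rng)
        s0 = score_peptide_model(gpsm, PARAMS)
        boosted = GPSM(
            matched_P=[
                MatchedFragment(m.target_mass, m.intensity, m.ppm, m.series, 1.0,
                                m.glycan_size, m.index, m.predicted)
                for m in gpsm.matched_P
            ],
            matched_G=gpsm.matched_G,
            coverage_P=gpsm.coverage_P, coverage_G=gpsm.coverage_G,
            coverage_G_core=gpsm.coverage_G_core,
        )
        assert score_peptide_model(boosted, PARAMS) >= s0 - 1e-12


class TestReductionIdentities:
    """The enhanced scores reduce exactly to the base scores when the model
    terms vanish, and smoothing with u_g = 0 is the identity."""

    @pytest.mark.parametrize("seed", range(10))
    def test_model_peptide_reduces_to_base(self, seed):
        rng = np.random.default_rng(seed)
        gpsm = random_gpsm(rng, n_p=2)  # < 3 matches: correlation pinned to 0
        for m in gpsm.matched_P:
            assert m.reliability == 0.0
        base = score_peptide_base(gpsm, PARAMS)
        model = score_peptide_model(gpsm, PARAMS)
        # with φ=0: inner sums equal; Cor_P = (0+1)*log10(m_p) remains
        expected = base + math.log10(gpsm.m_p) * gpsm.coverage_P
        assert model == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_model_glycan_reduces_to_base_when_sigfrag_zero(self, seed):
        rng = np.random.default_rng(100 + seed)
        gpsm = random_gpsm(rng)
        gpsm.matched_G = [
            MatchedFragment(m.target_mass, m.intensity, m.ppm, "Y", 0.0, 0, m.index, 0.0)
            for m in gpsm.matched_G
        ]
        assert sigfrag(gpsm) == 0
        assert score_glycan_model(gpsm, PARAMS) == pytest.approx(
            score_glycan_base(gpsm, PARAMS), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_smoothing_with_zero_u_is_identity(self, seed):
        rng = np.random.default_rng(200 + seed)
        gpsm = random_gpsm(rng)
        assert apply_smoothing(gpsm, PARAMS, 0.0) == pytest.approx(
            score_glycan_base(gpsm, PARAMS), abs=1e-12
        )
        assert apply_smoothing(gpsm, PARAMS, 0.0, model_enhanced=True) == pytest.approx(
            score_glycan_model(gpsm, PARAMS), abs=1e-12
        )

    def test_smoothing_gated_by_coverage(self):
        gpsm = GPSM(matched_G=[], coverage_G=0.0, coverage_G_core=0.0)
        assert apply_smoothing(gpsm, PARAMS, u_g=100.0) == 0.0

    def test_smoothing_arithmetic_example(self):
        # inner 10, u_g 2, coverage factor 0.8 -> 9.6 vs 8.0
        gpsm = GPSM(
            matched_G=[frag(10.0**10, series="Y", size=0)],
            coverage_G=0.64, coverage_G_core=1.0,
        )
        p = ScoringParams(alpha=0.5, beta=0.4)
        assert score_glycan_base(gpsm, p) == pytest.approx(8.0, abs=1e-9)
        assert apply_smoothing(gpsm, p, u_g=2.0) == pytest.approx(9.6, abs=1e-9)

    @pytest.mark.parametrize("w", [0.0, 1.0])
    def test_mixture_endpoints(self, w):
        rng = np.random.default_rng(9)
        gpsm = random_gpsm(rng)
        params = ScoringParams(w=w)
        biases = signature_ion_term(gpsm) + mass_accuracy_bias(gpsm.ppm_pre)
        total = score_total_base(gpsm, params)
        if w == 1.0:
            assert total == pytest.approx(score_peptide_base(gpsm, params) + biases, abs=1e-9)
        else:
            assert total == pytest.approx(score_glycan_base(gpsm, params) + biases, abs=1e-9)
        total_m = score_total_model(gpsm, params)
        if w == 1.0:
            assert total_m == pytest.approx(score_peptide_model(gpsm, params) + biases, abs=1e-9)
        else:
            assert total_m == pytest.approx(score_glycan_model(gpsm, params) + biases, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_scores_finite(self, seed):
        rng = np.random.default_rng(seed)
        gpsm = random_gpsm(rng)
        for fn in (score_total_base, score_total_model):
            assert math.isfinite(fn(gpsm, PARAMS))
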