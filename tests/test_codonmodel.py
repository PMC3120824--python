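import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomscan._codons import SENSE_CODONS
from venomscan.codonmodel import (
    BranchSiteParams,
    CodonFrequencies,
    RateOperator,
    build_rate_matrix,
    class_operators,
    estimate_f3x4,
    expected_rate,
    transition_probabilities,
)
from venomscan.seqio import CodonAlignment

from _oracles import SENSE, classify_pair, series_expm


class TestF3x4:
    def test_uniform_composition_gives_1_over_61(self):
        # one codon per taxon, each nucleotide once per position, no stops
        aln = CodonAlignment(
            ("t1", "t2", "t3", "t4"), ("AAA", "CCC", "GGG", "TTT")
        )
        freqs = estimate_f3x4(aln)
        np.testing.assert_allclose(freqs.pi, np.full(61, 1 / 61), atol=1e-12)

    def test_absent_nucleotide_zeroes_codons(self):
        # no G at the third codon position anywhere
        aln = CodonAlignment(("t1", "t2"), ("GCAGCC", "GCTGCA"))
        freqs = estimate_f3x4(aln)
        for codon in SENSE_CODONS:
            if codon[2] == "G":
                assert freqs.of(codon) == 0.0

    def test_hand_computed_products(self):
        # two taxa, three codons: ATG CCA TTT / ATG CCG TTC
        aln = CodonAlignment(("a", "b"), ("ATGCCATTT", "ATGCCGTTC"))
        # position-specific counts (both taxa pooled):
        f1 = {"A": 2 / 6, "C": 2 / 6, "G": 0.0, "T": 2 / 6}
        f2 = {"A": 0.0, "C": 2 / 6, "G": 0.0, "T": 4 / 6}
        f3 = {"A": 1 / 6, "C": 1 / 6, "G": 3 / 6, "T": 1 / 6}
        raw = {c: f1[c[0]] * f2[c[1]] * f3[c[2]] for c in SENSE}
        norm = sum(raw.values())
        freqs = estimate_f3x4(aln)
        for codon in ("ATG", "CCA", "TTC", "TTT", "CTG"):
            assert freqs.of(codon) == pytest.approx(raw[codon] / norm, abs=1e-12)

    def test_all_missing_position_errors(self):
        aln = CodonAlignment(("a",), ("NNN",))
        with pytest.raises(ValueError, match="position"):
            estimate_f3x4(aln)


def _random_freqs(rng):
    return CodonFrequencies(rng.dirichlet(np.ones(61)))


class TestRateMatrix:
    @given(
        kappa=st.floats(0.2, 10.0),
        omega=st.floats(0.0, 10.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_zero(self, kappa, omega, seed):
        freqs = _random_freqs(np.random.default_rng(seed))
        q = build_rate_matrix(freqs, kappa, omega)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)

    @given(
        kappa=st.floats(0.2, 10.0),
        omega=st.floats(0.01, 10.0),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=25, deadline=None)
    def test_reversibility(self, kappa, omega, seed):
        freqs = _random_freqs(np.random.default_rng(seed))
        q = build_rate_matrix(freqs, kappa, omega)
        flux = freqs.pi[:, None] * q
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)

    def test_kappa_omega_one_collapses_to_pi(self, uniform_freqs):
        q = build_rate_matrix(uniform_freqs, 1.0, 1.0, scale=False)
        for a, ca in enumerate(SENSE):
            for b, cb in enumerate(SENSE):
                neighbor, _, _ = classify_pair(ca, cb)
                if neighbor:
                    assert q[a, b] == pytest.approx(uniform_freqs.pi[b])
                elif a != b:
                    assert q[a, b] == 0.0

    def test_all_pairs_against_classification_oracle(self, rng):
        freqs = _random_freqs(rng)
        kappa, omega = 3.0, 0.4
        q = build_rate_matrix(freqs, kappa, omega, scale=False)
        for a, ca in enumerate(SENSE):
            for b, cb in enumerate(SENSE):
                if a == b:
                    continue
                neighbor, transition, nonsyn = classify_pair(ca, cb)
                expected = 0.0
                if neighbor:
                    expected = freqs.pi[b]
                    if transition:
                        expected *= kappa
                    if nonsyn:
                        expected *= omega
                assert q[a, b] == pytest.approx(expected, rel=1e-12)

    def test_synonymous_transition_example(self, uniform_freqs):
        # TTT -> TTC is a synonymous transition (Phe -> Phe)
        q = build_rate_matrix(uniform_freqs, 2.5, 0.1, scale=False)
        i = SENSE.index("TTT")
        j = SENSE.index("TTC")
        assert q[i, j] == pytest.approx(2.5 * uniform_freqs.pi[j])

    def test_scaled_expected_rate_is_one(self, rng):
        freqs = _random_freqs(rng)
        q = build_rate_matrix(freqs, 2.0, 0.3, scale=True)
        assert expected_rate(freqs, q) == pytest.approx(1.0)

    def test_invalid_parameters(self, uniform_freqs):
        with pytest.raises(ValueError):
            build_rate_matrix(uniform_freqs, 0.0, 1.0)
        with pytest.raises(ValueError):
            build_rate_matrix(uniform_freqs, 1.0, -0.5)


class TestTransitionProbabilities:
    def test_zero_time_identity(self, uniform_freqs):
        q = build_rate_matrix(uniform_freqs, 2.0, 0.5)
        np.testing.assert_allclose(transition_probabilities(q, 0.0), np.eye(61))

    def test_long_time_reaches_equilibrium(self, rng):
        freqs = _random_freqs(rng)
        q = build_rate_matrix(freqs, 2.0, 0.5)
        p = transition_probabilities(q, 50.0)
        np.testing.assert_allclose(p, np.tile(freqs.pi, (61, 1)), atol=1e-4)

    def test_matches_series_oracle(self, rng):
        freqs = _random_freqs(rng)
        q = build_rate_matrix(freqs, 2.0, 0.5)
        p = transition_probabilities(q, 0.1)
        np.testing.assert_allclose(p, series_expm(q, 0.1), atol=1e-10)

    def test_operator_matches_series_oracle(self, rng):
        freqs = _random_freqs(rng)
        op = RateOperator(freqs, 2.0, 0.5)
        q = build_rate_matrix(freqs, 2.0, 0.5, scale=False)
        np.testing.assert_allclose(
            op.transition_matrix(0.1), series_expm(q, 0.1), atol=1e-10
        )

    def test_rows_stochastic(self, rng):
        freqs = _random_freqs(rng)
        op = RateOperator(freqs, 3.0, 2.0)
        p = op.transition_matrix(0.7)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_time_rejected(self, uniform_freqs):
        q = build_rate_matrix(uniform_freqs, 2.0, 0.5)
        with pytest.raises(ValueError):
            transition_probabilities(q, -0.1)


class TestBranchSiteParams:
    @given(
        p0=st.floats(0.05, 0.9),
        p1=st.floats(0.05, 0.9),
        omega0=st.floats(0.001, 0.999),
    )
    @settings(max_examples=50, deadline=None)
    def test_proportions_sum_to_one(self, p0, p1, omega0):
        if p0 + p1 > 1:
            total = p0 + p1 + 1e-9
            p0, p1 = p0 / total, p1 / total
        params = BranchSiteParams(kappa=2, p0=p0, p1=p1, omega0=omega0)
        assert params.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_null_flag(self):
        assert BranchSiteParams(2, 0.5, 0.3, 0.1).is_null
        assert not BranchSiteParams(2, 0.5, 0.3, 0.1, omega2=2.0).is_null

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kappa": -1, "p0": 0.5, "p1": 0.3, "omega0": 0.1},
            {"kappa": 2, "p0": 0.8, "p1": 0.5, "omega0": 0.1},
            {"kappa": 2, "p0": 0.5, "p1": 0.3, "omega0": 1.5},
            {"kappa": 2, "p0": 0.5, "p1": 0.3, "omega0": 0.1, "omega2": 0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BranchSiteParams(**kwargs)

    def test_mixture_scale_uses_background_omegas(self, uniform_freqs):
        params = BranchSiteParams(kappa=2, p0=0.6, p1=0.2, omega0=0.05, omega2=8.0)
        ops, scale = class_operators(uniform_freqs, params)
        expected = (params.p0 + params.p2a) * ops["w0"].rate + (
            params.p1 + params.p2b
        ) * ops["w1"].rate
        assert scale == pytest.approx(expected)
        # scale must not depend on omega2 (foreground-only parameter)
        null = BranchSiteParams(kappa=2, p0=0.6, p1=0.2, omega0=0.05)
        _, scale_null = class_operators(uniform_freqs, null)
        assert scale == pytest.approx(scale_null)
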