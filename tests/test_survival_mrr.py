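import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from owlpath.exceptions import IllegalHistoryError
from owlpath.params import DetectionParameters, SurvivalCoefficients
from owlpath.survival_mrr import (
    EncounterHistory,
    _mrr_loglik_numpy,
    brute_force_history_prob,
    detection_arrays,
    enumerate_legal_histories,
    history_loglik,
    mrr_loglik_matrix,
    survival_prob,
)

DET = DetectionParameters(p_ring=0.5, p_vhf=0.5, r_ring=0.5, r_vhf=0.5)


def det(p, r):
    return DetectionParameters(p_ring=p, p_vhf=p, r_ring=r, r_vhf=r)


class TestSurvivalProb:
    def test_null_model_is_half(self):
        covs = {t: 0.0 for t in SurvivalCoefficients.TERMS[1:]}
        assert survival_prob(SurvivalCoefficients(), covs) == pytest.approx(0.5)

    def test_experience_odds_ratio(self):
        c = SurvivalCoefficients(b_experience=0.71)
        covs = {t: 0.0 for t in SurvivalCoefficients.TERMS[1:]}
        p0 = survival_prob(c, covs)
        p1 = survival_prob(c, dict(covs, experience=1.0))
        assert (p1 / (1 - p1)) / (p0 / (1 - p0)) == pytest.approx(np.exp(0.71))

    def test_monotone_increasing_for_positive_coefficient(self):
        c = SurvivalCoefficients(b_spot=0.3)
        covs = {t: 0.0 for t in SurvivalCoefficients.TERMS[1:]}
        phis = [survival_prob(c, dict(covs, spot=x)) for x in np.linspace(-3, 3, 7)]
        assert all(np.diff(phis) > 0)


class TestHistoryLoglik:
    def test_seen_alive_next_occasion(self):
        h = EncounterHistory(0, (1, 1))
        ll = history_loglik(h, [0.6], det(0.5, 0.5), "ring")
        assert ll == pytest.approx(np.log(0.30))

    def test_recovered_dead_next_occasion(self):
        h = EncounterHistory(0, (1, 2))
        ll = history_loglik(h, [0.6], det(0.5, 0.3), "ring")
        assert ll == pytest.approx(np.log(0.12))

    def test_unseen_mixes_both_fates(self):
        h = EncounterHistory(0, (1, 0))
        ll = history_loglik(h, [0.5], det(0.5, 0.5), "ring")
        assert ll == pytest.approx(np.log(0.5))

    def test_impossible_history_has_zero_probability(self):
        h = EncounterHistory(0, (1, 0, 0))
        ll = history_loglik(h, [1.0, 1.0], det(1.0 - 1e-12, 0.5), "ring")
        assert ll < -20

    def test_long_history_stays_finite(self):
        codes = (1,) + (0,) * 49
        h = EncounterHistory(0, codes)
        ll = history_loglik(h, np.full(49, 0.5), det(0.5, 0.5), "ring")
        assert np.isfinite(ll)


class TestIllegalHistories:
    @pytest.mark.parametrize(
        "first,codes",
        [
            (0, (0, 1)),        # release code missing
            (0, (1, 2, 1)),     # seen after dead recovery
            (0, (1, 2, 2)),     # two dead recoveries
            (1, (1, 1, 0)),     # nonzero before release
            (0, (1, 3)),        # unknown code
        ],
    )
    def test_rejected(self, first, codes):
        with pytest.raises(IllegalHistoryError):
            EncounterHistory(first, codes)


class TestOracleEquivalence:
    @given(
        st.integers(2, 8),
        st.floats(0.05, 0.95),
        st.floats(0.05, 0.95),
        st.floats(0.05, 0.95),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_forward_recursion_matches_enumeration(self, n_occ, p, r, phi0, seed):
        rng = np.random.default_rng(seed)
        phi = rng.uniform(0.05, 0.95, n_occ - 1)
        phi[0] = phi0
        d = det(p, r)
        for h in enumerate_legal_histories(n_occ):
            exact = brute_force_history_prob(h, phi, d, "ring")
            ll = history_loglik(h, phi, d, "ring")
            if exact == 0.0:
                assert ll == -np.inf
            else:
                assert abs(np.exp(ll) - exact) < 1e-10

    def test_total_probability_is_one(self):
        rng = np.random.default_rng(3)
        for n_occ in (3, 4, 5, 6):
            phi = rng.uniform(0.1, 0.9, n_occ - 1)
            d = det(rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9))
            total = sum(
                brute_force_history_prob(h, phi, d, "ring")
                for h in enumerate_legal_histories(n_occ)
            )
            assert total == pytest.approx(1.0, abs=1e-10)


class TestCJSLimit:
    def test_zero_recovery_reduces_to_cjs(self):
        """With r = 0 the joint model is the live-recapture CJS likelihood."""
        phi1, phi2, p = 0.7, 0.6, 0.4
        d = det(p, 1e-300)
        expect = {
            (1, 1, 1): phi1 * p * phi2 * p,
            (1, 1, 0): phi1 * p * (phi2 * (1 - p) + (1 - phi2)),
            (1, 0, 1): phi1 * (1 - p) * phi2 * p,
            (1, 0, 0): (1 - phi1)
            + phi1 * (1 - p) * ((1 - phi2) + phi2 * (1 - p)),
        }
        for codes, prob in expect.items():
            h = EncounterHistory(0, codes)
            ll = history_loglik(h, [phi1, phi2], d, "ring")
            assert np.exp(ll) == pytest.approx(prob, abs=1e-12)


class TestVectorizedKernel:
    def _random_histories(self, rng, n_ind, n_occ):
        all_h = list(enumerate_legal_histories(n_occ))
        picks = rng.choice(len(all_h), n_ind)
        codes = np.array([all_h[i].codes for i in picks])
        return codes, np.zeros(n_ind, dtype=int)

    def test_matches_scalar_loglik_and_numpy_fallback(self, rng):
        n_ind, n_occ = 40, 5
        codes, first = self._random_histories(rng, n_ind, n_occ)
        phi = rng.uniform(0.2, 0.9, (3, n_ind, n_occ - 1))
        p = rng.uniform(0.2, 0.9, (3, n_ind))
        r = rng.uniform(0.1, 0.9, (3, n_ind))
        fast = mrr_loglik_matrix(codes, first, phi, p, r)
        slow = _mrr_loglik_numpy(codes, first, phi, p, r)
        assert np.allclose(fast, slow, atol=1e-12)
        for i in range(5):
            h = EncounterHistory(0, tuple(codes[i]))
            d = det(p[0, i], r[0, i])
            assert fast[0, i] == pytest.approx(
                history_loglik(h, phi[0, i], d, "ring"), abs=1e-10
            )

    def test_staggered_release_ignores_pre_release_intervals(self, rng):
        codes = np.array([[0, 1, 1], [1, 1, 1]])
        first = np.array([1, 0])
        phi = np.full((2, 2), 0.6)
        ll = mrr_loglik_matrix(codes, first, phi, np.full(2, 0.5), np.full(2, 0.5))
        assert ll[0] == pytest.approx(np.log(0.3))
        assert ll[1] == pytest.approx(2 * np.log(0.3))

    def test_group_separation(self, rng):
        """Perturbing VHF detection never changes a ring bird's likelihood."""
        codes, first = self._random_histories(rng, 30, 5)
        groups = np.array(["ring"] * 15 + ["vhf"] * 15)
        phi = rng.uniform(0.3, 0.9, (30, 4))
        d1 = DetectionParameters(p_ring=0.4, p_vhf=0.8, r_ring=0.2, r_vhf=0.6)
        d2 = DetectionParameters(p_ring=0.4, p_vhf=0.95, r_ring=0.2, r_vhf=0.1)
        p1, r1 = detection_arrays(d1, groups)
        p2, r2 = detection_arrays(d2, groups)
        ll1 = mrr_loglik_matrix(codes, first, phi, p1, r1)
        ll2 = mrr_loglik_matrix(codes, first, phi, p2, r2)
        assert np.allclose(ll1[:15], ll2[:15])
        assert not np.allclose(ll1[15:], ll2[15:])
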