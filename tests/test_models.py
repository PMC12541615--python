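"""Forward-model correctness: operational variants, 4PL, log transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calcifit import (
    Concentrations,
    FourPLParams,
    OperationalModelParams,
    ab_to_logab,
    effect_4pl,
    effect_comparative,
    effect_complete,
    k_to_pk,
    logab_to_ab,
    pk_to_k,
)


def oracle_complete(Em, tauA, tauB, KA, KB, alpha, alphabeta, nT, nB, C, A, B):
    """Plain-arithmetic evaluation of the complete model, independent of the
    package's vectorised implementation."""
    x = (A + C) ** nB
    ka = KA ** nB
    num = tauA * x * (KB + alphabeta * B) + tauB * B * ka
    den = x * KB + ka * KB + ka * B + alpha * x * B
    if num == 0.0:
        return 0.0
    return Em * num ** nT / (den ** nT + num ** nT)


def oracle_comparative(Em, tauA, tauB, EC50, KB, alphabeta, nT, nB, C, A, B):
    x = (A + C) ** nB
    e = EC50 ** nB
    num = tauA * x * (KB + alphabeta * B) + tauB * B * e
    den = e * (KB + B)
    if num == 0.0:
        return 0.0
    return Em * num ** nT / (den ** nT + num ** nT)


class TestEffectComplete:
    def test_zero_everywhere_gives_zero(self):
        p = OperationalModelParams(Em=100, log_tauA=0, log_KA=-3, log_KB=-7,
                                   log_alphabeta=-2, C=0)
        assert effect_complete(p, Concentrations(0.0, 0.0)) == 0.0

    def test_hand_arithmetic_midpoint(self):
        # Em=100, tauA=1, KA=1e-3, KB=1e-7, ab=0.01, A=1e-3:
        # numerator 100*(1e-3*1e-7), denominator 3e-10 -> 100/3
        p = OperationalModelParams(Em=100, log_tauA=0, log_KA=-3, log_KB=-7,
                                   log_alphabeta=-2, nB=1, C=0)
        val = effect_complete(p, Concentrations(1e-3, 0.0))
        assert val == pytest.approx(100.0 / 3.0, rel=1e-12)

    def test_saturating_nam_shift_approaches_cooperativity_ceiling(self):
        # with alpha=0, tauB=0 the limiting B->inf curve is a right-shifted
        # vehicle curve; the EC50 shift saturates at (1+tauA)/(tauA*ab),
        # i.e. essentially 1/alphabeta for a high-efficacy agonist
        p = OperationalModelParams(Em=100, log_tauA=2, log_KA=-3, log_KB=-7,
                                   log_alphabeta=-2, nB=1, C=0)
        ab, tauA = p.alphabeta, p.tauA
        A = 10 ** np.linspace(-8, 0, 400)
        vehicle = effect_complete(p, Concentrations(A, np.zeros_like(A)))
        huge_B = effect_complete(p, Concentrations(A, np.full_like(A, 1.0)))

        def ec50(y):
            half = y.max() / 2
            return A[np.argmin(np.abs(y - half))]

        shift = ec50(huge_B) / ec50(vehicle)
        ceiling = (1 + tauA) / (tauA * ab)
        assert 0.3 * ceiling < shift <= 1.05 * ceiling

    def test_nam_monotone_nonincreasing_in_B_below_plateau(self):
        # the inhibition is monotone in B wherever the competitive-like
        # KA^nB*[B] denominator term dominates (agonist up to ~10x EC50);
        # at deeply saturating agonist the alphabeta*[B] efficacy term can
        # raise the plateau instead, so the window matters
        p = OperationalModelParams(Em=150, log_tauA=0.5, log_KA=-2.7,
                                   log_KB=-7, log_alphabeta=-1.5,
                                   nB=2.0, C=1e-4)
        A = 10 ** np.linspace(-5, -2, 12)
        B = np.concatenate([[0.0], 10 ** np.linspace(-9, -4, 11)])
        grid = effect_complete(
            p, Concentrations(A[:, None] * np.ones_like(B), B * np.ones((12, 1)))
        )
        assert grid.shape == (12, 12)
        assert np.all(np.diff(grid, axis=1) <= 1e-9)

    def test_rejects_negative_and_nonfinite_concentrations(self):
        p = OperationalModelParams(Em=100, log_tauA=0, log_KA=-3, log_KB=-7,
                                   log_alphabeta=-2)
        with pytest.raises(ValueError):
            effect_complete(p, Concentrations(-1e-3, 0.0))
        with pytest.raises(ValueError):
            effect_complete(p, Concentrations(np.nan, 0.0))


class TestEffectComparative:
    def test_hill_midpoint_reduction(self):
        p = OperationalModelParams(Em=100, log_tauA=0, logEC50=-3, log_KB=-7,
                                   log_alphabeta=-1, nB=1, C=0)
        assert effect_comparative(p, Concentrations(1e-3, 0.0)) == pytest.approx(50.0)

    def test_frozen_plugin_value(self):
        # exact fraction 1100/31 from plain arithmetic:
        # N = 1e-6 * 1.1e-7, D0 = 1e-6 * 2e-7
        p = OperationalModelParams(Em=100, log_tauA=0, logEC50=-3, log_KB=-7,
                                   log_alphabeta=-1, nB=2, C=0)
        val = effect_comparative(p, Concentrations(1e-3, 1e-7))
        assert val == pytest.approx(1100.0 / 31.0, rel=1e-12)

    def test_reduces_to_scaled_hill_at_zero_B(self):
        p = OperationalModelParams(Em=137.0, log_tauA=0, logEC50=-2.9,
                                   log_KB=-7, log_alphabeta=-1, nB=2.91,
                                   C=1e-4)
        A = 10 ** np.linspace(-5, -1, 50)
        got = effect_comparative(p, Concentrations(A, np.zeros_like(A)))
        x = (A + p.C) ** p.nB
        want = p.Em * x / (x + p.EC50 ** p.nB)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_matches_complete_variant_at_zero_B(self):
        # complete model at B=0 is Hill with EC50^nB = KA^nB/(1+tauA) and
        # plateau Em*tauA/(1+tauA); choose the comparative parameters to match
        tauA, nB, Em, log_KA = 4.0, 2.0, 180.0, -2.5
        pc = OperationalModelParams(Em=Em, log_tauA=np.log10(tauA),
                                    log_KA=log_KA, log_KB=-7,
                                    log_alphabeta=-2, nB=nB, C=1e-4)
        logEC50 = log_KA - np.log10(1 + tauA) / nB
        pq = OperationalModelParams(Em=Em * tauA / (1 + tauA), log_tauA=0,
                                    logEC50=logEC50, log_KB=-7,
                                    log_alphabeta=-2, nB=nB, C=1e-4)
        A = 10 ** np.linspace(-5, -1, 40)
        z = np.zeros_like(A)
        np.testing.assert_allclose(
            effect_complete(pc, Concentrations(A, z)),
            effect_comparative(pq, Concentrations(A, z)),
            rtol=1e-9,
        )


@settings(max_examples=250, deadline=None)
@given(
    Em=st.floats(10, 300),
    log_tauA=st.floats(-1.5, 2),
    log_KA=st.floats(-5, -1),
    log_KB=st.floats(-8, -5),
    log_ab=st.floats(-3, 0),
    nB=st.floats(0.5, 4),
    logA=st.floats(-7, -1),
    logB=st.floats(-9, -4),
)
def test_effect_bounded_by_Em_for_unit_transducer(
    Em, log_tauA, log_KA, log_KB, log_ab, nB, logA, logB
):
    p = OperationalModelParams(Em=Em, log_tauA=log_tauA, log_KA=log_KA,
                               log_KB=log_KB, log_alphabeta=log_ab,
                               nB=nB, nT=1.0, C=1e-4)
    val = effect_complete(p, Concentrations(10 ** logA, 10 ** logB))
    assert 0.0 <= val <= Em + 1e-9


def test_oracle_equivalence_complete_and_comparative():
    """Both vectorised effect functions agree with the plain-arithmetic
    oracle to 1e-9 relative on 1,000 random parameter draws."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(1000):
        kw = dict(
            Em=rng.uniform(10, 300),
            log_tauA=rng.uniform(-1.5, 2),
            log_tauB=rng.choice([-1000.0, rng.uniform(-2, 0)]),
            log_KB=rng.uniform(-8, -4),
            log_alphabeta=rng.uniform(-3, 0.5),
            alpha=rng.choice([0.0, rng.uniform(0, 2)]),
            nT=rng.uniform(0.5, 2),
            nB=rng.uniform(0.5, 4),
            C=rng.choice([0.0, 1e-4]),
        )
        A, B = 10 ** rng.uniform(-7, -1), 10 ** rng.uniform(-9, -4)
        pc = OperationalModelParams(log_KA=rng.uniform(-5, -1), **kw)
        want = oracle_complete(pc.Em, pc.tauA, pc.tauB, pc.KA, pc.KB,
                               pc.alpha, pc.alphabeta, pc.nT, pc.nB, pc.C, A, B)
        got = effect_complete(pc, Concentrations(A, B))
        worst = max(worst, abs(got - want) / max(abs(want), 1e-300))

        pq = OperationalModelParams(logEC50=rng.uniform(-5, -1), **kw)
        want = oracle_comparative(pq.Em, pq.tauA, pq.tauB, pq.EC50, pq.KB,
                                  pq.alphabeta, pq.nT, pq.nB, pq.C, A, B)
        got = effect_comparative(pq, Concentrations(A, B))
        worst = max(worst, abs(got - want) / max(abs(want), 1e-300))
    assert worst < 1e-9


class TestFourPL:
    @pytest.mark.parametrize(
        "params, logA, expected",
        [
            (FourPLParams(0, 100, -3, 1.0), -3.0, 50.0),
            (FourPLParams(0, 100, -3, 2.91), 3.0, 100.0),   # far above EC50
            (FourPLParams(10, 90, -2.94, 2.91), -2.94, 50.0),
        ],
    )
    def test_reference_points(self, params, logA, expected):
        assert effect_4pl(params, logA) == pytest.approx(expected, abs=1e-6)

    def test_strictly_increasing_for_positive_hill(self):
        p = FourPLParams(5, 150, -2.9, 2.5)
        x = np.linspace(-5, -1, 100)
        assert np.all(np.diff(effect_4pl(p, x)) > 0)


class TestTransforms:
    @pytest.mark.parametrize(
        "pk, k_printed, digits",
        [
            (7.06, 87, 0), (6.39, 407, 0), (9.0, 1.0, 1),
            (7.33, 47, 0), (6.76, 174, 0), (6.65, 224, 0),
        ],
    )
    def test_pk_to_k_reporting_pairs(self, pk, k_printed, digits):
        assert round(pk_to_k(pk), digits) == pytest.approx(k_printed)

    @pytest.mark.parametrize(
        "logab, ab_printed",
        [(-1.87, 0.0135), (0.0, 1.0), (-2.38, 0.00417),
         (-1.73, 0.019), (-0.95, 0.112)],
    )
    def test_logab_to_ab_reporting_pairs(self, logab, ab_printed):
        sig = len(str(ab_printed).replace("0.", "").lstrip("0"))
        assert float(f"{logab_to_ab(logab):.{sig}g}") == pytest.approx(ab_printed)

    @given(st.floats(3, 12))
    @settings(max_examples=100, deadline=None)
    def test_pk_round_trip(self, pk):
        assert k_to_pk(pk_to_k(pk)) == pytest.approx(pk, rel=1e-12)

    @given(st.floats(-4, 1))
    @settings(max_examples=100, deadline=None)
    def test_logab_round_trip(self, logab):
        assert ab_to_logab(logab_to_ab(logab)) == pytest.approx(logab, abs=1e-12)


class TestParamValidation:
    def test_requires_affinity_or_ec50(self):
        with pytest.raises(ValueError):
            OperationalModelParams(Em=100, log_tauA=0, log_KB=-7,
                                   log_alphabeta=-1)

    @pytest.mark.parametrize("field, bad", [("Em", -1.0), ("nT", 0.0),
                                            ("nB", -2.0), ("C", -1e-4)])
    def test_rejects_nonpositive_shape_parameters(self, field, bad):
        kw = dict(Em=100, log_tauA=0, log_KA=-3, log_KB=-7, log_alphabeta=-1)
        kw[field] = bad
        with pytest.raises(ValueError):
            OperationalModelParams(**kw)
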