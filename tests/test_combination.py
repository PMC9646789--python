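"""Combination index, DRI, isobologram and the Loewe-additive null."""

import math

import numpy as np
import pytest

import synerkit as sk
from synerkit.combination import ADDITIVE, ANTAGONISM, SYNERGISM


@pytest.fixture
def pair():
    a = sk.MedianEffectFit.from_parameters("a", 10.0, 1.2, "nM")
    b = sk.MedianEffectFit.from_parameters("b", 100.0, 2.0, "nM")
    return a, b


class TestCombinationIndex:
    def test_single_agent_at_own_ecx(self, pair):
        a, b = pair
        dx = sk.dose_for_effect(a, 0.7)
        assert sk.combination_index(dx, 0.0, a, b, 0.7) == pytest.approx(1.0, rel=1e-12)

    def test_loewe_additive_point(self, pair):
        a, b = pair
        fa = 0.6
        ci = sk.combination_index(
            sk.dose_for_effect(a, fa) / 2, sk.dose_for_effect(b, fa) / 2, a, b, fa
        )
        assert ci == pytest.approx(1.0, rel=1e-12)

    def test_published_98_percent_level(self, pair):
        # components at dx/4.38 and dx/4.08 reproduce the published 0.47
        a, b = pair
        fa = 0.98
        ci = sk.combination_index(
            sk.dose_for_effect(a, fa) / 4.38, sk.dose_for_effect(b, fa) / 4.08, a, b, fa
        )
        assert ci == pytest.approx(0.473, abs=5e-4)
        assert round(ci, 2) == 0.47

    def test_unit_rescaling_invariance(self, pair):
        a, b = pair
        fa, da, db = 0.4, 3.0, 20.0
        ci1 = sk.combination_index(da, db, a, b, fa)
        a2 = sk.MedianEffectFit.from_parameters("a", 1000 * a.Dm, a.m, "pM")
        ci2 = sk.combination_index(1000 * da, db, a2, b, fa)
        assert ci2 == pytest.approx(ci1, rel=1e-12)

    def test_domain_errors(self, pair):
        a, b = pair
        with pytest.raises(sk.DomainError):
            sk.combination_index(0.0, 0.0, a, b, 0.5)
        with pytest.raises(sk.DomainError):
            sk.combination_index(1.0, 1.0, a, b, 1.0)


class TestDoseReductionIndex:
    def test_no_reduction(self, pair):
        a, _ = pair
        dx = sk.dose_for_effect(a, 0.8)
        assert sk.dose_reduction_index(a, dx, 0.8) == pytest.approx(1.0, rel=1e-12)

    def test_twofold(self, pair):
        a, _ = pair
        dx = sk.dose_for_effect(a, 0.8)
        assert sk.dose_reduction_index(a, dx / 2, 0.8) == pytest.approx(2.0, rel=1e-12)

    def test_published_brequinar_halving(self, published_fits):
        fit = published_fits["brequinar"]
        dri = sk.dose_reduction_index(fit, 25.37, 0.9)
        assert dri == pytest.approx(2.0, abs=0.01)

    def test_zero_dose_rejected(self, pair):
        with pytest.raises(sk.DomainError):
            sk.dose_reduction_index(pair[0], 0.0, 0.5)


class TestCiFromDri:
    @pytest.mark.parametrize(
        "dri_a,dri_b,expected,printed",
        [
            (2.0, 2.0, 1.0, 1.00),
            (19.63, 9.33, 0.158, 0.16),
            (3.32, 4.08, 0.546, 0.55),
        ],
    )
    def test_examples(self, dri_a, dri_b, expected, printed):
        ci = sk.ci_from_dri(dri_a, dri_b)
        assert ci == pytest.approx(expected, abs=5e-4)
        assert round(ci, 2) == printed

    @pytest.mark.parametrize("seed", range(20))
    def test_identity_with_combination_index(self, pair, seed):
        # the DRI route and the direct dose route are algebraically the same
        a, b = pair
        rng = np.random.default_rng(seed)
        fa = float(rng.uniform(0.05, 0.95))
        da = float(rng.uniform(0.1, 50.0))
        db = float(rng.uniform(0.1, 500.0))
        dri_a = sk.dose_reduction_index(a, da, fa)
        dri_b = sk.dose_reduction_index(b, db, fa)
        assert sk.ci_from_dri(dri_a, dri_b) == pytest.approx(
            sk.combination_index(da, db, a, b, fa), rel=1e-12
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(sk.DomainError):
            sk.ci_from_dri(-1.0, 2.0)


class TestClassification:
    @pytest.mark.parametrize(
        "ci,label",
        [(0.47, SYNERGISM), (1.03, ADDITIVE), (1.14, ANTAGONISM),
         (0.95, ADDITIVE), (1.0, ADDITIVE), (0.9499, SYNERGISM)],
    )
    def test_band_0_05(self, ci, label):
        assert sk.classify_interaction(ci, 0.05) == label

    def test_strict_band(self):
        assert sk.classify_interaction(1.0, 0.0) == ADDITIVE
        assert sk.classify_interaction(1.0001, 0.0) == ANTAGONISM


class TestIsobologram:
    def test_on_line(self, pair):
        a, b = pair
        fa = 0.5
        (xa, xb), side = sk.isobologram_point(
            a.Dm / 2, b.Dm / 2, a, b, fa
        )
        assert xa + xb == pytest.approx(1.0, rel=1e-12)
        assert side == "on"

    def test_below_line_synergy(self, pair):
        a, b = pair
        fa = 0.98
        (xa, xb), side = sk.isobologram_point(
            sk.dose_for_effect(a, fa) / 4.38, sk.dose_for_effect(b, fa) / 4.08, a, b, fa
        )
        assert side == "below"
        assert (xa, xb) == pytest.approx((1 / 4.38, 1 / 4.08), rel=1e-12)

    def test_above_line(self, pair):
        a, b = pair
        fa = 0.5
        (_, _), side = sk.isobologram_point(
            0.9 * sk.dose_for_effect(a, fa), 0.9 * sk.dose_for_effect(b, fa), a, b, fa
        )
        assert side == "above"

    @pytest.mark.parametrize("seed", range(20))
    def test_never_disagrees_with_classification(self, pair, seed):
        a, b = pair
        rng = np.random.default_rng(1000 + seed)
        fa = float(rng.uniform(0.05, 0.95))
        da = float(rng.uniform(0.01, 30.0))
        db = float(rng.uniform(0.01, 300.0))
        ci = sk.combination_index(da, db, a, b, fa)
        label = sk.classify_interaction(ci, 0.05)
        _, side = sk.isobologram_point(da, db, a, b, fa, 0.05)
        assert {"below": SYNERGISM, "on": ADDITIVE, "above": ANTAGONISM}[side] == label


class TestSolveLoeweMixture:
    def test_identical_agents_reduce_to_single(self):
        a = sk.MedianEffectFit.from_parameters("a", 10.0, 1.5)
        fa = sk.solve_loewe_mixture(a, a, (0.5, 0.5), 10.0)
        assert fa == pytest.approx(0.5, abs=1e-9)

    def test_unit_slope_analytic(self):
        a = sk.MedianEffectFit.from_parameters("a", 10.0, 1.0)
        fa = sk.solve_loewe_mixture(a, a, (0.5, 0.5), 90.0)
        assert fa == pytest.approx(0.9, abs=1e-9)

    def test_heterogeneous_vs_grid_search_oracle(self):
        a = sk.MedianEffectFit.from_parameters("a", 10.0, 1.0)
        b = sk.MedianEffectFit.from_parameters("b", 100.0, 2.0)
        total, p = 60.0, 0.5
        fa = sk.solve_loewe_mixture(a, b, (p, 1 - p), total)
        # independent oracle: dense grid on fa minimising the additivity residual
        grid = np.linspace(1e-6, 1 - 1e-6, 10**6)
        dx_a = a.Dm * (grid / (1 - grid)) ** (1 / a.m)
        dx_b = b.Dm * (grid / (1 - grid)) ** (1 / b.m)
        resid = np.abs(p * total / dx_a + (1 - p) * total / dx_b - 1.0)
        assert fa == pytest.approx(float(grid[resid.argmin()]), abs=1e-6)

    def test_degenerate_ratio_is_single_agent(self):
        a = sk.MedianEffectFit.from_parameters("a", 10.0, 1.3)
        b = sk.MedianEffectFit.from_parameters("b", 99.0, 0.7)
        fa = sk.solve_loewe_mixture(a, b, (1.0, 0.0), 25.0)
        assert fa == pytest.approx(sk.effect_at_dose(a, 25.0), abs=1e-9)

    def test_bad_total_dose(self):
        a = sk.MedianEffectFit.from_parameters("a", 10.0, 1.0)
        with pytest.raises(sk.DomainError):
            sk.solve_loewe_mixture(a, a, (0.5, 0.5), 0.0)


class TestFaCiProfile:
    GRID = [0.1, 0.3, 0.5, 0.7, 0.9]

    def test_self_combination_is_additive(self, pair):
        a, _ = pair
        points = sk.fa_ci_profile(a, (1.0, 0.0), a, pair[1], self.GRID)
        for p in points:
            assert p.ci == pytest.approx(1.0, rel=1e-12)
            assert p.label == ADDITIVE
            assert math.isinf(p.dri_b)

    def test_loewe_mixture_scores_ci_one(self):
        # agents sharing m: the additive mixture is itself median-effect
        # with 1/Dm_mix = p/Dm_a + q/Dm_b, so CI must be exactly 1
        a = sk.MedianEffectFit.from_parameters("a", 10.0, 1.4)
        b = sk.MedianEffectFit.from_parameters("b", 200.0, 1.4)
        p = 0.3
        dm_mix = 1.0 / (p / a.Dm + (1 - p) / b.Dm)
        mix = sk.MedianEffectFit.from_parameters("a+b", dm_mix, 1.4)
        for pt in sk.fa_ci_profile(mix, (p, 1 - p), a, b, self.GRID):
            assert pt.ci == pytest.approx(1.0, abs=1e-6)

    def test_potent_mixture_is_synergistic_at_high_fa(self, pair):
        a, b = pair
        # mixture more potent than any additive split at high effect
        mix = sk.MedianEffectFit.from_parameters("a+b", 3.0, 1.5)
        points = sk.fa_ci_profile(mix, (0.5, 0.5), a, b, self.GRID)
        assert points[-1].ci < 1.0
        assert points[-1].label == SYNERGISM

    def test_empty_grid_rejected(self, pair):
        with pytest.raises(sk.DomainError):
            sk.fa_ci_profile(pair[0], (0.5, 0.5), pair[0], pair[1], [])

    def test_ci_dri_identity_within_points(self, pair):
        a, b = pair
        mix = sk.MedianEffectFit.from_parameters("a+b", 30.0, 1.1)
        for p in sk.fa_ci_profile(mix, (0.4, 0.6), a, b, self.GRID):
            assert p.ci == pytest.approx(1 / p.dri_a + 1 / p.dri_b, rel=1e-12)
            assert p.ci == pytest.approx(p.dose_a / p.dx_a + p.dose_b / p.dx_b, rel=1e-12)


class TestFixedRatioDesign:
    def test_valid_design(self):
        d = sk.FixedRatioDesign(
            agent_a="a", agent_b="b", levels=(0.1, 0.5, 0.9),
            ec_doses={"a": (1.0, 5.0, 25.0), "b": (2.0, 10.0, 50.0)},
            ratio_fractions=(0.5, 0.5),
        )
        assert d.levels == (0.1, 0.5, 0.9)

    def test_nonmonotone_ec_doses_rejected(self):
        with pytest.raises(sk.DomainError):
            sk.FixedRatioDesign(
                agent_a="a", agent_b="b", levels=(0.1, 0.5, 0.9),
                ec_doses={"a": (5.0, 1.0, 25.0), "b": (2.0, 10.0, 50.0)},
                ratio_fractions=(0.5, 0.5),
            )

    def test_ratio_must_sum_to_one(self):
        with pytest.raises(sk.DomainError):
            sk.FixedRatioDesign(
                agent_a="a", agent_b="b", levels=(0.1, 0.9),
                ec_doses={"a": (1.0, 25.0), "b": (2.0, 50.0)},
                ratio_fractions=(0.6, 0.6),
            )

    def test_default_ratio_is_dm_proportions(self, pair):
        a, b = pair
        p, q = sk.default_ratio_fractions(a, b)
        assert p + q == pytest.approx(1.0)
        assert p / q == pytest.approx(a.Dm / b.Dm, rel=1e-12)
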