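"""PRE forward model: prefactor, rates, intensity ratios, localization."""

import dataclasses
import math

import numpy as np
import pytest

from methylassign.pre import (DEFAULT_CONSTANTS, G_E_FREE, GridSpec,
                              PhysicalConstants, PREObservation,
                              PREParameters, SpinLabelSite, compare_pre,
                              gamma2_H, gamma2_MQ, intensity_ratio, kappa_H,
                              localize_spin_label, mq_scaling, place_electron,
                              predict_pre_profile)
from methylassign.structure import MethylGroup

from conftest import make_structure

# Frozen against a 40-digit arbitrary-precision evaluation of the closed
# forms (mpmath), independently of the implementation under test.
KAPPA_ORACLE = 1.2310756375152504e16          # A^6 s^-2, g = 2.0
GAMMA2_20A_ORACLE = 12.311565564873557        # s^-1 at r = 20 A, 850 MHz
RATIO_AT_20A_ORACLE = 0.6031878904561645
MQ_FACTOR_ORACLE = 1.0632541487688964


def _methyl(num, coord):
    coord = np.asarray(coord, dtype=float)
    return MethylGroup("A", num, "MET", "e", coord, coord, "n/a")


class TestKappaH:
    def test_matches_high_precision_oracle(self):
        assert kappa_H() == pytest.approx(KAPPA_ORACLE, rel=1e-12)

    def test_matches_printed_value(self):
        assert kappa_H() == pytest.approx(1.2311e16, rel=5e-4)

    def test_quadratic_in_gamma_h(self):
        doubled = dataclasses.replace(DEFAULT_CONSTANTS,
                                      gamma_H=2 * DEFAULT_CONSTANTS.gamma_H)
        assert kappa_H(doubled) == pytest.approx(4 * kappa_H(), rel=1e-12)

    def test_spin_factor_ratio(self):
        s1 = dataclasses.replace(DEFAULT_CONSTANTS, S_e=1.0)
        assert kappa_H(s1) / kappa_H() == pytest.approx(8.0 / 3.0, rel=1e-12)

    def test_codata_free_electron_g_runs_higher(self):
        codata = dataclasses.replace(DEFAULT_CONSTANTS, g_e=G_E_FREE)
        assert kappa_H(codata) / kappa_H() == pytest.approx(
            (G_E_FREE / 2.0) ** 2, rel=1e-12)

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError):
            PhysicalConstants(gamma_H=-1.0)


class TestGamma2:
    def test_frozen_scalar_value(self):
        assert gamma2_H(20.0, PREParameters()) == pytest.approx(
            GAMMA2_20A_ORACLE, rel=1e-12)

    def test_far_field_limit(self):
        assert gamma2_H(1e6, PREParameters()) < 1e-18

    def test_halving_r_multiplies_by_64(self):
        p = PREParameters()
        assert gamma2_H(10.0, p) == pytest.approx(64 * gamma2_H(20.0, p),
                                                  rel=1e-12)

    def test_r6_law_constant(self):
        p = PREParameters()
        rng = np.random.default_rng(2)
        r = rng.uniform(3.0, 80.0, size=200)
        product = gamma2_H(r, p) * r ** 6
        assert np.all(np.abs(product / product[0] - 1.0) < 1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            gamma2_H(0.0, PREParameters())
        with pytest.raises(ValueError):
            gamma2_H(-5.0, PREParameters())


class TestMQScaling:
    def test_printed_factor(self):
        assert round(mq_scaling(), 3) == 1.063

    def test_zero_maps_to_zero(self):
        assert gamma2_MQ(0.0, PREParameters()) == 0.0

    def test_hundred_scales_to_106_3(self):
        val = gamma2_MQ(100.0, PREParameters())
        assert val == pytest.approx(100 * MQ_FACTOR_ORACLE, rel=1e-12)
        assert round(val, 1) == 106.3

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gamma2_MQ(-1.0, PREParameters())


class TestIntensityRatio:
    def test_identity_at_zero(self):
        assert intensity_ratio(0.0, PREParameters()) == 1.0

    def test_vanishes_at_large_pre(self):
        assert intensity_ratio(1e6, PREParameters()) < 1e-12

    def test_frozen_value_at_20A(self):
        p = PREParameters()
        assert intensity_ratio(gamma2_H(20.0, p), p) == pytest.approx(
            RATIO_AT_20A_ORACLE, rel=1e-12)

    def test_strictly_decreasing_and_bounded(self):
        p = PREParameters()
        g = np.linspace(0.0, 500.0, 2000)
        ratios = intensity_ratio(g, p)
        assert np.all(np.diff(ratios) < 0)
        assert np.all(ratios > 0.0) and np.all(ratios <= 1.0)

    def test_negative_pre_rejected(self):
        with pytest.raises(ValueError):
            intensity_ratio(-0.1, PREParameters())


class TestParameters:
    def test_s2_range_enforced(self):
        with pytest.raises(ValueError):
            PREParameters(s2=0.0)
        with pytest.raises(ValueError):
            PREParameters(s2=1.2)

    def test_omega0_from_spectrometer_frequency(self):
        p = PREParameters(h1_freq_hz=850e6)
        assert p.omega0 == pytest.approx(2 * math.pi * 850e6)


class TestPlaceElectron:
    def test_explicit_uses_given_coordinate(self, leucine_structure):
        site = place_electron(leucine_structure, "A", 1, mode="explicit",
                              coord=(1.0, 2.0, 3.0))
        assert np.allclose(site.electron_coord, [1.0, 2.0, 3.0])

    def test_zero_offset_sits_on_cb(self, leucine_structure):
        site = place_electron(leucine_structure, "A", 1, offset=0.0)
        assert np.allclose(site.electron_coord,
                           leucine_structure.residue("A", 1).atoms["CB"])

    def test_offset_along_ca_cb_axis(self):
        st = make_structure(["ALA"])
        res = st.residues[("A", 1)]
        res.atoms["CA"] = np.array([0.0, 0.0, 0.0])
        res.atoms["CB"] = np.array([1.5, 0.0, 0.0])
        site = place_electron(st, "A", 1, offset=7.0)
        assert np.allclose(site.electron_coord, [8.5, 0.0, 0.0])

    def test_missing_cb_rejected(self):
        st = make_structure(["ALA"])
        del st.residues[("A", 1)].atoms["CB"]
        with pytest.raises(ValueError, match="CB"):
            place_electron(st, "A", 1)


class TestPredictProfile:
    def test_far_field_ratios_near_one(self):
        methyls = [_methyl(i + 1, (i * 3.0, 0, 0)) for i in range(5)]
        site = SpinLabelSite("t", None, np.array([0.0, 500.0, 0.0]))
        preds = predict_pre_profile(methyls, site, PREParameters())
        assert all(p.ratio > 0.99 for p in preds)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(4)
        methyls = [_methyl(i + 1, c)
                   for i, c in enumerate(rng.uniform(-15, 15, (10, 3)))]
        site = SpinLabelSite("t", None, np.array([20.0, 0.0, 0.0]))
        p = PREParameters()
        fwd = {x.methyl_id: x.ratio
               for x in predict_pre_profile(methyls, site, p)}
        rev = {x.methyl_id: x.ratio
               for x in predict_pre_profile(methyls[::-1], site, p)}
        assert fwd == rev

    def test_composition_of_scalar_operations(self):
        rng = np.random.default_rng(9)
        methyls = [_methyl(i + 1, c)
                   for i, c in enumerate(rng.uniform(-20, 20, (20, 3)))]
        electron = np.array([25.0, 10.0, -5.0])
        site = SpinLabelSite("t", None, electron)
        p = PREParameters()
        for pred in predict_pre_profile(methyls, site, p):
            m = next(x for x in methyls if x.id == pred.methyl_id)
            r = float(np.linalg.norm(m.pseudo - electron))
            g2 = gamma2_H(r, p)
            assert pred.r_en == pytest.approx(r, rel=1e-12)
            assert pred.gamma2_h == pytest.approx(g2, rel=1e-12)
            assert pred.gamma2_mq == pytest.approx(gamma2_MQ(g2, p), rel=1e-12)
            assert pred.ratio == pytest.approx(intensity_ratio(g2, p),
                                               rel=1e-12)

    def test_monotone_in_distance(self):
        methyls = [_methyl(i + 1, (5.0 + 5 * i, 0, 0)) for i in range(6)]
        site = SpinLabelSite("t", None, np.zeros(3))
        preds = predict_pre_profile(methyls, site, PREParameters())
        ratios = [p.ratio for p in preds]
        assert ratios == sorted(ratios)


class TestComparePRE:
    def _predictions(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        methyls = [_methyl(i + 1, c)
                   for i, c in enumerate(rng.uniform(-15, 15, (n, 3)))]
        site = SpinLabelSite("t", None, np.array([18.0, 0.0, 0.0]))
        return predict_pre_profile(methyls, site, PREParameters())

    def test_noise_free_round_trip(self):
        preds = self._predictions()
        obs = [PREObservation(p.methyl_id, p.ratio, 1.0) for p in preds]
        report = compare_pre(obs, preds)
        assert report.rms == 0.0
        assert report.n_consistent == report.n_compared == len(preds)

    def test_single_perturbation_detected(self):
        preds = self._predictions()
        obs = [PREObservation(p.methyl_id, p.ratio, 1.0) for p in preds]
        obs[3] = PREObservation(obs[3].key, obs[3].i_para + 0.5, 1.0)
        report = compare_pre(obs, preds, tolerance=0.2)
        assert report.n_compared - report.n_consistent == 1

    def test_unquantifiable_skipped(self):
        preds = self._predictions()
        obs = [PREObservation(p.methyl_id, p.ratio, 1.0,
                              quantifiable=(i != 0))
               for i, p in enumerate(preds)]
        assert compare_pre(obs, preds).n_compared == len(preds) - 1

    def test_no_overlap_raises(self):
        preds = self._predictions()
        with pytest.raises(ValueError):
            compare_pre([PREObservation("missing", 0.5, 1.0)], preds)

    def test_rms_tracks_noise_level(self):
        # Monte-Carlo oracle: with N(0, 0.05) noise on 50 ratios the mean
        # RMS residual over 100 seeds approaches 0.05
        preds = self._predictions(n=50, seed=1)
        rms_values = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            obs = [PREObservation(p.methyl_id,
                                  p.ratio + rng.normal(0.0, 0.05), 1.0)
                   for p in preds]
            rms_values.append(compare_pre(obs, preds).rms)
        assert np.mean(rms_values) == pytest.approx(0.05, abs=0.005)


class TestLocalization:
    def _constellation(self, n=30, seed=6):
        rng = np.random.default_rng(seed)
        return [_methyl(i + 1, c)
                for i, c in enumerate(rng.uniform(-15, 15, (n, 3)))]

    def _observe(self, methyls, electron, sigma=0.0, seed=0):
        site = SpinLabelSite("t", None, np.asarray(electron, dtype=float))
        preds = predict_pre_profile(methyls, site, PREParameters())
        rng = np.random.default_rng(seed)
        return [PREObservation(p.methyl_id,
                               max(0.0, p.ratio
                                   + (rng.normal(0, sigma) if sigma else 0.0)),
                               1.0)
                for p in preds]

    def test_on_grid_exact_recovery(self):
        methyls = self._constellation()
        electron = np.array([10.0, -4.0, 6.0])
        obs = self._observe(methyls, electron)
        grid = GridSpec((-20, -20, -20), (20, 20, 20), 2.0)
        result = localize_spin_label(obs, methyls, PREParameters(), grid)
        assert np.allclose(result.coord, electron)
        assert result.objective < 1e-20

    def test_off_grid_within_one_step(self):
        methyls = self._constellation(seed=8)
        electron = np.array([7.3, -2.6, 4.9])
        obs = self._observe(methyls, electron)
        grid = GridSpec((-16, -16, -16), (16, 16, 16), 1.0)
        result = localize_spin_label(obs, methyls, PREParameters(), grid)
        assert np.all(np.abs(result.coord - electron) <= 1.0 + 1e-9)

    def test_too_few_observations_rejected(self):
        methyls = self._constellation(n=3)
        obs = self._observe(methyls, [5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            localize_spin_label(obs, methyls, PREParameters(),
                                GridSpec((-5, -5, -5), (5, 5, 5), 5.0))

    def test_collinear_geometry_flagged(self):
        methyls = [_methyl(i + 1, (4.0 * i, 0.0, 0.0)) for i in range(6)]
        obs = self._observe(methyls, [10.0, 3.0, 0.0])
        result = localize_spin_label(obs, methyls, PREParameters(),
                                     GridSpec((0, -6, -6), (20, 6, 6), 3.0))
        assert result.degenerate_geometry

    def test_noisy_recovery_rate(self):
        # sigma = 0.05 on 40 methyls: electron recovered within 3 A in
        # >= 90% of 50 seeds (2-A grid)
        methyls = self._constellation(n=40, seed=13)
        electron = np.array([12.0, 6.0, -8.0])
        grid = GridSpec((-18, -18, -18), (18, 18, 18), 2.0)
        hits = 0
        for seed in range(50):
            obs = self._observe(methyls, electron, sigma=0.05, seed=seed)
            result = localize_spin_label(obs, methyls, PREParameters(), grid)
            if np.linalg.norm(result.coord - electron) <= 3.0:
                hits += 1
        assert hits >= 45
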