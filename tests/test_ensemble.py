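"""Coarse-grained pool generation, Debye profiles, GA selection."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from idpprof.ensemble import (
    Conformer,
    bimodality_split,
    chi_square,
    debye_profile,
    generate_chain,
    generate_pool,
    rg_distribution_summary,
    select_subensemble_ga,
)
from idpprof.saxs import SAXSCurve
from idpprof.synth import synth_ensemble_mixture

S_GRID = np.linspace(0.01, 0.2, 40)


class TestChainGeometry:
    def test_two_residue_chain_rg(self):
        rng = np.random.default_rng(0)
        conf = generate_chain(2, rng)
        assert conf.rg == pytest.approx(1.9, abs=1e-9)  # half the 3.8 Å bond

    def test_bond_lengths_fixed(self):
        conf = generate_chain(60, np.random.default_rng(1))
        bonds = np.linalg.norm(np.diff(conf.coords, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 3.8, atol=1e-9)

    def test_excluded_volume_respected(self):
        conf = generate_chain(80, np.random.default_rng(2))
        n = len(conf.coords)
        d = pdist(conf.coords)
        idx = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
        sep = idx[:, 1] - idx[:, 0]
        assert np.all(d[sep == 2] >= 3.3 - 1e-9)
        assert np.all(d[sep >= 3] >= 8.0 - 1e-9)

    def test_pool_deterministic_under_seed(self):
        a = generate_pool(40, 5, seed=7)
        b = generate_pool(40, 5, seed=7)
        for ca, cb in zip(a.conformers, b.conformers):
            np.testing.assert_array_equal(ca.coords, cb.coords)
        assert not np.allclose(
            a.conformers[0].coords, generate_pool(40, 5, seed=8).conformers[0].coords
        )

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            generate_chain(1, np.random.default_rng(0))


class TestDebyeProfile:
    def test_coherent_limit_at_zero_angle(self):
        conf = generate_chain(30, np.random.default_rng(3))
        i = debye_profile(conf, np.array([1e-9]), form_factor=2.0, bin_width=None)
        assert i[0] == pytest.approx(4.0 * 30**2, rel=1e-6)

    def test_two_point_closed_form(self):
        conf = Conformer(coords=np.array([[0.0, 0, 0], [0, 0, 5.0]]), rg=2.5)
        s = np.array([0.001, 0.1, 0.5])
        expected = 2.0 * (1.0 + np.sin(s * 5.0) / (s * 5.0))
        np.testing.assert_allclose(
            debye_profile(conf, s, bin_width=None), expected, rtol=1e-12
        )

    def test_rigid_motion_invariance(self):
        conf = generate_chain(50, np.random.default_rng(4))
        i_ref = debye_profile(conf, S_GRID, bin_width=None)
        rng = np.random.default_rng(5)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        moved = Conformer(coords=conf.coords @ R.T + np.array([10.0, -3.0, 7.0]),
                          rg=conf.rg)
        i_moved = debye_profile(moved, S_GRID, bin_width=None)
        np.testing.assert_allclose(i_moved, i_ref, rtol=1e-8)

    def test_binned_approximation_close_to_exact(self):
        conf = generate_chain(60, np.random.default_rng(6))
        exact = debye_profile(conf, S_GRID, bin_width=None)
        binned = debye_profile(conf, S_GRID, bin_width=0.5)
        np.testing.assert_allclose(binned, exact, rtol=2e-3)

    def test_profile_guinier_matches_coordinate_rg(self):
        conf = generate_chain(100, np.random.default_rng(8))
        s = np.linspace(0.002, 0.8 / conf.rg, 60)
        i = debye_profile(conf, s, bin_width=None)
        from idpprof.saxs import guinier_fit

        fit = guinier_fit(SAXSCurve(s, i, 0.01 * i), srg_cutoff=0.8)
        assert fit.rg == pytest.approx(conf.rg, rel=0.02)


class TestChiSquare:
    def make_data(self, model, sigma_frac=0.02, seed=0, noisy=True):
        sigma = sigma_frac * model
        rng = np.random.default_rng(seed)
        i = model + rng.normal(0, sigma) if noisy else model.copy()
        return SAXSCurve(S_GRID, i, sigma)

    def test_identical_curves_give_zero(self):
        model = 100.0 * np.exp(-(S_GRID**2) * 300.0) + 1.0
        data = self.make_data(model, noisy=False)
        chi2, scale = chi_square(model, data)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert scale == pytest.approx(1.0)

    def test_scale_invariance(self):
        model = 100.0 * np.exp(-(S_GRID**2) * 300.0) + 1.0
        data = self.make_data(5.0 * model, noisy=False)
        chi2, scale = chi_square(model, data)
        assert chi2 == pytest.approx(0.0, abs=1e-18)
        assert scale == pytest.approx(5.0)

    def test_matched_noise_gives_unit_chi2(self):
        # 400 points: the reduced-chi2 sampling sd is sqrt(2/399) ~ 0.07
        s = np.linspace(0.01, 0.2, 400)
        model = 100.0 * np.exp(-(s**2) * 300.0) + 1.0
        sigma = 0.02 * model
        rng = np.random.default_rng(5)
        data = SAXSCurve(s, model + rng.normal(0, sigma), sigma)
        chi2, _ = chi_square(model, data)
        assert chi2 == pytest.approx(1.0, abs=0.25)

    def test_grid_mismatch_rejected(self):
        model = np.ones(len(S_GRID) - 1)
        data = self.make_data(np.ones(len(S_GRID)), noisy=False)
        with pytest.raises(ValueError, match="grid mismatch"):
            chi_square(model, data)


@pytest.fixture(scope="module")
def small_pool():
    pool = generate_pool(40, 60, seed=9).with_profiles(S_GRID)
    return pool


class TestGASelection:
    def data_from_member(self, pool, idx, seed=0, sigma_frac=0.02):
        model = pool.profiles[idx]
        sigma = sigma_frac * model
        rng = np.random.default_rng(seed)
        return SAXSCurve(S_GRID, model + rng.normal(0, sigma), sigma)

    def test_selection_beats_pool_average(self, small_pool):
        data = self.data_from_member(small_pool, 11)
        chi2_pool, _ = chi_square(small_pool.profiles.mean(axis=0), data)
        sel = select_subensemble_ga(
            small_pool, data, ensemble_size=5, generations=20, seed=1
        )
        assert sel.chi2 <= chi2_pool

    def test_elitism_makes_best_chi2_non_increasing(self, small_pool):
        data = self.data_from_member(small_pool, 3, seed=2)
        sel = select_subensemble_ga(
            small_pool, data, ensemble_size=5, generations=30, seed=3
        )
        assert np.all(np.diff(sel.history) <= 1e-12)

    def test_zero_generations_returns_best_initial(self, small_pool):
        data = self.data_from_member(small_pool, 3, seed=2)
        sel = select_subensemble_ga(
            small_pool, data, ensemble_size=5, generations=0, seed=3
        )
        assert sel.chi2 >= 0
        assert len(sel.member_indices) == 5

    def test_profiles_required(self):
        pool = generate_pool(20, 3, seed=1)
        data = SAXSCurve(S_GRID, np.ones(len(S_GRID)), np.ones(len(S_GRID)))
        with pytest.raises(ValueError, match="profiles"):
            select_subensemble_ga(pool, data)


class TestRgSummary:
    def test_whole_pool_selection_has_zero_shift(self, small_pool):
        data = SAXSCurve(
            S_GRID,
            small_pool.profiles.mean(axis=0),
            0.01 * small_pool.profiles.mean(axis=0),
        )
        sel = select_subensemble_ga(
            small_pool, data, ensemble_size=10, generations=0, seed=0
        )
        # emulate "selection = whole pool" by overriding indices
        from idpprof.ensemble import EnsembleSelection

        full = EnsembleSelection(
            member_indices=np.arange(len(small_pool)),
            chi2=0.0,
            scale=1.0,
            rgs=small_pool.rgs,
        )
        summary = rg_distribution_summary(small_pool, full)
        assert summary["shift"] == pytest.approx(0.0, abs=1e-12)

    def test_unimodal_sample_not_flagged(self):
        rng = np.random.default_rng(1)
        values = rng.normal(30.0, 3.0, 200)
        assert not bimodality_split(values)["bimodal"]

    def test_separated_mixture_flagged_with_modes(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([
            rng.normal(25.0, 2.0, 100), rng.normal(60.0, 5.0, 100)
        ])
        split = bimodality_split(values)
        assert split["bimodal"]
        assert split["modes"][0] == pytest.approx(25.0, rel=0.1)
        assert split["modes"][1] == pytest.approx(60.0, rel=0.1)


class TestMixtureGenerator:
    def test_single_component_is_unimodal(self):
        pool, truth = synth_ensemble_mixture(
            40, (1.0,), ("coil",), 60, seed=4
        )
        assert len(pool) == 60
        assert not bimodality_split(pool.rgs)["bimodal"]

    def test_components_have_distinct_scales(self):
        pool, truth = synth_ensemble_mixture(
            60, (0.5, 0.5), ("compact", "extended"), 40, seed=5
        )
        lo, hi = truth["component_mean_rg"]
        assert hi > 1.8 * lo

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            synth_ensemble_mixture(40, (0.6, 0.6), ("compact", "coil"), 10)
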