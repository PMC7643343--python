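"""Guinier, Kratky, indirect Fourier transform and shape ratios."""

import numpy as np
import pytest

from idpprof.saxs import (
    SAXSCurve,
    guinier_fit,
    ift_pr,
    kratky_transform,
    pr_moments,
    read_dat,
    rg_rs_shape_ratio,
    scan_dmax,
    write_dat,
    _ift_design,
)
from idpprof.synth import SynthesisRecipe, sphere_pr, synth_saxs


class TestCurveValidation:
    def test_rejects_unsorted_s(self):
        s = np.array([0.01, 0.03, 0.02] + list(np.linspace(0.04, 0.2, 10)))
        with pytest.raises(ValueError):
            SAXSCurve(s, np.ones_like(s), np.ones_like(s))

    def test_rejects_nonpositive_sigma(self):
        s = np.linspace(0.01, 0.2, 12)
        with pytest.raises(ValueError):
            SAXSCurve(s, np.ones_like(s), np.zeros_like(s))

    def test_ascii_roundtrip(self, tmp_path, sphere50_curve):
        curve, _ = sphere50_curve
        path = tmp_path / "c.dat"
        write_dat(curve, path, header="test curve")
        back = read_dat(path)
        np.testing.assert_allclose(back.s, curve.s, rtol=1e-5)
        np.testing.assert_allclose(back.i, curve.i, rtol=1e-5)

    def test_nm_header_converts_grid(self, tmp_path):
        path = tmp_path / "nm.dat"
        s_nm = np.linspace(0.1, 2.0, 20)
        lines = ["# s in 1/nm"] + [f"{s} 1.0 0.01" for s in s_nm]
        path.write_text("\n".join(lines))
        curve = read_dat(path)
        np.testing.assert_allclose(curve.s, s_nm / 10.0)


class TestGuinier:
    def test_exact_gaussian_inverts_closed_form(self):
        s = np.linspace(0.004, 0.06, 120)
        i = 7.0 * np.exp(-(s**2) * 50.0**2 / 3.0)
        fit = guinier_fit(SAXSCurve(s, i, 0.01 * i))
        assert fit.rg == pytest.approx(50.0, rel=1e-6)
        assert fit.i0 == pytest.approx(7.0, rel=1e-6)

    def test_sphere_recovery_tight_window(self):
        """At s*Rg <= 0.5, on a grid that samples the low-angle region,
        the Guinier approximation holds to < 0.5%."""
        s = np.linspace(0.002, 0.213, 500)
        curve, truth = synth_saxs(
            SynthesisRecipe("sphere", {"radius": 50.0}, s_grid=s)
        )
        fit = guinier_fit(curve, srg_cutoff=0.5)
        assert fit.rg == pytest.approx(truth["rg"], rel=5e-3)

    def test_sphere_recovery_default_window(self, sphere50_curve):
        """The conventional 1.3 cutoff carries a known percent-level bias."""
        curve, truth = sphere50_curve
        fit = guinier_fit(curve)
        assert fit.rg == pytest.approx(truth["rg"], rel=0.03)

    def test_debye_chain_recovery(self, debye52_curve):
        curve, truth = debye52_curve
        fit = guinier_fit(curve, srg_cutoff=0.8)
        assert fit.rg == pytest.approx(truth["rg"], rel=0.03)

    def test_window_respects_cutoff(self, sphere50_curve):
        curve, _ = sphere50_curve
        fit = guinier_fit(curve, srg_cutoff=1.0)
        assert fit.srg_max <= 1.0 + 0.05
        assert fit.n_points >= 5

    def test_nonpositive_intensities_dropped_with_warning(self):
        s = np.linspace(0.01, 0.2, 60)
        i = np.exp(-(s**2) * 900.0)
        i[-3:] = -1e-6
        with pytest.warns(UserWarning, match="non-positive"):
            fit = guinier_fit(SAXSCurve(s, i, 0.01 * np.abs(i) + 1e-9))
        assert fit.rg > 0


class TestKratky:
    def test_sphere_called_globular(self, sphere50_curve):
        curve, _ = sphere50_curve
        assert kratky_transform(curve, 1.0)[2] == "globular"

    def test_debye_chain_called_disordered(self, debye52_curve):
        curve, _ = debye52_curve
        assert kratky_transform(curve, 1.0)[2] == "disordered"

    def test_flat_curve_called_disordered(self):
        s = np.linspace(0.01, 0.2, 50)
        curve = SAXSCurve(s, np.ones_like(s), 0.01 * np.ones_like(s))
        assert kratky_transform(curve, 1.0)[2] == "disordered"

    def test_gaussian_peak_position_analytic(self):
        """s^2*exp(-s^2 rg^2/3) peaks at s = sqrt(3)/rg."""
        rg = 40.0
        s = np.linspace(0.005, 0.2, 2000)
        i = np.exp(-(s**2) * rg**2 / 3.0)
        curve = SAXSCurve(s, i, 0.01 * i)
        ss, y, _ = kratky_transform(curve, 1.0)
        assert ss[np.argmax(y)] == pytest.approx(np.sqrt(3.0) / rg, rel=5e-3)


class TestIFT:
    def test_sphere_pr_matches_closed_form(self, sphere50_curve):
        curve, _ = sphere50_curve
        pr = ift_pr(curve, 100.0)
        truth = sphere_pr(pr.r, 50.0)
        p_norm = pr.p / np.trapezoid(pr.p, pr.r)
        t_norm = truth / np.trapezoid(truth, pr.r)
        assert np.max(np.abs(p_norm - t_norm)) < 0.02 * t_norm.max()
        assert pr.rg == pytest.approx(np.sqrt(3.0 / 5.0) * 50.0, rel=0.01)

    def test_endpoints_clamped(self, sphere50_curve):
        curve, _ = sphere50_curve
        pr = ift_pr(curve, 100.0)
        assert pr.p[0] == 0.0 and pr.p[-1] == 0.0

    def test_rg_second_moment_identity(self, sphere50_curve):
        """The reported Rg is exactly the quadrature second moment."""
        curve, _ = sphere50_curve
        pr = ift_pr(curve, 100.0)
        p = np.clip(pr.p, 0.0, None)
        _, rg = pr_moments(pr.r, p)
        assert pr.rg == pytest.approx(rg, rel=1e-12)

    def test_forward_transform_reproduces_noisy_data(self, lab_s_grid):
        """chi2 of the regularized solution stays near 1 on matched noise."""
        curve, _ = synth_saxs(
            SynthesisRecipe(
                "sphere", {"radius": 50.0}, noise_fraction=0.02, seed=7,
                s_grid=lab_s_grid,
            )
        )
        pr = ift_pr(curve, 100.0)
        assert pr.chi2 <= 1.5

    def test_zero_dmax_rejected(self, sphere50_curve):
        with pytest.raises(ValueError):
            ift_pr(sphere50_curve[0], 0.0)

    def test_guinier_and_pr_rg_agree(self, sphere50_curve, debye52_curve):
        curve, _ = sphere50_curve
        gf = guinier_fit(curve, srg_cutoff=0.65)
        pr = ift_pr(curve, 100.0)
        assert pr.rg == pytest.approx(gf.rg, rel=0.05)

    def test_design_matrix_is_debye_quadrature(self):
        """K @ p integrates 4*pi*p(r)*sinc(sr) on the grid (trapezoid)."""
        s = np.linspace(0.01, 0.2, 30)
        r = np.linspace(0.0, 80.0, 161)
        p = np.sin(np.pi * r / 80.0) ** 2
        direct = np.array([
            4.0 * np.pi * np.trapezoid(p * np.sinc(si * r / np.pi), r)
            for si in s
        ])
        np.testing.assert_allclose(_ift_design(s, r) @ p, direct, rtol=1e-10)


class TestDmaxScan:
    def test_sphere_scan_selects_true_diameter(self, sphere50_curve):
        curve, _ = sphere50_curve
        assert scan_dmax(curve, [80.0, 100.0, 120.0, 160.0]).dmax == 100.0

    def test_single_candidate_returned(self, sphere50_curve):
        assert scan_dmax(sphere50_curve[0], [110.0]).dmax == 110.0

    def test_noisy_sphere_stays_near_truth(self, lab_s_grid):
        curve, _ = synth_saxs(
            SynthesisRecipe(
                "sphere", {"radius": 50.0}, noise_fraction=0.02, seed=42,
                s_grid=lab_s_grid,
            )
        )
        sel = scan_dmax(curve, [80.0, 90.0, 100.0, 110.0, 120.0, 160.0])
        assert 90.0 <= sel.dmax <= 110.0


class TestShapeRatio:
    @pytest.mark.parametrize(
        "rg, rs, label, ratio",
        [
            (54.1, 44.7, "intermediate", 1.2),  # expanded but bent chain
            (72.4, 44.7, "prolate", 1.62),
            (38.9, 50.0, "sphere-like", 0.778),
            (46.5, 50.0, "oblate", 0.93),
            (120.0, 50.0, "extended", 2.4),
        ],
    )
    def test_interval_labels(self, rg, rs, label, ratio):
        result = rg_rs_shape_ratio(rg, rs)
        assert result.label == label
        assert round(result.ratio, 1) == round(ratio, 1)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            rg_rs_shape_ratio(-1.0, 10.0)
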