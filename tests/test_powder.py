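import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidorder import (
    CSAComponent,
    OrientationDistribution,
    QuadComponent,
    apply_lorentzian_broadening,
    chain_to_quad_components,
    compose,
    composition,
    composition_to_phosphorus_components,
    csa_axis,
    csa_powder_subspectrum,
    effective_delta_sigma,
    orientation_weights,
    p31_param_table,
    quad_axis,
    quad_powder_subspectrum,
)
from lipidorder.spectra_io import Spectrum

from _oracles import brute_force_csa_hist, brute_force_quad_hist, rebin_spectrum


class TestOrientationWeights:
    def test_sphere_is_sine_weighted(self):
        dist = OrientationDistribution(epsilon=0.0, n_angles=1000)
        theta, w = orientation_weights(dist)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(w) == len(w) - 1  # max at 90 degrees
        expected = np.sin(np.radians(theta))
        np.testing.assert_allclose(w / w.sum(), expected / expected.sum(), rtol=1e-12)

    def test_prolate_deformation_depletes_zero_degree_edge(self):
        sphere = OrientationDistribution(0.0, 1000)
        prolate = OrientationDistribution(0.3, 1000)
        _, w0 = orientation_weights(sphere)
        _, w1 = orientation_weights(prolate)
        assert w1[0] / w0[0] < 1.0

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            OrientationDistribution(epsilon=-0.1)


class TestEffectiveDeltaSigma:
    def test_second_legendre_endpoints(self):
        assert effective_delta_sigma(-60.0, 0.0) == pytest.approx(-60.0)
        assert effective_delta_sigma(-60.0, 90.0) == pytest.approx(30.0)

    def test_magic_angle_nulls_anisotropy(self):
        assert abs(effective_delta_sigma(-60.0, 54.7356)) < 1e-6 * 60.0

    def test_tilt_out_of_range(self):
        with pytest.raises(ValueError):
            effective_delta_sigma(-60.0, 95.0)


class TestQuadSubspectrum:
    def test_zero_splitting_is_central_line(self, sphere):
        comp = QuadComponent(0.0, weight=1.0, linewidth=0.0)
        sp = quad_powder_subspectrum(comp, sphere, quad_axis(10.0, n=512))
        assert abs(sp.axis[np.argmax(sp.intensity)]) < 2 * sp.dx
        assert sp.integral() == pytest.approx(1.0, rel=1e-3)

    def test_edges_and_shoulders(self, sphere):
        s = 29.4
        comp = QuadComponent(s, weight=2.0, linewidth=0.0)
        sp = quad_powder_subspectrum(comp, sphere, quad_axis(s, n=4096))
        pos = sp.axis > 0
        horn = sp.axis[pos][np.argmax(sp.intensity[pos])]
        assert horn == pytest.approx(s / 2.0, abs=2 * sp.dx)  # horns split by s
        support = sp.axis[sp.intensity > 1e-9 * sp.intensity.max()]
        assert support.max() == pytest.approx(s, abs=2 * sp.dx)  # shoulder at s

    def test_symmetric_and_conserves_weight(self, sphere):
        comp = QuadComponent(25.0, weight=3.0, linewidth=150.0)
        sp = quad_powder_subspectrum(comp, sphere, quad_axis(25.0, n=2048))
        np.testing.assert_allclose(sp.intensity, sp.intensity[::-1], atol=1e-9 * sp.intensity.max())
        assert sp.integral() == pytest.approx(3.0, rel=1e-3)

    def test_narrow_grid_rejected(self, sphere):
        comp = QuadComponent(29.4, weight=1.0)
        with pytest.raises(ValueError, match="too narrow"):
            quad_powder_subspectrum(comp, sphere, quad_axis(20.0))

    def test_rigid_bound_enforced(self):
        with pytest.raises(ValueError, match="rigid limit"):
            QuadComponent(130.0, weight=1.0)


class TestCSASubspectrum:
    def test_edge_positions(self, sphere):
        comp = CSAComponent(-47.0, -1.0, linewidth=0.0)
        sp = csa_powder_subspectrum(comp, sphere, csa_axis([comp], n=4096))
        perp = sp.axis[np.argmax(sp.intensity)]
        assert perp == pytest.approx(-1.0 + 47.0 / 3.0, abs=2 * sp.dx)  # 14.667
        support = sp.axis[sp.intensity > 1e-9 * sp.intensity.max()]
        assert support.min() == pytest.approx(-1.0 - 2 * 47.0 / 3.0, abs=2 * sp.dx)
        assert support.max() - support.min() == pytest.approx(47.0, abs=4 * sp.dx)

    def test_isotropic_component_is_singlet(self, sphere):
        comp = CSAComponent(0.0, delta_iso=-1.0, linewidth=0.0)
        sp = csa_powder_subspectrum(comp, sphere, np.linspace(-20, 20, 512))
        assert sp.axis[np.argmax(sp.intensity)] == pytest.approx(-1.0, abs=2 * sp.dx)

    def test_first_moment_is_isotropic_shift(self, sphere):
        comp = CSAComponent(-47.0, -1.0, linewidth=0.0)
        sp = csa_powder_subspectrum(comp, sphere, csa_axis([comp], n=4096))
        assert sp.first_moment() == pytest.approx(-1.0, abs=0.02)

    def test_narrow_grid_rejected(self, sphere):
        comp = CSAComponent(-47.0, -1.0)
        with pytest.raises(ValueError, match="too narrow"):
            csa_powder_subspectrum(comp, sphere, np.linspace(-20, 20, 512))


class TestOracleEquivalence:
    """Implemented lineshapes vs brute-force orientation histograms."""

    @pytest.mark.parametrize("epsilon", [0.0, 0.3])
    def test_quad_matches_histogram(self, epsilon):
        dist = OrientationDistribution(epsilon=epsilon, n_angles=4096)
        s = 29.4
        axis = quad_axis(s, n=8192)
        comp = QuadComponent(s, weight=1.0, linewidth=0.0)
        sp = quad_powder_subspectrum(comp, dist, axis)
        edges = np.linspace(axis[0], axis[-1], 257)
        impl = rebin_spectrum(sp.axis, sp.intensity, edges)
        oracle = brute_force_quad_hist(s, epsilon, edges, n_samples=1_000_000)
        assert np.abs(impl / impl.sum() - oracle / oracle.sum()).sum() < 0.01

    def test_csa_matches_histogram(self):
        dist = OrientationDistribution(epsilon=0.0, n_angles=4096)
        comp = CSAComponent(-47.0, -1.0, linewidth=0.0)
        axis = csa_axis([comp], n=8192)
        sp = csa_powder_subspectrum(comp, dist, axis)
        edges = np.linspace(axis[0], axis[-1], 257)
        impl = rebin_spectrum(sp.axis, sp.intensity, edges)
        oracle = brute_force_csa_hist(-47.0, -1.0, 0.0, edges, n_samples=1_000_000)
        assert np.abs(impl / impl.sum() - oracle / oracle.sum()).sum() < 0.01


class TestBroadening:
    def test_zero_lb_is_identity(self, popc_quad_spectrum):
        _, sp = popc_quad_spectrum
        out = apply_lorentzian_broadening(sp, 0.0)
        np.testing.assert_array_equal(out.intensity, sp.intensity)

    def test_delta_input_becomes_lorentzian_of_fwhm(self):
        axis = np.linspace(-10.0, 10.0, 4001)
        y = np.zeros(4001)
        y[2000] = 1.0
        sp = Spectrum(axis, y, "2H", 76.0)
        out = apply_lorentzian_broadening(sp, 300.0)
        half = out.intensity.max() / 2.0
        above = out.axis[out.intensity >= half]
        assert above.max() - above.min() == pytest.approx(0.3, rel=0.05)  # 300 Hz

    @given(lb=st.floats(min_value=10.0, max_value=300.0),
           s=st.floats(min_value=5.0, max_value=60.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_integral_conserved(self, lb, s):
        dist = OrientationDistribution(n_angles=512)
        comp = QuadComponent(s, weight=2.0, linewidth=0.0)
        sp = quad_powder_subspectrum(comp, dist, quad_axis(s, n=1024))
        out = apply_lorentzian_broadening(sp, lb)
        assert out.integral() == pytest.approx(sp.integral(), rel=1e-3)

    def test_non_uniform_grid_rejected(self):
        axis = np.sort(np.concatenate([np.linspace(-10, 10, 100), [10.5]]))
        sp = Spectrum(axis, np.ones(axis.size), "2H", 76.0)
        with pytest.raises(ValueError, match="uniform"):
            apply_lorentzian_broadening(sp, 100.0)


class TestCompositionExpansion:
    @pytest.mark.parametrize("name, n", [("NER", 7), ("MV1", 7), ("POPC", 1)])
    def test_component_counts(self, name, n):
        comps = composition_to_phosphorus_components(
            composition(name), p31_param_table(name)
        )
        assert len(comps) == n
        assert sum(c.weight for c in comps) == pytest.approx(1.0)

    def test_pip2_contributes_three_environments(self):
        comps = composition_to_phosphorus_components(
            composition("POPC/PIP2"), p31_param_table("POPC/PIP2")
        )
        pip2 = [c for c in comps if c.label.startswith("PIP2")]
        assert len(pip2) == 3
        assert len(comps) == 4

    def test_missing_parameter_row_names_label(self):
        params = p31_param_table("NER")
        params = params[params["label"] != "PIP2_5"]
        with pytest.raises(KeyError, match="PIP2_5"):
            composition_to_phosphorus_components(composition("NER"), params)

    def test_cholesterol_contributes_no_phosphate(self):
        weights = composition("POPC/Chol").phosphate_weights()
        assert set(weights) == {"PC"}
        assert weights["PC"] == pytest.approx(1.0)


class TestChainExpansion:
    def test_perdeuterated_palmitoyl_gives_15_groups(self):
        profile = {k: 30.0 - k for k in range(2, 17)}
        comps = chain_to_quad_components("palmitoyl-d31", profile)
        assert len(comps) == 15
        assert sum(c.weight for c in comps) == pytest.approx(31.0)
        methyl = [c for c in comps if c.label == "k16"]
        assert methyl[0].weight == pytest.approx(3.0)

    def test_plateau_group_merges_to_weight_18(self):
        comps = chain_to_quad_components(
            "palmitoyl-d31",
            {"plateau": 29.4, **{k: 25.0 - k for k in range(11, 17)}},
        )
        plateau = [c for c in comps if c.label == "k2-10"][0]
        assert plateau.weight == pytest.approx(18.0)  # 9 CD2 groups

    def test_single_position_chain(self):
        comps = chain_to_quad_components("C16-d3", {16: 3.6})
        assert len(comps) == 1
        assert comps[0].weight == pytest.approx(3.0)

    def test_unknown_chain_and_missing_positions(self):
        with pytest.raises(KeyError, match="unknown chain"):
            chain_to_quad_components("oleoyl-d33", {2: 10.0})
        with pytest.raises(ValueError, match="no splitting"):
            chain_to_quad_components("palmitoyl-d31", {"plateau": 29.4})


class TestCompose:
    def test_single_component_equals_broadened_subspectrum(self, sphere):
        comp = QuadComponent(20.0, weight=2.0, linewidth=100.0)
        axis = quad_axis(20.0, n=1024)
        a = compose([comp], sphere, 0.0, axis)
        b = quad_powder_subspectrum(comp, sphere, axis)
        np.testing.assert_allclose(a.intensity, b.intensity, atol=1e-12)

    def test_linearity_in_weights(self, sphere):
        axis = quad_axis(20.0, n=1024)
        one = QuadComponent(20.0, weight=2.0, linewidth=100.0)
        halves = [QuadComponent(20.0, weight=1.0, linewidth=100.0)] * 2
        np.testing.assert_allclose(
            compose(halves, sphere, 50.0, axis).intensity,
            compose([one], sphere, 50.0, axis).intensity,
            rtol=1e-10,
        )

    def test_mixed_nuclei_rejected(self, sphere):
        with pytest.raises(ValueError, match="mix"):
            compose(
                [QuadComponent(20.0, 1.0), CSAComponent(-47.0)],
                sphere, 0.0, quad_axis(60.0),
            )

    def test_superposition_breadth_and_integral(self, sphere):
        comps = composition_to_phosphorus_components(
            composition("MV1"), p31_param_table("MV1")
        )
        axis = csa_axis(comps, n=2048, margin=0.35)
        total = compose(comps, sphere, 100.0, axis)
        widest = max(comps, key=lambda c: abs(c.delta_sigma))
        sub = csa_powder_subspectrum(widest, sphere, axis)
        thresh = 0.01
        def breadth(sp):
            sel = sp.axis[sp.intensity > thresh * sp.intensity.max()]
            return sel.max() - sel.min()
        assert breadth(total) >= breadth(sub) - 2 * total.dx
        assert total.integral() == pytest.approx(sum(c.weight for c in comps), rel=1e-3)


class TestMonotonicity:
    def test_breadth_increases_with_splitting(self, sphere):
        def breadth(s):
            comp = QuadComponent(s, 1.0, linewidth=0.0)
            sp = quad_powder_subspectrum(comp, sphere, quad_axis(60.0, n=2048))
            sel = sp.axis[sp.intensity > 1e-6 * sp.intensity.max()]
            return sel.max() - sel.min()

        widths = [breadth(s) for s in (10.0, 20.0, 40.0)]
        assert widths[0] < widths[1] < widths[2]

    def test_breadth_increases_with_anisotropy(self, sphere):
        def breadth(ds):
            comp = CSAComponent(ds, 0.0, linewidth=0.0)
            sp = csa_powder_subspectrum(comp, sphere, np.linspace(-80, 50, 2048))
            sel = sp.axis[sp.intensity > 1e-6 * sp.intensity.max()]
            return sel.max() - sel.min()

        widths = [breadth(ds) for ds in (-15.0, -30.0, -60.0)]
        assert widths[0] < widths[1] < widths[2]
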