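import numpy as np
import pytest

from permeapoly.constants import ATOMIC_NUMBERS
from permeapoly.core import SystemConfiguration, Trajectory
from permeapoly.structure import (
    RDFResult,
    accessible_surface_area,
    fractional_free_volume,
    q_to_two_theta,
    rdf,
    structure_factor,
    two_theta_to_q,
    xray_form_factor,
)
from permeapoly.synthetic import lattice_frame


def single_frame_traj(frame: SystemConfiguration) -> Trajectory:
    return Trajectory(positions=frame.positions[None], boxes=frame.box,
                      elements=frame.elements, types=frame.types)


class TestRDF:
    def test_ideal_gas_is_flat(self, ideal_gas_traj):
        res = rdf(ideal_gas_traj, dr=0.2)
        sel = (res.r > 3.0) & (res.r < 10.0)
        assert abs(res.g[sel].mean() - 1.0) < 0.05

    def test_two_fixed_particles_hand_normalisation(self):
        """One pair at 5 Å in a 20 Å box: a single occupied bin whose g value
        matches the shell normalisation done by hand."""
        frame = SystemConfiguration(
            positions=[[5.0, 10.0, 10.0], [10.0, 10.0, 10.0]],
            box=[20.0] * 3, elements=["A", "A"])
        dr = 0.1
        res = rdf(single_frame_traj(frame), dr=dr)
        occupied = np.flatnonzero(res.counts > 0)
        assert len(occupied) == 1
        i = occupied[0]
        assert res.r[i] == pytest.approx(5.0, abs=dr)
        # ordered pairs: 2; ideal = n_a (n_b - 1)/V * shell = 2 * 1/8000 * shell
        edges = np.array([i * dr, (i + 1) * dr])
        shell = 4.0 / 3.0 * np.pi * (edges[1] ** 3 - edges[0] ** 3)
        expected = 2.0 / (2 * (1 / 8000.0) * shell)
        assert res.g[i] == pytest.approx(expected, rel=1e-12)

    def test_sc_lattice_first_shell(self):
        """Simple cubic, a = 4 Å: first peak at 4 Å, coordination 6."""
        frame = lattice_frame("sc", 4.0, 4)
        res = rdf(single_frame_traj(frame), dr=0.05)
        first = np.flatnonzero(res.g > 0.5)[0]
        assert res.r[first] == pytest.approx(4.0, abs=0.05)
        assert res.coordination_number(4.5) == pytest.approx(6.0, rel=0.03)

    def test_fcc_lattice_first_shell(self):
        frame = lattice_frame("fcc", 4.0, 3)
        res = rdf(single_frame_traj(frame), dr=0.05)
        first = np.flatnonzero(res.g > 0.5)[0]
        assert res.r[first] == pytest.approx(4.0 / np.sqrt(2.0), abs=0.05)
        assert res.coordination_number(3.4) == pytest.approx(12.0, rel=0.03)

    def test_normalisation_counts_pairs(self, ideal_gas_traj):
        """∫ ρ g 4πr² dr up to L/2 approximates the pair count per particle."""
        res = rdf(ideal_gas_traj, dr=0.1)
        integral = np.sum(res.rho_b * res.g * 4 * np.pi * res.r**2) * res.dr
        # expected ordered partners within the L/2 sphere
        expected = res.rho_b * 4.0 / 3.0 * np.pi * (res.r[-1] + res.dr / 2) ** 3
        assert integral == pytest.approx(expected, rel=0.05)

    def test_r_max_beyond_half_box_rejected(self, ideal_gas_traj):
        with pytest.raises(ValueError):
            rdf(ideal_gas_traj, r_max=16.0)


class TestStructureFactor:
    def test_ideal_gas_unity(self):
        """g ≡ 1 gives S(q) = 1 identically."""
        r = np.arange(0.025, 10.0, 0.05)
        res_rdf = RDFResult(r=r, g=np.ones_like(r), counts=np.ones_like(r),
                            rho_a=0.01, rho_b=0.01, n_a=100, n_b=100, dr=0.05)
        q = np.linspace(0.5, 15.0, 40)
        sf = structure_factor({("C", "C"): res_rdf}, {"C": 1.0}, 0.01, q)
        assert np.allclose(sf.total, 1.0, atol=1e-12)

    def test_matches_debye_double_sum(self):
        """Random N = 60 single-element frame: FT of the binned g equals the
        minimum-image Debye sum with the same Lorch damping and r-truncation."""
        rng = np.random.default_rng(0)
        n, box = 60, 12.0
        pos = rng.random((n, 3)) * box
        traj = Trajectory(positions=pos[None], boxes=np.array([box] * 3),
                          elements=np.full(n, "C", dtype=object))
        dr = 0.02
        g = rdf(traj, dr=dr)
        rho = n / box**3
        q = np.linspace(1.0, 8.0, 25)
        sf = structure_factor({("C", "C"): g}, {"C": 1.0}, rho, q,
                              form_factors={"C": np.ones_like(q)})
        r_max = g.r[-1] + dr / 2
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.round(d / box)
        rij = np.sqrt((d**2).sum(-1))[np.triu_indices(n, 1)]
        rij = rij[rij <= r_max]
        w = np.sinc(rij / r_max)  # Lorch damping
        rr = np.linspace(0.0, r_max, 4000)
        wr = np.sinc(rr / r_max)
        oracle = []
        for qi in q:
            pair = 2.0 / n * np.sum(w * np.sin(qi * rij) / (qi * rij))
            background = 4 * np.pi * rho / qi * np.trapezoid(
                rr * np.sin(qi * rr) * wr, rr)
            oracle.append(1.0 + pair - background)
        assert np.max(np.abs(sf.total - np.array(oracle))) < 0.02

    def test_equal_form_factors_reduce_to_single_species(self):
        """Splitting one element into two labels with identical f(q) leaves
        the X-ray total unchanged."""
        rng = np.random.default_rng(4)
        n, box = 40, 10.0
        pos = rng.random((n, 3)) * box
        labels = np.array(["A"] * 25 + ["B"] * 15, dtype=object)
        traj_mixed = Trajectory(positions=pos[None], boxes=np.array([box] * 3),
                                elements=labels)
        traj_one = Trajectory(positions=pos[None], boxes=np.array([box] * 3),
                              elements=np.full(n, "A", dtype=object))
        dr = 0.05
        q = np.linspace(1.0, 6.0, 15)
        f_flat = np.full_like(q, 3.7)
        rdfs_mixed = {}
        for pair in [("A", "A"), ("A", "B"), ("B", "B")]:
            rdfs_mixed[pair] = rdf(traj_mixed, pair[0], pair[1], dr=dr)
        sf_mixed = structure_factor(
            rdfs_mixed, {"A": 25 / 40, "B": 15 / 40}, n / box**3, q,
            form_factors={"A": f_flat, "B": f_flat})
        sf_one = structure_factor(
            {("A", "A"): rdf(traj_one, dr=dr)}, {"A": 1.0}, n / box**3, q,
            form_factors={"A": f_flat})
        assert np.allclose(sf_mixed.total, sf_one.total, atol=5e-3)

    def test_missing_pair_rdf_raises(self):
        r = np.arange(0.05, 5.0, 0.1)
        g = RDFResult(r=r, g=np.ones_like(r), counts=r, dr=0.1)
        with pytest.raises(KeyError, match="missing pair"):
            structure_factor({("C", "C"): g}, {"C": 0.5, "O": 0.5}, 0.01,
                             np.array([1.0]))

    def test_q_weighted_view(self):
        r = np.arange(0.05, 5.0, 0.1)
        g = RDFResult(r=r, g=np.ones_like(r), counts=r, dr=0.1)
        q = np.array([1.0, 2.0])
        sf = structure_factor({("C", "C"): g}, {"C": 1.0}, 0.01, q)
        assert np.allclose(sf.q_weighted, q * sf.total)


class TestFormFactors:
    @pytest.mark.parametrize("element", ["H", "C", "O"])
    def test_f0_equals_atomic_number(self, element):
        assert xray_form_factor(element, 0.0) == pytest.approx(
            ATOMIC_NUMBERS[element], abs=0.01)

    @pytest.mark.parametrize("element", ["H", "C", "O"])
    def test_monotone_decreasing(self, element):
        q = np.linspace(0.0, 10.0, 400)
        f = xray_form_factor(element, q)
        assert np.all(np.diff(f) < 0)

    def test_unknown_element_raises(self):
        with pytest.raises(KeyError):
            xray_form_factor("Zz", 1.0)


class TestAngleConversion:
    def test_zero_and_known_value(self):
        assert q_to_two_theta(0.0) == 0.0
        # q = 1.63 Å⁻¹ with Cu Kα (1.5406 Å): 2θ = 2 asin(qλ/4π) = 23.06°
        assert q_to_two_theta(1.63, 1.5406) == pytest.approx(23.055, abs=0.01)

    def test_round_trip_identity(self):
        for tt in (5.0, 23.8, 60.0):
            assert two_theta_to_q(q_to_two_theta(two_theta_to_q(tt))) == \
                pytest.approx(two_theta_to_q(tt), rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            q_to_two_theta(10.0, 3.0)


class TestFreeVolume:
    def test_empty_box_is_all_free(self):
        frame = SystemConfiguration(positions=np.empty((0, 3)), box=[10.0] * 3)
        ffv, se = fractional_free_volume(frame, 0.0, 1000, seed=1)
        assert ffv == 1.0

    def test_single_sphere_analytic(self):
        """One r = 2 Å sphere in a 10 Å cube: FFV = 1 − (4π/3)8/1000."""
        frame = SystemConfiguration(positions=[[5.0, 5.0, 5.0]], box=[10.0] * 3,
                                    elements=["S"])
        n = 200000
        ffv, se = fractional_free_volume(frame, 0.0, n, seed=2,
                                         radii={"S": 2.0})
        exact = 1.0 - 4.0 * np.pi / 3.0 * 8.0 / 1000.0
        assert ffv == pytest.approx(exact, abs=3 * max(se, 1e-4))

    def test_huge_probe_blocks_everything(self):
        frame = SystemConfiguration(positions=[[5.0, 5.0, 5.0]], box=[10.0] * 3,
                                    elements=["S"])
        ffv, _ = fractional_free_volume(frame, 20.0, 2000, seed=3,
                                        radii={"S": 2.0})
        assert ffv == 0.0

    def test_monotone_in_probe_radius(self):
        rng = np.random.default_rng(9)
        frame = SystemConfiguration(positions=rng.random((20, 3)) * 15.0,
                                    box=[15.0] * 3,
                                    elements=np.full(20, "C", dtype=object))
        vals = [fractional_free_volume(frame, pr, 20000, seed=5)[0]
                for pr in (0.0, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestSurfaceArea:
    def test_isolated_sphere_exact(self):
        frame = SystemConfiguration(positions=[[10.0] * 3], box=[20.0] * 3,
                                    elements=["S"])
        asa, se = accessible_surface_area(frame, 0.0, 200, seed=1,
                                          radii={"S": 2.0})
        assert asa == pytest.approx(4.0 * np.pi * 4.0, rel=1e-12)
        assert se == 0.0

    def test_two_overlapping_spheres_cap_formula(self):
        """Two equal spheres (R) at distance d < 2R: ASA = 4πR² + 2πRd."""
        R, d = 2.0, 1.5
        frame = SystemConfiguration(
            positions=[[8.0, 10.0, 10.0], [8.0 + d, 10.0, 10.0]],
            box=[20.0] * 3, elements=["S", "S"])
        n_pts = 20000
        asa, se = accessible_surface_area(frame, 0.0, n_pts, seed=4,
                                          radii={"S": R})
        exact = 4.0 * np.pi * R**2 + 2.0 * np.pi * R * d
        assert asa == pytest.approx(exact, abs=max(4 * se, 0.05 * exact))

    def test_probe_inflation_equals_inflated_hard_radii(self):
        rng = np.random.default_rng(11)
        frame = SystemConfiguration(positions=rng.random((6, 3)) * 12.0,
                                    box=[12.0] * 3,
                                    elements=np.full(6, "C", dtype=object))
        a1, _ = accessible_surface_area(frame, 1.0, 400, seed=6,
                                        radii={"C": 1.7})
        a2, _ = accessible_surface_area(frame, 0.0, 400, seed=6,
                                        radii={"C": 2.7})
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_monotone_in_probe_for_fixed_pair(self):
        frame = SystemConfiguration(
            positions=[[5.0, 5.0, 5.0], [7.5, 5.0, 5.0]],
            box=[20.0] * 3, elements=["C", "C"])
        # exposed *fraction* of each sphere shrinks as the probe grows
        fracs = []
        for pr in (0.0, 0.8, 1.6):
            asa, _ = accessible_surface_area(frame, pr, 5000, seed=7)
            r_infl = 1.7 + pr
            fracs.append(asa / (2 * 4 * np.pi * r_infl**2))
        assert all(a >= b - 1e-9 for a, b in zip(fracs, fracs[1:]))
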