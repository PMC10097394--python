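import numpy as np
import pytest
from scipy.integrate import quad

from permeapoly.core import SystemConfiguration
from permeapoly.energy import (
    NonbondedParams,
    cohesive_energy,
    pair_energy,
    tail_correction,
    total_potential_energy,
)


def two_type_params(lj_form="12-6", combining="lorentz_berthelot", cutoff=3.9,
                    qa=0.0, qb=0.0):
    return NonbondedParams(
        types={"A": {"sigma": 1.2, "epsilon": 0.4, "charge": qa},
               "B": {"sigma": 1.0, "epsilon": 0.2, "charge": qb}},
        lj_form=lj_form, combining=combining, cutoff=cutoff,
    )


class TestPairEnergy:
    def test_lj126_zero_crossing_and_minimum(self):
        p = NonbondedParams(types={"A": {"sigma": 2.0, "epsilon": 0.7}}, cutoff=12.0)
        assert pair_energy(2.0, "A", "A", p) == pytest.approx(0.0, abs=1e-14)
        assert pair_energy(2.0 * 2 ** (1 / 6), "A", "A", p) == pytest.approx(-0.7)

    def test_lj96_minimum_at_r0(self):
        p = NonbondedParams(types={"A": {"sigma": 2.5, "epsilon": 0.3}},
                            lj_form="9-6", cutoff=12.0)
        # substituting r = r0 gives eps*(2 - 3) = -eps
        assert pair_energy(2.5, "A", "A", p) == pytest.approx(-0.3)

    @pytest.mark.parametrize("combining", ["lorentz_berthelot", "sixth_power"])
    @pytest.mark.parametrize("lj_form", ["12-6", "9-6"])
    def test_pair_symmetry(self, combining, lj_form):
        p = two_type_params(lj_form=lj_form, combining=combining, qa=0.2, qb=-0.1)
        for r in (0.9, 1.3, 2.7):
            assert pair_energy(r, "A", "B", p) == pair_energy(r, "B", "A", p)

    def test_zero_beyond_cutoff_and_singularity(self):
        p = two_type_params(cutoff=3.0)
        assert pair_energy(3.5, "A", "B", p) == 0.0
        with pytest.raises(ValueError):
            pair_energy(0.0, "A", "A", p)

    def test_coulomb_term(self):
        p = NonbondedParams(
            types={"A": {"sigma": 1.0, "epsilon": 0.0, "charge": 1.0}},
            cutoff=50.0)
        # pure Coulomb between unit charges: k_e / r
        assert pair_energy(10.0, "A", "A", p) == pytest.approx(138.935457644382)


class TestTailCorrection:
    def test_zero_epsilon_gives_zero(self):
        p = NonbondedParams(types={"A": {"sigma": 1.0, "epsilon": 0.0}}, cutoff=3.0)
        assert tail_correction(p, {"A": 0.05}, 1000.0) == 0.0

    @pytest.mark.parametrize("lj_form", ["12-6", "9-6"])
    def test_matches_quadrature_oracle(self, lj_form):
        p = NonbondedParams(types={"A": {"sigma": 1.2, "epsilon": 0.4}},
                            lj_form=lj_form, cutoff=3.0)
        rho, vol = 0.02, 1000.0
        integral, _ = quad(
            lambda r: pair_energy(r, "A", "A", p, apply_cutoff=False) * r * r,
            3.0, np.inf)
        oracle = 2.0 * np.pi * vol * rho**2 * integral
        assert tail_correction(p, {"A": rho}, vol) == pytest.approx(oracle, rel=1e-9)

    def test_single_type_126_closed_form(self):
        p = NonbondedParams(types={"A": {"sigma": 1.1, "epsilon": 0.5}}, cutoff=4.0)
        rho, vol = 0.03, 500.0
        s, e, rc = 1.1, 0.5, 4.0
        closed = 8 * np.pi * rho**2 * vol * e * s**3 * (
            (s / rc) ** 9 / 9.0 - (s / rc) ** 3 / 3.0)
        assert tail_correction(p, {"A": rho}, vol) == pytest.approx(closed, rel=1e-12)

    def test_density_doubling_quadruples(self):
        p = NonbondedParams(types={"A": {"sigma": 1.0, "epsilon": 0.3}}, cutoff=3.0)
        u1 = tail_correction(p, {"A": 0.01}, 800.0)
        u2 = tail_correction(p, {"A": 0.02}, 800.0)
        assert u2 == pytest.approx(4.0 * u1)


def brute_force_energy(frame, params):
    """O(N²) double loop with an explicit 27-image search."""
    pos, box = frame.positions, frame.box
    n = len(pos)
    shifts = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float) * box
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[j] - pos[i]
            r = min(np.linalg.norm(d + s) for s in shifts)
            if r <= params.cutoff:
                total += pair_energy(r, frame.types[i], frame.types[j], params)
    return total


class TestTotalEnergy:
    def test_dimer_at_lj_minimum(self):
        p = NonbondedParams(types={"A": {"sigma": 2.0, "epsilon": 1.3}}, cutoff=9.0)
        r_min = 2.0 * 2 ** (1 / 6)
        frame = SystemConfiguration(
            positions=[[0, 0, 0], [r_min, 0, 0]], box=[20, 20, 20],
            elements=["A", "A"])
        assert total_potential_energy(frame, p) == pytest.approx(-1.3)

    @pytest.mark.parametrize("combining", ["lorentz_berthelot", "sixth_power"])
    def test_matches_brute_force_images(self, combining):
        rng = np.random.default_rng(17)
        n, box = 15, 8.0
        frame = SystemConfiguration(
            positions=rng.random((n, 3)) * box, box=[box] * 3,
            elements=np.array(["A"] * 8 + ["B"] * 7, dtype=object))
        p = two_type_params(combining=combining, qa=0.15, qb=-0.15)
        e = total_potential_energy(frame, p)
        assert e == pytest.approx(brute_force_energy(frame, p), abs=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        frame = SystemConfiguration(
            positions=rng.random((10, 3)) * 7.0, box=[7.0] * 3,
            elements=np.full(10, "A", dtype=object))
        p = NonbondedParams(types={"A": {"sigma": 1.0, "epsilon": 0.2}}, cutoff=3.4)
        e0 = total_potential_energy(frame, p)
        shifted = SystemConfiguration(
            positions=frame.positions + np.array([1.7, -2.9, 0.4]),
            box=frame.box, elements=frame.elements)
        assert total_potential_energy(shifted, p) == pytest.approx(e0, rel=1e-12)

    def test_minimum_image_violation_raises(self):
        frame = SystemConfiguration(
            positions=[[0, 0, 0]], box=[6, 6, 6],
            elements=["A"])
        p = NonbondedParams(types={"A": {"sigma": 1.0, "epsilon": 0.1}}, cutoff=4.0)
        with pytest.raises(ValueError, match="minimum-image"):
            total_potential_energy(frame, p)

    def test_tail_flag_lowers_energy_for_attractive_fluid(self):
        rng = np.random.default_rng(5)
        frame = SystemConfiguration(
            positions=rng.random((30, 3)) * 10.0, box=[10.0] * 3,
            elements=np.full(30, "A", dtype=object))
        base = NonbondedParams(types={"A": {"sigma": 1.0, "epsilon": 0.4}}, cutoff=5.0)
        tailed = NonbondedParams(types={"A": {"sigma": 1.0, "epsilon": 0.4}},
                                 cutoff=5.0, tail=True)
        # the attractive tail integral is negative for rc > sigma
        assert total_potential_energy(frame, tailed) < total_potential_energy(frame, base)


def compact_two_chain_frame():
    """Two compact 5-atom clusters, each well inside the box (no intra-chain
    wrapping), separated by ~3 Å.  Intra-cluster spacing stays near σ so the
    energies remain well-conditioned."""
    template = np.array([[0, 0, 0], [1.6, 0, 0], [0, 1.6, 0],
                         [0, 0, 1.6], [1.6, 1.6, 0]], dtype=float)
    a = np.array([5.0, 5.0, 5.0]) + template
    b = np.array([9.5, 5.3, 5.1]) + template * 1.05
    return SystemConfiguration(
        positions=np.vstack([a, b]), box=[20.0] * 3,
        elements=np.full(10, "A", dtype=object),
        chain_ids=np.array([0] * 5 + [1] * 5))


class TestCohesiveEnergy:
    def test_single_isolated_chain_has_zero_cohesion(self):
        rng = np.random.default_rng(1)
        frame = SystemConfiguration(
            positions=5.0 + rng.random((6, 3)) * 2.0, box=[30.0] * 3,
            elements=np.full(6, "A", dtype=object),
            chain_ids=np.zeros(6, dtype=int))
        p = NonbondedParams(types={"A": {"sigma": 1.0, "epsilon": 0.3}}, cutoff=6.0)
        br = cohesive_energy(frame, p)
        assert br.e_coh == pytest.approx(0.0, abs=1e-12)
        assert br.delta_mpa05 == 0.0

    def test_matches_interchain_pair_sum_oracle(self):
        frame = compact_two_chain_frame()
        p = NonbondedParams(types={"A": {"sigma": 1.5, "epsilon": 0.5}}, cutoff=8.0)
        br = cohesive_energy(frame, p)
        inter = 0.0
        for i in range(frame.n_atoms):
            for j in range(i + 1, frame.n_atoms):
                if frame.chain_ids[i] == frame.chain_ids[j]:
                    continue
                d = frame.positions[j] - frame.positions[i]
                d -= frame.box * np.round(d / frame.box)
                r = np.linalg.norm(d)
                if r <= p.cutoff:
                    inter += pair_energy(r, "A", "A", p)
        assert br.e_coh == pytest.approx(-inter, abs=1e-9)

    def test_delta_squared_times_volume_identity(self):
        frame = compact_two_chain_frame()
        p = NonbondedParams(types={"A": {"sigma": 1.5, "epsilon": 0.5}}, cutoff=8.0)
        br = cohesive_energy(frame, p)
        if br.e_coh > 0:
            assert br.delta_mpa05**2 * br.volume_cm3_per_mol == pytest.approx(
                br.e_coh * 1e3, rel=1e-10)

    def test_ced_to_delta_arithmetic(self):
        """CED of 400 MPa corresponds to δ = 20 MPa^0.5."""
        frame = compact_two_chain_frame()
        p = NonbondedParams(types={"A": {"sigma": 1.5, "epsilon": 0.5}}, cutoff=8.0)
        br = cohesive_energy(frame, p)
        # rescale to a constructed CED of exactly 400 MPa
        scale = 400.0 / br.ced_mpa
        assert np.sqrt(br.ced_mpa * scale) == pytest.approx(20.0)


class TestParamsValidation:
    def test_rejects_bad_forms_and_values(self):
        with pytest.raises(ValueError):
            NonbondedParams(types={}, lj_form="10-4")
        with pytest.raises(ValueError):
            NonbondedParams(types={}, combining="geometric")
        with pytest.raises(ValueError):
            NonbondedParams(types={"A": {"sigma": -1.0, "epsilon": 0.1}})
        with pytest.raises(ValueError):
            NonbondedParams(types={"A": {"sigma": 1.0, "epsilon": -0.1}})

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        doc = {"lj_form": "9-6", "combining": "sixth_power", "cutoff": 10.0,
               "tail": True,
               "types": {"C_HB": {"sigma": 3.8, "epsilon": 0.25, "charge": 0.0}}}
        f = tmp_path / "ff.yaml"
        f.write_text(yaml.safe_dump(doc))
        p = NonbondedParams.from_yaml(f)
        assert p.lj_form == "9-6" and p.combining == "sixth_power"
        assert p.sigma("C_HB") == 3.8 and p.tail is True
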