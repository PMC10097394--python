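"""Synthetic fixtures with known ground truth for every estimator.

These generators stand in for molecular-dynamics trajectories and
pressure-decay apparatus output.  They make no claim of reproducing
polymer physics — each emits the simplest ensemble whose true answer is
known in closed form (or prescribed), so the downstream estimators can be
validated quantitatively:

- ideal-gas frames   → g(r) = 1, S(q) = 1, μ_ex = 0
- LJ-fluid frames    → dilute-limit βμ_ex = 2ρB₂, virial pressure
- Brownian walkers   → MSD slope 6 D_true
- perfect lattices   → RDF peaks / coordination numbers by geometry
- pressure decay     → Fickian traces from prescribed (S_true, D_true)

Every generator is deterministic for a fixed seed and records its ground
truth alongside the fixture.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BAR_TO_PA, CM3_TO_M3, R_GAS, R_GAS_KJ
from .core import SystemConfiguration, Trajectory
from .sorption import SorptionStep, crank_finite_uptake, crank_infinite_uptake

__all__ = [
    "GroundTruth",
    "ideal_gas_frames",
    "lj_fluid_frames",
    "lj_reduced_temperature_K",
    "lj_virial_pressure",
    "brownian_trajectory",
    "lattice_frame",
    "synthetic_pressure_decay",
]


@dataclass
class GroundTruth:
    """Generator provenance: name, seed and the true parameter set."""

    generator: str
    seed: int | None
    params: dict = field(default_factory=dict)


def ideal_gas_frames(n_atoms: int, box_edge: float, n_frames: int,
                     seed: int, dt_ps: float = 1.0) -> Trajectory:
    """I.i.d. uniform positions per frame: a non-interacting reference gas."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    pos = rng.random((n_frames, n_atoms, 3)) * box_edge
    traj = Trajectory(
        positions=pos,
        boxes=np.array([box_edge] * 3, dtype=float),
        dt_ps=dt_ps,
        elements=np.full(n_atoms, "X", dtype=object),
        metadata={"ground_truth": GroundTruth(
            "ideal_gas_frames", seed,
            {"n_atoms": n_atoms, "box_edge": box_edge})},
    )
    return traj


def lj_reduced_temperature_K(t_star: float) -> float:
    """Kelvin temperature at which RT (kJ/mol) equals t_star for ε = 1 kJ/mol.

    Lets reduced-unit LJ fixtures (σ = 1 Å, ε = 1 kJ/mol) be fed to the
    kelvin-based estimators with β ε = 1/T*.
    """
    return t_star / R_GAS_KJ


def lj_fluid_frames(n_atoms: int, t_star: float, rho_star: float,
                    n_frames: int, seed: int, sweeps_per_frame: int = 20,
                    burn_in_sweeps: int = 400, cutoff: float | None = None,
                    dt_ps: float = 1.0, epsilon: float = 1.0) -> Trajectory:
    """Metropolis NVT Monte Carlo of a reduced-unit LJ fluid (σ=ε=1).

    The box edge follows from L³ = N/ρ*.  Single-particle trial moves with
    the maximum displacement tuned toward ~50% acceptance during burn-in;
    frames are sampled every ``sweeps_per_frame`` sweeps afterwards.  The
    acceptance rate is stored in the metadata and a tuning warning is
    attached when it leaves [0.1, 0.9].  Energies use the truncated
    (unshifted) 12-6 potential with the stored cutoff, the same convention
    the package's insertion and energy estimators apply.
    """
    if rho_star <= 0 or t_star <= 0:
        raise ValueError("t_star and rho_star must be positive")
    edge = (n_atoms / rho_star) ** (1.0 / 3.0)
    rc = cutoff if cutoff is not None else min(edge / 2.0, 4.0)
    if rc > edge / 2.0:
        raise ValueError("cutoff exceeds half the box")
    rng = np.random.default_rng(seed)
    pos = rng.random((n_atoms, 3)) * edge
    box = np.array([edge] * 3)
    beta = 1.0 / t_star

    def particle_energy(i, xi, coords):
        d = coords - xi
        d -= box * np.round(d / box)
        r2 = np.einsum("ij,ij->i", d, d)
        r2[i] = np.inf
        r2 = r2[r2 <= rc * rc]
        inv6 = (1.0 / r2) ** 3
        return float(np.sum(4.0 * epsilon * (inv6 * inv6 - inv6)))

    max_disp = 0.3
    acc_hist = []
    frames = np.empty((n_frames, n_atoms, 3))
    total_sweeps = burn_in_sweeps + n_frames * sweeps_per_frame
    f_idx = 0
    for sweep in range(total_sweeps):
        accepted = 0
        order = rng.integers(0, n_atoms, size=n_atoms)
        disp = (rng.random((n_atoms, 3)) - 0.5) * 2.0 * max_disp
        us = rng.random(n_atoms)
        for k, i in enumerate(order):
            old = pos[i].copy()
            e_old = particle_energy(i, old, pos)
            new = (old + disp[k]) % edge
            e_new = particle_energy(i, new, pos)
            if e_new <= e_old or us[k] < np.exp(-beta * (e_new - e_old)):
                pos[i] = new
                accepted += 1
        rate = accepted / n_atoms
        acc_hist.append(rate)
        if sweep < burn_in_sweeps and (sweep + 1) % 20 == 0:
            recent = np.mean(acc_hist[-20:])
            if recent < 0.4:
                max_disp = max(max_disp * 0.8, 0.01)
            elif recent > 0.6:
                max_disp = min(max_disp * 1.2, edge / 4.0)
        if sweep >= burn_in_sweeps and (sweep - burn_in_sweeps + 1) % sweeps_per_frame == 0:
            frames[f_idx] = pos
            f_idx += 1
    frames = frames[:f_idx]
    acceptance = float(np.mean(acc_hist[burn_in_sweeps:])) if len(acc_hist) > burn_in_sweeps else float(np.mean(acc_hist))
    meta = {
        "ground_truth": GroundTruth(
            "lj_fluid_frames", seed,
            {"t_star": t_star, "rho_star": rho_star, "cutoff": rc,
             "box_edge": edge, "epsilon": epsilon}),
        "acceptance_rate": acceptance,
        "max_displacement": max_disp,
    }
    if not 0.1 <= acceptance <= 0.9:
        meta["tuning_warning"] = (
            f"acceptance rate {acceptance:.2f} outside [0.1, 0.9]; "
            "adjust the maximum displacement"
        )
    return Trajectory(
        positions=frames,
        boxes=box,
        dt_ps=dt_ps,
        elements=np.full(n_atoms, "LJ", dtype=object),
        types=np.full(n_atoms, "LJ", dtype=object),
        metadata=meta,
    )


def lj_virial_pressure(traj: Trajectory, t_star: float,
                       cutoff: float | None = None) -> float:
    """Reduced virial pressure P* = ρT* + ⟨Σ r·f⟩/(3V) of LJ frames.

    Uses the truncated 12-6 force; no tail correction.
    """
    rc = cutoff if cutoff is not None else traj.metadata.get(
        "ground_truth", GroundTruth("", None, {})).params.get("cutoff", 4.0)
    n = traj.n_atoms
    virials = []
    for fi in range(traj.n_frames):
        box = traj.boxes[fi]
        p = traj.positions[fi]
        w = 0.0
        for i in range(n - 1):
            d = p[i + 1:] - p[i]
            d -= box * np.round(d / box)
            r2 = np.einsum("ij,ij->i", d, d)
            r2 = r2[r2 <= rc * rc]
            inv6 = (1.0 / r2) ** 3
            # r·F = 24(2 x12 − x6) for 12-6
            w += float(np.sum(24.0 * (2.0 * inv6 * inv6 - inv6)))
        virials.append(w / (3.0 * np.prod(box)))
    rho = n / float(np.prod(traj.boxes[0]))
    return rho * t_star + float(np.mean(virials))


def brownian_trajectory(n_molecules: int, d_true: float, dt_ps: float,
                        n_frames: int, seed: int,
                        box_edge: float = 1000.0) -> Trajectory:
    """Independent Brownian walkers with a prescribed true diffusivity.

    Gaussian increments with per-axis variance 2 D_true dt (D_true in
    Å²/ps).  Coordinates are emitted unwrapped; the nominal box only
    provides a valid container.
    """
    if d_true <= 0:
        raise ValueError("d_true must be positive")
    rng = np.random.default_rng(seed)
    steps = rng.normal(
        scale=np.sqrt(2.0 * d_true * dt_ps),
        size=(n_frames - 1, n_molecules, 3),
    )
    start = rng.random((1, n_molecules, 3)) * box_edge
    pos = np.concatenate([start, start + np.cumsum(steps, axis=0)], axis=0)
    return Trajectory(
        positions=pos,
        boxes=np.array([box_edge] * 3),
        dt_ps=dt_ps,
        wrapped=False,
        molecule_ids=np.arange(n_molecules),
        metadata={"ground_truth": GroundTruth(
            "brownian_trajectory", seed,
            {"d_true_A2_ps": d_true, "dt_ps": dt_ps})},
    )


def lattice_frame(kind: str, a: float, n_cells: int,
                  element: str = "X") -> SystemConfiguration:
    """Perfect periodic lattice (sc or fcc) for RDF / S(q) geometry checks."""
    if n_cells < 2:
        raise ValueError("need at least 2 cells per axis")
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    grid = np.array(np.meshgrid(*[np.arange(n_cells)] * 3,
                                indexing="ij")).reshape(3, -1).T.astype(float)
    if kind == "sc":
        basis = np.array([[0.0, 0.0, 0.0]])
    elif kind == "fcc":
        basis = np.array([
            [0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5],
        ])
    else:
        raise ValueError("kind must be 'sc' or 'fcc'")
    pos = (grid[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    edge = n_cells * a
    n = len(pos)
    return SystemConfiguration(
        positions=pos,
        box=np.array([edge] * 3),
        elements=np.full(n, element, dtype=object),
        metadata={"ground_truth": GroundTruth(
            "lattice_frame", None, {"kind": kind, "a": a, "n_cells": n_cells})},
    )


def synthetic_pressure_decay(
    s_true: float,
    d_true: float,
    thickness_um: float,
    cell_volume_cm3: float,
    temperature_K: float,
    p0_bar: float,
    sample_mass_g: float,
    n_points: int = 200,
    t_max_s: float | None = None,
    noise_sd_bar: float = 0.0,
    seed: int = 0,
    kinetics: str = "finite_reservoir",
    gas: str = "",
    crystallinity: float | None = None,
) -> SorptionStep:
    """Pressure-decay trace from Fickian slab kinetics and Henry sorption.

    The equilibrium pressure solves the cell mass balance with Henry
    uptake n_eq = S_true · m · p_eq, giving p_eq = p0/(1+k) with
    k = S_true m R T / (V 10⁵); the transient follows the limited-volume
    Crank solution (or the constant-concentration series when
    ``kinetics='infinite_reservoir'``, appropriate for small depletion).
    Optional i.i.d. Gaussian pressure noise on every point after t = 0.

    S_true in mol kg⁻¹ bar⁻¹, D_true in cm²/s.
    """
    for name, v in [("s_true", s_true), ("d_true", d_true),
                    ("thickness_um", thickness_um),
                    ("cell_volume_cm3", cell_volume_cm3),
                    ("temperature_K", temperature_K), ("p0_bar", p0_bar),
                    ("sample_mass_g", sample_mass_g)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    m_kg = sample_mass_g * 1e-3
    v_m3 = cell_volume_cm3 * CM3_TO_M3
    k = s_true * m_kg * R_GAS * temperature_K / (v_m3 * BAR_TO_PA)
    frac = k / (1.0 + k)  # fraction of dosed gas ultimately absorbed
    if frac > 0.999:
        raise ValueError(
            "configuration absorbs essentially all the dosed gas "
            f"(depletion {frac:.4f}); reduce S, mass or increase the cell volume"
        )
    p_eq = p0_bar / (1.0 + k)
    ell_cm = thickness_um * 1e-4
    if t_max_s is None:
        t_max_s = 1.5 * ell_cm**2 / d_true
    t = np.linspace(0.0, t_max_s, n_points)
    if kinetics == "finite_reservoir":
        alpha = (1.0 - frac) / frac
        m_norm = crank_finite_uptake(t, d_true, thickness_um, alpha)
    elif kinetics == "infinite_reservoir":
        m_norm = crank_infinite_uptake(t, d_true, thickness_um)
    else:
        raise ValueError("kinetics must be 'finite_reservoir' or 'infinite_reservoir'")
    p = p0_bar - (p0_bar - p_eq) * m_norm
    if noise_sd_bar > 0:
        rng = np.random.default_rng(seed)
        p = p + np.concatenate([[0.0], rng.normal(0.0, noise_sd_bar, len(p) - 1)])
    return SorptionStep(
        time_s=t,
        pressure_bar=p,
        cell_volume_cm3=cell_volume_cm3,
        temperature_K=temperature_K,
        sample_mass_g=sample_mass_g,
        thickness_um=thickness_um,
        crystallinity=crystallinity,
        gas=gas,
        metadata={"ground_truth": GroundTruth(
            "synthetic_pressure_decay", seed,
            {"s_true_mol_kg_bar": s_true, "d_true_cm2_s": d_true,
             "p_eq_bar": p_eq, "absorbed_fraction": frac,
             "noise_sd_bar": noise_sd_bar, "kinetics": kinetics})},
    )
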