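"""Widom test-particle insertion: excess chemical potential and Henry
solubility of a dilute penetrant in host configurations.

A ghost copy of the gas molecule is inserted at uniformly random positions
(and, for rigid multi-site molecules, uniformly random orientations) into
each trajectory frame.  The Boltzmann factor of its interaction energy with
the host is averaged over all insertions,

    μ_ex = −RT ln ⟨exp(−ΔU/RT)⟩,

and converts to the molar-basis Henry solubility coefficient

    S = 1/(ρRT) · exp(−μ_ex/RT)   [mol kg⁻¹ Pa⁻¹],

which reduces to the ideal Henry limit at μ_ex = 0 and increases for
favourable (μ_ex < 0) insertion.  When frame volumes vary (NPT snapshots)
the volume-weighted estimator ⟨V e^{−βΔU}⟩/⟨V⟩ is used.  The host never
contains the penetrant: the infinite-dilution limit is realised by ghost
insertions only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import BAR_TO_PA, M_CH4, M_CO2, N_AVOGADRO, R_GAS, V_STP_CM3
from .core import Trajectory
from .energy import COULOMB_KJ_A, NonbondedParams, _lj

__all__ = [
    "PenetrantModel",
    "SolubilityCoefficient",
    "WidomResult",
    "default_penetrant",
    "widom_excess_mu",
    "solubility_from_mu",
    "solubility_selectivity",
    "molecules_at_pressure",
]


@dataclass(frozen=True)
class PenetrantModel:
    """Rigid multi-site gas molecule for ghost insertion.

    ``sites`` is a tuple of (offset_xyz Å, nonbonded type label) pairs with
    offsets measured from the molecular centre; parameter values for the
    site types are supplied through the host's :class:`NonbondedParams`.
    """

    name: str
    sites: tuple
    molar_mass: float  # g/mol
    rigid: bool = True

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def offsets(self) -> np.ndarray:
        return np.array([s[0] for s in self.sites], dtype=float)

    def site_types(self) -> list:
        return [s[1] for s in self.sites]


# CO2: rigid linear 3-site, C at the centre, O at ±1.16 Å (EPM2 geometry).
# CH4: single united-atom site.
_CO2 = PenetrantModel(
    "CO2",
    (((0.0, 0.0, 0.0), "C_co2"), ((0.0, 0.0, 1.16), "O_co2"), ((0.0, 0.0, -1.16), "O_co2")),
    M_CO2,
)
_CH4 = PenetrantModel("CH4", (((0.0, 0.0, 0.0), "C_ch4"),), M_CH4)


def default_penetrant(name: str) -> PenetrantModel:
    """Built-in CO₂ (rigid 3-site linear) and CH₄ (united atom) models."""
    key = name.strip().lower()
    if key == "co2":
        return _CO2
    if key == "ch4":
        return _CH4
    raise KeyError(f"no built-in penetrant named {name!r}")


@dataclass
class SolubilityCoefficient:
    """Henry solubility with unit views.

    ``mol_per_kg_bar`` is the molar-basis value used for selectivities;
    ``g_per_g_bar`` multiplies by the penetrant molar mass; the volumetric
    view needs the polymer density.
    """

    mol_per_kg_bar: float
    se: float = 0.0
    molar_mass: float = 0.0  # g/mol of the gas
    rho_kg_m3: float = 0.0  # polymer density
    basis: str = "molar"

    @property
    def g_per_g_bar(self) -> float:
        return self.mol_per_kg_bar * self.molar_mass * 1e-3

    @property
    def cm3stp_per_cm3_bar(self) -> float:
        # mol/kg/bar × cm³(STP)/mol × kg/cm³(polymer)
        return self.mol_per_kg_bar * V_STP_CM3 * self.rho_kg_m3 * 1e-6


@dataclass
class WidomResult:
    mu_ex: float  # kJ/mol
    se_mu: float  # block-averaged standard error, kJ/mol
    boltzmann_mean: float  # ⟨exp(−βΔU)⟩ (volume weighted)
    n_insertions: int
    temperature: float  # K
    rho_kg_m3: float
    solubility: SolubilityCoefficient = None
    seed: int | None = None
    n_blocks: int = 10
    block_means: np.ndarray = field(default=None, repr=False)


def _ghost_host_energy(site_pos, site_sig, site_eps, site_q, site_hard,
                       host_pos, host_sig, host_eps, host_q, host_hard,
                       box, params: NonbondedParams):
    """Interaction energy of ghost site sets with all host atoms.

    ``site_pos`` has shape (n_ins, n_sites, 3); returns ΔU (n_ins,) kJ/mol
    with +inf for hard-core overlap.  Cross parameters follow the
    configured combining rule.
    """
    n_ins, n_sites, _ = site_pos.shape
    n_host = len(host_pos)
    flat = site_pos.reshape(n_ins * n_sites, 3)
    d = flat[:, None, :] - host_pos[None, :, :]
    d -= box * np.round(d / box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))

    # per-(site, host) mixed parameters, tiled over insertions
    if params.combining == "lorentz_berthelot":
        smix = 0.5 * (site_sig[:, None] + host_sig[None, :])
        emix = np.sqrt(site_eps[:, None] * host_eps[None, :])
    else:
        s6i = site_sig[:, None] ** 6
        s6j = host_sig[None, :] ** 6
        smix = (0.5 * (s6i + s6j)) ** (1.0 / 6.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            emix = np.where(
                s6i + s6j > 0,
                2.0 * np.sqrt(site_eps[:, None] * host_eps[None, :])
                * (site_sig[:, None] ** 3 * host_sig[None, :] ** 3) / (s6i + s6j),
                0.0,
            )
    qq = site_q[:, None] * host_q[None, :]
    hsum = site_hard[:, None] + host_hard[None, :]

    smix_t = np.tile(smix, (n_ins, 1))
    emix_t = np.tile(emix, (n_ins, 1))
    qq_t = np.tile(qq, (n_ins, 1))
    hsum_t = np.tile(hsum, (n_ins, 1))

    within = r <= params.cutoff
    rsafe = np.where(r > 0, r, 1.0)
    u = np.where(within, _lj(rsafe, smix_t, emix_t, params.lj_form), 0.0)
    u = u + np.where(within & (qq_t != 0.0), COULOMB_KJ_A * qq_t / rsafe, 0.0)
    overlap = (hsum_t > 0) & (r < hsum_t)
    u = np.where(overlap | (r == 0.0), np.inf, u)
    return u.reshape(n_ins, n_sites, n_host).sum(axis=(1, 2))


def widom_excess_mu(
    traj: Trajectory,
    penetrant: PenetrantModel,
    params: NonbondedParams,
    n_insertions: int,
    temperature: float,
    seed: int,
    n_blocks: int = 10,
    chunk_size: int = 20000,
) -> WidomResult:
    """Excess chemical potential of a ghost penetrant over a trajectory.

    Insertions are pooled across frames (split as evenly as possible);
    the standard error comes from ≥ ``n_blocks`` contiguous insertion
    blocks.  Deterministic for a fixed seed.
    """
    if n_insertions < 1:
        raise ValueError("n_insertions must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    RT = R_GAS / 1000.0 * temperature  # kJ/mol

    host_types = traj.types
    host_sig, host_eps, host_q, host_hard = params.tables(host_types)
    site_types = penetrant.site_types()
    site_sig = np.array([params.sigma(t) for t in site_types])
    site_eps = np.array([params.epsilon(t) for t in site_types])
    site_q = np.array([params.charge(t) for t in site_types])
    site_hard = np.array([params.hard_radius(t) for t in site_types])
    offsets = penetrant.offsets()
    multi_site = penetrant.n_sites > 1

    n_frames = traj.n_frames
    per_frame = np.full(n_frames, n_insertions // n_frames, dtype=int)
    per_frame[: n_insertions % n_frames] += 1

    boltz_all = np.empty(n_insertions)
    weight_all = np.empty(n_insertions)
    pos_cursor = 0
    volumes = np.prod(traj.boxes, axis=1)
    vary_volume = not np.allclose(volumes, volumes[0])

    for fi in range(n_frames):
        n_f = int(per_frame[fi])
        if n_f == 0:
            continue
        box = traj.boxes[fi]
        host_pos = traj.positions[fi]
        vol = volumes[fi]
        done = 0
        while done < n_f:
            n_c = min(chunk_size, n_f - done)
            centers = rng.random((n_c, 3)) * box
            if multi_site and penetrant.rigid:
                rmats = Rotation.random(n_c, rng=rng).as_matrix()
                site_pos = centers[:, None, :] + np.einsum("nij,sj->nsi", rmats, offsets)
            else:
                site_pos = centers[:, None, :] + offsets[None, :, :]
            du = _ghost_host_energy(
                site_pos, site_sig, site_eps, site_q, site_hard,
                host_pos, host_sig, host_eps, host_q, host_hard, box, params,
            )
            with np.errstate(over="ignore"):
                b = np.exp(-du / RT)
            b = np.where(np.isfinite(b), b, 0.0)  # hard overlaps -> 0
            sl = slice(pos_cursor + done, pos_cursor + done + n_c)
            boltz_all[sl] = b
            weight_all[sl] = vol if vary_volume else 1.0
            done += n_c
        pos_cursor += n_f

    mean_b = float(np.average(boltz_all, weights=weight_all))
    if mean_b <= 0.0:
        raise ValueError(
            "no accessible volume: every insertion overlapped the host; "
            "cannot take ln of a zero Boltzmann average"
        )
    mu = -RT * np.log(mean_b)

    # block averaging over the insertion sequence
    nb = max(n_blocks, 10)
    nb = min(nb, n_insertions)
    edges = np.linspace(0, n_insertions, nb + 1).astype(int)
    block_means = np.array(
        [np.average(boltz_all[a:b], weights=weight_all[a:b]) for a, b in zip(edges[:-1], edges[1:])]
    )
    se_b = float(block_means.std(ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0
    se_mu = RT * se_b / mean_b  # δμ = RT δ⟨B⟩/⟨B⟩

    # host density from frames
    mass_amu = traj.masses.sum()
    rho = mass_amu / N_AVOGADRO / (volumes.mean() * 1e-24) * 1000.0  # kg/m³

    sol = solubility_from_mu(mu, rho, temperature, penetrant.molar_mass, se_mu=se_mu)
    return WidomResult(
        mu_ex=float(mu),
        se_mu=se_mu,
        boltzmann_mean=mean_b,
        n_insertions=n_insertions,
        temperature=temperature,
        rho_kg_m3=rho,
        solubility=sol,
        seed=seed,
        n_blocks=nb,
        block_means=block_means,
    )


def solubility_from_mu(mu_ex: float, rho: float, temperature: float,
                       molar_mass: float, se_mu: float = 0.0) -> SolubilityCoefficient:
    """Henry solubility coefficient from an excess chemical potential.

    S = 1/(ρRT) exp(−μ_ex/RT) in mol kg⁻¹ Pa⁻¹, reported ×10⁵ as
    mol kg⁻¹ bar⁻¹ (molar basis).  ρ in kg/m³, μ_ex in kJ/mol.
    """
    if rho <= 0 or temperature <= 0 or molar_mass <= 0:
        raise ValueError("rho, temperature and molar_mass must be positive")
    RT_J = R_GAS * temperature
    s_pa = np.exp(-mu_ex * 1000.0 / RT_J) / (rho * RT_J)  # mol/(kg Pa)
    s_bar = s_pa * BAR_TO_PA
    se = s_bar * (se_mu * 1000.0 / RT_J)
    return SolubilityCoefficient(
        mol_per_kg_bar=float(s_bar),
        se=float(se),
        molar_mass=molar_mass,
        rho_kg_m3=rho,
    )


def solubility_selectivity(s_i, s_j) -> float:
    """Solubility–selectivity α^S = S_i/S_j on a molar basis.

    Accepts floats (assumed molar basis) or :class:`SolubilityCoefficient`
    objects, whose bases must agree.
    """
    if isinstance(s_i, SolubilityCoefficient) and isinstance(s_j, SolubilityCoefficient):
        if s_i.basis != s_j.basis:
            raise ValueError(f"mixed bases: {s_i.basis} vs {s_j.basis}")
        s_i, s_j = s_i.mol_per_kg_bar, s_j.mol_per_kg_bar
    elif isinstance(s_i, SolubilityCoefficient) or isinstance(s_j, SolubilityCoefficient):
        raise ValueError("compare two SolubilityCoefficient objects or two floats")
    if s_j <= 0:
        raise ValueError("denominator solubility must be positive")
    return float(s_i) / float(s_j)


def molecules_at_pressure(s_mol_kg_bar: float, pressure_bar: float,
                          system_mass_kg: float, rounding: str = "half_up",
                          min_one: bool = True) -> int:
    """Number of gas molecules a system absorbs at a given pressure.

    N = S·p·m·N_A, rounded half-up by default (``floor``/``ceil``
    available).  With ``min_one`` (default), any strictly positive loading
    rounds to at least one molecule so that dilute-penetrant runs are
    never empty.
    """
    if pressure_bar < 0:
        raise ValueError("pressure must be >= 0")
    x = s_mol_kg_bar * pressure_bar * system_mass_kg * N_AVOGADRO
    if rounding == "half_up":
        n = int(np.floor(x + 0.5))
    elif rounding == "floor":
        n = int(np.floor(x))
    elif rounding == "ceil":
        n = int(np.ceil(x))
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    if min_one and x > 0:
        n = max(n, 1)
    return n
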