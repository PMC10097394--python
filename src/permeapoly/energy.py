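"""Reduced nonbonded energy model: LJ 12-6 / 9-6 + truncated Coulomb.

Energies are kJ/mol, lengths Å.  Interactions are evaluated under the
minimum-image convention in orthorhombic boxes with a spherical cutoff;
the standard analytic tail correction for the dispersion part is optional.
Cohesive energy is the difference between the summed isolated-chain
energies and the total box energy, and yields the cohesive energy density
and the Hildebrand solubility parameter δ = √CED.

Two LJ functional forms and two combining rules are supported so the
kernels cover both the common 12-6/Lorentz–Berthelot convention and the
9-6/sixth-power convention used by class-II force fields; parameters are
always user inputs.

Electrostatics are minimum-image truncated Coulomb.  This is adequate for
the neutral, low-charge reduced systems the package targets, and is *not*
a substitute for mesh Ewald accuracy in highly charged systems.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_KJ_A, N_AVOGADRO
from .core import SystemConfiguration

__all__ = [
    "NonbondedParams",
    "EnergyBreakdown",
    "pair_energy",
    "tail_correction",
    "total_potential_energy",
    "cohesive_energy",
]

LJ_FORMS = ("12-6", "9-6")
COMBINING_RULES = ("lorentz_berthelot", "sixth_power")


@dataclass
class NonbondedParams:
    """Per-type nonbonded parameter table plus evaluation conventions.

    ``types`` maps a type label to a dict with keys ``sigma`` (σ for 12-6,
    r₀ for 9-6; Å), ``epsilon`` (kJ/mol), optional ``charge`` (e) and
    optional ``hard_radius`` (Å, infinite energy inside — used for
    hard-sphere test systems).
    """

    types: dict
    lj_form: str = "12-6"
    combining: str = "lorentz_berthelot"
    cutoff: float = 12.0
    tail: bool = False

    def __post_init__(self):
        if self.lj_form not in LJ_FORMS:
            raise ValueError(f"lj_form must be one of {LJ_FORMS}")
        if self.combining not in COMBINING_RULES:
            raise ValueError(f"combining must be one of {COMBINING_RULES}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for label, p in self.types.items():
            if p.get("epsilon", 0.0) < 0:
                raise ValueError(f"epsilon must be >= 0 for type {label}")
            if p.get("sigma", 1.0) <= 0:
                raise ValueError(f"sigma must be > 0 for type {label}")

    @classmethod
    def from_yaml(cls, path) -> "NonbondedParams":
        """Load a parameter table from a YAML file.

        Schema: top-level keys ``lj_form``, ``combining``, ``cutoff``,
        ``tail`` and a ``types`` mapping of label -> {sigma, epsilon,
        charge, hard_radius}.
        """
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "types" not in doc:
            raise ValueError("parameter file must define a 'types' mapping")
        return cls(
            types=doc["types"],
            lj_form=doc.get("lj_form", "12-6"),
            combining=doc.get("combining", "lorentz_berthelot"),
            cutoff=float(doc.get("cutoff", 12.0)),
            tail=bool(doc.get("tail", False)),
        )

    def sigma(self, t):
        return float(self.types[t]["sigma"])

    def epsilon(self, t):
        return float(self.types[t].get("epsilon", 0.0))

    def charge(self, t):
        return float(self.types[t].get("charge", 0.0))

    def hard_radius(self, t):
        r = self.types[t].get("hard_radius")
        return float(r) if r is not None else 0.0

    def mix(self, ti, tj):
        """Cross-interaction (σ_ij, ε_ij) under the configured rule."""
        si, sj = self.sigma(ti), self.sigma(tj)
        ei, ej = self.epsilon(ti), self.epsilon(tj)
        if self.combining == "lorentz_berthelot":
            return 0.5 * (si + sj), np.sqrt(ei * ej)
        # sixth-power rule (class-II): r0_ij from mean sixth powers,
        # epsilon weighted by the r0^3 products
        s6i, s6j = si**6, sj**6
        sij = (0.5 * (s6i + s6j)) ** (1.0 / 6.0)
        denom = s6i + s6j
        eij = 2.0 * np.sqrt(ei * ej) * (si**3 * sj**3) / denom if denom > 0 else 0.0
        return sij, eij

    def tables(self, type_labels):
        """Vectorized per-atom parameter arrays for an atom type list."""
        sig = np.array([self.sigma(t) for t in type_labels])
        eps = np.array([self.epsilon(t) for t in type_labels])
        q = np.array([self.charge(t) for t in type_labels])
        hard = np.array([self.hard_radius(t) for t in type_labels])
        return sig, eps, q, hard


def _lj(r, sigma, epsilon, form):
    if form == "12-6":
        x6 = (sigma / r) ** 6
        return 4.0 * epsilon * (x6 * x6 - x6)
    x3 = (sigma / r) ** 3
    x6 = x3 * x3
    return epsilon * (2.0 * x6 * x3 - 3.0 * x6)


def pair_energy(r, type_i, type_j, params: NonbondedParams,
                apply_cutoff: bool = True):
    """Nonbonded pair energy u(r) between two typed sites, kJ/mol.

    Zero beyond the cutoff (before any tail correction); +inf inside the
    summed hard radii when hard cores are defined.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    sij, eij = params.mix(type_i, type_j)
    u = _lj(r, sij, eij, params.lj_form)
    qq = params.charge(type_i) * params.charge(type_j)
    if qq != 0.0:
        u = u + COULOMB_KJ_A * qq / r
    hard = params.hard_radius(type_i) + params.hard_radius(type_j)
    if hard > 0:
        u = np.where(r < hard, np.inf, u)
    if apply_cutoff:
        u = np.where(r > params.cutoff, 0.0, u)
    return u if u.ndim else float(u)


def _tail_pair_integral(sigma, epsilon, rc, form):
    """∫_rc^∞ u(r) r² dr for the dispersion form, analytic."""
    if epsilon == 0.0:
        return 0.0
    if form == "12-6":
        s3 = (sigma / rc) ** 3
        s9 = s3**3
        return 4.0 * epsilon * sigma**3 * (s9 / 9.0 - s3 / 3.0)
    # 9-6: ∫ r² ε[2(r0/r)^9 − 3(r0/r)^6] dr = ε [r0^9/(3 rc^6) − r0^6/rc^3]
    return epsilon * (sigma**9 / (3.0 * rc**6) - sigma**6 / rc**3)


def tail_correction(params: NonbondedParams, number_densities: dict,
                    volume: float) -> float:
    """Analytic long-range dispersion correction for a homogeneous fluid.

    U_tail = 2π V Σ_ab ρ_a ρ_b ∫_rc^∞ u_ab(r) r² dr, with ρ in Å⁻³ and
    ``volume`` in Å³; returns kJ/mol (per box).  Assumes g(r) = 1 beyond
    the cutoff.
    """
    if params.cutoff <= 0:
        raise ValueError("tail correction requires a positive cutoff")
    labels = list(number_densities)
    u = 0.0
    for a in labels:
        for b in labels:
            sij, eij = params.mix(a, b)
            integral = _tail_pair_integral(sij, eij, params.cutoff, params.lj_form)
            u += number_densities[a] * number_densities[b] * integral
    return 2.0 * np.pi * volume * u


def _pair_sum(positions, box, sig, eps, q, hard, params, pair_mask=None):
    """Minimum-image pairwise energy over unique pairs; box=None disables PBC."""
    n = len(positions)
    rc = params.cutoff
    total = 0.0
    for i in range(n - 1):
        d = positions[i + 1:] - positions[i]
        if box is not None:
            d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        if pair_mask is not None:
            keep = pair_mask[i, i + 1:]
        else:
            keep = np.ones(n - i - 1, dtype=bool)
        keep &= r <= rc
        if not np.any(keep):
            continue
        r = r[keep]
        if np.any(r <= 0):
            raise ValueError("coincident atoms: zero pair separation")
        sij_arr = sig[i + 1:][keep]
        eij_arr = eps[i + 1:][keep]
        if params.combining == "lorentz_berthelot":
            smix = 0.5 * (sig[i] + sij_arr)
            emix = np.sqrt(eps[i] * eij_arr)
        else:
            s6i, s6j = sig[i] ** 6, sij_arr**6
            smix = (0.5 * (s6i + s6j)) ** (1.0 / 6.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                emix = np.where(
                    s6i + s6j > 0,
                    2.0 * np.sqrt(eps[i] * eij_arr) * (sig[i] ** 3 * sij_arr**3) / (s6i + s6j),
                    0.0,
                )
        u = _lj(r, smix, emix, params.lj_form)
        qq = q[i] * q[i + 1:][keep]
        u = u + COULOMB_KJ_A * qq / r
        hsum = hard[i] + hard[i + 1:][keep]
        overlap = (hsum > 0) & (r < hsum)
        if np.any(overlap):
            return np.inf
        total += float(u.sum())
    return total


def total_potential_energy(frame: SystemConfiguration, params: NonbondedParams,
                           exclude_same_chain: bool = False,
                           use_pbc: bool = True) -> float:
    """Total nonbonded energy of a configuration, kJ/mol.

    Minimum image in the orthorhombic box (cutoff ≤ L/2 enforced), optional
    tail correction when ``params.tail`` is set, optional exclusion of
    same-chain pairs.
    """
    box = frame.box if use_pbc else None
    if use_pbc and params.cutoff > frame.box.min() / 2.0:
        raise ValueError(
            f"cutoff {params.cutoff} Å violates the minimum-image bound "
            f"L/2 = {frame.box.min() / 2.0:.3f} Å"
        )
    sig, eps, q, hard = params.tables(frame.types)
    mask = None
    if exclude_same_chain:
        cids = frame.chain_ids
        mask = cids[:, None] != cids[None, :]
    e = _pair_sum(frame.positions, box, sig, eps, q, hard, params, mask)
    if params.tail and use_pbc:
        dens = {}
        for t in np.unique(frame.types):
            dens[t] = np.count_nonzero(frame.types == t) / frame.volume
        e += tail_correction(params, dens, frame.volume)
    return e


@dataclass
class EnergyBreakdown:
    """Box energy, per-chain isolated energies, cohesive energy and δ."""

    total: float  # kJ/mol
    per_chain: dict = field(default_factory=dict)  # chain id -> kJ/mol
    e_coh: float = 0.0  # kJ/mol
    volume_cm3_per_mol: float = 0.0
    ced_mpa: float = 0.0
    delta_mpa05: float = 0.0


def cohesive_energy(frame: SystemConfiguration, params: NonbondedParams) -> EnergyBreakdown:
    """Cohesive energy, CED and Hildebrand δ of a chain-partitioned box.

    E_coh = Σ_chains E(chain isolated, no periodic images) − E(box).
    CED [MPa] = E_coh [kJ/mol] / V [cm³/mol] × 10³; δ = √CED [MPa^0.5].
    With no bonded terms, "intramolecular" means same-chain membership.
    """
    e_box = total_potential_energy(frame, params)
    per_chain = {}
    for cid, idx in frame.chain_indices().items():
        sub = SystemConfiguration(
            positions=frame.positions[idx],
            box=frame.box,
            elements=frame.elements[idx],
            types=frame.types[idx],
            masses=frame.masses[idx],
            charges=frame.charges[idx],
            chain_ids=frame.chain_ids[idx],
        )
        per_chain[cid] = total_potential_energy(sub, params, use_pbc=False)
    e_coh = sum(per_chain.values()) - e_box
    vol_cm3_mol = frame.volume * 1e-24 * N_AVOGADRO
    ced = e_coh / vol_cm3_mol * 1e3 if vol_cm3_mol > 0 else 0.0
    delta = np.sqrt(ced) if ced > 0 else 0.0
    return EnergyBreakdown(
        total=e_box,
        per_chain=per_chain,
        e_coh=e_coh,
        volume_cm3_per_mol=vol_cm3_mol,
        ced_mpa=ced,
        delta_mpa05=float(delta),
    )
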