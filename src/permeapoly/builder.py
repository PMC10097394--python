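"""Random-copolymer topology and box construction for PHBV systems.

PHBV is a random copolymer of 3-hydroxybutyrate (HB, repeat C4H6O2, 12
atoms) and 3-hydroxyvalerate (HV, repeat C5H8O2, 15 atoms).  The builder
emits chemically labelled particles with user-supplied nonbonded types —
a reduced representation sufficient for insertion, RDF and cohesive-energy
pipelines — not a bonded force field.  The boxes it packs are seeded
random-coil walks with no claim of equilibration; they exist to exercise
and test the downstream estimators.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ATOMIC_MASSES, N_AVOGADRO
from .core import SystemConfiguration

__all__ = [
    "MonomerTemplate",
    "ChainTopology",
    "HB",
    "HV",
    "MONOMERS",
    "WATER_CAP_MASS",
    "generate_copolymer_sequence",
    "build_chain",
    "assemble_box",
    "system_summary",
]


@dataclass(frozen=True)
class MonomerTemplate:
    """One repeat unit: label, formula, and its flat atom list.

    ``atoms`` is a tuple of (element, nonbonded type, partial charge)
    entries; masses come from the standard atomic masses table.
    """

    label: str
    formula: dict
    atoms: tuple

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def molar_mass(self) -> float:
        return sum(ATOMIC_MASSES[el] * n for el, n in self.formula.items())


def _repeat_atoms(formula: dict, tag: str) -> tuple:
    atoms = []
    for el, n in sorted(formula.items()):
        for _ in range(n):
            atoms.append((el, f"{el}_{tag}", 0.0))
    return tuple(atoms)


# Repeat-unit chemistry: HB = C4H6O2 (86.090 g/mol), HV = C5H8O2 (100.117).
# Partial charges default to zero (they sum to zero per repeat by
# construction); callers may substitute their own templates with charges.
HB = MonomerTemplate("HB", {"C": 4, "H": 6, "O": 2}, _repeat_atoms({"C": 4, "H": 6, "O": 2}, "HB"))
HV = MonomerTemplate("HV", {"C": 5, "H": 8, "O": 2}, _repeat_atoms({"C": 5, "H": 8, "O": 2}, "HV"))
MONOMERS = {"HB": HB, "HV": HV}

# H– / –OH chain caps add one water-equivalent mass per chain when enabled
WATER_CAP_MASS = 2 * ATOMIC_MASSES["H"] + ATOMIC_MASSES["O"]  # 18.015 g/mol


@dataclass
class ChainTopology:
    """An ordered monomer sequence with additive mass and atom bookkeeping."""

    sequence: list
    end_caps: bool = False
    monomers: dict = field(default_factory=lambda: MONOMERS)

    def __post_init__(self):
        unknown = set(self.sequence) - set(self.monomers)
        if unknown:
            raise KeyError(f"unknown monomer label(s): {sorted(unknown)}")
        if not self.sequence:
            raise ValueError("empty monomer sequence")

    @property
    def n_monomers(self) -> int:
        return len(self.sequence)

    @property
    def molar_mass(self) -> float:
        m = sum(self.monomers[s].molar_mass for s in self.sequence)
        if self.end_caps:
            m += WATER_CAP_MASS
        return m

    @property
    def n_atoms(self) -> int:
        n = sum(self.monomers[s].n_atoms for s in self.sequence)
        if self.end_caps:
            n += 3  # H + O + H
        return n

    @property
    def x_hv(self) -> float:
        return self.sequence.count("HV") / len(self.sequence)

    def atom_records(self) -> list:
        """Flat (element, type, charge, mass) list over the whole chain."""
        recs = []
        for s in self.sequence:
            for el, typ, q in self.monomers[s].atoms:
                recs.append((el, typ, q, ATOMIC_MASSES[el]))
        if self.end_caps:
            recs.append(("H", "H_cap", 0.0, ATOMIC_MASSES["H"]))
            recs.append(("O", "O_cap", 0.0, ATOMIC_MASSES["O"]))
            recs.append(("H", "H_cap", 0.0, ATOMIC_MASSES["H"]))
        return recs


def generate_copolymer_sequence(n_monomers: int, x_hv: float, seed: int) -> list:
    """Draw a random HB/HV sequence with i.i.d. Bernoulli(x_hv) HV placement.

    Deterministic for a fixed seed.  Blockiness / reactivity-ratio effects
    are deliberately not modelled; each position is independent.
    """
    if not 0.0 <= x_hv <= 1.0:
        raise ValueError(f"x_hv must lie in [0, 1], got {x_hv}")
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.random(n_monomers)
    return ["HV" if u < x_hv else "HB" for u in draws]


def build_chain(sequence: list, end_caps: bool = False) -> ChainTopology:
    """Assemble a chain topology from an ordered monomer-label list."""
    return ChainTopology(list(sequence), end_caps=end_caps)


def assemble_box(
    chains: list,
    target_density: float,
    seed: int,
    step_length: float = 1.5,
) -> SystemConfiguration:
    """Pack chains into a cubic periodic box at a target mass density.

    The cube edge follows from L³ = M_total / (N_A ρ); atoms are placed as
    seeded random-coil walks (fixed step length, uniformly random direction)
    wrapped into the box.  No excluded volume, no equilibration — the box
    is a topologically labelled particle cloud for pipeline testing.

    Parameters
    ----------
    chains : list of ChainTopology
    target_density : g/cm³
    seed : RNG seed (deterministic coordinates for a fixed seed)
    """
    if not chains:
        raise ValueError("need at least one chain")
    if target_density <= 0:
        raise ValueError("target_density must be positive")
    total_mass = sum(c.molar_mass for c in chains)  # g/mol
    volume_cm3 = total_mass / (N_AVOGADRO * target_density)
    edge = (volume_cm3 * 1e24) ** (1.0 / 3.0)  # Å
    box = np.array([edge, edge, edge])

    rng = np.random.default_rng(seed)
    elements, types, charges, masses, chain_ids = [], [], [], [], []
    pos = []
    for cid, chain in enumerate(chains):
        recs = chain.atom_records()
        start = rng.random(3) * edge
        # random coil: isotropic unit steps of fixed length
        steps = rng.normal(size=(len(recs) - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        walk = np.vstack([start, start + np.cumsum(step_length * steps, axis=0)])
        walk %= edge
        pos.append(walk)
        for el, typ, q, m in recs:
            elements.append(el)
            types.append(typ)
            charges.append(q)
            masses.append(m)
            chain_ids.append(cid)

    n_hv = sum(c.sequence.count("HV") for c in chains)
    n_mono = sum(c.n_monomers for c in chains)
    return SystemConfiguration(
        positions=np.vstack(pos),
        box=box,
        elements=np.array(elements, dtype=object),
        types=np.array(types, dtype=object),
        masses=np.array(masses),
        charges=np.array(charges),
        chain_ids=np.array(chain_ids),
        x_hv=n_hv / n_mono,
        metadata={"seed": seed, "target_density": target_density},
    )


def system_summary(system: SystemConfiguration) -> dict:
    """Counts report: atoms, chains, composition, mass, density, box edge."""
    chains = system.chain_indices()
    return {
        "n_atoms": system.n_atoms,
        "n_chains": len(chains),
        "x_hv": system.x_hv,
        "total_mass_g_per_mol": system.total_mass,
        "density_g_per_cm3": system.density,
        "box_edges_A": system.box.tolist(),
    }
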