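"""Shared in-memory containers: particle configurations and trajectories.

A :class:`SystemConfiguration` is a single static snapshot (atoms, chains,
orthorhombic box); a :class:`Trajectory` is an ordered sequence of frames
with uniform time spacing.  Boxes are orthorhombic throughout; positions are
Cartesian Å.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SystemConfiguration", "Trajectory"]


@dataclass
class SystemConfiguration:
    """One particle configuration in an orthorhombic periodic box.

    Parameters
    ----------
    positions : (N, 3) float array, Å
    box : (3,) float array, edge lengths Å
    elements : (N,) array of element symbols
    types : (N,) array of nonbonded type labels
    masses : (N,) float array, amu
    charges : (N,) float array, e
    chain_ids : (N,) int array; partitions atoms into chains (-1 = no chain)
    x_hv : mole fraction of HV repeat units, if the system is a copolymer
    """

    positions: np.ndarray
    box: np.ndarray
    elements: np.ndarray = None
    types: np.ndarray = None
    masses: np.ndarray = None
    charges: np.ndarray = None
    chain_ids: np.ndarray = None
    x_hv: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        n = len(self.positions)
        if self.elements is None:
            self.elements = np.full(n, "X", dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        if self.types is None:
            self.types = self.elements.copy()
        self.types = np.asarray(self.types, dtype=object)
        if self.masses is None:
            self.masses = np.zeros(n)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.charges is None:
            self.charges = np.zeros(n)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.chain_ids is None:
            self.chain_ids = np.full(n, -1, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype=int)
        for arr, name in [
            (self.elements, "elements"),
            (self.types, "types"),
            (self.masses, "masses"),
            (self.charges, "charges"),
            (self.chain_ids, "chain_ids"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        """Box volume in Å³."""
        return float(np.prod(self.box))

    @property
    def total_mass(self) -> float:
        """Total mass in amu (== g/mol of box contents)."""
        return float(self.masses.sum())

    @property
    def density(self) -> float:
        """Mass density in g/cm³."""
        from .constants import N_AVOGADRO

        return self.total_mass / N_AVOGADRO / (self.volume * 1e-24)

    def chain_indices(self) -> dict[int, np.ndarray]:
        """Atom index arrays per chain id (excluding -1)."""
        out = {}
        for cid in np.unique(self.chain_ids):
            if cid < 0:
                continue
            out[int(cid)] = np.flatnonzero(self.chain_ids == cid)
        return out


@dataclass
class Trajectory:
    """Ordered frames with a constant atom count and uniform time spacing.

    ``positions`` has shape (n_frames, N, 3); ``boxes`` is (n_frames, 3).
    ``dt_ps`` is the spacing between consecutive stored frames in ps.
    ``images`` optionally stores integer periodic image flags (n_frames, N, 3)
    so that unwrapped = positions + images * box.
    """

    positions: np.ndarray
    boxes: np.ndarray
    dt_ps: float = 1.0
    elements: np.ndarray = None
    types: np.ndarray = None
    masses: np.ndarray = None
    charges: np.ndarray = None
    chain_ids: np.ndarray = None
    molecule_ids: np.ndarray = None
    images: np.ndarray | None = None
    wrapped: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, N, 3)")
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.boxes.ndim == 1:
            self.boxes = np.tile(self.boxes, (self.n_frames, 1))
        if self.boxes.shape != (self.n_frames, 3) or np.any(self.boxes <= 0):
            raise ValueError("boxes must be (n_frames, 3) positive edges")
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")
        n = self.n_atoms
        if self.elements is None:
            self.elements = np.full(n, "X", dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        if self.types is None:
            self.types = self.elements.copy()
        self.types = np.asarray(self.types, dtype=object)
        if self.masses is None:
            self.masses = np.ones(n)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.charges is None:
            self.charges = np.zeros(n)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.chain_ids is None:
            self.chain_ids = np.full(n, -1, dtype=int)
        if self.molecule_ids is None:
            self.molecule_ids = np.arange(n, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype=int)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.images is not None:
            self.images = np.asarray(self.images, dtype=int)
            if self.images.shape != self.positions.shape:
                raise ValueError("images must match positions shape")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> SystemConfiguration:
        """Extract frame ``i`` as a :class:`SystemConfiguration`."""
        return SystemConfiguration(
            positions=self.positions[i],
            box=self.boxes[i],
            elements=self.elements,
            types=self.types,
            masses=self.masses,
            charges=self.charges,
            chain_ids=self.chain_ids,
        )

    def unwrapped_positions(self) -> np.ndarray:
        """Continuous (unwrapped) coordinates for displacement analysis.

        Uses stored image flags when present; otherwise coordinates are
        assumed already unwrapped (``wrapped=False``).  Wrapped coordinates
        without image flags cannot be unwrapped reliably and raise.
        """
        if self.images is not None:
            return self.positions + self.images * self.boxes[:, None, :]
        if not self.wrapped:
            return self.positions
        raise ValueError(
            "trajectory is wrapped and has no image flags; cannot compute "
            "continuous displacements — supply image flags or unwrapped "
            "coordinates"
        )
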