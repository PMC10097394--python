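"""Structural characterisation: g(r), X-ray-weighted S(q), free volume.

The radial distribution function is the shell-normalised pair histogram
averaged over frames.  Partial structure factors come from the Fourier
transform of (g_ab − 1), optionally damped with a Lorch window against
truncation ripple, and are combined into the X-ray total with
Faber–Ziman weighting by atomic form factors:

    S_ab(q) = δ_ab + 4πρ √(c_a c_b) ∫ (g_ab(r) − 1) r sin(qr)/q W(r) dr
    S(q)    = Σ_ab c_a c_b f_a f_b S_ab(q) / (Σ_a c_a f_a)²

Form factors use the standard four-Gaussian crystallographic
parameterisation with f(0) = Z.  Fractional free volume and accessible
surface area are Monte-Carlo probe estimates on hard-sphere radii
(Bondi van der Waals radii by default).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BONDI_RADII
from .core import SystemConfiguration, Trajectory

__all__ = [
    "RDFResult",
    "StructureFactorResult",
    "rdf",
    "structure_factor",
    "xray_form_factor",
    "q_to_two_theta",
    "two_theta_to_q",
    "fractional_free_volume",
    "accessible_surface_area",
]

# Four-Gaussian X-ray form-factor coefficients (a1..a4, b1..b4, c),
# International Tables for Crystallography parameterisation:
# f(q) = Σ a_k exp(−b_k (q/4π)²) + c, with f(0) = Z.
FORM_FACTOR_COEFFS = {
    "H": ([0.489918, 0.262003, 0.196767, 0.049879],
          [20.6593, 7.74039, 49.5519, 2.20159], 0.001305),
    "C": ([2.31000, 1.02000, 1.58860, 0.865000],
          [20.8439, 10.2075, 0.568700, 51.6512], 0.215600),
    "O": ([3.04850, 2.28680, 1.54630, 0.867000],
          [13.2771, 5.70110, 0.323900, 32.9089], 0.250800),
    "N": ([12.2126, 3.13220, 2.01250, 1.16630],
          [0.005700, 9.89330, 28.9975, 0.582600], -11.529),
}


@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, Å
    g: np.ndarray
    counts: np.ndarray
    selection_a: str = "all"
    selection_b: str = "all"
    rho_a: float = 0.0  # number densities, Å⁻³
    rho_b: float = 0.0
    n_a: int = 0
    n_b: int = 0
    dr: float = 0.0
    same_selection: bool = False

    def coordination_number(self, r_max: float) -> float:
        """Running coordination number ∫₀^{r_max} 4πρ_b r² g(r) dr."""
        keep = self.r <= r_max
        return float(np.sum(4.0 * np.pi * self.rho_b * self.r[keep] ** 2
                            * self.g[keep]) * self.dr)


def _resolve_selection(traj: Trajectory, sel) -> np.ndarray:
    """Selection -> atom index array.  None/'all', a type/element label,
    or an explicit index array."""
    if sel is None or (isinstance(sel, str) and sel == "all"):
        return np.arange(traj.n_atoms)
    if isinstance(sel, str):
        hit = (traj.types == sel) | (traj.elements == sel)
        if not hit.any():
            raise KeyError(f"selection {sel!r} matches no atoms")
        return np.flatnonzero(hit)
    return np.asarray(sel, dtype=int)


def rdf(traj: Trajectory, selection_a="all", selection_b="all",
        r_max: float | None = None, dr: float = 0.1) -> RDFResult:
    """Shell-normalised radial distribution function g_AB(r).

    Averaged over frames; the self case (identical selections) excludes
    i = j pairs.  ``r_max`` defaults to, and may not exceed, L/2.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    half_box = float(traj.boxes.min() / 2.0)
    if r_max is None:
        r_max = half_box
    if r_max > half_box + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the box {half_box:.4f}")
    ia = _resolve_selection(traj, selection_a)
    ib = _resolve_selection(traj, selection_b)
    same = len(ia) == len(ib) and np.array_equal(np.sort(ia), np.sort(ib))
    n_bins = int(np.floor(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    counts = np.zeros(n_bins)
    vol_sum = 0.0
    for fi in range(traj.n_frames):
        box = traj.boxes[fi]
        pa = traj.positions[fi][ia]
        pb = traj.positions[fi][ib]
        d = pa[:, None, :] - pb[None, :, :]
        d -= box * np.round(d / box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        if same:
            iu = ~np.eye(len(ia), dtype=bool)
            r = r[iu]
        else:
            r = r.ravel()
        h, _ = np.histogram(r, bins=edges)
        counts += h
        vol_sum += float(np.prod(box))
    counts /= traj.n_frames
    vol = vol_sum / traj.n_frames
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_a, n_b = len(ia), len(ib)
    # ideal pair count in a shell: N_a * rho_b * V_shell (minus self pairs)
    rho_b_eff = (n_b - (1 if same else 0)) / vol
    ideal = n_a * rho_b_eff * shell
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    return RDFResult(
        r=centers, g=g, counts=counts,
        selection_a=str(selection_a), selection_b=str(selection_b),
        rho_a=n_a / vol, rho_b=n_b / vol, n_a=n_a, n_b=n_b,
        dr=dr, same_selection=same,
    )


def xray_form_factor(element: str, q) -> np.ndarray | float:
    """Atomic X-ray form factor f(q) (dimensionless), f(0) = Z."""
    if element not in FORM_FACTOR_COEFFS:
        raise KeyError(
            f"no form-factor coefficients for element {element!r}; "
            f"available: {sorted(FORM_FACTOR_COEFFS)}"
        )
    a, b, c = FORM_FACTOR_COEFFS[element]
    q = np.asarray(q, dtype=float)
    s2 = (q / (4.0 * np.pi)) ** 2
    f = c + sum(ak * np.exp(-bk * s2) for ak, bk in zip(a, b))
    return f if f.ndim else float(f)


@dataclass
class StructureFactorResult:
    q: np.ndarray  # Å⁻¹
    total: np.ndarray  # X-ray-weighted S(q)
    partials: dict = field(default_factory=dict)  # (a, b) -> S_ab(q)
    species: list = field(default_factory=list)
    concentrations: dict = field(default_factory=dict)
    window: str = "lorch"

    @property
    def q_weighted(self) -> np.ndarray:
        """qS(q), convenient for locating the amorphous halo."""
        return self.q * self.total


def structure_factor(rdfs: dict, concentrations: dict, rho: float,
                     q_grid, window: str = "lorch",
                     form_factors: dict | None = None) -> StructureFactorResult:
    """X-ray-weighted total structure factor from partial RDFs.

    Parameters
    ----------
    rdfs : dict mapping unordered species pairs (a, b) to RDFResult on a
        common r grid (every pair must be present).
    concentrations : species -> number fraction c_a (must sum to 1).
    rho : total number density, Å⁻³.
    window : 'lorch' (default) damps the r-space truncation at r_max;
        'none' uses the bare integrand.
    form_factors : optional species -> f(q) callable/array override;
        defaults to the element form factors (species labels must then be
        element symbols).
    """
    species = sorted(concentrations)
    c = np.array([concentrations[s] for s in species])
    if not np.isclose(c.sum(), 1.0):
        raise ValueError("concentrations must sum to 1")
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q grid must be strictly positive")

    def lookup(a, b):
        if (a, b) in rdfs:
            return rdfs[(a, b)]
        if (b, a) in rdfs:
            return rdfs[(b, a)]
        raise KeyError(f"missing pair RDF for ({a}, {b})")

    r = lookup(species[0], species[0]).r
    dr = r[1] - r[0] if len(r) > 1 else lookup(species[0], species[0]).dr
    r_max = r[-1] + dr / 2.0
    if window == "lorch":
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(r > 0, np.sin(np.pi * r / r_max) / (np.pi * r / r_max), 1.0)
    elif window == "none":
        W = np.ones_like(r)
    else:
        raise ValueError("window must be 'lorch' or 'none'")

    partials = {}
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if j < i:
                continue
            res = lookup(a, b)
            if len(res.r) != len(r) or not np.allclose(res.r, r):
                raise ValueError("all pair RDFs must share a common r grid")
            integrand = (res.g - 1.0) * r * W
            # ∫ (g−1) r sin(qr)/q W dr
            ft = np.array([np.sum(integrand * np.sin(qi * r)) * dr / qi for qi in q])
            s_ab = (1.0 if i == j else 0.0) + 4.0 * np.pi * rho * np.sqrt(c[i] * c[j]) * ft
            partials[(a, b)] = s_ab

    if form_factors is None:
        f = {s: xray_form_factor(s, q) for s in species}
    else:
        f = {s: (ff(q) if callable(ff) else np.asarray(ff)) for s, ff in form_factors.items()}
    mean_f = sum(concentrations[s] * f[s] for s in species)
    total = np.zeros_like(q)
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            s_ab = partials[(a, b)] if j >= i else partials[(b, a)]
            w_ab = np.sqrt(c[i] * c[j]) * f[a] * f[b]
            total += w_ab * s_ab
    total /= mean_f**2
    return StructureFactorResult(
        q=q, total=total, partials=partials, species=species,
        concentrations=dict(concentrations), window=window,
    )


def q_to_two_theta(q, wavelength: float = 1.5406) -> np.ndarray | float:
    """Scattering-vector magnitude to scattering angle 2θ (degrees).

    2θ = 2 asin(qλ/4π); default wavelength is Cu Kα (1.5406 Å).
    """
    q = np.asarray(q, dtype=float)
    x = q * wavelength / (4.0 * np.pi)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("qλ/4π must lie in [0, 1]")
    out = np.degrees(2.0 * np.arcsin(x))
    return out if out.ndim else float(out)


def two_theta_to_q(two_theta, wavelength: float = 1.5406) -> np.ndarray | float:
    """Inverse of :func:`q_to_two_theta`."""
    tt = np.asarray(two_theta, dtype=float)
    out = 4.0 * np.pi * np.sin(np.radians(tt / 2.0)) / wavelength
    return out if out.ndim else float(out)


def _atom_radii(frame: SystemConfiguration, radii: dict | None) -> np.ndarray:
    table = dict(BONDI_RADII)
    if radii:
        table.update(radii)
    out = np.empty(frame.n_atoms)
    for i, (el, ty) in enumerate(zip(frame.elements, frame.types)):
        if ty in table:
            out[i] = table[ty]
        elif el in table:
            out[i] = table[el]
        else:
            raise KeyError(f"no hard radius for atom type {ty!r} / element {el!r}")
    return out


def fractional_free_volume(frame: SystemConfiguration, probe_radius: float = 0.0,
                           n_probes: int = 100000, seed: int = 0,
                           radii: dict | None = None) -> tuple:
    """Monte-Carlo fractional free volume for a spherical probe.

    Fraction of uniform points whose minimum-image distance to every atom
    exceeds (atom radius + probe radius).  Returns (FFV, binomial SE).
    """
    rng = np.random.default_rng(seed)
    if frame.n_atoms == 0:
        return 1.0, 0.0
    r_atoms = _atom_radii(frame, radii) + probe_radius
    box = frame.box
    free = 0
    chunk = max(1, int(2e6 / max(frame.n_atoms, 1)))
    done = 0
    while done < n_probes:
        n_c = min(chunk, n_probes - done)
        pts = rng.random((n_c, 3)) * box
        d = pts[:, None, :] - frame.positions[None, :, :]
        d -= box * np.round(d / box)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        free += int(np.count_nonzero(np.all(r2 > r_atoms[None, :] ** 2, axis=1)))
        done += n_c
    p = free / n_probes
    se = np.sqrt(max(p * (1 - p), 0.0) / n_probes)
    return float(p), float(se)


def _sphere_points(n: int, rng) -> np.ndarray:
    """Uniform random points on the unit sphere."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def accessible_surface_area(frame: SystemConfiguration, probe_radius: float = 0.0,
                            n_points_per_atom: int = 500, seed: int = 0,
                            radii: dict | None = None) -> tuple:
    """Shrake–Rupley-style accessible surface area, Å².

    Per atom, sample points on the sphere of radius (atom + probe); count
    the fraction not buried inside any neighbour's inflated sphere
    (minimum image) and scale by the sphere area.  Returns (ASA, MC SE).
    """
    rng = np.random.default_rng(seed)
    r_infl = _atom_radii(frame, radii) + probe_radius
    box = frame.box
    total = 0.0
    var = 0.0
    for i in range(frame.n_atoms):
        pts = frame.positions[i] + r_infl[i] * _sphere_points(n_points_per_atom, rng)
        others = np.arange(frame.n_atoms) != i
        if not np.any(others):
            frac, se_f = 1.0, 0.0
        else:
            d = pts[:, None, :] - frame.positions[None, others, :]
            d -= box * np.round(d / box)
            r2 = np.einsum("ijk,ijk->ij", d, d)
            exposed = np.all(r2 > r_infl[None, others] ** 2, axis=1)
            frac = float(exposed.mean())
            se_f = np.sqrt(max(frac * (1 - frac), 0.0) / n_points_per_atom)
        area = 4.0 * np.pi * r_infl[i] ** 2
        total += frac * area
        var += (se_f * area) ** 2
    return float(total), float(np.sqrt(var))
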