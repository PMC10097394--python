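"""Self-diffusivity from mean-square displacements via the Einstein relation.

The MSD is averaged over molecules and over multiple time origins,

    MSD(τ) = ⟨ |r(t₀+τ) − r(t₀)|² ⟩_{molecules, origins},

computed on molecular centres of mass from unwrapped coordinates.  The
Fickian (diffusive) regime is located as the longest contiguous stretch of
lag times where the log–log slope of MSD(τ) is 1 within a tolerance, and
the diffusivity follows from the Einstein relation D = slope/6 of a
weighted least-squares line over that window, converted to cm²/s.

Self-diffusivities approximate binary (mutual) diffusivities only at
infinite dilution; that assumption is the caller's to satisfy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import A2_PER_PS_TO_CM2_PER_S
from .core import Trajectory

__all__ = [
    "MSDResult",
    "msd",
    "detect_fickian_window",
    "einstein_diffusivity",
    "diffusivity_selectivity",
]


@dataclass
class MSDResult:
    lag_ps: np.ndarray  # lag times, ps (starting at 0)
    msd_A2: np.ndarray  # Å²
    n_origins: np.ndarray  # origin pairs averaged at each lag
    per_molecule: np.ndarray = field(default=None, repr=False)  # (n_lags, n_mol)
    dt_ps: float = 1.0
    window: tuple | None = None  # selected Fickian lag-index window
    D_cm2_s: float | None = None
    D_se: float | None = None

    def loglog_slope(self) -> np.ndarray:
        """d log MSD / d log τ by central differences (lag 0 excluded -> nan)."""
        out = np.full(len(self.lag_ps), np.nan)
        t = self.lag_ps[1:]
        m = self.msd_A2[1:]
        good = m > 0
        lt, lm = np.log(t[good]), np.log(m[good])
        if good.sum() >= 3:
            out[1:][good] = np.gradient(lm, lt)
        return out


def _molecule_centers(traj: Trajectory, selection=None) -> np.ndarray:
    """Mass-weighted molecular centres, (n_frames, n_mol, 3), unwrapped."""
    pos = traj.unwrapped_positions()
    mol = traj.molecule_ids
    if selection is not None:
        keep = np.isin(mol, np.asarray(selection))
        pos = pos[:, keep, :]
        mol = mol[keep]
        masses = traj.masses[keep]
    else:
        masses = traj.masses
    ids = np.unique(mol)
    centers = np.empty((traj.n_frames, len(ids), 3))
    for k, mid in enumerate(ids):
        idx = np.flatnonzero(mol == mid)
        w = masses[idx]
        if w.sum() <= 0:
            w = np.ones(len(idx))
        centers[:, k, :] = np.einsum("fij,i->fj", pos[:, idx, :], w) / w.sum()
    return centers


def msd(traj: Trajectory, selection=None, max_lag: int | None = None,
        origin_stride: int = 1) -> MSDResult:
    """Multi-time-origin MSD of molecular centres of mass.

    Origins are spaced ``origin_stride`` frames apart (1 = every frame,
    maximal averaging at the price of correlated origins).  Refuses wrapped
    coordinates without image flags.
    """
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")
    centers = _molecule_centers(traj, selection)
    n_frames, n_mol, _ = centers.shape
    if max_lag is None:
        max_lag = n_frames - 1
    max_lag = min(max_lag, n_frames - 1)
    lags = np.arange(max_lag + 1)
    msd_vals = np.zeros(max_lag + 1)
    per_mol = np.zeros((max_lag + 1, n_mol))
    counts = np.zeros(max_lag + 1, dtype=int)
    counts[0] = len(range(0, n_frames, origin_stride))
    for lag in lags[1:]:
        d = centers[lag:, :, :] - centers[:-lag, :, :]
        d = d[::origin_stride]
        sq = np.einsum("oij,oij->oi", d, d)  # (n_origins, n_mol)
        per_mol[lag] = sq.mean(axis=0)
        msd_vals[lag] = sq.mean()
        counts[lag] = sq.shape[0]
    return MSDResult(
        lag_ps=lags * traj.dt_ps,
        msd_A2=msd_vals,
        n_origins=counts,
        per_molecule=per_mol,
        dt_ps=traj.dt_ps,
    )


def detect_fickian_window(result: MSDResult, slope_tol: float = 0.1,
                          tail_exclude: float = 0.3) -> tuple:
    """Longest contiguous lag range with log–log slope within 1 ± tol.

    The last ``tail_exclude`` fraction of lags is excluded (few origin
    pairs, poor statistics).  Raises with the observed slope range when no
    diffusive stretch exists.
    """
    n = len(result.lag_ps)
    if n < 10:
        raise ValueError("need at least 10 lags to locate the Fickian regime")
    slopes = result.loglog_slope()
    hi = int(np.floor(n * (1.0 - tail_exclude)))
    ok = np.zeros(n, dtype=bool)
    valid = ~np.isnan(slopes[:hi])
    ok[:hi] = valid & (np.abs(slopes[:hi] - 1.0) <= slope_tol)
    # longest run of True
    best_len, best = 0, None
    i = 0
    while i < hi:
        if ok[i]:
            j = i
            while j + 1 < hi and ok[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len, best = j - i + 1, (i, j)
            i = j + 1
        else:
            i += 1
    if best is None or best_len < 3:
        s = slopes[1:hi][~np.isnan(slopes[1:hi])]
        raise ValueError(
            "no Fickian (slope ≈ 1) regime found; observed log-log slopes in "
            f"[{s.min():.3f}, {s.max():.3f}]" if len(s) else
            "no Fickian regime found; MSD vanishes everywhere"
        )
    return best


def einstein_diffusivity(result: MSDResult, window: tuple | None = None) -> MSDResult:
    """Einstein-relation diffusivity D = slope/6 over the Fickian window.

    Weighted least squares of MSD vs τ (weights = number of origin pairs,
    free intercept); the slope in Å²/ps converts to cm²/s via 10⁻⁴.
    Returns the input result with ``window``, ``D_cm2_s`` and ``D_se``
    filled in.
    """
    if window is None:
        window = detect_fickian_window(result)
    i0, i1 = window
    if i1 - i0 + 1 < 3:
        raise ValueError("Fickian window must span at least 3 lag points")
    t = result.lag_ps[i0 : i1 + 1]
    y = result.msd_A2[i0 : i1 + 1]
    w = result.n_origins[i0 : i1 + 1].astype(float)
    X = np.column_stack([np.ones_like(t), t])
    xtw = X.T * w
    xtwx = xtw @ X
    beta = np.linalg.solve(xtwx, xtw @ y)
    cov = np.linalg.inv(xtwx)
    resid = y - X @ beta
    dof = max(len(t) - 2, 1)
    s2 = float((w * resid * resid).sum()) / dof
    slope = float(beta[1])
    slope_se = float(np.sqrt(s2 * cov[1, 1]))
    result.window = (int(i0), int(i1))
    result.D_cm2_s = slope / 6.0 * A2_PER_PS_TO_CM2_PER_S
    result.D_se = slope_se / 6.0 * A2_PER_PS_TO_CM2_PER_S
    return result


def diffusivity_selectivity(d_i: float, d_j: float) -> float:
    """Diffusivity–selectivity α^D = D_i/D_j."""
    if d_j <= 0:
        raise ValueError("denominator diffusivity must be positive")
    return float(d_i) / float(d_j)
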