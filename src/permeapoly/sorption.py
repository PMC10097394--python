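"""Pressure-decay sorption reduction and solution-diffusion assembly.

A pressure-decay step doses a known amount of gas into a closed cell with
a polymer film; the mass uptake follows from the pressure drop via a gas
equation of state.  Equilibrium (p, c) points build a Henry isotherm whose
zero-intercept slope is the solubility coefficient S = c/p.  The step
kinetics fit the Fickian slab (Crank) solutions for the diffusivity D:
either the constant-surface-concentration series (infinite reservoir) or
the limited-volume solution with root equation tan(q_n) = −α q_n, which
captures the decay of interfacial concentration as the cell pressure
falls.

For semicrystalline samples, a two-phase model with impermeable,
non-sorbing crystals rescales solubility to the amorphous basis,
S_am = S_sc / (1 − X_c).  Solution-diffusion performance combines the
coefficients: P = D·S, α = P_i/P_j = α^D · α^S.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .constants import BAR_TO_PA, BARRER_SI, CM3_TO_M3, R_GAS

__all__ = [
    "SorptionStep",
    "Isotherm",
    "HenryFit",
    "TransportRecord",
    "step_uptake",
    "henry_fit",
    "crank_infinite_uptake",
    "crank_finite_uptake",
    "finite_reservoir_roots",
    "fickian_d_fit",
    "scale_to_amorphous",
    "scale_to_semicrystalline",
    "assemble_performance",
]

SERIES_TOL = 1e-10
SERIES_MIN_TERMS = 50
SERIES_MAX_TERMS = 100000


@dataclass
class SorptionStep:
    """One pressure-decay sorption step.

    ``time_s`` and ``pressure_bar`` are the recorded trace; thickness is
    the full film thickness (both faces exposed).
    """

    time_s: np.ndarray
    pressure_bar: np.ndarray
    cell_volume_cm3: float
    temperature_K: float
    sample_mass_g: float
    thickness_um: float
    crystallinity: float | None = None
    gas: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_bar = np.asarray(self.pressure_bar, dtype=float)
        if self.time_s.shape != self.pressure_bar.shape:
            raise ValueError("time and pressure traces must align")
        if len(self.time_s) < 2:
            raise ValueError("need at least two trace points")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.thickness_um <= 0:
            raise ValueError("film thickness must be positive")
        if self.sample_mass_g <= 0 or self.cell_volume_cm3 <= 0:
            raise ValueError("sample mass and cell volume must be positive")

    @property
    def p_initial(self) -> float:
        return float(self.pressure_bar[0])

    @property
    def p_final(self) -> float:
        return float(self.pressure_bar[-1])


def step_uptake(step: SorptionStep, eos: str = "ideal",
                b_virial_cm3_mol: float | None = None,
                noise_band_bar: float = 0.0) -> np.ndarray:
    """Moles absorbed vs time from the cell mass balance.

    n(t) = V_cell [p(0) − p(t)] / (z R T) with z = 1 (ideal) or the
    second-virial compressibility z = 1 + B p/(RT) evaluated at the mean
    cell pressure.  A significantly negative computed uptake (beyond
    ``noise_band_bar`` on the trace) indicates a leak and raises.
    """
    p = step.pressure_bar
    dp = step.p_initial - p  # bar
    if np.any(dp < -max(noise_band_bar, 0.0) * 3 - 1e-12):
        raise ValueError(
            "pressure rises beyond the noise band: negative uptake "
            "(possible leak or dosing artefact)"
        )
    RT = R_GAS * step.temperature_K  # J/mol
    if eos == "ideal":
        z = 1.0
    elif eos == "virial":
        if b_virial_cm3_mol is None:
            raise ValueError("virial EOS needs b_virial_cm3_mol")
        p_mean_pa = 0.5 * (step.p_initial + p) * BAR_TO_PA
        z = 1.0 + (b_virial_cm3_mol * CM3_TO_M3) * p_mean_pa / RT
    else:
        raise ValueError("eos must be 'ideal' or 'virial'")
    v_m3 = step.cell_volume_cm3 * CM3_TO_M3
    return v_m3 * dp * BAR_TO_PA / (z * RT)


@dataclass
class Isotherm:
    """Equilibrium sorption isotherm: concentration (mol/kg) vs pressure (bar)."""

    pressure_bar: np.ndarray
    concentration_mol_kg: np.ndarray
    gas: str = ""
    basis: str = "total"  # 'total' (semicrystalline) or 'amorphous'
    crystallinity: float | None = None

    def __post_init__(self):
        self.pressure_bar = np.atleast_1d(np.asarray(self.pressure_bar, dtype=float))
        self.concentration_mol_kg = np.atleast_1d(
            np.asarray(self.concentration_mol_kg, dtype=float))
        if self.pressure_bar.shape != self.concentration_mol_kg.shape:
            raise ValueError("pressure and concentration must align")
        if np.any(self.concentration_mol_kg < 0):
            raise ValueError("concentrations must be >= 0")
        order = np.argsort(self.pressure_bar)
        self.pressure_bar = self.pressure_bar[order]
        self.concentration_mol_kg = self.concentration_mol_kg[order]


@dataclass
class HenryFit:
    S_mol_kg_bar: float
    se: float
    r_squared: float
    max_residual: float
    nonlinear: bool = False


def henry_fit(isotherm: Isotherm, nonlinearity_tol: float = 0.05) -> HenryFit:
    """Zero-intercept least squares c = S·p with a linearity diagnostic.

    ``nonlinear`` flags isotherms whose largest relative residual exceeds
    ``nonlinearity_tol`` (convexity/concavity beyond Henry behaviour).
    """
    p = isotherm.pressure_bar
    c = isotherm.concentration_mol_kg
    if len(p) < 1:
        raise ValueError("need at least one isotherm point")
    s = float(np.sum(p * c) / np.sum(p * p))
    resid = c - s * p
    ss_tot = float(np.sum((c - c.mean()) ** 2)) if len(p) > 1 else 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    scale = max(np.abs(c).max(), 1e-300)
    max_rel = float(np.abs(resid).max() / scale)
    dof = max(len(p) - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(p * p))) if len(p) > 1 else 0.0
    return HenryFit(s, se, r2, max_rel, nonlinear=max_rel > nonlinearity_tol)


def crank_infinite_uptake(t_s, d_cm2_s: float, thickness_um: float) -> np.ndarray:
    """Constant-surface-concentration Fickian slab uptake M(t)/M∞.

    M/M∞ = 1 − Σ_n 8/((2n+1)²π²) exp(−(2n+1)²π² D t/ℓ²) for a film of
    full thickness ℓ with both faces exposed.
    """
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    ell_cm = thickness_um * 1e-4
    tau = d_cm2_s * t / ell_cm**2
    pos = tau > 0  # M(0) = 0 exactly; the series converges only for t > 0
    taup = tau[pos]
    acc = np.zeros_like(taup)
    for n in range(SERIES_MAX_TERMS):
        k = (2 * n + 1) ** 2 * np.pi**2
        term = 8.0 / k * np.exp(-k * taup)
        acc += term
        if n >= SERIES_MIN_TERMS and (term.size == 0 or term.max() < SERIES_TOL):
            break
    out = np.zeros_like(tau)
    out[pos] = 1.0 - acc
    return np.clip(out, 0.0, 1.0)


def finite_reservoir_roots(alpha: float, n_roots: int) -> np.ndarray:
    """Positive roots q_n of tan(q) = −α q (limited-volume slab problem)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    roots = np.empty(n_roots)

    def g(q):
        return np.sin(q) + alpha * q * np.cos(q)

    for n in range(1, n_roots + 1):
        lo, hi = (n - 0.5) * np.pi, n * np.pi
        roots[n - 1] = brentq(g, lo + 1e-12, hi - 1e-12)
    return roots


def crank_finite_uptake(t_s, d_cm2_s: float, thickness_um: float,
                        alpha: float, n_roots: int = 200) -> np.ndarray:
    """Limited-volume (finite-reservoir) Fickian slab uptake M(t)/M∞.

    α is the ratio of gas-phase to sample capacity: the fraction of dosed
    gas ultimately absorbed is 1/(1+α).  The film (thickness ℓ, both faces
    exposed) maps onto Crank's half-thickness l = ℓ/2:

        M/M∞ = 1 − Σ_n 2α(1+α)/(1+α+α²q_n²) exp(−D q_n² t / l²),
        tan(q_n) = −α q_n.

    As α → ∞ this reduces to the constant-surface-concentration series.
    """
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    half_cm = thickness_um * 1e-4 / 2.0
    qn = finite_reservoir_roots(alpha, n_roots)
    coeff = 2.0 * alpha * (1.0 + alpha) / (1.0 + alpha + alpha**2 * qn**2)
    out = np.zeros_like(t)
    pos = t > 0  # M(0) = 0 exactly; avoids the truncated-series residue
    expo = np.exp(-d_cm2_s * np.outer(t[pos], qn**2) / half_cm**2)
    out[pos] = 1.0 - expo @ coeff
    return np.clip(out, 0.0, 1.0)


def fickian_d_fit(step: SorptionStep, model: str = "finite_reservoir",
                  eos: str = "ideal", b_virial_cm3_mol: float | None = None,
                  noise_band_bar: float = 0.0) -> tuple:
    """Fit the slab diffusivity D (cm²/s) to one pressure-decay step.

    The normalised uptake M(t)/M∞ comes from the cell mass balance with
    M∞ at the final (equilibrium) pressure.  ``finite_reservoir``
    (default) accounts for the decay of interfacial concentration via the
    limited-volume Crank solution with α inferred from the equilibrium
    pressure drop; ``infinite_reservoir`` uses the constant-concentration
    series.  Returns (D, SE) from the nonlinear least-squares fit.
    """
    n_t = step_uptake(step, eos=eos, b_virial_cm3_mol=b_virial_cm3_mol,
                      noise_band_bar=noise_band_bar)
    # equilibrium uptake from the tail of the trace; averaging suppresses
    # pressure noise and its scatter feeds the normalisation uncertainty
    n_tail = max(3, len(n_t) // 10)
    n_inf = float(np.mean(n_t[-n_tail:]))
    se_ninf = float(np.std(n_t[-n_tail:], ddof=1) / np.sqrt(n_tail))
    if n_inf <= 0:
        raise ValueError("no measurable uptake in this step")
    m_norm = n_t / n_inf
    # monotonicity check beyond the noise band; a point-to-point difference
    # of two independent noisy readings has sd sqrt(2)*sd, and the gate is
    # applied to every consecutive pair, so use a family-wise (~1%) threshold
    n_diffs = max(len(n_t) - 1, 2)
    z_crit = np.sqrt(2.0 * np.log(n_diffs / 0.01))
    tol = z_crit * np.sqrt(2.0) * noise_band_bar / max(
        step.p_initial - step.p_final, 1e-300) + 1e-9
    drops = np.diff(m_norm)
    if np.any(drops < -tol):
        raise ValueError(
            "normalised uptake is non-monotone beyond the noise band; "
            "check the pressure trace quality"
        )
    t = step.time_s - step.time_s[0]

    if model == "infinite_reservoir":
        def predict(d):
            return crank_infinite_uptake(t, d, step.thickness_um)
    elif model == "finite_reservoir":
        frac = (step.p_initial - step.p_final) / step.p_initial
        frac = min(max(frac, 1e-12), 1 - 1e-12)
        alpha = (1.0 - frac) / frac

        def predict(d):
            return crank_finite_uptake(t, d, step.thickness_um, alpha)
    else:
        raise ValueError("model must be 'infinite_reservoir' or 'finite_reservoir'")

    # initial guess from the half-time rule D t_1/2 / ell^2 ~ 0.049
    ell_cm = step.thickness_um * 1e-4
    i_half = int(np.searchsorted(m_norm, 0.5))
    t_half = t[min(i_half, len(t) - 1)] or t[1]
    d0 = 0.04919 * ell_cm**2 / t_half

    def fit_for(norm):
        fit = least_squares(lambda x: predict(10.0 ** x[0]) - norm,
                            x0=[np.log10(d0)], method="lm")
        return fit

    fit = fit_for(m_norm)
    d_hat = 10.0 ** fit.x[0]
    # residual-based SE via the Jacobian in log10 D, propagated to D
    dof = max(len(t) - 1, 1)
    s2 = float(np.sum(fit.fun**2)) / dof
    jtj = float((fit.jac.T @ fit.jac).ravel()[0])
    se_log = np.sqrt(s2 / jtj) if jtj > 0 else np.inf
    se_d = d_hat * np.log(10.0) * se_log
    # propagate the M∞ normalisation uncertainty by refitting at n_inf ± SE
    if se_ninf > 0 and np.isfinite(se_ninf):
        d_shift = 10.0 ** fit_for(n_t / (n_inf + se_ninf)).x[0]
        se_d = float(np.hypot(se_d, abs(d_shift - d_hat)))
    return float(d_hat), float(se_d)


def scale_to_amorphous(s_semicrystalline: float, crystallinity: float) -> float:
    """Amorphous-basis solubility: S_am = S_sc / (1 − X_c).

    Two-phase model: crystals sorb nothing, so all uptake lives in the
    amorphous fraction (1 − X_c) of the mass.
    """
    if not 0.0 <= crystallinity < 1.0:
        raise ValueError("crystallinity must lie in [0, 1)")
    return s_semicrystalline / (1.0 - crystallinity)


def scale_to_semicrystalline(s_amorphous: float, crystallinity: float) -> float:
    """Inverse of :func:`scale_to_amorphous`: S_sc = S_am (1 − X_c)."""
    if not 0.0 <= crystallinity < 1.0:
        raise ValueError("crystallinity must lie in [0, 1)")
    return s_amorphous * (1.0 - crystallinity)


@dataclass
class TransportRecord:
    """Solution-diffusion performance for a gas pair.

    P = D·S per gas and α = α^S·α^D hold exactly by construction.
    Units: S in mol kg⁻¹ bar⁻¹, D in cm²/s, P in mol cm² kg⁻¹ bar⁻¹ s⁻¹
    (the product of the two); ``permeability_barrer`` converts through the
    polymer density when one is supplied.
    """

    gas_i: str
    gas_j: str
    S_i: float
    D_i: float
    S_j: float
    D_j: float
    rho_g_cm3: float | None = None

    def __post_init__(self):
        for name in ("S_i", "D_i", "S_j", "D_j"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def P_i(self) -> float:
        return self.S_i * self.D_i

    @property
    def P_j(self) -> float:
        return self.S_j * self.D_j

    @property
    def alpha_S(self) -> float:
        return self.S_i / self.S_j

    @property
    def alpha_D(self) -> float:
        return self.D_i / self.D_j

    @property
    def alpha(self) -> float:
        return self.P_i / self.P_j

    def permeability_barrer(self, gas: str = "i") -> float:
        """P in Barrer; requires the polymer density (g/cm³).

        P_SI [mol m⁻¹ s⁻¹ Pa⁻¹] = D[cm²/s]·10⁻⁴ · S[mol/kg/bar]·ρ[kg/m³]/10⁵,
        then divided by 1 Barrer = 3.346e-16 mol m⁻¹ s⁻¹ Pa⁻¹.
        """
        if self.rho_g_cm3 is None:
            raise ValueError("Barrer conversion needs the polymer density")
        s, d = (self.S_i, self.D_i) if gas == "i" else (self.S_j, self.D_j)
        rho_kg_m3 = self.rho_g_cm3 * 1000.0
        p_si = d * 1e-4 * s * rho_kg_m3 / BAR_TO_PA
        return p_si / BARRER_SI

    def as_dict(self) -> dict:
        return {
            "gas_i": self.gas_i, "gas_j": self.gas_j,
            "S_i_mol_kg_bar": self.S_i, "S_j_mol_kg_bar": self.S_j,
            "D_i_cm2_s": self.D_i, "D_j_cm2_s": self.D_j,
            "P_i": self.P_i, "P_j": self.P_j,
            "alpha": self.alpha, "alpha_S": self.alpha_S, "alpha_D": self.alpha_D,
        }


def assemble_performance(s_i: float, d_i: float, s_j: float, d_j: float,
                         gas_i: str = "i", gas_j: str = "j",
                         rho_g_cm3: float | None = None) -> TransportRecord:
    """Combine per-gas (S, D) into a solution-diffusion TransportRecord."""
    return TransportRecord(gas_i, gas_j, s_i, d_i, s_j, d_j, rho_g_cm3)
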