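"""Shear-regulated kinetics of the graft wall.

The wall of a vein graft is modeled as two well-mixed compartments, the
tunica intima and tunica media.  Each carries quiescent smooth muscle
cells ``Q`` (logistic turnover toward a volume-derived carrying
capacity), synthetic smooth muscle cells ``S`` (phenotype switch,
proliferation/apoptosis, media-to-intima migration, growth-factor
drive), and collagen ``C`` (produced by synthetic cells, first-order
degradation).  Two growth-factor pools, PDGF (``G_P``) and FGF-2
(``G_F``), accumulate at a constant rate and degrade at a rate
proportional to the wall shear stress (WSS).

The mechanical input enters through nitric oxide: NO production rises
linearly with WSS, and the intimal proliferation, apoptosis and
migration coefficients are scaled down by the NO production relative to
a saturation rate.  High shear therefore quenches intimal growth; low
shear (< ~0.5 Pa) lets the synthetic phenotype expand — the mechanism
behind neointimal hyperplasia localizing at anastomoses.

All kinetic rates are per day; amounts are cells, ng and grams; volumes
are m^3; WSS is in Pa.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

__all__ = [
    "WallState",
    "KineticParameters",
    "LayerCapacity",
    "ShearRates",
    "nitric_oxide_rate",
    "shear_dependent_rates",
    "wall_rhs",
    "integrate_wall_state",
    "growth_factor_steady_state",
    "tissue_volumes",
    "carrying_capacity",
    "fit_pdgf_degradation",
]

#: ordering of the state vector used throughout the package
STATE_FIELDS = ("Q_i", "S_i", "C_i", "G_P", "G_F", "Q_m", "S_m", "C_m")


@dataclass
class WallState:
    """Biochemical state of one wall patch (intima + media).

    Attributes
    ----------
    Q_i, Q_m : float
        Quiescent smooth muscle cells in intima / media [cells].
    S_i, S_m : float
        Synthetic smooth muscle cells in intima / media [cells].
    C_i, C_m : float
        Collagen mass in intima / media [g].
    G_P, G_F : float
        PDGF and FGF-2 amounts in the intima [ng].
    """

    Q_i: float = 0.0
    S_i: float = 0.0
    C_i: float = 0.0
    G_P: float = 0.0
    G_F: float = 0.0
    Q_m: float = 0.0
    S_m: float = 0.0
    C_m: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "WallState":
        return cls(**{f: float(v) for f, v in zip(STATE_FIELDS, y)})

    def validate(self) -> None:
        for f in STATE_FIELDS:
            v = getattr(self, f)
            if not np.isfinite(v):
                raise ValueError(f"wall state field {f} is not finite: {v}")
            if v < 0:
                raise ValueError(f"wall state field {f} is negative: {v}")


@dataclass
class KineticParameters:
    """Rate constants of the wall-growth model.

    Defaults are the published constants of the model; ``phi`` (growth
    factor -> cell production coupling) has no published value and must
    be set deliberately — file loaders require it explicitly.

    Units: rates are per day unless noted; ``zeta_g``/``theta_g`` in
    ng/day; ``lambda_c`` in g/(day·cell); ``k_P``/``k_F`` in
    1/(day·Pa); NO coefficients in nM/s (``no_unit_scale`` converts the
    raw linear-law output to nM/s, see Notes); densities in cells/m^3
    and g/m^3.

    Notes
    -----
    The published NO production law ``R_NO = c0 + c1*WSS`` is printed
    with ambiguous units next to a saturation rate of 0.1 uM/s.  Taken
    literally the production/saturation ratio would exceed one already
    at zero shear.  The adopted convention reads the law's output as
    nM/s, i.e. ``R_NO_MAX = 100`` nM/s, and additionally clamps the
    ratio to [0, 1].  Both are config-exposed (``no_unit_scale``,
    ``clamp_ratio``).
    """

    beta: float = 5e-4            # quiescent-cell turnover [1/day]
    gamma: float = 1e-4           # quiescent -> synthetic differentiation [1/day]
    p_m: float = 0.122            # medial SMC proliferation [1/day]
    a_m: float = 0.0715           # medial SMC apoptosis [1/day]
    m0: float = 0.0251            # medial SMC migration coefficient [1/day]
    phi: float = 1.0              # cell production per growth factor [cells/(ng·day)]
    lambda_c: float = 2.16e-13    # collagen production [g/(day·cell)]
    chi: float = 0.033            # collagen degradation [1/day]
    zeta_g: float = 0.0776        # PDGF production [ng/day]
    theta_g: float = 0.1394       # FGF-2 production [ng/day]
    k_P: float = 1.94e-4          # PDGF degradation slope vs WSS [1/(day·Pa)]
    k_F: float = 6.97e-4          # FGF-2 degradation slope vs WSS [1/(day·Pa)]
    c0: float = 1.74              # NO production at zero shear [nM/s]
    c1: float = 7.52              # NO production slope [nM/(s·Pa)]
    R_NO_MAX: float = 100.0       # saturation NO production [nM/s]
    rho_s: float = 2.18e14        # cell density [cells/m^3]
    rho_c: float = 2e3            # collagen density [g/m^3]
    no_unit_scale: float = 1.0    # multiplies (c0 + c1*wss); unit convention hook
    clamp_ratio: bool = True      # clamp R_NO/R_NO_MAX into [0, 1]
    media_equilibrium: bool = False  # rescale a_m so p_m - a_m - m0 = 0

    RATE_FIELDS = (
        "beta", "gamma", "p_m", "a_m", "m0", "phi", "lambda_c", "chi",
        "zeta_g", "theta_g", "k_P", "k_F", "R_NO_MAX", "rho_s", "rho_c",
    )

    def __post_init__(self) -> None:
        for f in self.RATE_FIELDS:
            if getattr(self, f) < 0:
                raise ValueError(f"kinetic parameter {f} must be >= 0")

    @property
    def a_m_effective(self) -> float:
        """Medial apoptosis rate; in media-equilibrium mode rescaled so the
        medial synthetic pool is stationary (p_m - a_m - m0 = 0)."""
        if self.media_equilibrium:
            return self.p_m - self.m0
        return self.a_m

    def replace(self, **kw) -> "KineticParameters":
        return dataclasses.replace(self, **kw)


@dataclass
class LayerCapacity:
    """Carrying capacities of a wall patch.

    ``Q_max = V_max * rho_s``: the cell ceiling is set by the volume
    available to the layer times cell density.
    """

    Q_i_max: float
    Q_m_max: float
    V_i_max: float
    V_m_max: float

    def __post_init__(self) -> None:
        for f in ("Q_i_max", "Q_m_max", "V_i_max", "V_m_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"capacity field {f} must be > 0")

    @classmethod
    def from_volumes(cls, V_i_max: float, V_m_max: float,
                     params: KineticParameters) -> "LayerCapacity":
        return cls(
            Q_i_max=carrying_capacity(V_i_max, params),
            Q_m_max=carrying_capacity(V_m_max, params),
            V_i_max=V_i_max,
            V_m_max=V_m_max,
        )


@dataclass
class ShearRates:
    """Shear-dependent kinetic coefficients at one WSS value."""

    R_NO: float       # NO production rate [nM/s]
    ratio: float      # clamped R_NO / R_NO_MAX
    p_i: float        # intimal proliferation [1/day]
    a_i: float        # intimal apoptosis [1/day]
    m: float          # media->intima migration [1/day]
    zeta_d: float     # PDGF degradation [1/day]
    theta_d: float    # FGF-2 degradation [1/day]


def nitric_oxide_rate(wss: float, params: KineticParameters | None = None) -> float:
    """NO production rate for a given wall shear stress.

    Linear law ``R_NO = c0 + c1 * wss`` (output scaled by
    ``no_unit_scale``), strictly increasing in shear for ``c1 > 0``.
    """
    if params is None:
        params = KineticParameters()
    if wss < 0:
        raise ValueError(f"wall shear stress must be >= 0 Pa, got {wss}")
    return params.no_unit_scale * (params.c0 + params.c1 * wss)


def shear_dependent_rates(wss: float, params: KineticParameters | None = None) -> ShearRates:
    """Evaluate all shear-dependent kinetic coefficients at one WSS.

    The intimal proliferation/apoptosis/migration coefficients are the
    medial values scaled by ``1 - R_NO/R_NO_MAX`` (NO inhibition);
    growth-factor degradation is linear in shear.
    """
    if params is None:
        params = KineticParameters()
    if params.R_NO_MAX <= 0:
        raise ValueError("R_NO_MAX must be > 0")
    r_no = nitric_oxide_rate(wss, params)
    ratio = r_no / params.R_NO_MAX
    if params.clamp_ratio:
        ratio = min(max(ratio, 0.0), 1.0)
    one_minus = 1.0 - ratio
    return ShearRates(
        R_NO=r_no,
        ratio=ratio,
        p_i=params.p_m * one_minus,
        a_i=params.a_m_effective * one_minus,
        m=params.m0 * one_minus,
        zeta_d=params.k_P * wss,
        theta_d=params.k_F * wss,
    )


def wall_rhs(state: WallState | np.ndarray, rates: ShearRates,
             params: KineticParameters, cap: LayerCapacity) -> np.ndarray:
    """Time derivative of the eight wall states [per day].

    dQ   = beta*Q*(1 - Q/Q_max)                         (both layers)
    dS_i = gamma*Q_i + (p_i - a_i)*S_i + m*S_m + phi*(G_P + G_F)
    dS_m = gamma*Q_m + (p_m - a_m - m)*S_m
    dC   = lambda*S - chi*C                             (both layers)
    dG_P = zeta_g - zeta_d*G_P
    dG_F = theta_g - theta_d*G_F
    """
    y = state.as_array() if isinstance(state, WallState) else np.asarray(state, dtype=float)
    Q_i, S_i, C_i, G_P, G_F, Q_m, S_m, C_m = y
    if cap.Q_i_max <= 0 or cap.Q_m_max <= 0:
        raise ValueError("carrying capacities must be > 0")
    a_m = params.a_m_effective
    dQ_i = params.beta * Q_i * (1.0 - Q_i / cap.Q_i_max)
    dQ_m = params.beta * Q_m * (1.0 - Q_m / cap.Q_m_max)
    dS_i = (params.gamma * Q_i + (rates.p_i - rates.a_i) * S_i
            + rates.m * S_m + params.phi * (G_P + G_F))
    # migration out of the media matches the shear-dependent inflow to the intima
    dS_m = params.gamma * Q_m + (params.p_m - a_m - rates.m) * S_m
    dC_i = S_i * params.lambda_c - C_i * params.chi
    dC_m = S_m * params.lambda_c - C_m * params.chi
    dG_P = params.zeta_g - rates.zeta_d * G_P
    dG_F = params.theta_g - rates.theta_d * G_F
    return np.array([dQ_i, dS_i, dC_i, dG_P, dG_F, dQ_m, dS_m, dC_m])


@dataclass
class WallTrajectory:
    """Daily-sampled solution of the wall ODE at constant shear."""

    t: np.ndarray                 # sample times [days]
    y: np.ndarray                 # (n_samples, 8) states, STATE_FIELDS order
    wss: float
    states: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.states:
            self.states = [WallState.from_array(row) for row in self.y]

    @property
    def final(self) -> WallState:
        return self.states[-1]


_NEG_TOL = 1e-9  # relative non-negativity tolerance for integrator output


def integrate_wall_state(state0: WallState, wss: float,
                         params: KineticParameters, cap: LayerCapacity,
                         days: float, dt: float = 1.0,
                         rtol: float = 1e-8, atol: float = 1e-6) -> WallTrajectory:
    """Integrate the wall ODE at constant WSS for ``days`` days.

    Uses an adaptive explicit Runge-Kutta scheme (RK45) with output
    sampled every ``dt`` days (default 1, the biochemical step of the
    remodeling cycle).  Samples are projected onto the non-negative
    orthant: violations below a 1e-9 relative tolerance are clipped,
    larger ones abort with a diagnostic.
    """
    if days <= 0:
        raise ValueError("days must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state0.validate()
    rates = shear_dependent_rates(wss, params)
    t_eval = np.arange(0.0, days + 0.5 * dt, dt)
    if t_eval[-1] < days:
        t_eval = np.append(t_eval, days)
    t_eval[-1] = days
    sol = solve_ivp(
        lambda t, y: wall_rhs(y, rates, params, cap),
        (0.0, days), state0.as_array(), method="RK45",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"wall ODE integration failed: {sol.message}")
    y = sol.y.T
    scale = np.maximum(np.abs(y).max(axis=0), 1.0)
    worst = (y / scale).min()
    if worst < -_NEG_TOL:
        raise RuntimeError(
            f"integrator produced negative population beyond tolerance "
            f"(relative violation {worst:.3e}) at WSS={wss} Pa")
    y = np.clip(y, 0.0, None)
    return WallTrajectory(t=sol.t, y=y, wss=wss)


def growth_factor_steady_state(params: KineticParameters, wss: float) -> tuple[float, float]:
    """Steady growth-factor amounts ``(G_P*, G_F*)`` at constant shear.

    ``G_P* = zeta_g / (k_P * wss)`` and analogously for FGF-2; at zero
    shear degradation vanishes and the pools grow without bound.
    """
    if wss <= 0:
        raise ValueError("no growth-factor steady state at WSS <= 0: "
                         "degradation vanishes and the pool accumulates unboundedly")
    return params.zeta_g / (params.k_P * wss), params.theta_g / (params.k_F * wss)


def tissue_volumes(state: WallState, params: KineticParameters) -> tuple[float, float]:
    """Layer volumes ``(V_i, V_m)`` in m^3 from cell counts and collagen.

    ``V = (S + Q)/rho_s + C/rho_c`` per layer.
    """
    if params.rho_s <= 0 or params.rho_c <= 0:
        raise ValueError("densities must be > 0")
    V_i = (state.S_i + state.Q_i) / params.rho_s + state.C_i / params.rho_c
    V_m = (state.S_m + state.Q_m) / params.rho_s + state.C_m / params.rho_c
    return V_i, V_m


def carrying_capacity(V_max: float, params: KineticParameters) -> float:
    """Cell carrying capacity of a layer of maximum volume ``V_max`` [m^3]."""
    if V_max <= 0:
        raise ValueError("V_max must be > 0")
    return V_max * params.rho_s


def fit_pdgf_degradation(t: np.ndarray, g_p: np.ndarray,
                         params: KineticParameters, g_p0: float = 0.0) -> float:
    """Recover the PDGF degradation rate from a sampled trajectory.

    Least-squares fit of the closed form
    ``G_P(t) = G* + (G_P(0) - G*) exp(-zeta_d t)``, ``G* = zeta_g/zeta_d``,
    with ``zeta_d`` the only free parameter (``zeta_g`` and the initial
    amount known).  Returns the estimate in 1/day.
    """
    t = np.asarray(t, dtype=float)
    g_p = np.asarray(g_p, dtype=float)

    def model(tt, zeta_d):
        g_star = params.zeta_g / zeta_d
        return g_star + (g_p0 - g_star) * np.exp(-zeta_d * tt)

    zeta0 = params.k_P  # order-of-magnitude start: slope at 1 Pa
    popt, _ = curve_fit(model, t, g_p, p0=[zeta0], bounds=(1e-12, np.inf))
    return float(popt[0])
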