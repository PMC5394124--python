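"""Reduced-order pulsatile hemodynamics.

Replaces a full 3-D CFD stage with station-wise Poiseuille shear on an
axisymmetric vessel tree driven by a periodic inflow waveform, with
lumped-parameter (Windkessel) outflow boundaries setting the flow split
at bifurcations.  The biochemical model consumes only the cycle-averaged
wall shear stress, which at these radii is dominated by the cycle-mean
flow, so a quasi-steady shear law is used (Womersley effects neglected).

Hemodynamic wall indices:

* TAWSS — time-averaged magnitude of wall shear stress over a cycle;
* OSI   — oscillatory shear index, 0 (unidirectional) to 0.5 (purely
  oscillatory);
* RRT   — relative residence time, ``1 / ((1 - 2 OSI) * TAWSS)``.

Units are SI internally (m, s, Pa, m^3/s); file loaders convert from
the clinical units (mm, ml, Pa·s/ml).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import uniform_filter1d

from .vessel_geometry import VesselTree

__all__ = [
    "FlowWaveform",
    "WindkesselElement",
    "WindkesselNetwork",
    "ShearSeries",
    "StationField",
    "smooth_waveform",
    "parabolic_profile",
    "flow_rate_from_vmax",
    "station_wss",
    "tawss",
    "osi",
    "rrt",
    "steady_flow_split",
    "solve_windkessel",
    "calibrate_outlet_parameters",
    "compute_field",
]

BLOOD_VISCOSITY = 0.0035   # Pa·s
BLOOD_DENSITY = 1050.0     # kg/m^3


@dataclass
class FlowWaveform:
    """One period of a sampled periodic inflow.

    ``t`` holds strictly increasing sample times in ``[0, period)``;
    the signal extends periodically, ``v(t + period) = v(t)``.  ``kind``
    tags the sample values as centerline velocity [m/s] or volumetric
    flow [m^3/s].
    """

    t: np.ndarray
    v: np.ndarray
    period: float
    kind: str = "flow"  # "flow" | "velocity"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.period <= 0:
            raise ValueError("waveform period must be > 0")
        if self.t.size < 8:
            raise ValueError("waveform needs at least 8 samples per period")
        if self.t.size != self.v.size:
            raise ValueError("time and value arrays differ in length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.t[0] < 0 or self.t[-1] >= self.period:
            raise ValueError("sample times must lie in [0, period)")
        if self.kind not in ("flow", "velocity"):
            raise ValueError(f"waveform kind must be 'flow' or 'velocity', got {self.kind!r}")

    @property
    def mean(self) -> float:
        """Cycle mean by periodic trapezoidal rule."""
        tc, vc = self._closed()
        return float(np.trapezoid(vc, tc) / self.period)

    def _closed(self) -> tuple[np.ndarray, np.ndarray]:
        """Samples with the periodic seam closed (first point repeated at t0+T)."""
        return (np.append(self.t, self.t[0] + self.period),
                np.append(self.v, self.v[0]))

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation at arbitrary times."""
        tc, vc = self._closed()
        return np.interp((np.asarray(times, dtype=float) - self.t[0]) % self.period
                         + self.t[0], tc, vc)

    def to_flow(self, inlet_radius: float) -> "FlowWaveform":
        """Convert a velocity-tagged waveform to volumetric flow via the
        parabolic-profile relation ``Q = v_max * pi * R^2 / 2``."""
        if self.kind == "flow":
            return self
        q = flow_rate_from_vmax(1.0, inlet_radius) * self.v
        return replace(self, v=q, kind="flow")


@dataclass
class WindkesselElement:
    """One lumped outflow boundary: resistance R [Pa·s/m^3], capacitance
    C [m^3/Pa] and optional inertance L [Pa·s^2/m^3] (default 0)."""

    R: float
    C: float = 0.0
    L: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("Windkessel resistance must be > 0")
        if self.C < 0 or self.L < 0:
            raise ValueError("Windkessel C and L must be >= 0")


@dataclass
class WindkesselNetwork:
    """Parallel bank of outflow elements, one per tree outlet, all fed
    from a common junction node and independently grounded."""

    elements: dict[str, WindkesselElement]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("network needs at least one element")

    def check_outlets(self, outlet_ids) -> None:
        missing = set(outlet_ids) - set(self.elements)
        if missing:
            raise ValueError(f"no Windkessel element for outlets: {sorted(missing)}")


@dataclass
class ShearSeries:
    """Signed wall shear stress over one cycle at one station."""

    station_id: str
    t: np.ndarray
    tau: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.t.size == 0:
            raise ValueError("empty shear series")
        if self.t.size != self.tau.size:
            raise ValueError("time and shear arrays differ in length")


def smooth_waveform(raw: FlowWaveform, window: int) -> FlowWaveform:
    """Centered moving average with periodic wrap.

    Removes the unphysiological spikes of Doppler-derived velocity
    traces; preserves the cycle mean exactly and never raises the
    maximum.  ``window`` must be odd (centered) and at most the sample
    count.  Assumes a uniform sampling grid.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if not 1 <= window <= raw.t.size:
        raise ValueError("smoothing window must be in [1, n_samples]")
    dts = np.diff(np.append(raw.t, raw.t[0] + raw.period))
    if not np.allclose(dts, dts[0], rtol=1e-8):
        raise ValueError("moving-average smoothing requires a uniform sampling grid")
    v = uniform_filter1d(raw.v, size=window, mode="wrap")
    return replace(raw, v=v)


def parabolic_profile(vmax: float, r: float, Rmax: float) -> float:
    """Axial velocity of a parabolic (Poiseuille) profile at radius r:
    ``u(r) = vmax * (1 - r^2/Rmax^2)``."""
    if Rmax <= 0:
        raise ValueError("lumen radius must be > 0")
    if r < 0 or r > Rmax:
        raise ValueError("radial position must lie in [0, Rmax]")
    return vmax * (1.0 - r * r / (Rmax * Rmax))


def flow_rate_from_vmax(vmax: float, Rmax: float) -> float:
    """Volumetric flow of a parabolic profile: ``Q = vmax * pi * Rmax^2 / 2``."""
    if Rmax <= 0:
        raise ValueError("lumen radius must be > 0")
    return vmax * np.pi * Rmax * Rmax / 2.0


def station_wss(Q: float, radius: float, mu: float = BLOOD_VISCOSITY) -> float:
    """Signed Poiseuille wall shear stress ``tau = 4 mu Q / (pi r^3)``."""
    if radius <= 0:
        raise ValueError("station radius must be > 0 (occluded station?)")
    if mu <= 0:
        raise ValueError("viscosity must be > 0")
    return 4.0 * mu * Q / (np.pi * radius ** 3)


def _close_period(series: ShearSeries) -> tuple[np.ndarray, np.ndarray]:
    t, tau = series.t, series.tau
    if t[-1] < series.period:
        t = np.append(t, t[0] + series.period)
        tau = np.append(tau, tau[0])
    return t, tau


def tawss(series: ShearSeries) -> float:
    """Time-averaged wall shear stress magnitude over one cycle
    (trapezoidal rule, periodic seam closed)."""
    t, tau = _close_period(series)
    return float(np.trapezoid(np.abs(tau), t) / series.period)


def osi(series: ShearSeries) -> float:
    """Oscillatory shear index ``0.5 * (1 - |∫tau| / ∫|tau|)`` in [0, 0.5];
    defined as 0 for an identically zero series."""
    t, tau = _close_period(series)
    denom = np.trapezoid(np.abs(tau), t)
    if denom == 0:
        return 0.0
    val = 0.5 * (1.0 - abs(np.trapezoid(tau, t)) / denom)
    return float(min(max(val, 0.0), 0.5))


def rrt(tawss_value: float, osi_value: float) -> float:
    """Relative residence time ``1 / ((1 - 2 OSI) * TAWSS)`` [1/Pa]."""
    if tawss_value <= 0:
        raise ValueError("RRT needs TAWSS > 0")
    if not 0 <= osi_value <= 0.5:
        raise ValueError("OSI must lie in [0, 0.5]")
    if osi_value >= 0.5:
        raise ValueError("RRT unbounded at OSI = 0.5 (purely oscillatory shear)")
    return 1.0 / ((1.0 - 2.0 * osi_value) * tawss_value)


def steady_flow_split(resistances) -> np.ndarray:
    """Flow fractions of a parallel resistive bank: conductance ratios."""
    r = np.asarray(list(resistances), dtype=float)
    if r.size == 0:
        raise ValueError("empty resistance list")
    if np.any(r <= 0):
        raise ValueError("all resistances must be > 0")
    g = 1.0 / r
    return g / g.sum()


@dataclass
class WindkesselSolution:
    """Last (periodically converged) cycle of a lumped-network solve."""

    t: np.ndarray                       # times within the final cycle [s]
    pressure: np.ndarray                # junction pressure [Pa]
    outlet_flows: dict[str, np.ndarray]  # flow delivered through each outlet [m^3/s]
    converged: bool
    cycle_residual: float               # max relative pressure change, last two cycles


def solve_windkessel(network: WindkesselNetwork, inflow: FlowWaveform,
                     dt: float | None = None, n_cycles: int = 6) -> WindkesselSolution:
    """Integrate the lumped outflow network driven by a periodic inflow.

    Hydraulic-electrical analogy: the prescribed inflow enters a common
    junction whose pressure P loads each outlet element in parallel.
    Per element, the capacitor hangs at the junction and the resistor
    (with optional series inertance) drains to ground:

        sum(C_k) dP/dt = Q_in(t) - sum(q_k),
        q_k = P/R_k                    (L_k = 0)
        L_k dq_k/dt = P - R_k q_k      (L_k > 0)

    Fixed-step RK4 from zero pressure over ``n_cycles`` cycles; the last
    cycle is returned once the cycle-to-cycle peak pressure change drops
    below 0.5% (a warning is emitted otherwise).  For a purely resistive
    bank the outlet flows sum to the inflow at every instant.
    """
    if inflow.kind != "flow":
        raise ValueError("solve_windkessel needs a flow-tagged waveform "
                         "(convert velocity via FlowWaveform.to_flow)")
    period = inflow.period
    if dt is None:
        dt = period / 1000.0
    if dt > period / 100.0:
        raise ValueError("dt must be <= period/100")
    if n_cycles < 2:
        raise ValueError("need at least 2 cycles to assess periodicity")

    ids = list(network.elements)
    R = np.array([network.elements[k].R for k in ids])
    C = np.array([network.elements[k].C for k in ids])
    L = np.array([network.elements[k].L for k in ids])
    C_tot = C.sum()
    inertial = L > 0

    n_per = int(round(period / dt))
    dt = period / n_per  # snap so cycles tile exactly

    def q_in(t):
        return inflow.sample(np.atleast_1d(t))[0]

    # state: [P, q_k for inertial outlets]
    n_q = int(inertial.sum())

    def rhs(t, y):
        P = y[0]
        q = np.empty(len(ids))
        q[~inertial] = P / R[~inertial]
        if n_q:
            q[inertial] = y[1:]
        dy = np.empty_like(y)
        if C_tot > 0:
            dy[0] = (q_in(t) - q.sum()) / C_tot
        else:
            dy[0] = 0.0
        if n_q:
            dy[1:] = (P - R[inertial] * y[1:]) / L[inertial]
        return dy

    y = np.zeros(1 + n_q)
    prev_cycle_p = None
    converged = False
    residual = np.inf
    t_cycle = np.arange(n_per + 1) * dt

    for cycle in range(n_cycles):
        p_hist = np.empty(n_per + 1)
        q_hist = np.empty((n_per + 1, len(ids)))

        def record(i, t, y):
            P = y[0]
            if C_tot == 0:
                # purely resistive junction: algebraic pressure
                P = q_in(t) / (1.0 / R).sum()
            p_hist[i] = P
            q_hist[i, ~inertial] = P / R[~inertial]
            if n_q:
                q_hist[i, inertial] = y[1:]

        t0 = cycle * period
        record(0, t0, y)
        for i in range(n_per):
            t = t0 + i * dt
            k1 = rhs(t, y)
            k2 = rhs(t + dt / 2, y + dt / 2 * k1)
            k3 = rhs(t + dt / 2, y + dt / 2 * k2)
            k4 = rhs(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            record(i + 1, t + dt, y)

        if prev_cycle_p is not None:
            scale = max(np.abs(p_hist).max(), 1e-30)
            residual = float(np.abs(p_hist - prev_cycle_p).max() / scale)
            if residual < 5e-3:
                converged = True
                if cycle >= 1:
                    break
        prev_cycle_p = p_hist.copy()

    if not converged:
        warnings.warn(
            f"Windkessel solve did not reach periodic convergence in {n_cycles} "
            f"cycles (residual {residual:.3e}); returning last cycle", RuntimeWarning)
    flows = {k: q_hist[:, j].copy() for j, k in enumerate(ids)}
    return WindkesselSolution(t=t_cycle, pressure=p_hist, outlet_flows=flows,
                              converged=converged, cycle_residual=residual)


def calibrate_outlet_parameters(network: WindkesselNetwork, targets: Mapping[str, float],
                                inflow: FlowWaveform, tol: float = 0.01,
                                max_iter: int = 100) -> WindkesselNetwork:
    """Rescale outlet resistances so cycle-mean outlet flows match targets.

    Fixed-point conductance update ``g_k <- g_k * (measured_k/target_k)^-1``
    (capacitances held); stops when every outlet mean flow is within
    ``tol`` relative of its target.  Targets must sum to the inflow mean
    within 2% (mass feasibility).
    """
    network.check_outlets(targets.keys())
    if set(targets) != set(network.elements):
        raise ValueError("targets must cover exactly the network outlets")
    q_mean = inflow.mean
    tsum = sum(targets.values())
    if abs(tsum - q_mean) > 0.02 * abs(q_mean):
        raise ValueError(
            f"infeasible targets: sum {tsum:.4g} vs inflow mean {q_mean:.4g} m^3/s")
    elements = dict(network.elements)
    ids = list(elements)
    tvec = np.array([targets[k] for k in ids])
    if np.any(tvec <= 0):
        raise ValueError("target flows must be > 0")
    for _ in range(max_iter):
        trial = WindkesselNetwork(elements=elements)
        sol = solve_windkessel(trial, inflow, dt=inflow.period / 200, n_cycles=8)
        measured = np.array([
            np.trapezoid(sol.outlet_flows[k], sol.t) / inflow.period for k in ids])
        err = np.abs(measured - tvec) / tvec
        if err.max() < tol:
            return trial
        factors = measured / tvec  # conductance too high where flow too high
        elements = {
            k: replace(elements[k], R=elements[k].R * factors[j])
            for j, k in enumerate(ids)}
    raise RuntimeError("outlet calibration did not converge within max_iter")


@dataclass
class StationField:
    """Per-station hemodynamic summary for one epoch."""

    station_id: str
    z: float
    radius: float
    tags: tuple
    tawss: float
    osi: float
    rrt: float
    series: ShearSeries = field(repr=False, default=None)


def compute_field(tree: VesselTree, inflow: FlowWaveform,
                  network: WindkesselNetwork | None = None,
                  mu: float = BLOOD_VISCOSITY, rho: float = BLOOD_DENSITY,
                  disturbance: Mapping[str, float] | None = None,
                  radius_floor: float = 1e-4) -> list[StationField]:
    """Station-wise shear field: waveform propagation + Poiseuille shear.

    The inflow waveform (converted to flow at the inlet radius if
    velocity-tagged) is pushed through the tree; at each bifurcation the
    flow splits by the downstream Windkessel conductances (single-outlet
    trees carry the full flow everywhere).  Each station's signed shear
    series is ``4 mu Q(t) / (pi r^3)``, optionally scaled by a
    per-station multiplicative disturbance profile emulating the shear
    depression near anastomoses and bifurcations that a full 3-D solve
    resolves.  Stations at or below ``radius_floor`` are evaluated at
    the floor radius with a warning.
    """
    tree.validate()
    q_in = inflow.to_flow(tree.inlet_radius)
    if network is not None:
        network.check_outlets(tree.outlet_ids)
        fracs = steady_flow_split([network.elements[k].R for k in tree.outlet_ids])
        outlet_frac = dict(zip(tree.outlet_ids, fracs))
    else:
        if len(tree.outlet_ids) > 1:
            raise ValueError("a Windkessel network is required for multi-outlet trees")
        outlet_frac = {tree.outlet_ids[0]: 1.0}
    seg_frac = tree.segment_flow_fractions(outlet_frac)

    out: list[StationField] = []
    for seg_name, stations in tree.segments.items():
        f = seg_frac[seg_name]
        for st in stations:
            r = st.radius
            if r <= radius_floor:
                warnings.warn(f"station {st.id} at/below occlusion floor; "
                              f"shear evaluated at floor radius", RuntimeWarning)
                r = radius_floor
            scale = 1.0
            if disturbance is not None:
                scale = disturbance.get(st.id, 1.0)
            tau = scale * 4.0 * mu * (f * q_in.v) / (np.pi * r ** 3)
            series = ShearSeries(station_id=st.id, t=q_in.t, tau=tau, period=q_in.period)
            ta = tawss(series)
            os_ = osi(series)
            rr = rrt(ta, os_) if (ta > 0 and os_ < 0.5) else float("inf")
            out.append(StationField(station_id=st.id, z=st.z, radius=st.radius,
                                    tags=tuple(st.tags), tawss=ta, osi=os_,
                                    rrt=rr, series=series))
    return out
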