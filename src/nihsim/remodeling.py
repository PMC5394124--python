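"""The hemodynamics <-> wall-growth feedback loop.

One remodeling epoch: (1) the reduced-order hemodynamics yields a
cycle-averaged wall shear stress per station; (2) each station's wall
kinetics are integrated at 1-day steps with its TAWSS held frozen for
the coupling interval (time-scale splitting: cardiac cycles are
seconds, wall growth is months); (3) the intimal volume gained is laid
onto the geometry as an inward ring, shrinking the lumen; (4) the shear
field is recomputed on the narrowed lumen and the cycle repeats until
the total simulated time is covered.

Shrinking a lumen at fixed flow raises its shear (tau ~ r^-3), which
quenches the NO-mediated growth stimulus — the negative feedback that
lets low-shear regions (anastomoses) keep growing while shear
normalizes elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .biochemistry import (KineticParameters, LayerCapacity, WallState,
                           integrate_wall_state, shear_dependent_rates,
                           tissue_volumes)
from .hemodynamics import (FlowWaveform, StationField, WindkesselNetwork,
                           compute_field)
from .vessel_geometry import VesselTree, apply_growth, occlusion_percentage

__all__ = [
    "RemodelingConfig",
    "EpochRecord",
    "RemodelingHistory",
    "initialize_wall_patches",
    "run_remodeling",
    "low_wss_area",
    "summarize",
]

ANASTOMOSIS_TAGS = frozenset({"proximal_anastomosis", "distal_anastomosis", "bifurcation"})


@dataclass
class RemodelingConfig:
    """Knobs of the remodeling loop.

    ``coupling_interval_days`` is how long TAWSS stays frozen between
    hemodynamic recomputes (default 60 d, one clinical follow-up step);
    ``dt_bio_days`` the biochemical output step (default 1 d).  Initial
    wall patches are seeded at ``q_init_fraction`` of the quiescent
    carrying capacity with a synthetic-cell seed of ``s_seed_fraction``
    of Q, collagen at its turnover steady state and growth factors at
    their shear steady state.  The intimal carrying volume is the
    annulus from the lumen down to ``intima_reserve_fraction`` of the
    initial radius (default 0.9, i.e. a healthy intimal layer about a
    tenth of the radius thick); the media is a fixed annulus of
    ``media_thickness``.  The defaults put a 120-day femoropopliteal
    run in the published growth regime (order 1 mm of intimal
    thickening, concentrated at the anastomoses).
    """

    total_days: float = 120.0
    coupling_interval_days: float = 60.0
    dt_bio_days: float = 1.0
    low_wss_threshold: float = 0.5        # Pa
    restenosis_threshold: float = 50.0    # percent area loss
    rng_seed: int = 0
    radius_floor: float = 1e-4            # m
    mu: float = 0.0035                    # Pa·s
    rho: float = 1050.0                   # kg/m^3
    q_init_fraction: float = 0.95
    s_seed_fraction: float = 1e-4
    intima_reserve_fraction: float = 0.9
    media_thickness: float = 5e-4         # m

    def __post_init__(self) -> None:
        if self.total_days < 1:
            raise ValueError("total_days must be >= 1")
        if not 0 < self.coupling_interval_days <= self.total_days:
            raise ValueError("coupling interval must be in (0, total_days]")
        if not 0 < self.dt_bio_days <= self.coupling_interval_days:
            raise ValueError("dt_bio_days must be in (0, coupling_interval_days]")

    def epoch_durations(self) -> list[float]:
        """Epoch lengths summing exactly to total_days (last may be short)."""
        out = []
        remaining = self.total_days
        while remaining > 1e-9:
            d = min(self.coupling_interval_days, remaining)
            out.append(d)
            remaining -= d
        out[-1] += self.total_days - sum(out)  # absorb rounding
        return out


@dataclass
class EpochRecord:
    """Snapshot at the end of one epoch (epoch 0 = day 0, pre-growth)."""

    day: float
    tree: VesselTree                      # deep-copied geometry after growth
    fields: list[StationField]            # shear field that drove this epoch
    wall: dict[str, WallState]
    dV_i: dict[str, float]                # intimal volume laid down [m^3]
    stimulus: dict[str, float]            # net intimal proliferation p_i - a_i [1/day]
    occlusion: dict[str, float]           # percent vs baseline
    low_wss_area_cm2: float

    @property
    def tawss(self) -> dict[str, float]:
        return {f.station_id: f.tawss for f in self.fields}


@dataclass
class RemodelingHistory:
    epochs: list[EpochRecord] = field(default_factory=list)
    tree0: VesselTree | None = None
    config: RemodelingConfig | None = None

    @property
    def final_tree(self) -> VesselTree:
        return self.epochs[-1].tree


def initialize_wall_patches(tree: VesselTree, params: KineticParameters,
                            tawss: Mapping[str, float],
                            config: RemodelingConfig) -> None:
    """Attach a healthy-baseline wall patch to every station, in place.

    Capacities derive from the volume available to each layer:
    intimal ceiling = annulus from the current lumen down to
    ``intima_reserve_fraction`` of the initial radius, medial volume a
    fixed annulus outside the lumen.  Growth factors start at their
    steady state for the station's initial shear (zero at zero shear).
    """
    for st in tree.stations():
        r, L = st.radius, st.length
        V_i_max = np.pi * (r ** 2 - (config.intima_reserve_fraction * r) ** 2) * L
        r_out = r + config.media_thickness
        V_m_max = np.pi * (r_out ** 2 - r ** 2) * L
        cap = LayerCapacity.from_volumes(V_i_max, V_m_max, params)
        Q_i = config.q_init_fraction * cap.Q_i_max
        Q_m = config.q_init_fraction * cap.Q_m_max
        S_i = config.s_seed_fraction * Q_i
        S_m = config.s_seed_fraction * Q_m
        w = tawss[st.id]
        # steady state needs nonzero degradation; otherwise start empty
        G_P = params.zeta_g / (params.k_P * w) if params.k_P * w > 0 else 0.0
        G_F = params.theta_g / (params.k_F * w) if params.k_F * w > 0 else 0.0
        # collagen turnover steady state C* = S*lambda/chi (empty if no turnover)
        c_per_s = params.lambda_c / params.chi if params.chi > 0 else 0.0
        st.capacity = cap
        st.wall = WallState(
            Q_i=Q_i, S_i=S_i, C_i=S_i * c_per_s,
            G_P=G_P, G_F=G_F,
            Q_m=Q_m, S_m=S_m, C_m=S_m * c_per_s,
        )


def low_wss_area(tree: VesselTree, tawss: Mapping[str, float],
                 threshold: float = 0.5, station_filter: Callable | None = None) -> float:
    """Lateral lumen surface [cm^2] of stations with TAWSS below threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    total = 0.0
    for st in tree.stations():
        if station_filter is not None and not station_filter(st):
            continue
        if tawss[st.id] < threshold:
            total += st.lateral_area
    return total * 1e4  # m^2 -> cm^2


def run_remodeling(tree: VesselTree, inflow: FlowWaveform,
                   network: WindkesselNetwork | None,
                   params: KineticParameters, config: RemodelingConfig,
                   disturbance: Mapping[str, float] | None = None,
                   tawss_source: Callable[[VesselTree], Mapping[str, float]] | None = None,
                   ) -> RemodelingHistory:
    """Run the full feedback loop and return the epoch-by-epoch history.

    ``tawss_source`` optionally replaces the built-in reduced-order
    hemodynamics with any per-station TAWSS provider (e.g. values read
    from a file or a CFD export); the rest of the loop is unchanged.
    The input tree is not mutated.  The run is fully deterministic.
    """
    tree = tree.copy()
    tree0 = tree.copy()
    area0 = {st.id: st.cross_section for st in tree0.stations()}
    # mass-flow inflow is fixed for the whole run: a velocity-tagged
    # waveform is converted once, at the post-surgery inlet radius
    inflow = inflow.to_flow(tree0.inlet_radius)

    def shear_field(t: VesselTree) -> list[StationField]:
        if tawss_source is not None:
            vals = tawss_source(t)
            return [StationField(station_id=st.id, z=st.z, radius=st.radius,
                                 tags=tuple(st.tags), tawss=float(vals[st.id]),
                                 osi=0.0, rrt=(1.0 / vals[st.id] if vals[st.id] > 0
                                               else float("inf")))
                    for st in t.stations()]
        return compute_field(t, inflow, network, mu=config.mu, rho=config.rho,
                             disturbance=disturbance,
                             radius_floor=config.radius_floor)

    def record(day, fields, dV, stim) -> EpochRecord:
        occ = {st.id: occlusion_percentage(
            area0[st.id], min(st.cross_section, area0[st.id]))
            for st in tree.stations()}
        ta = {f.station_id: f.tawss for f in fields}
        return EpochRecord(
            day=day, tree=tree.copy(), fields=fields,
            wall={st.id: WallState(**vars(st.wall)) for st in tree.stations()},
            dV_i=dV, stimulus=stim, occlusion=occ,
            low_wss_area_cm2=low_wss_area(tree, ta, config.low_wss_threshold),
        )

    history = RemodelingHistory(tree0=tree0, config=config)
    fields = shear_field(tree)
    tawss0 = {f.station_id: f.tawss for f in fields}
    initialize_wall_patches(tree, params, tawss0, config)
    zero = {st.id: 0.0 for st in tree.stations()}
    stim0 = {sid: _stimulus(tawss0[sid], params) for sid in tawss0}
    history.epochs.append(record(0.0, fields, dict(zero), stim0))

    day = 0.0
    for duration in config.epoch_durations():
        ta = {f.station_id: f.tawss for f in fields}
        dV: dict[str, float] = {}
        stim: dict[str, float] = {}
        for st in tree.stations():
            w = ta[st.id]
            stim[st.id] = _stimulus(w, params)
            v_i0, _ = tissue_volumes(st.wall, params)
            traj = integrate_wall_state(st.wall, w, params, st.capacity,
                                        days=duration, dt=config.dt_bio_days)
            st.wall = traj.final
            v_i1, _ = tissue_volumes(st.wall, params)
            dV[st.id] = v_i1 - v_i0
            if not st.occluded:
                apply_growth(st, dV[st.id], floor=config.radius_floor)
        day += duration
        fields = shear_field(tree)
        history.epochs.append(record(day, fields, dV, stim))
    return history


def _stimulus(wss: float, params: KineticParameters) -> float:
    r = shear_dependent_rates(wss, params)
    return r.p_i - r.a_i


def summarize(history: RemodelingHistory) -> dict:
    """Tabular report of a remodeling run.

    Returns a dict with an ``epochs`` DataFrame (day, low-WSS area,
    TAWSS extrema and their tags, max occlusion), a ``stations``
    DataFrame (final per-station geometry, occlusion and growth) and
    the ``restenosis`` list of stations at or past the area-loss
    threshold.
    """
    if not history.epochs:
        raise ValueError("empty history")
    cfg = history.config or RemodelingConfig()
    erows = []
    for ep in history.epochs:
        ta = ep.tawss
        ids = list(ta)
        lo = min(ids, key=lambda s: ta[s])
        hi = max(ids, key=lambda s: ta[s])
        tag_of = {st.id: ",".join(st.tags) for st in ep.tree.stations()}
        erows.append({
            "day": ep.day,
            "low_wss_area_cm2": ep.low_wss_area_cm2,
            "min_tawss_pa": ta[lo], "min_tawss_station": lo, "min_tawss_tags": tag_of[lo],
            "max_tawss_pa": ta[hi], "max_tawss_station": hi, "max_tawss_tags": tag_of[hi],
            "max_occlusion_pct": max(ep.occlusion.values()),
        })
    first, last = history.epochs[0], history.epochs[-1]
    growth = {sid: 0.0 for sid in first.dV_i}
    for ep in history.epochs:
        for sid, v in ep.dV_i.items():
            growth[sid] += v
    srows = []
    for st0, st in zip(history.tree0.stations(), last.tree.stations()):
        srows.append({
            "station": st.id, "z_m": st.z, "tags": ",".join(st.tags),
            "radius0_mm": st0.radius * 1e3, "radius_mm": st.radius * 1e3,
            "occlusion_pct": last.occlusion[st.id],
            "growth_mm3": growth[st.id] * 1e9,
            "tawss0_pa": first.tawss[st.id], "tawss_pa": last.tawss[st.id],
            "occluded": st.occluded,
        })
    stations = pd.DataFrame(srows)
    restenosis = [(r["station"], r["occlusion_pct"]) for _, r in stations.iterrows()
                  if r["occlusion_pct"] >= cfg.restenosis_threshold]
    return {
        "epochs": pd.DataFrame(erows),
        "stations": stations,
        "restenosis": restenosis,
    }
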