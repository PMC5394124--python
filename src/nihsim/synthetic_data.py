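"""Synthetic study fixtures: graft geometries, Doppler-like inflow
waveforms and shear-disturbance profiles.

No public imaging or waveform data exist for peripheral vein grafts of
this kind (clinical CT/Doppler records are deidentified), so every
input the simulator needs is generated here:

* graft trees with the published bypass dimensions — a femoropopliteal
  graft (30 cm, inlet radius 2.72 mm tapering to 2.67 mm) and a
  femorodistal graft (90 cm trunk, 6.29 mm tapering to 0.96 mm, with
  collateral outlets of 2.71 / 1.63 / 1.0 mm);
* triphasic femoral-artery-like velocity waveforms with a 1.1 s cardiac
  period, contaminated with seeded multiplicative noise and spikes so
  that moving-average smoothing is genuinely needed;
* per-station shear "disturbance" multipliers that depress wall shear
  near anastomoses and bifurcations, emulating the flow separation a
  3-D solve resolves there (deepest at the distal anastomosis, where
  shear as low as 0.2 Pa is expected pre-remodeling).

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hemodynamics import FlowWaveform, WindkesselElement, WindkesselNetwork
from .vessel_geometry import Station, VesselTree

__all__ = [
    "FixtureSpec",
    "make_graft",
    "synth_doppler",
    "disturbance_profile",
    "write_fixture",
    "TABLE_WINDKESSEL_ML",
]

PRESETS = ("femoropopliteal", "femorodistal", "straight_tube")

#: published lumped-model constants in clinical units (Pa·s/ml, ml/Pa)
TABLE_WINDKESSEL_ML = {
    "C_ml_per_pa": 12.6e-6,
    "R_deep_femoral_anterior": 5.5e5,
    "R_deep_femoral_posterior": 4.5e5,
    "R_posterior_distal_proximal": 4.5e5,  # duplicated printed row
    "R_popliteal_anterior": 3e3,
    "R_popliteal_posterior": 2e3,
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic run fixture."""

    preset: str = "femoropopliteal"
    n_stations: int = 21          # per segment (branches use fewer)
    noise_sd: float = 0.05        # relative waveform noise
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if self.n_stations < 3:
            raise ValueError("need at least 3 stations per segment")


def _segment(name: str, z0: float, length: float, r_start: float, r_end: float,
             n: int, tags_first=(), tags_last=()) -> list[Station]:
    """Uniformly spaced stations with linearly tapering radius."""
    dz = length / n
    z = z0 + (np.arange(n) + 0.5) * dz
    radii = np.linspace(r_start, r_end, n)
    stations = []
    for i in range(n):
        tags = ["plain"]
        if i <= 1 and tags_first:
            tags = list(tags_first)
        if i >= n - 2 and tags_last:
            tags = list(tags_last)
        stations.append(Station(id=f"{name}:{i:03d}", z=float(z[i]),
                                radius=float(radii[i]), length=dz, tags=tuple(tags)))
    return stations


def make_graft(preset: str = "femoropopliteal", spec: FixtureSpec | None = None) -> VesselTree:
    """Build a synthetic graft tree for one of the presets.

    ``femoropopliteal``: single 30 cm segment, radius 2.72 -> 2.67 mm,
    ends tagged proximal/distal anastomosis.  ``femorodistal``: 90 cm
    trunk, 6.29 -> 0.96 mm, with three collateral outlets (2.71, 1.63,
    1.0 mm) branching at 20/40/75% of the trunk, plus the main
    (popliteal) outlet — four outlets in total.  ``straight_tube``:
    uniform-radius control.
    """
    if spec is None:
        spec = FixtureSpec(preset=preset)
    n = spec.n_stations
    mm = 1e-3

    if preset == "femoropopliteal":
        seg = _segment("graft", 0.0, 0.30, 2.72 * mm, 2.67 * mm, n,
                       tags_first=("inlet", "proximal_anastomosis"),
                       tags_last=("distal_anastomosis", "outlet"))
        return VesselTree(segments={"graft": seg})

    if preset == "straight_tube":
        seg = _segment("tube", 0.0, 0.30, 2.7 * mm, 2.7 * mm, n,
                       tags_first=("inlet",), tags_last=("outlet",))
        return VesselTree(segments={"tube": seg})

    # femorodistal: trunk split at the three branch points
    L = 0.90
    branch_at = (0.20, 0.40, 0.75)
    r_in, r_out = 6.29 * mm, 0.96 * mm

    def trunk_radius(frac):
        return r_in + (r_out - r_in) * frac

    bounds = (0.0, *branch_at, 1.0)
    trunk_names = ("trunk_a", "trunk_b", "trunk_c", "popliteal")
    n_branch = max(3, n // 4)
    segments: dict[str, list[Station]] = {}
    for j, name in enumerate(trunk_names):
        f0, f1 = bounds[j], bounds[j + 1]
        n_seg = max(3, int(round(n * (f1 - f0))))
        first = ("inlet", "proximal_anastomosis") if j == 0 else ()
        last = ("bifurcation",) if j < 3 else ("distal_anastomosis", "outlet")
        segments[name] = _segment(name, L * f0, L * (f1 - f0),
                                  trunk_radius(f0), trunk_radius(f1), n_seg,
                                  tags_first=first, tags_last=last)
    branch_info = (
        ("deep_femoral_anterior", 2.71 * mm, branch_at[0]),
        ("deep_femoral_posterior", 1.63 * mm, branch_at[1]),
        ("posterior_distal_proximal", 1.0 * mm, branch_at[2]),
    )
    for name, r, frac in branch_info:
        segments[name] = _segment(name, L * frac, 0.03, r, r, n_branch,
                                  tags_first=("bifurcation",), tags_last=("outlet",))
    connectivity = {
        "trunk_a": ["deep_femoral_anterior", "trunk_b"],
        "trunk_b": ["deep_femoral_posterior", "trunk_c"],
        "trunk_c": ["posterior_distal_proximal", "popliteal"],
    }
    return VesselTree(segments=segments, connectivity=connectivity)


def synth_doppler(period: float = 1.1, peak: float = 1.3, noise_sd: float = 0.05,
                  seed: int = 42, n_samples: int = 220) -> FlowWaveform:
    """Triphasic femoral-artery-like centerline-velocity waveform.

    Three-Gaussian template over one cardiac period (default 1.1 s): a
    systolic peak, an early-diastolic reverse-flow dip and a late
    diastolic rebound on a small forward baseline, normalized so the
    systolic maximum equals ``peak`` [m/s].  Seeded multiplicative
    Gaussian noise plus sparse large spikes emulate raw Doppler traces;
    ``noise_sd=0`` returns the clean template.
    """
    if peak <= 0:
        raise ValueError("peak velocity must be > 0")
    t = np.arange(n_samples) * period / n_samples
    s = t / period

    def g(center, width):
        return np.exp(-0.5 * ((s - center) / width) ** 2)

    template = 0.30 + 1.0 * g(0.14, 0.05) - 0.45 * g(0.33, 0.055) + 0.18 * g(0.55, 0.10)
    v = peak * template / template.max()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + noise_sd * rng.standard_normal(n_samples))
        n_spikes = max(3, n_samples // 40)
        idx = rng.choice(n_samples, size=n_spikes, replace=False)
        v[idx] *= 1.0 + rng.uniform(0.4, 0.9, size=n_spikes) * rng.choice([-1, 1], size=n_spikes)
    return FlowWaveform(t=t, v=v, period=period, kind="velocity")


def disturbance_profile(tree: VesselTree, dip_depth: float = 0.81,
                        dip_width: float = 3.0, seed: int = 0,
                        proximal_scale: float = 0.7) -> dict[str, float]:
    """Per-station multiplicative shear multiplier in (0, 1].

    Gaussian dips (width ``dip_width`` stations) are centered at tagged
    stations: depth ``dip_depth`` at distal anastomoses and
    ``proximal_scale * dip_depth`` at proximal anastomoses and
    bifurcations, so the global minimum lands at a distal-anastomosis
    station.  Plain stations far from any tag keep multiplier 1.
    Deterministic given its arguments (the seed is kept for interface
    symmetry with the other generators and does not inject noise).
    """
    if not 0 < dip_depth < 1:
        raise ValueError("dip_depth must be in (0, 1)")
    depth_by_tag = {
        "distal_anastomosis": dip_depth,
        "proximal_anastomosis": proximal_scale * dip_depth,
        "bifurcation": proximal_scale * dip_depth,
    }
    out: dict[str, float] = {}
    for stations in tree.segments.values():
        centers = []  # (index, depth)
        for i, st in enumerate(stations):
            depths = [depth_by_tag[t] for t in st.tags if t in depth_by_tag]
            if depths:
                centers.append((i, max(depths)))
        for i, st in enumerate(stations):
            dip = 0.0
            for j, depth in centers:
                dip = max(dip, depth * np.exp(-0.5 * ((i - j) / dip_width) ** 2))
            out[st.id] = float(max(1.0 - dip, 0.05))
    return out


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete, self-consistent run directory.

    Produces ``tree.json``, ``wave.csv``, ``wk.json``, ``params.yaml``
    and ``run.yaml``; ``nihsim simulate --config run.yaml`` runs
    end-to-end on the result.  Returns the paths written.
    """
    from . import io as nio
    from .biochemistry import KineticParameters
    from .remodeling import RemodelingConfig

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = make_graft(spec.preset, spec)
    wave = synth_doppler(noise_sd=spec.noise_sd, seed=spec.rng_seed)
    network = fixture_network(spec.preset)
    params = KineticParameters()
    if spec.preset == "femorodistal":
        # only one remodeling cycle over the 8-month horizon
        config = RemodelingConfig(total_days=240, coupling_interval_days=240,
                                  rng_seed=spec.rng_seed)
    else:
        config = RemodelingConfig(total_days=120, coupling_interval_days=60,
                                  rng_seed=spec.rng_seed)

    paths = {
        "tree": out / "tree.json",
        "wave": out / "wave.csv",
        "network": out / "wk.json",
        "params": out / "params.yaml",
        "run": out / "run.yaml",
    }
    nio.save_tree(tree, paths["tree"])
    nio.save_waveform(wave, paths["wave"])
    nio.save_network(network, paths["network"])
    nio.save_params(params, paths["params"])
    nio.save_run_config(config, wave, paths["run"],
                        tree="tree.json", waveform="wave.csv",
                        network="wk.json", params="params.yaml")
    return paths


def fixture_network(preset: str) -> WindkesselNetwork:
    """Windkessel bank matching a preset's outlets (SI units).

    The femorodistal bank carries the published values: the three
    collaterals take the printed deep-femoral/posterior resistances and
    the main popliteal outlet the popliteal-posterior resistance; the
    single printed capacitance is shared by all outlets.  Single-outlet
    presets get one element with the popliteal-anterior resistance.
    """
    T = TABLE_WINDKESSEL_ML
    c_si = T["C_ml_per_pa"] * 1e-6          # ml/Pa -> m^3/Pa

    def el(r_ml):
        return WindkesselElement(R=r_ml * 1e6, C=c_si)  # Pa·s/ml -> Pa·s/m^3

    if preset == "femorodistal":
        return WindkesselNetwork(elements={
            "deep_femoral_anterior": el(T["R_deep_femoral_anterior"]),
            "deep_femoral_posterior": el(T["R_deep_femoral_posterior"]),
            "posterior_distal_proximal": el(T["R_posterior_distal_proximal"]),
            "popliteal": el(T["R_popliteal_posterior"]),
        })
    outlet = "graft" if preset == "femoropopliteal" else "tube"
    return WindkesselNetwork(elements={outlet: el(T["R_popliteal_anterior"])})
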