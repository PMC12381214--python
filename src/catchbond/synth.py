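"""Synthetic AFM-SMFS data with known ground truth.

Generates the four data products the analysis consumes, at desk scale and
with every event logged so downstream stages can be verified end to end:

* constant-speed force–extension curves: an elastin-like tether (rendered
  with the FRC elasticity used by the analysis transform), a two-domain
  fingerprint that unfolds in four 50–80 pN sawtooth peaks adding 32 nm of
  contour length, optional pathway-linked intermediate unfolding
  increments (median ~15 nm), and a terminal rupture drawn from a
  multi-state kinetic model;
* force-clamp force–time traces with setpoint jitter, a 15 ms detection
  floor and optional non-specific-adhesion artifacts;
* rupture-force/loading-rate record tables (bypassing curve rendering);
* Hill-equation bead-titration tables.

All generators are pure functions of (configuration, seed); per-curve
randomness is drawn from a counter-based substream of the master seed so
datasets are reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landscape import BEParams
from .montecarlo import (
    ForceClampConfig,
    StateModel,
    _pick_winners,
    _slots_by_state,
    _SLOTS,
    _PATHWAYS,
    _STATE_NAMES,
    simulate_constant_speed,
    simulate_force_clamp,
    ConstantSpeedConfig,
)
from .pipeline import ClampTrace, ForceCurve
from .polymer import FRCParams, ThermalContext, frc_force_from_relative_extension

__all__ = [
    "HandleModel",
    "NoiseModel",
    "TruthEvent",
    "GroundTruth",
    "generate_constant_speed_curve",
    "generate_force_clamp_trace",
    "generate_rupture_dataset",
    "generate_hill_titration",
]


@dataclass(frozen=True)
class HandleModel:
    """Geometry of the tethered construct and its unfolding fingerprint.

    Defaults encode the experimental construct: two ELP handles (~65 nm
    each), two fingerprint domains unfolding in four peaks within 50–80 pN
    that add 32 nm of contour in total, and a folded-protein offset chosen
    so the post-fingerprint contour length is ~190 nm.  Intermediate
    complex-unfolding increments (median 15 nm) fire with a configurable
    probability when the bond changes state.
    """

    tether_contour_length: float = 130.0  # nm, both ELP handles
    tether_persistence: float = 0.4  # nm, used by the WLC shortcut generators
    folded_offset: float = 28.0  # nm, folded-protein contribution (free parameter)
    fingerprint_domains: int = 2
    fingerprint_events_per_domain: int = 2
    fingerprint_increment_per_event: float = 8.0  # nm
    fingerprint_force_range: tuple[float, float] = (50.0, 80.0)  # pN
    intermediate_increment_median: float = 15.0  # nm
    intermediate_increment_sd: float = 5.0  # nm
    intermediate_probability: float = 0.4  # per state transition

    def __post_init__(self) -> None:
        if self.tether_contour_length <= 0:
            raise ValueError("tether_contour_length must be positive")
        lo, hi = self.fingerprint_force_range
        if not 0 < lo < hi:
            raise ValueError("fingerprint_force_range must be an increasing pair")

    @property
    def n_fingerprint_events(self) -> int:
        return self.fingerprint_domains * self.fingerprint_events_per_domain

    @property
    def initial_contour(self) -> float:
        return self.tether_contour_length + self.folded_offset

    @property
    def fingerprint_total_increment(self) -> float:
        return self.n_fingerprint_events * self.fingerprint_increment_per_event


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections added on top of the ideal curve."""

    force_noise_sd: float = 2.0  # pN
    baseline_drift: float = 0.0  # pN/nm
    sampling_rate: float = 5000.0  # Hz (clamp traces)
    nonspecific_adhesion_rate: float = 0.0  # probability per curve

    def __post_init__(self) -> None:
        if min(
            self.force_noise_sd, self.sampling_rate, self.nonspecific_adhesion_rate
        ) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class TruthEvent:
    kind: str  # fingerprint | intermediate | rupture
    extension: float  # nm
    force: float  # pN
    contour_increment: float  # nm
    state: str  # bond state when the event fired


@dataclass
class GroundTruth:
    """Per-curve event log: what the generator actually did."""

    curve_id: str
    events: list[TruthEvent] = field(default_factory=list)
    pathway: str = ""
    rupture_force: float = math.nan
    rupture_extension: float = math.nan
    final_contour: float = math.nan
    state_path: str = "N"
    lifetime: float = math.nan  # clamp traces only
    below_detection_floor: bool = False
    censored: bool = False
    adhesion_artifact: bool = False

    def validate(self) -> None:
        ext = [e.extension for e in self.events]
        if any(b <= a for a, b in zip(ext, ext[1:])):
            raise AssertionError("event extensions must be strictly increasing")
        n_rupture = sum(e.kind == "rupture" for e in self.events)
        if not self.censored and n_rupture != 1:
            raise AssertionError("a bound curve must contain exactly one rupture")


def _curve_rng(seed, index: int = 0) -> np.random.Generator:
    """Counter-based per-curve substream: reproducible and order-independent."""
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng([int(seed), int(index)])


def generate_constant_speed_curve(
    model: StateModel,
    handle: HandleModel | None = None,
    noise: NoiseModel | None = None,
    speed: float = 1600.0,
    spring_constant: float = 0.1,
    seed=None,
    curve_index: int = 0,
    frc: FRCParams | None = None,
    thermal: ThermalContext | None = None,
    grid_step: float = 0.25,
    tail_nm: float = 40.0,
    curve_id: str | None = None,
    experiment_id: str = "exp0",
) -> tuple[ForceCurve, GroundTruth]:
    """Render one constant-speed retraction curve plus its ground truth.

    The tether is stretched along an even extension grid; the force follows
    the FRC elasticity at the current contour length, which grows by fixed
    increments when fingerprint domains unfold (deterministic force
    thresholds drawn within the 50–80 pN window) and by ~15 nm intermediate
    increments when the bond model changes state.  Rupture is drawn from
    the state model with the same shuffled-event kinetic Monte Carlo rule
    as the dedicated simulator.  At zero noise, every logged event is
    recoverable by the curve pipeline.
    """
    if speed <= 0 or spring_constant <= 0:
        raise ValueError("speed and spring_constant must be positive")
    handle = handle or HandleModel()
    noise = noise or NoiseModel()
    frc = frc or FRCParams()
    thermal = thermal or ThermalContext()
    rng = _curve_rng(seed, curve_index)
    curve_id = curve_id or f"curve{curve_index:05d}"

    n_fp = handle.n_fingerprint_events
    lo, hi = handle.fingerprint_force_range
    fp_thresholds = np.sort(rng.uniform(lo, hi, size=n_fp))
    fp_next = 0

    beta = thermal.beta
    k0_e, dx_e = model.edge_arrays()
    slots_by_state = _slots_by_state(model)

    contour = handle.initial_contour
    state = 0
    truth = GroundTruth(curve_id=curve_id)
    xs, fs = [0.0], [0.0]
    x, prev_head, t = 0.0, 0.0, 0.0
    max_ratio = 0.995
    ruptured = False

    while True:
        x += grid_step
        ratio = x / contour
        if ratio >= max_ratio:
            truth.censored = True
            break
        F = frc_force_from_relative_extension(ratio, frc)
        xs.append(x)
        fs.append(F)
        head = x + F / (1000.0 * spring_constant)  # N/m -> pN/nm
        dt = (head - prev_head) / speed
        prev_head, t = head, t + dt

        # at most one event per grid step keeps event extensions distinct
        if fp_next < n_fp and F >= fp_thresholds[fp_next]:
            inc = handle.fingerprint_increment_per_event
            contour += inc
            truth.events.append(TruthEvent("fingerprint", x, F, inc, _STATE_NAMES[state]))
            fp_next += 1
            continue

        slots = slots_by_state.get(state)
        if not slots:
            continue
        P = 1.0 - np.exp(-k0_e[slots] * np.exp(np.clip(beta * F * dx_e[slots], None, 700.0)) * dt)
        success = rng.random(len(slots)) < P
        if not success.any():
            continue
        winner = slots[int(_pick_winners(rng, success[None, :])[0])]
        _, _, new_state = _SLOTS[winner]
        if new_state < 0:
            truth.events.append(TruthEvent("rupture", x, F, 0.0, _STATE_NAMES[state]))
            truth.pathway = _PATHWAYS[state]
            truth.rupture_force = F
            truth.rupture_extension = x
            truth.final_contour = contour
            ruptured = True
            break
        state = new_state
        truth.state_path += "->" + _STATE_NAMES[state]
        if rng.random() < handle.intermediate_probability:
            inc = max(
                1.0,
                rng.normal(handle.intermediate_increment_median, handle.intermediate_increment_sd),
            )
            contour += inc
            truth.events.append(TruthEvent("intermediate", x, F, inc, _STATE_NAMES[state]))

    # post-rupture zero-force tail
    if ruptured:
        for _ in range(int(tail_nm / grid_step)):
            x += grid_step
            xs.append(x)
            fs.append(0.0)

    force = np.asarray(fs)
    extension = np.asarray(xs)
    if noise.nonspecific_adhesion_rate > 0 and rng.random() < noise.nonspecific_adhesion_rate:
        truth.adhesion_artifact = True
        x_a = rng.uniform(30.0, 70.0)
        height = rng.uniform(100.0, 300.0)
        rise = (extension > x_a - 10.0) & (extension <= x_a)
        force = force + np.where(rise, height * (extension - (x_a - 10.0)) / 10.0, 0.0)
    if noise.baseline_drift:
        force = force + noise.baseline_drift * extension
    if noise.force_noise_sd:
        force = force + rng.normal(0.0, noise.force_noise_sd, size=force.size)

    curve = ForceCurve(
        extension=extension,
        force=force,
        pulling_speed=speed,
        spring_constant=spring_constant,
        curve_id=curve_id,
        experiment_id=experiment_id,
    )
    truth.validate()
    return curve, truth


def generate_force_clamp_trace(
    model: StateModel,
    setpoint: float,
    noise: NoiseModel | None = None,
    seed=None,
    trace_index: int = 0,
    thermal: ThermalContext | None = None,
    setpoint_offset_sd: float = 2.0,
    ramp_rate: float = 400.0,  # pN/s, cantilever-limited force rise
    retraction_distance: float = 100.0,  # nm
    n_head_step_artifacts: int = 0,
    max_time: float = 10.0,
    time_step: float = 1e-4,
    trace_id: str | None = None,
    experiment_id: str = "exp0",
) -> tuple[ClampTrace, GroundTruth]:
    """Render one force-clamp force–time trace plus its ground truth.

    The trace ramps to the (jittered) setpoint, holds it with Gaussian
    force noise for a lifetime drawn from the state model under constant
    force, then drops to zero and resumes retraction.  The clamped force
    differs from the target by a per-trace offset (instrument setpoint
    accuracy ~5 pN).  Lifetimes below the 15 ms feedback floor are
    generated but flagged.
    """
    if setpoint <= 0:
        raise ValueError("setpoint must be positive")
    noise = noise or NoiseModel()
    thermal = thermal or ThermalContext()
    rng = _curve_rng(seed, trace_index)
    trace_id = trace_id or f"trace{trace_index:05d}"

    actual = setpoint + (rng.normal(0.0, setpoint_offset_sd) if setpoint_offset_sd else 0.0)
    actual = max(actual, 1.0)
    cfg = ForceClampConfig(
        setpoints=(actual,),
        time_step=time_step,
        max_time=max_time,
        replicates=1,
        seed=int(rng.integers(2**31 - 1)),
        thermal=thermal,
    )
    records, _ = simulate_force_clamp(model, cfg)
    row = records.iloc[0]
    lifetime = float(row["lifetime_s"])
    censored = bool(row["censored"])

    dt = 1.0 / noise.sampling_rate
    t_ramp = actual / ramp_rate
    n_ramp = max(2, int(round(t_ramp / dt)))
    n_clamp = max(1, int(round(lifetime / dt)))
    n_tail = max(2, int(round(0.05 / dt)))
    n = n_ramp + n_clamp + n_tail
    t = np.arange(n) * dt

    force = np.empty(n)
    force[:n_ramp] = np.linspace(0.0, actual, n_ramp, endpoint=False)
    force[n_ramp : n_ramp + n_clamp] = actual
    force[n_ramp + n_clamp :] = 0.0

    head = np.empty(n)
    head[:n_ramp] = np.linspace(0.0, retraction_distance, n_ramp, endpoint=False)
    head[n_ramp : n_ramp + n_clamp] = retraction_distance
    head[n_ramp + n_clamp :] = np.linspace(
        retraction_distance, retraction_distance + 20.0, n_tail
    )
    if n_head_step_artifacts:
        # discrete feedback jumps during the clamp plateau (artifact injection)
        pos = np.linspace(n_ramp, n_ramp + n_clamp, n_head_step_artifacts + 2)[1:-1]
        for p in pos.astype(int):
            head[p:] += 8.0

    if noise.force_noise_sd:
        force = force + rng.normal(0.0, noise.force_noise_sd, size=n)

    trace = ClampTrace(
        time=t,
        force=force,
        head_height=head,
        target_setpoint=setpoint,
        trace_id=trace_id,
        experiment_id=experiment_id,
    )
    truth = GroundTruth(
        curve_id=trace_id,
        pathway=str(row["pathway"]),
        lifetime=lifetime,
        below_detection_floor=lifetime < 0.015,
        censored=censored,
        state_path=str(row["state_path"]),
    )
    return trace, truth


def generate_rupture_dataset(
    model: StateModel,
    speeds=(800.0, 1600.0, 3200.0, 6400.0),
    n_per_speed: int = 500,
    seed=None,
    n_experiments: int = 1,
    spring_constant: float = 0.1,
    tether_contour: float = 190.0,
    tether_persistence: float = 0.4,
    grid_step: float = 0.1,
    thermal: ThermalContext | None = None,
) -> pd.DataFrame:
    """Rupture records straight from the kinetic simulator (no curve render).

    One row per un-censored replicate with rupture force, local loading
    rate, pulling speed, an experiment id (replicates split evenly), and
    the hidden true pathway in ``pathway_truth``.  ``n_per_speed = 0``
    returns an empty table.
    """
    from .polymer import WLCParams

    thermal = thermal or ThermalContext()
    frames = []
    if n_per_speed > 0:
        for j, speed in enumerate(speeds):
            cfg = ConstantSpeedConfig(
                pulling_speed=float(speed),
                spring_constant=spring_constant,
                tether=WLCParams(tether_contour, tether_persistence),
                grid_step=grid_step,
                replicates=int(n_per_speed),
                seed=None if seed is None else int(np.random.default_rng([int(seed), j]).integers(2**31 - 1)),
                thermal=thermal,
            )
            sim = simulate_constant_speed(model, cfg)
            sim = sim[~sim["censored"]].copy()
            sim["experiment_id"] = [
                f"exp{i % max(1, n_experiments)}" for i in range(len(sim))
            ]
            frames.append(sim)
    if not frames:
        return pd.DataFrame(
            columns=[
                "rupture_force_pN",
                "loading_rate_pN_s",
                "pulling_speed_nm_s",
                "pathway_truth",
                "experiment_id",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"pathway": "pathway_truth"})
    return out[
        [
            "rupture_force_pN",
            "loading_rate_pN_s",
            "pulling_speed_nm_s",
            "pathway_truth",
            "experiment_id",
        ]
    ]


def generate_hill_titration(
    kd: float,
    hill_n: float = 1.0,
    bmax: float = 1.0,
    concentrations=None,
    noise_sd: float = 0.0,
    seed=None,
    baseline: float = 0.0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Bead-titration table from the Hill binding isotherm.

    Default design mirrors the assay: seven 5-fold dilutions starting at
    100x the expected dissociation constant.  Signal = baseline +
    bmax * c^n / (kd^n + c^n) plus Gaussian noise.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if concentrations is None:
        concentrations = [100.0 * kd / 5.0**i for i in range(7)]
    conc = np.asarray(concentrations, dtype=float)
    rng = _curve_rng(seed)
    rows = []
    for rep in range(n_replicates):
        mean = baseline + bmax * conc**hill_n / (kd**hill_n + conc**hill_n)
        signal = mean + (rng.normal(0.0, noise_sd, size=conc.size) if noise_sd else 0.0)
        for c, s in zip(conc, signal):
            rows.append({"concentration_nM": c, "signal": s, "replicate": rep})
    return pd.DataFrame(rows)
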