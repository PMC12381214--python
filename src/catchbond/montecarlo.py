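"""Kinetic Monte Carlo simulation of multi-state receptor:ligand bond rupture.

The bond is modelled as a three-state graph — native (N) and two
force-induced intermediates (I1, I2) — with rupture edges N->unbound (P0),
I1->unbound (P1) and I2->unbound (P2), forward transitions N->I1->I2 and,
for the reversible variant, the corresponding back-transitions.  Every edge
carries Bell kinetics k(F) = k0*exp(beta*F*dx).

Two experimental protocols are simulated:

* constant-speed pulling: a worm-like-chain tether is stretched along an
  evenly spaced molecular-extension grid; force follows the WLC, the AFM
  head height adds the cantilever deflection H = X + F/k, and time advances
  as dt = dH/V.  At each grid step every eligible event fires with
  probability P = 1 - exp(-k(F)*dt); the events are shuffled and the first
  success executes.
* force clamp: force is constant, so per-step event probabilities are
  constant and the shuffled-step process is sampled exactly with geometric
  waiting times (ties between simultaneous successes broken uniformly).

The transition-barrier edges are experimentally invisible; they are
estimated by a random search that repeatedly draws candidate edge
parameters, simulates rupture-force histograms at each pulling speed and
scores them against target histograms by the sum of squared residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landscape import BEParams
from .polymer import ThermalContext, WLCParams, wlc_force

__all__ = [
    "StateModel",
    "ConstantSpeedConfig",
    "ForceClampConfig",
    "TransitionSearchConfig",
    "simulate_constant_speed",
    "simulate_force_clamp",
    "analytic_pathway_lifetime",
    "fit_transition_parameters",
    "compare_transition_models",
    "single_state_model",
    "example_catch_bond_model",
]

_STATE_NAMES = ("N", "I1", "I2")
_PATHWAYS = ("P0", "P1", "P2")

# Event slots: (description, source state, new state; -1 = unbound)
_SLOTS = (
    ("P0", 0, -1),
    ("N->I1", 0, 1),
    ("P1", 1, -1),
    ("I1->I2", 1, 2),
    ("I1->N", 1, 0),
    ("P2", 2, -1),
    ("I2->I1", 2, 1),
)


@dataclass(frozen=True)
class StateModel:
    """Three-state bond graph with Bell kinetics on every edge.

    Reverse edges must be both present (reversible model) or both absent
    (irreversible model).
    """

    p0: BEParams
    p1: BEParams
    p2: BEParams
    n_to_i1: BEParams
    i1_to_i2: BEParams
    i1_to_n: BEParams | None = None
    i2_to_i1: BEParams | None = None

    def __post_init__(self) -> None:
        if (self.i1_to_n is None) != (self.i2_to_i1 is None):
            raise ValueError(
                "reverse edges i1_to_n and i2_to_i1 must both be present "
                "(reversible) or both absent (irreversible)"
            )

    @property
    def reversible(self) -> bool:
        return self.i1_to_n is not None

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(k0, dx) arrays over the 7 event slots; absent edges get k0 = 0."""
        zero = BEParams(0.0, 0.0)
        edges = [
            self.p0,
            self.n_to_i1,
            self.p1,
            self.i1_to_i2,
            self.i1_to_n or zero,
            self.p2,
            self.i2_to_i1 or zero,
        ]
        k0 = np.array([e.k0 for e in edges])
        dx = np.array([e.delta_x for e in edges])
        return k0, dx

    def to_dict(self) -> dict:
        def _edge(e):
            return None if e is None else {"k0_per_s": e.k0, "delta_x_nm": e.delta_x}

        return {
            "p0": _edge(self.p0),
            "p1": _edge(self.p1),
            "p2": _edge(self.p2),
            "n_to_i1": _edge(self.n_to_i1),
            "i1_to_i2": _edge(self.i1_to_i2),
            "i1_to_n": _edge(self.i1_to_n),
            "i2_to_i1": _edge(self.i2_to_i1),
            "reversible": self.reversible,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateModel":
        def _edge(v):
            return None if v is None else BEParams(v["k0_per_s"], v["delta_x_nm"])

        return cls(
            p0=_edge(d["p0"]),
            p1=_edge(d["p1"]),
            p2=_edge(d["p2"]),
            n_to_i1=_edge(d["n_to_i1"]),
            i1_to_i2=_edge(d["i1_to_i2"]),
            i1_to_n=_edge(d.get("i1_to_n")),
            i2_to_i1=_edge(d.get("i2_to_i1")),
        )


def single_state_model(params: BEParams) -> StateModel:
    """A pure slip bond: only the P0 rupture edge is active."""
    off = BEParams(0.0, 0.0)
    return StateModel(p0=params, p1=off, p2=off, n_to_i1=off, i1_to_i2=off)


def example_catch_bond_model() -> StateModel:
    """A demonstration reversible three-state catch-bond model.

    The distance to the transition state decreases and the zero-force
    stability increases from P0 to P2; the forward transitions carry large
    delta_x, so moderate force funnels the complex into the mechanically
    stable intermediates (slip-to-catch, ~20 pN).  The reverse transitions
    are also force-promoted, with small prefactors: negligible in the catch
    regime but dominant above ~80 pN, where complexes cascade back toward N
    and rupture through P0.  The resulting phenomenology — mean clamp
    lifetime peaking near 40 pN, P0 dominating at both force extremes, P2
    in between — is the qualitative behaviour of a multi-state catch bond;
    the numbers are illustrative defaults of this package, not
    experimentally fitted constants.
    """
    return StateModel(
        p0=BEParams(k0=2.0, delta_x=0.5),
        p1=BEParams(k0=0.5, delta_x=0.25),
        p2=BEParams(k0=0.15, delta_x=0.1),
        n_to_i1=BEParams(k0=0.08, delta_x=1.2),
        i1_to_i2=BEParams(k0=0.3, delta_x=0.7),
        i1_to_n=BEParams(k0=0.001, delta_x=0.45),
        i2_to_i1=BEParams(k0=0.001, delta_x=0.45),
    )


@dataclass(frozen=True)
class ConstantSpeedConfig:
    """Constant-speed pulling protocol.

    ``spring_constant`` is in N/m (1 N/m = 1000 pN/nm).  The tether
    defaults to a WLC with the final contour length of the experimental
    construct (190 nm) and polypeptide persistence length 0.4 nm.
    """

    pulling_speed: float  # nm/s
    spring_constant: float = 0.1  # N/m
    tether: WLCParams = field(default_factory=lambda: WLCParams(190.0, 0.4))
    grid_step: float = 0.1  # nm
    replicates: int = 500
    seed: int | None = None
    thermal: ThermalContext = field(default_factory=ThermalContext)
    max_force: float = 1500.0  # pN; grid truncated where the WLC exceeds this

    def __post_init__(self) -> None:
        if self.pulling_speed <= 0:
            raise ValueError("pulling_speed must be positive")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class ForceClampConfig:
    """Force-clamp protocol: constant setpoints, fixed time step, 10 s cap."""

    setpoints: tuple[float, ...]  # pN
    time_step: float = 1e-4  # s
    max_time: float = 10.0  # s
    replicates: int = 100
    seed: int | None = None
    thermal: ThermalContext = field(default_factory=ThermalContext)

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if any(s <= 0 for s in self.setpoints):
            raise ValueError("setpoints must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def force_schedule(cfg: ConstantSpeedConfig) -> dict[str, np.ndarray]:
    """Deterministic pulling schedule shared by all replicates.

    Returns extension ``x`` (nm), WLC force ``F`` (pN), head height ``H``
    (nm), time ``t`` (s) and the local loading rate ``r`` = dF/dt (pN/s)
    from the WLC + cantilever series compliance.
    """
    L = cfg.tether.contour_length_L
    x = np.arange(cfg.grid_step, L, cfg.grid_step)
    F = wlc_force(x, cfg.tether, cfg.thermal)
    keep = F <= cfg.max_force
    x, F = x[keep], F[keep]
    H = x + F / (1000.0 * cfg.spring_constant)  # N/m -> pN/nm
    t = np.concatenate([[0.0], np.cumsum(np.diff(H))]) / cfg.pulling_speed
    r = np.gradient(F, t)
    return {"x": x, "F": F, "H": H, "t": t, "r": r}


def _pick_winners(rng: np.random.Generator, success: np.ndarray) -> np.ndarray:
    """Uniformly choose one successful event per row (rows with >=1 success).

    Equivalent in distribution to shuffling the events and executing the
    first success: a uniform permutation restricted to the success set is a
    uniform permutation of it.
    """
    keys = rng.random(success.shape)
    keys[~success] = np.inf
    return np.argmin(keys, axis=1)


def simulate_constant_speed(model: StateModel, cfg: ConstantSpeedConfig) -> pd.DataFrame:
    """Simulate rupture of ``cfg.replicates`` bonds pulled at constant speed.

    Returns one row per replicate: rupture force (pN), rupture time (s),
    local loading rate at rupture (pN/s), pathway (P0/P1/P2), number of
    state transitions, visited-state path, and a censored flag for
    replicates whose tether was exhausted before rupture.
    """
    sched = force_schedule(cfg)
    F, t, r = sched["F"], sched["t"], sched["r"]
    n_steps = len(F) - 1
    dt = np.diff(t)

    beta = cfg.thermal.beta
    k0, dx = model.edge_arrays()
    # P[i, e]: probability that edge e fires during step i at force F[i]
    expo = np.clip(beta * np.outer(F[:-1], dx), None, 700.0)
    P = 1.0 - np.exp(-(k0 * np.exp(expo)) * dt[:, None])

    slots_by_state = _slots_by_state(model)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.replicates
    state = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    rupture_force = np.full(n, np.nan)
    rupture_time = np.full(n, np.nan)
    loading_rate = np.full(n, np.nan)
    pathway = np.full(n, "", dtype=object)
    paths: list[list[str]] = [["N"] for _ in range(n)]

    for i in range(n_steps):
        if not alive.any():
            break
        for s, slots in slots_by_state.items():
            idx = np.flatnonzero(alive & (state == s))
            if idx.size == 0:
                continue
            success = rng.random((idx.size, len(slots))) < P[i, slots]
            hit_rows = success.any(axis=1)
            if not hit_rows.any():
                continue
            winners = _pick_winners(rng, success[hit_rows])
            for row, w in zip(idx[hit_rows], winners):
                name, _, new_state = _SLOTS[slots[w]]
                if new_state < 0:
                    alive[row] = False
                    rupture_force[row] = F[i]
                    rupture_time[row] = t[i]
                    loading_rate[row] = r[i]
                    pathway[row] = _PATHWAYS[s]
                else:
                    state[row] = new_state
                    paths[row].append(_STATE_NAMES[new_state])

    return pd.DataFrame(
        {
            "replicate": np.arange(n),
            "mode": "constant_speed",
            "pulling_speed_nm_s": cfg.pulling_speed,
            "rupture_force_pN": rupture_force,
            "rupture_time_s": rupture_time,
            "loading_rate_pN_s": loading_rate,
            "pathway": pathway,
            "n_transitions": [len(p) - 1 for p in paths],
            "state_path": ["->".join(p) for p in paths],
            "censored": alive,
        }
    )


def _slots_by_state(model: StateModel) -> dict[int, list[int]]:
    by_state: dict[int, list[int]] = {0: [], 1: [], 2: []}
    k0, _ = model.edge_arrays()
    for slot, (_, src, _) in enumerate(_SLOTS):
        if k0[slot] > 0:
            by_state[src].append(slot)
    return {s: slots for s, slots in by_state.items() if slots}


def simulate_force_clamp(
    model: StateModel, cfg: ForceClampConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate clamp lifetimes at each setpoint.

    The per-step event probabilities P = 1 - exp(-k(F)*dt) are constant, so
    the stepped process is sampled exactly: each eligible event draws a
    geometric number of steps to first success, the earliest event executes,
    and ties (simultaneous successes in one step) are broken uniformly.

    Returns ``(records, frequencies)``: one row per replicate (lifetime,
    pathway, censored flag, state path), and per-setpoint relative pathway
    frequencies (events through each pathway / total simulations).
    """
    beta = cfg.thermal.beta
    k0, dx = model.edge_arrays()
    slots_by_state = _slots_by_state(model)
    rng = np.random.default_rng(cfg.seed)
    rows = []

    worst = max(
        float(np.max(k0 * np.exp(np.clip(beta * s * dx, None, 700.0))))
        for s in cfg.setpoints
    )
    if cfg.time_step * worst > 0.1:
        warnings.warn(
            f"time_step * max off-rate reaches {cfg.time_step * worst:.3g} > 0.1; "
            "faster-than-step events collapse onto single intervals "
            "(at most one event per interval)",
            stacklevel=2,
        )

    for setpoint in cfg.setpoints:
        rates = k0 * np.exp(np.clip(beta * setpoint * dx, None, 700.0))
        P = 1.0 - np.exp(-rates * cfg.time_step)
        max_steps = int(math.ceil(cfg.max_time / cfg.time_step))

        for rep in range(cfg.replicates):
            state, steps_used, path = 0, 0, ["N"]
            lifetime, pathway, censored = np.nan, "", True
            while steps_used < max_steps:
                slots = slots_by_state.get(state)
                if not slots:  # absorbing bound state: no eligible events
                    break
                waits = _geometric_steps(rng, P[slots])
                w = int(np.min(waits))
                if steps_used + w > max_steps:
                    break
                tied = np.flatnonzero(waits == w)
                slot = slots[int(rng.choice(tied))]
                steps_used += w
                name, _, new_state = _SLOTS[slot]
                if new_state < 0:
                    lifetime = steps_used * cfg.time_step
                    pathway = _PATHWAYS[state]
                    censored = False
                    break
                state = new_state
                path.append(_STATE_NAMES[new_state])
            rows.append(
                {
                    "replicate": rep,
                    "mode": "force_clamp",
                    "setpoint_pN": setpoint,
                    "lifetime_s": lifetime if not censored else cfg.max_time,
                    "pathway": pathway,
                    "n_transitions": len(path) - 1,
                    "state_path": "->".join(path),
                    "censored": censored,
                }
            )

    records = pd.DataFrame(rows)
    freq_rows = []
    for setpoint, grp in records.groupby("setpoint_pN"):
        total = len(grp)
        for pw in _PATHWAYS:
            freq_rows.append(
                {
                    "setpoint_pN": setpoint,
                    "pathway": pw,
                    "frequency": float((grp["pathway"] == pw).sum()) / total,
                }
            )
    return records, pd.DataFrame(freq_rows)


def _geometric_steps(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    """Steps until first success for each probability (inf when p == 0)."""
    out = np.full(p.shape, np.inf)
    u = rng.random(p.shape)
    pos = p > 0
    full = p >= 1.0
    with np.errstate(divide="ignore"):
        out[pos] = np.floor(np.log(u[pos]) / np.log1p(-np.minimum(p[pos], 1 - 1e-16))) + 1
    out[full] = 1.0
    return out


def analytic_pathway_lifetime(
    params: BEParams, force: float, ctx: ThermalContext | None = None
) -> float:
    """Single-barrier Bell lifetime 1 / (k0 * exp(beta*F*dx)) in seconds."""
    ctx = ctx or ThermalContext()
    return 1.0 / (params.k0 * math.exp(ctx.beta * force * params.delta_x))


# ---------------------------------------------------------------------------
# Hidden-barrier random search


@dataclass(frozen=True)
class TransitionSearchConfig:
    """Random-search settings for the experimentally invisible barriers.

    k0 is drawn log-uniformly within its bounds (they span seven decades);
    delta_x uniformly.  Each candidate set is scored by the SSR between
    simulated and target probability-normalised rupture-force histograms
    (20 pN bins) summed over pulling speeds; the best fraction of starts is
    polished by a coordinate-wise multiplicative line search.
    """

    k0_bounds: tuple[float, float] = (1e-5, 100.0)
    dx_bounds: tuple[float, float] = (0.01, 10.0)
    n_starts: int = 10_000
    replicates: int = 500
    bin_width: float = 20.0  # pN
    refine_top_fraction: float = 0.01
    refine_iterations: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_starts < 1 or self.replicates < 1:
            raise ValueError("n_starts and replicates must be >= 1")


@dataclass
class TransitionSearchResult:
    model: StateModel
    ssr: float
    per_speed_ssr: dict[float, float]
    n_evaluations: int
    best_ssr_trace: list[float]
    config: TransitionSearchConfig


def _target_histograms(
    targets: dict[float, np.ndarray], bin_width: float
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    fmax = max(float(np.max(v)) for v in targets.values())
    edges = np.arange(0.0, fmax + 2 * bin_width, bin_width)
    hists = {}
    for speed, forces in targets.items():
        counts, _ = np.histogram(forces, bins=edges)
        hists[speed] = counts / len(forces)
    return edges, hists


def _score_model(
    model: StateModel,
    base_cfg: ConstantSpeedConfig,
    speeds: list[float],
    edges: np.ndarray,
    target_hists: dict[float, np.ndarray],
    replicates: int,
    seed: int,
) -> tuple[float, dict[float, float]]:
    per_speed = {}
    for j, speed in enumerate(speeds):
        cfg = replace(base_cfg, pulling_speed=speed, replicates=replicates, seed=seed + j)
        sim = simulate_constant_speed(model, cfg)
        forces = sim.loc[~sim["censored"], "rupture_force_pN"].to_numpy()
        counts, _ = np.histogram(forces, bins=edges)
        h = counts / len(sim)
        per_speed[speed] = float(np.sum((h - target_hists[speed]) ** 2))
    return sum(per_speed.values()), per_speed


def _transition_edges(reversible: bool) -> list[str]:
    names = ["n_to_i1", "i1_to_i2"]
    if reversible:
        names += ["i1_to_n", "i2_to_i1"]
    return names


def _with_edges(skeleton: StateModel, values: dict[str, BEParams]) -> StateModel:
    return replace(skeleton, **values)


def fit_transition_parameters(
    skeleton: StateModel,
    targets: dict[float, np.ndarray],
    base_cfg: ConstantSpeedConfig,
    search: TransitionSearchConfig,
) -> TransitionSearchResult:
    """Fit the hidden transition-edge parameters by seeded random search.

    ``skeleton`` carries the experimentally fitted rupture edges (P0/P1/P2),
    which stay fixed; its transition edges mark which edges exist
    (reversible vs irreversible) and are re-drawn each start.  ``targets``
    maps pulling speed (nm/s) to the experimental rupture forces (pN).
    """
    speeds = sorted(targets)
    edges, target_hists = _target_histograms(targets, search.bin_width)
    rng = np.random.default_rng(search.seed)
    lo_k, hi_k = search.k0_bounds
    lo_x, hi_x = search.dx_bounds
    edge_names = _transition_edges(skeleton.reversible)

    evaluated: list[tuple[float, dict[str, BEParams]]] = []
    trace: list[float] = []
    n_eval = 0
    for _ in range(search.n_starts):
        values = {
            nm: BEParams(
                k0=float(np.exp(rng.uniform(np.log(lo_k), np.log(hi_k)))),
                delta_x=float(rng.uniform(lo_x, hi_x)),
            )
            for nm in edge_names
        }
        ssr, _ = _score_model(
            _with_edges(skeleton, values),
            base_cfg,
            speeds,
            edges,
            target_hists,
            search.replicates,
            seed=int(rng.integers(2**31 - 1)),
        )
        n_eval += 1
        evaluated.append((ssr, values))
        trace.append(min(ssr, trace[-1]) if trace else ssr)

    if not evaluated or not np.isfinite(min(e[0] for e in evaluated)):
        raise RuntimeError("transition search produced no finite SSR")

    evaluated.sort(key=lambda e: e[0])
    n_refine = max(1, int(round(search.refine_top_fraction * search.n_starts)))
    best_ssr, best_values = evaluated[0]
    for ssr0, values in evaluated[:n_refine]:
        ssr_r, values_r, n_used = _refine(
            values, ssr0, skeleton, base_cfg, speeds, edges, target_hists, search, rng
        )
        n_eval += n_used
        trace.append(min(trace[-1], ssr_r))
        if ssr_r < best_ssr:
            best_ssr, best_values = ssr_r, values_r

    best_model = _with_edges(skeleton, best_values)
    _, per_speed = _score_model(
        best_model, base_cfg, speeds, edges, target_hists, search.replicates,
        seed=int(rng.integers(2**31 - 1)),
    )
    return TransitionSearchResult(
        model=best_model,
        ssr=best_ssr,
        per_speed_ssr=per_speed,
        n_evaluations=n_eval,
        best_ssr_trace=trace,
        config=search,
    )


def _refine(values, ssr0, skeleton, base_cfg, speeds, edges, target_hists, search, rng):
    """Coordinate-wise multiplicative polish of one candidate edge set."""
    best_ssr, best = ssr0, dict(values)
    n_used = 0
    lo_k, hi_k = search.k0_bounds
    lo_x, hi_x = search.dx_bounds
    for _ in range(search.refine_iterations):
        for nm in list(best):
            for attr, lo, hi in (("k0", lo_k, hi_k), ("delta_x", lo_x, hi_x)):
                for factor in (2.0, 0.5):
                    cand = dict(best)
                    cur = getattr(best[nm], attr)
                    newv = float(np.clip(cur * factor, lo, hi))
                    cand[nm] = replace(best[nm], **{attr: newv})
                    ssr, _ = _score_model(
                        _with_edges(skeleton, cand), base_cfg, speeds, edges,
                        target_hists, search.replicates,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    n_used += 1
                    if ssr < best_ssr:
                        best_ssr, best = ssr, cand
    return best_ssr, best, n_used


def compare_transition_models(
    reversible: StateModel,
    irreversible: StateModel,
    targets: dict[float, np.ndarray],
    base_cfg: ConstantSpeedConfig,
    search: TransitionSearchConfig,
) -> dict:
    """Fit both model variants with equal budgets and report which wins.

    Refuses unequal budgets; returns per-speed and total SSR for each fit,
    the preferred (lower total SSR) variant, and the fitted models.
    """
    if not reversible.reversible:
        raise ValueError("first model must be reversible")
    if irreversible.reversible:
        raise ValueError("second model must be irreversible")
    seed = search.seed if search.seed is not None else 0
    fit_rev = fit_transition_parameters(
        reversible, targets, base_cfg, replace(search, seed=seed)
    )
    fit_irr = fit_transition_parameters(
        irreversible, targets, base_cfg, replace(search, seed=seed + 1)
    )
    return {
        "reversible": fit_rev,
        "irreversible": fit_irr,
        "preferred": "reversible" if fit_rev.ssr <= fit_irr.ssr else "irreversible",
        "ssr_reversible": fit_rev.ssr,
        "ssr_irreversible": fit_irr.ssr,
        "budget": {"n_starts": search.n_starts, "replicates": search.replicates},
    }
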