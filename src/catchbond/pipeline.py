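"""Force-curve filtering, fingerprint identification and rupture extraction.

Constant-speed AFM retraction curves are baseline-corrected, scanned for
sawtooth peaks, transformed into contour-length space with the FRC model,
screened against the single-molecule fingerprint criteria, and reduced to
per-complex rupture records (rupture force, loading rate, final contour
length, intermediate unfolding increments).  Force-clamp force-vs-time
traces are screened for non-specific adhesion signatures and reduced to
setpoint/lifetime records.

Filter rules and fingerprint criteria follow the experimental protocol for
an ELP-tethered construct with two ddFLN4 fingerprint domains: reject
curves with peaks within the first ~100 nm of extension, with no peaks, or
with more than 9 peaks; accept either a bare rupture (<100 pN near the
folded-construct contour length) or a rupture preceded by the four-peak
50–80 pN ddFLN4 pattern adding 32 nm of contour length.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, medfilt

from .polymer import DEFAULT_NOISE_FLOOR_PN, FRCParams, frc_contour_length

__all__ = [
    "ForceCurve",
    "PeakEvent",
    "RuptureRecord",
    "ClampTrace",
    "LifetimeRecord",
    "FingerprintCriteria",
    "ClampFilterConfig",
    "baseline_subtract",
    "detect_peaks",
    "prefilter",
    "to_contour_length",
    "identify_fingerprint",
    "extract_rupture",
    "filter_clamp_traces",
    "estimate_setpoint_and_lifetime",
]


@dataclass
class ForceCurve:
    """One baselined or raw retraction trace: extension (nm) vs force (pN)."""

    extension: np.ndarray
    force: np.ndarray
    pulling_speed: float  # nm/s
    spring_constant: float  # N/m
    curve_id: str = "curve"
    experiment_id: str = "exp"
    baseline_flag: str = ""

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape or self.extension.size < 2:
            raise ValueError("extension and force must be equal-length arrays (>= 2)")
        if np.any(np.diff(self.extension) < 0):
            raise ValueError("extension must be non-decreasing")

    @property
    def time(self) -> np.ndarray:
        """Time axis (s) from head height H = x + F/k at the pulling speed."""
        H = self.extension + self.force / (1000.0 * self.spring_constant)
        return (H - H[0]) / self.pulling_speed


@dataclass
class PeakEvent:
    """One detected sawtooth peak, annotated with contour-length bookkeeping."""

    index: int
    peak_force: float  # pN
    extension: float  # nm
    contour_before: float = math.nan  # nm
    contour_after: float = math.nan  # nm
    kind: str = "unknown"  # fingerprint | intermediate | rupture | unknown

    @property
    def increment(self) -> float:
        return self.contour_after - self.contour_before


@dataclass
class RuptureRecord:
    """One complex rupture reduced from a fingerprint-positive curve."""

    rupture_force: float  # pN
    loading_rate: float  # pN/s; NaN when the rise segment was degenerate
    final_contour_length: float  # nm
    pathway: str = "unassigned"  # P0 | P1 | P2 | unassigned
    subtype: str = "unassigned"  # a | b | c | unassigned
    intermediate_increments: tuple[float, ...] = ()
    pulling_speed: float = math.nan
    experiment_id: str = ""
    curve_id: str = ""
    flags: str = ""


@dataclass
class ClampTrace:
    """Force-clamp force vs time trace with the feedback head-height channel."""

    time: np.ndarray  # s
    force: np.ndarray  # pN
    head_height: np.ndarray  # nm
    target_setpoint: float  # pN
    trace_id: str = "trace"
    experiment_id: str = "exp"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.head_height = np.asarray(self.head_height, dtype=float)
        if not (self.time.shape == self.force.shape == self.head_height.shape):
            raise ValueError("time, force and head_height must be equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class LifetimeRecord:
    """Setpoint estimate and bond lifetime for one accepted clamp trace."""

    setpoint_estimate: float  # pN
    lifetime: float  # s
    force_bin: float  # lower edge of the 10 pN setpoint bin
    accepted: bool = True
    rejection_reason: str = ""
    trace_id: str = ""
    experiment_id: str = ""


def baseline_subtract(curve: ForceCurve, tail_threshold: float = 10.0) -> ForceCurve:
    """Zero the post-rupture tail and remove a linear baseline tilt.

    The tail is everything beyond the last sample whose median-smoothed
    force exceeds ``tail_threshold``; a line fitted to the tail is
    subtracted from the whole curve, forcing the tail median to 0.  Curves
    without an identifiable tail are flagged and passed through unchanged.
    """
    f_s = medfilt(curve.force, 5) if curve.force.size >= 5 else curve.force
    above = np.flatnonzero(f_s > tail_threshold)
    tail_start = (above[-1] + 3) if above.size else 0
    if curve.extension.size - tail_start < 10:
        return replace(curve, baseline_flag="no_tail")
    xt = curve.extension[tail_start:]
    ft = curve.force[tail_start:]
    slope, intercept = np.polyfit(xt, ft, 1)
    corrected = curve.force - (slope * curve.extension + intercept)
    corrected -= np.median(corrected[tail_start:])
    return replace(curve, force=corrected, baseline_flag="")


def detect_peaks(
    curve: ForceCurve,
    min_prominence: float = 10.0,
    min_drop: float = 10.0,
    smooth_window: int = 5,
) -> list[PeakEvent]:
    """Sawtooth peaks: prominent maxima followed by a force drop >= min_drop.

    The force is median-smoothed (window in samples) before peak finding; a
    monotone ramp yields an empty list.  Events are returned in order of
    extension.
    """
    f = curve.force
    if smooth_window >= 3 and f.size >= smooth_window:
        f = medfilt(f, smooth_window | 1)
    idx, _ = find_peaks(f, prominence=min_prominence)
    events = []
    boundaries = list(idx[1:]) + [f.size]
    w = max(2, smooth_window)
    for i, nxt in zip(idx, boundaries):
        ahead = f[i:nxt] if nxt > i else f[i:]
        if ahead.size and (f[i] - np.min(ahead)) >= min_drop:
            # smoothing shifts the apex; re-locate it on the raw signal
            lo = max(0, i - w)
            hi = min(curve.force.size, i + w + 1)
            i = lo + int(np.argmax(curve.force[lo:hi]))
            events.append(
                PeakEvent(
                    index=int(i),
                    peak_force=float(curve.force[i]),
                    extension=float(curve.extension[i]),
                )
            )
    return events


def prefilter(
    curves_with_peaks: list[tuple[ForceCurve, list[PeakEvent]]],
    min_first_peak_extension: float = 100.0,
    max_peaks: int = 9,
) -> tuple[list[tuple[ForceCurve, list[PeakEvent]]], list[tuple[ForceCurve, str]]]:
    """Automated curve filter preceding fingerprint identification.

    Rejects, with exactly one reason each: ``early_peak`` (a sawtooth within
    the first ~100 nm of extension — the non-specific adhesion signature),
    ``no_peaks``, and ``too_many_peaks`` (more than 9).
    """
    kept, rejected = [], []
    for curve, peaks in curves_with_peaks:
        if peaks and min(p.extension for p in peaks) < min_first_peak_extension:
            rejected.append((curve, "early_peak"))
        elif not peaks:
            rejected.append((curve, "no_peaks"))
        elif len(peaks) > max_peaks:
            rejected.append((curve, "too_many_peaks"))
        else:
            kept.append((curve, peaks))
    return kept, rejected


def to_contour_length(
    curve: ForceCurve,
    frc: FRCParams | None = None,
    noise_floor: float = DEFAULT_NOISE_FLOOR_PN,
) -> np.ndarray:
    """Per-sample contour length (nm) via the FRC transform.

    Samples below the force noise floor are NaN (excluded, not zeroed);
    within one unfolding plateau the contour length is constant to within
    noise.
    """
    frc = frc or FRCParams()
    return np.asarray(
        frc_contour_length(curve.force, curve.extension, frc, noise_floor=noise_floor)
    )


@dataclass(frozen=True)
class FingerprintCriteria:
    """Tolerances making the fingerprint criteria's '~' values explicit.

    criterion 1: a bare rupture < 100 pN at the folded-construct contour
    length (~135 nm) with no fingerprint unfolding; criterion 2: four
    50–80 pN peaks adding 32 nm of contour, rupture at ~190 nm.
    """

    criterion1_max_force: float = 100.0  # pN
    criterion1_contour: float = 135.0  # nm
    criterion1_contour_tol: float = 10.0  # nm
    fingerprint_force_range: tuple[float, float] = (50.0, 80.0)  # pN, hard window
    fingerprint_peaks: int = 4
    fingerprint_total_increment: float = 32.0  # nm
    fingerprint_increment_tol: float = 4.0  # nm
    final_contour: float = 190.0  # nm
    final_contour_tol: float = 15.0  # nm


def _annotate_contours(
    curve: ForceCurve, peaks: list[PeakEvent], contour: np.ndarray, guard: int = 3
) -> None:
    """Fill contour_before/contour_after from inter-peak contour plateaus."""
    cuts = [0] + [p.index for p in peaks] + [contour.size]
    for j, p in enumerate(peaks):
        before = contour[cuts[j] : max(cuts[j], p.index - guard)]
        after = contour[p.index + guard : cuts[j + 2] - (guard if j + 1 < len(peaks) else 0)]
        before = before[np.isfinite(before)]
        after = after[np.isfinite(after)]
        p.contour_before = float(np.median(before)) if before.size else math.nan
        p.contour_after = float(np.median(after)) if after.size else math.nan


def identify_fingerprint(
    curve: ForceCurve,
    peaks: list[PeakEvent],
    contour: np.ndarray | None = None,
    criteria: FingerprintCriteria | None = None,
    frc: FRCParams | None = None,
) -> str:
    """Classify a prefiltered curve as ``criterion1``, ``criterion2`` or ``reject``.

    Side effect: annotates each peak's contour bookkeeping and kind
    (fingerprint / intermediate / rupture).
    """
    crit = criteria or FingerprintCriteria()
    if contour is None:
        contour = to_contour_length(curve, frc)
    if not peaks:
        return "reject"
    _annotate_contours(curve, peaks, contour)
    terminal = peaks[-1]
    terminal.kind = "rupture"
    inner = peaks[:-1]
    lo, hi = crit.fingerprint_force_range
    in_window = [p for p in inner if lo <= p.peak_force <= hi]
    for p in inner:
        p.kind = "intermediate"

    # criterion 2: a ddFLN4-complete curve
    if len(in_window) >= crit.fingerprint_peaks:
        target = crit.fingerprint_total_increment
        best, best_err = None, math.inf
        for combo in itertools.combinations(in_window, crit.fingerprint_peaks):
            total = sum(p.increment for p in combo)
            if math.isnan(total):
                continue
            err = abs(total - target)
            if err < best_err:
                best, best_err = combo, err
        # intermediate unfolding adds its increments on top of the ~190 nm
        # fingerprint-complete contour; credit them before comparing
        extra = 0.0
        if best is not None:
            extra = sum(
                p.increment
                for p in inner
                if p not in best and math.isfinite(p.increment)
            )
        if (
            best is not None
            and best_err <= crit.fingerprint_increment_tol
            and math.isfinite(terminal.contour_before)
            and abs(terminal.contour_before - crit.final_contour - extra)
            <= crit.final_contour_tol
        ):
            for p in best:
                p.kind = "fingerprint"
            return "criterion2"

    # criterion 1: bare low-force rupture at the folded contour length
    if (
        not inner
        and terminal.peak_force < crit.criterion1_max_force
        and math.isfinite(terminal.contour_before)
        and abs(terminal.contour_before - crit.criterion1_contour)
        <= crit.criterion1_contour_tol
    ):
        return "criterion1"
    return "reject"


def extract_rupture(
    curve: ForceCurve,
    peaks: list[PeakEvent],
    classification: str,
    loading_fraction: float = 0.3,
    min_fit_samples: int = 5,
) -> RuptureRecord:
    """Reduce a classified curve to a rupture record.

    The loading rate is the slope of a linear force-vs-time fit over the
    final rise: from the last local force minimum before the terminal peak,
    restricted to forces above ``loading_fraction`` of the rupture force.
    A rise segment with fewer than ``min_fit_samples`` samples leaves the
    loading rate undefined (NaN) and flags the record.
    """
    if classification not in ("criterion1", "criterion2"):
        raise ValueError("extract_rupture requires a fingerprint-positive curve")
    terminal = peaks[-1]
    t = curve.time
    start = peaks[-2].index + 1 if len(peaks) > 1 else 0
    seg_f = curve.force[start : terminal.index + 1]
    rel_min = int(np.argmin(seg_f))
    rise0 = start + rel_min
    sel = np.arange(rise0, terminal.index + 1)
    sel = sel[curve.force[sel] >= loading_fraction * terminal.peak_force]
    flags = ""
    if sel.size >= min_fit_samples:
        slope = float(np.polyfit(t[sel], curve.force[sel], 1)[0])
    else:
        slope, flags = math.nan, "degenerate_rise"
    increments = tuple(
        p.increment for p in peaks if p.kind == "intermediate" and math.isfinite(p.increment)
    )
    subtype = "a" if classification == "criterion1" else ("c" if increments else "b")
    return RuptureRecord(
        rupture_force=terminal.peak_force,
        loading_rate=slope,
        final_contour_length=terminal.contour_before,
        subtype=subtype,
        intermediate_increments=increments,
        pulling_speed=curve.pulling_speed,
        experiment_id=curve.experiment_id,
        curve_id=curve.curve_id,
        flags=flags,
    )


def rupture_table(records: list[RuptureRecord]) -> pd.DataFrame:
    """Rupture records as a tidy table with unit-suffixed columns."""
    return pd.DataFrame(
        {
            "rupture_force_pN": [r.rupture_force for r in records],
            "loading_rate_pN_s": [r.loading_rate for r in records],
            "final_contour_length_nm": [r.final_contour_length for r in records],
            "pathway": [r.pathway for r in records],
            "subtype": [r.subtype for r in records],
            "n_intermediates": [len(r.intermediate_increments) for r in records],
            "intermediate_increments_nm": [
                ";".join(f"{v:.2f}" for v in r.intermediate_increments) for r in records
            ],
            "pulling_speed_nm_s": [r.pulling_speed for r in records],
            "experiment_id": [r.experiment_id for r in records],
            "curve_id": [r.curve_id for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Force clamp


@dataclass(frozen=True)
class ClampFilterConfig:
    """Non-specific clamping filter thresholds.

    A trace is rejected when it shows more than ``max_head_steps`` discrete
    head-height jumps (> ``head_step_threshold`` nm between feedback
    plateaus), a retraction distance outside [40, 200] nm, or a lifetime
    below the 15 ms feedback-regularisation floor.
    """

    max_head_steps: int = 3
    head_step_threshold: float = 5.0  # nm
    min_retraction: float = 40.0  # nm
    max_retraction: float = 200.0  # nm
    lifetime_floor: float = 0.015  # s
    setpoint_window: float = 0.005  # s


def _count_head_steps(head: np.ndarray, threshold: float) -> int:
    smooth = medfilt(head, 5) if head.size >= 5 else head
    return int(np.sum(np.abs(np.diff(smooth)) > threshold))


def estimate_setpoint_and_lifetime(
    trace: ClampTrace, cfg: ClampFilterConfig | None = None
) -> LifetimeRecord:
    """Setpoint and lifetime of one clamp trace.

    The setpoint estimate is the highest mean force over any sliding ~5 ms
    window during clamping; the lifetime runs from clamp start until the
    head resumes retraction (force falls off the setpoint).  A clamp
    segment shorter than the averaging window is flagged.
    """
    cfg = cfg or ClampFilterConfig()
    f = trace.force
    target = trace.target_setpoint
    on = np.flatnonzero(f >= 0.9 * target)
    if on.size == 0:
        return LifetimeRecord(
            setpoint_estimate=math.nan, lifetime=0.0, force_bin=math.nan,
            accepted=False, rejection_reason="no_clamp_segment",
            trace_id=trace.trace_id, experiment_id=trace.experiment_id,
        )
    start = on[0]
    below = np.flatnonzero(f[start:] < 0.5 * target)
    end = start + below[0] if below.size else f.size - 1
    lifetime = float(trace.time[end] - trace.time[start])

    dt = float(np.median(np.diff(trace.time)))
    w = max(1, int(round(cfg.setpoint_window / dt)))
    clamp_f = f[start:end]
    reason = ""
    if clamp_f.size >= w:
        means = np.convolve(clamp_f, np.ones(w) / w, mode="valid")
        setpoint = float(np.max(means))
    else:
        setpoint = float(np.mean(clamp_f)) if clamp_f.size else math.nan
        reason = "clamp_shorter_than_window"
    return LifetimeRecord(
        setpoint_estimate=setpoint,
        lifetime=lifetime,
        force_bin=math.floor(setpoint / 10.0) * 10.0 if math.isfinite(setpoint) else math.nan,
        accepted=reason == "",
        rejection_reason=reason,
        trace_id=trace.trace_id,
        experiment_id=trace.experiment_id,
    )


def filter_clamp_traces(
    traces: list[ClampTrace], cfg: ClampFilterConfig | None = None
) -> tuple[list[LifetimeRecord], list[tuple[ClampTrace, str]]]:
    """Screen clamp traces for non-specific events and extract lifetimes.

    Rejection reasons: ``head_steps``, ``retraction_short``,
    ``retraction_long``, ``lifetime_floor`` (exactly one per rejected
    trace, checked in that order).
    """
    cfg = cfg or ClampFilterConfig()
    accepted, rejected = [], []
    for trace in traces:
        if _count_head_steps(trace.head_height, cfg.head_step_threshold) > cfg.max_head_steps:
            rejected.append((trace, "head_steps"))
            continue
        # retraction distance up to bond rupture; the post-rupture pull-away
        # of the head does not count
        above = np.flatnonzero(trace.force >= 0.5 * trace.target_setpoint)
        end = above[-1] if above.size else trace.force.size - 1
        retraction = float(np.ptp(trace.head_height[: end + 1]))
        if retraction < cfg.min_retraction:
            rejected.append((trace, "retraction_short"))
            continue
        if retraction > cfg.max_retraction:
            rejected.append((trace, "retraction_long"))
            continue
        record = estimate_setpoint_and_lifetime(trace, cfg)
        if record.lifetime < cfg.lifetime_floor:
            rejected.append((trace, "lifetime_floor"))
            continue
        accepted.append(record)
    return accepted, rejected


def lifetime_table(records: list[LifetimeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "setpoint_estimate_pN": [r.setpoint_estimate for r in records],
            "lifetime_s": [r.lifetime for r in records],
            "force_bin_pN": [r.force_bin for r in records],
            "accepted": [r.accepted for r in records],
            "rejection_reason": [r.rejection_reason for r in records],
            "trace_id": [r.trace_id for r in records],
            "experiment_id": [r.experiment_id for r in records],
        }
    )
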