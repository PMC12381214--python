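"""Closed-form polymer elasticity models.

Two models are used throughout the package, in complementary roles:

* the freely rotating chain (FRC) — rigid bonds of length ``b`` joined at a
  fixed angle ``gamma`` — which maps measured force–extension data into
  contour-length space.  For a polypeptide stretched between an AFM tip and
  a surface the FRC describes the full 20–700 pN force range with a single
  parameter set, which is why it is preferred over the worm-like chain for
  the analysis transform.
* the worm-like chain (WLC, Marko–Siggia interpolation), used to *generate*
  forces along an extension axis when driving kinetic Monte Carlo
  simulations of bond rupture.

Units are fixed package-wide: nm, pN, s, K.  ``1 N/m == 1 pN/nm`` so AFM
spring constants can be used numerically unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThermalContext",
    "FRCParams",
    "WLCParams",
    "frc_kuhn_length",
    "frc_persistence_length",
    "frc_relative_extension",
    "frc_force_from_relative_extension",
    "frc_contour_length",
    "frc_branch_discontinuities",
    "wlc_force",
    "wlc_extension",
]

#: Boltzmann constant in pN·nm/K.
BOLTZMANN_PN_NM = 0.013807

#: Default contour-length noise floor (pN); below this force the inversion
#: x -> L amplifies force noise too strongly to be useful.
DEFAULT_NOISE_FLOOR_PN = 10.0


@dataclass(frozen=True)
class ThermalContext:
    """Temperature and Boltzmann constant shared by all force–rate formulas."""

    temperature: float = 298.15  # K
    boltzmann_kB: float = BOLTZMANN_PN_NM  # pN·nm/K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.boltzmann_kB <= 0:
            raise ValueError("boltzmann_kB must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy in pN·nm."""
        return self.boltzmann_kB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(kB·T) in 1/(pN·nm)."""
        return 1.0 / self.kBT


@dataclass(frozen=True)
class FRCParams:
    """Freely rotating chain parameters for a polypeptide tether.

    Defaults are the standard FRC polypeptide values (b = 0.4 nm backbone
    segment, gamma = 41 degrees, correction constant c = 2); they are a
    documented choice, configurable per analysis.
    """

    bond_length_b: float = 0.4  # nm
    bond_angle_gamma: float = math.radians(41.0)  # rad
    correction_c: float = 2.0
    temperature: float = 298.15  # K
    boltzmann_kB: float = BOLTZMANN_PN_NM

    def __post_init__(self) -> None:
        if self.bond_length_b <= 0:
            raise ValueError("bond_length_b must be positive")
        if not 0.0 < self.bond_angle_gamma < math.pi / 2:
            raise ValueError("bond_angle_gamma must lie in (0, pi/2)")
        if self.correction_c <= 0:
            raise ValueError("correction_c must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        return self.boltzmann_kB * self.temperature


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters: contour length L and persistence length p."""

    contour_length_L: float  # nm
    persistence_length_p: float = 0.4  # nm
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.contour_length_L <= 0:
            raise ValueError("contour_length_L must be positive")
        if self.persistence_length_p <= 0:
            raise ValueError("persistence_length_p must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def frc_kuhn_length(params: FRCParams) -> float:
    """Kuhn length a = b(1+cos g) / ((1-cos g) cos(g/2)) in nm."""
    g = params.bond_angle_gamma
    cg = math.cos(g)
    denom = (1.0 - cg) * math.cos(g / 2.0)
    if denom == 0.0:
        raise ValueError("bond angle gamma = 0 leaves the Kuhn length undefined")
    return params.bond_length_b * (1.0 + cg) / denom


def frc_persistence_length(params: FRCParams) -> float:
    """FRC persistence length p = b cos(g/2) / |ln cos g| in nm."""
    g = params.bond_angle_gamma
    cg = math.cos(g)
    if cg <= 0.0:
        raise ValueError("cos(gamma) must be positive for the FRC persistence length")
    denom = abs(math.log(cg))
    if denom == 0.0:
        raise ValueError("gamma = 0 gives an infinite persistence length")
    return params.bond_length_b * math.cos(g / 2.0) / denom


def _frc_thresholds(params: FRCParams) -> tuple[float, float, float, float]:
    """(a, p, F_low_mid, F_mid_high): Kuhn/persistence lengths and the two
    branch-boundary forces of the piecewise extension law."""
    a = frc_kuhn_length(params)
    p = frc_persistence_length(params)
    b = params.bond_length_b
    kBT = params.kBT
    # Fb/kBT < b/p  <=>  F < kBT/p ;  Fb/kBT > p/b  <=>  F > kBT*p/b^2
    return a, p, kBT / p, kBT * p / (b * b)


def frc_relative_extension(force, params: FRCParams):
    """Relative extension x/L of an FRC at tension ``force`` (pN).

    Piecewise law with three force regimes (entropic linear, intermediate,
    and high-force 1/F saturation).  Boundary equality is assigned to the
    middle branch (closed interval); the printed inequalities are strict and
    leave the boundaries open.  Accepts scalars or arrays.
    """
    F = np.asarray(force, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be non-negative")
    a, p, f_lo, f_hi = _frc_thresholds(params)
    b = params.bond_length_b
    c = params.correction_c
    kBT = params.kBT

    low = F * a / (3.0 * kBT)
    with np.errstate(divide="ignore"):
        mid = 1.0 - (4.0 * F * p / kBT) ** -0.5
        high = 1.0 - (c * F * b / kBT) ** -1.0
    out = np.where(F < f_lo, low, np.where(F <= f_hi, mid, high))
    if out.ndim == 0:
        return float(out)
    return out


def frc_force_from_relative_extension(ratio, params: FRCParams):
    """Invert the FRC extension law: tension (pN) producing x/L = ``ratio``.

    Each branch is inverted in closed form; where more than one branch is
    admissible (the law is discontinuous at the low/mid boundary) the lowest
    admissible force is returned, matching a loading trajectory that starts
    from zero force.  Round-trips exactly with :func:`frc_relative_extension`.
    """
    rho = np.asarray(ratio, dtype=float)
    if np.any(rho < 0) or np.any(rho >= 1.0):
        raise ValueError("relative extension must lie in [0, 1)")
    a, p, f_lo, f_hi = _frc_thresholds(params)
    b = params.bond_length_b
    c = params.correction_c
    kBT = params.kBT

    f_low = 3.0 * kBT * rho / a
    with np.errstate(divide="ignore"):
        f_mid = kBT / (4.0 * p * (1.0 - rho) ** 2)
        f_high = kBT / (c * b * (1.0 - rho))
    out = np.where(
        f_low < f_lo,
        f_low,
        np.where(f_mid <= f_hi, np.maximum(f_mid, f_lo), f_high),
    )
    if out.ndim == 0:
        return float(out)
    return out


def frc_contour_length(
    force,
    extension,
    params: FRCParams,
    noise_floor: float = DEFAULT_NOISE_FLOOR_PN,
):
    """Contour length L = extension / (x/L)(F) in nm.

    Samples with force below ``noise_floor`` are undefined (the inversion
    amplifies noise there) and returned as NaN so callers can exclude rather
    than zero them.  Scalar or array input.
    """
    F = np.asarray(force, dtype=float)
    x = np.asarray(extension, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be non-negative")
    rel = np.asarray(frc_relative_extension(np.maximum(F, 0.0), params))
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where((F >= noise_floor) & (rel > 0), x / rel, np.nan)
    if L.ndim == 0:
        return float(L)
    return L


def frc_branch_discontinuities(params: FRCParams) -> dict[str, dict[str, float]]:
    """Diagnostic: jumps of x/L at the two branch boundaries.

    The piecewise law is not guaranteed continuous; with polypeptide
    defaults the low/mid boundary jumps down while the mid/high boundary is
    continuous (exactly so for c = 2).  Reported, never masked.
    """
    a, p, f_lo, f_hi = _frc_thresholds(params)
    b = params.bond_length_b
    c = params.correction_c
    kBT = params.kBT
    low_at_lo = f_lo * a / (3.0 * kBT)
    mid_at_lo = 1.0 - (4.0 * f_lo * p / kBT) ** -0.5
    mid_at_hi = 1.0 - (4.0 * f_hi * p / kBT) ** -0.5
    high_at_hi = 1.0 - (c * f_hi * b / kBT) ** -1.0
    return {
        "low_mid": {
            "force_pN": f_lo,
            "below": low_at_lo,
            "above": mid_at_lo,
            "jump": mid_at_lo - low_at_lo,
        },
        "mid_high": {
            "force_pN": f_hi,
            "below": mid_at_hi,
            "above": high_at_hi,
            "jump": high_at_hi - mid_at_hi,
        },
    }


def wlc_force(extension, params: WLCParams, ctx: ThermalContext | None = None):
    """Marko–Siggia WLC interpolation force (pN) at ``extension`` (nm).

    F = (kBT/p) [ 1/(4(1-x/L)^2) - 1/4 + x/L ]; strictly increasing in x and
    divergent as x -> L.  Raises for extension >= L.
    """
    if ctx is None:
        ctx = ThermalContext(temperature=params.temperature)
    x = np.asarray(extension, dtype=float)
    L = params.contour_length_L
    if np.any(x < 0) or np.any(x >= L):
        raise ValueError("extension must lie in [0, L)")
    ratio = x / L
    out = (ctx.kBT / params.persistence_length_p) * (
        0.25 / (1.0 - ratio) ** 2 - 0.25 + ratio
    )
    if out.ndim == 0:
        return float(out)
    return out


def wlc_extension(force, params: WLCParams, ctx: ThermalContext | None = None):
    """Numerically invert :func:`wlc_force`: extension (nm) at tension (pN).

    The Marko–Siggia force is a cubic in x/L; the physical root in [0, 1) is
    found with a vectorised bisection (monotonicity makes it unique).
    """
    if ctx is None:
        ctx = ThermalContext(temperature=params.temperature)
    F = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(F < 0):
        raise ValueError("force must be non-negative")
    lo = np.zeros_like(F)
    hi = np.full_like(F, 1.0 - 1e-12)
    for _ in range(80):  # bisection to ~machine precision in x/L
        midr = 0.5 * (lo + hi)
        fmid = (ctx.kBT / params.persistence_length_p) * (
            0.25 / (1.0 - midr) ** 2 - 0.25 + midr
        )
        takes = fmid < F
        lo = np.where(takes, midr, lo)
        hi = np.where(takes, hi, midr)
    out = 0.5 * (lo + hi) * params.contour_length_L
    if np.isscalar(force) or np.asarray(force).ndim == 0:
        return float(out[0])
    return out
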