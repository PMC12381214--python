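"""Nonparametric statistical protocols and the Hill-equation binding fit.

Bond lifetimes and rupture forces from different unbinding pathways are not
expected to be normally distributed (they mix several kinetic states), so
the analysis screens groups with Shapiro–Wilk and then uses Kruskal–Wallis
omnibus tests followed by either Dunn's multiple-comparison tests
(Šidák-adjusted, with a compact letter display) or pairwise Wilcoxon
rank-sum tests.  All tests are two-sided at alpha = 0.05.

Titration data from the bead-binding assay is fitted with the Hill
equation, signal = baseline + bmax * c^n / (kd^n + c^n), to extract the
equilibrium dissociation constant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "normality_screen",
    "kruskal_dunn",
    "kruskal_wilcoxon_pairwise",
    "compact_letter_display",
    "HillFitResult",
    "fit_hill",
]


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {str(i): np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def normality_screen(groups, alpha: float = 0.05, min_n: int = 3) -> pd.DataFrame:
    """Shapiro–Wilk screen per group; groups below ``min_n`` are skipped."""
    rows = []
    for name, values in _as_groups(groups).items():
        if values.size < min_n:
            rows.append(
                {"group": name, "n": values.size, "W": math.nan, "p": math.nan,
                 "non_normal": False, "skipped": "too_few_observations"}
            )
            continue
        W, p = sps.shapiro(values)
        rows.append(
            {"group": name, "n": values.size, "W": float(W), "p": float(p),
             "non_normal": bool(p < alpha), "skipped": ""}
        )
    return pd.DataFrame(rows)


@dataclass
class MultipleComparisonResult:
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # symmetric matrix of (adjusted) p-values
    letters: dict[str, str]  # compact letter display (empty for rank-sum variant)
    method: str


def _kruskal(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    values = list(groups.values())
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence of any difference
        return 0.0, 1.0
    H, p = sps.kruskal(*values)
    return float(H), float(p)


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-tests on Kruskal–Wallis ranks with tie-corrected variance."""
    names = list(groups)
    sizes = {k: v.size for k, v in groups.items()}
    pooled = np.concatenate([groups[k] for k in names])
    ranks = sps.rankdata(pooled)
    N = pooled.size
    mean_ranks, start = {}, 0
    for k in names:
        mean_ranks[k] = float(np.mean(ranks[start : start + sizes[k]]))
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1.0))
    var_base = N * (N + 1.0) / 12.0 - tie_term

    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        pij = 2.0 * sps.norm.sf(abs(z))
        p.loc[a, b] = p.loc[b, a] = pij
    return p


def _sidak(p: pd.DataFrame) -> pd.DataFrame:
    """Šidák family-wise adjustment over all pairwise comparisons."""
    m = len(p) * (len(p) - 1) // 2
    adj = 1.0 - (1.0 - p) ** m
    np.fill_diagonal(adj.values, 1.0)
    return adj.clip(upper=1.0)


def compact_letter_display(
    pairwise: pd.DataFrame, means: dict[str, float], alpha: float = 0.05
) -> dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different.

    Insert-and-absorb: start from one letter covering all groups; for every
    significant pair split each letter containing both; absorb letters that
    became subsets of others.  Letters are assigned a–z in order of the
    group means.
    """
    names = sorted(means, key=means.get)
    letters: list[set[str]] = [set(names)]
    for a, b in itertools.combinations(names, 2):
        if pairwise.loc[a, b] >= alpha:
            continue
        for s in [s for s in letters if a in s and b in s]:
            letters.remove(s)
            letters.extend([s - {a}, s - {b}])
        letters = [
            s for s in letters if s and not any(s < o for o in letters if o is not s)
        ]
    # deduplicate while keeping deterministic order by lowest-mean member
    unique: list[set[str]] = []
    for s in letters:
        if s not in unique:
            unique.append(s)
    unique.sort(key=lambda s: min(names.index(g) for g in s))
    out = {name: "" for name in names}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", unique):
        for g in s:
            out[g] += letter
    return out


def kruskal_dunn(groups, alpha: float = 0.05) -> MultipleComparisonResult:
    """Kruskal–Wallis omnibus test + Dunn's tests with Šidák adjustment.

    Returns the omnibus result, the symmetric adjusted p-value matrix and a
    compact letter display at ``alpha`` (shared letter = no significant
    difference).  All-identical data yields omnibus p = 1 by convention.
    """
    g = _as_groups(groups)
    H, p_omni = _kruskal(g)
    p_adj = _sidak(_dunn_pairwise(g))
    means = {k: float(np.mean(v)) for k, v in g.items()}
    return MultipleComparisonResult(
        omnibus_statistic=H,
        omnibus_p=p_omni,
        pairwise=p_adj,
        letters=compact_letter_display(p_adj, means, alpha),
        method="kruskal-dunn-sidak",
    )


def kruskal_wilcoxon_pairwise(groups) -> MultipleComparisonResult:
    """Kruskal–Wallis omnibus test + pairwise Wilcoxon rank-sum tests."""
    g = _as_groups(groups)
    H, p_omni = _kruskal(g)
    names = list(g)
    p = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        res = sps.mannwhitneyu(g[a], g[b], alternative="two-sided")
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return MultipleComparisonResult(
        omnibus_statistic=H,
        omnibus_p=p_omni,
        pairwise=p,
        letters={},
        method="kruskal-wilcoxon",
    )


@dataclass(frozen=True)
class HillFitResult:
    """Hill-equation fit: dissociation constant, cooperativity, amplitudes."""

    kd: float  # same units as the concentrations
    hill_n: float
    bmax: float
    baseline: float
    stderr: dict[str, float]
    ssr: float


def fit_hill(
    titration: pd.DataFrame,
    concentration_column: str = "concentration_nM",
    signal_column: str = "signal",
    hill_bounds: tuple[float, float] = (0.5, 4.0),
    fit_baseline: bool = True,
) -> HillFitResult:
    """Nonlinear least-squares Hill fit over a log-spaced initialisation grid.

    Needs >= 5 concentration points spanning the half-saturation region.
    Initial kd values cover the measured concentration range
    logarithmically and the Hill coefficient is bounded to
    ``hill_bounds``; the best converged start wins.  An all-flat signal is
    unidentifiable and raises.
    """
    c = titration[concentration_column].to_numpy(dtype=float)
    y = titration[signal_column].to_numpy(dtype=float)
    if np.unique(c).size < 5:
        raise ValueError("Hill fit needs >= 5 distinct concentrations")
    span = float(np.ptp(y))
    if span <= 0 or not np.isfinite(span):
        raise ValueError("signal carries no concentration dependence (unidentifiable)")

    def residual(params):
        kd, n = params["kd"], params["hill_n"]
        model = params["baseline"] + params["bmax"] * c**n / (kd**n + c**n)
        return model - y

    best = None
    kd_grid = np.geomspace(c[c > 0].min(), c.max(), 7)
    for kd0 in kd_grid:
        for n0 in (0.5, 1.0, 2.0, 4.0):
            params = lmfit.Parameters()
            params.add("kd", value=float(kd0), min=1e-12)
            params.add("hill_n", value=float(n0), min=hill_bounds[0], max=hill_bounds[1])
            params.add("bmax", value=span, min=1e-12)
            params.add(
                "baseline", value=float(np.min(y)), vary=fit_baseline
            )
            try:
                res = lmfit.minimize(residual, params, method="leastsq")
            except Exception:
                continue
            if not res.success:
                continue
            ssr = float(np.sum(res.residual**2))
            if best is None or ssr < best[0]:
                best = (ssr, res)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from any start")
    ssr, res = best
    stderr = {
        name: (float(par.stderr) if par.stderr is not None else math.nan)
        for name, par in res.params.items()
    }
    return HillFitResult(
        kd=float(res.params["kd"]),
        hill_n=float(res.params["hill_n"]),
        bmax=float(res.params["bmax"]),
        baseline=float(res.params["baseline"]),
        stderr=stderr,
        ssr=ssr,
    )
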