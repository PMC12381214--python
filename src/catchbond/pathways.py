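"""Gaussian-mixture classification of rupture forces into unbinding pathways.

Pooled rupture forces from one experiment are square-root transformed and
z-standardised, then fitted with 1-D Gaussian mixtures of 1–4 components
(multiple restarts, BIC selection).  Pathways P0 < P1 < P2 are the
components ordered by ascending mean.  When a fourth component is selected
it is treated as minor experimental variance: its records are reclassified
into the overlapping parent components (Bhattacharyya overlap criterion)
so three effective pathways remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "ForceTransform",
    "GMMResult",
    "preprocess_forces",
    "fit_pathway_gmm",
    "reclassify_fourth_component",
    "assign_pathways",
    "pathway_proportions",
]

PATHWAY_LABELS = ("P0", "P1", "P2", "P3")


@dataclass(frozen=True)
class ForceTransform:
    """Invertible sqrt + z-standardisation applied before GMM fitting."""

    mean: float
    sd: float

    def forward(self, forces) -> np.ndarray:
        f = np.asarray(forces, dtype=float)
        if np.any(f <= 0):
            raise ValueError("rupture forces must be positive")
        return (np.sqrt(f) - self.mean) / self.sd

    def inverse(self, z) -> np.ndarray:
        return (np.asarray(z, dtype=float) * self.sd + self.mean) ** 2


@dataclass
class GMMResult:
    """Mixture fit in transformed space plus per-record responsibilities."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray  # transformed space
    variances: np.ndarray
    responsibilities: np.ndarray  # (n_records, n_components)
    transform: ForceTransform
    scores: dict[int, float]  # candidate n -> selection score (BIC)
    converged: bool = True
    reclassified: bool = False
    reclassification_flag: str = ""

    def component_means_pN(self) -> np.ndarray:
        """Component centres mapped back to force units."""
        return self.transform.inverse(self.means)


def preprocess_forces(forces) -> tuple[np.ndarray, ForceTransform]:
    """Square-root transform then z-standardise pooled rupture forces.

    Returns the transformed values (mean 0, variance 1) and the invertible
    transform parameters.  A singleton (or zero-variance) input maps to 0.
    """
    f = np.asarray(forces, dtype=float)
    if f.size == 0:
        raise ValueError("no rupture forces given")
    if np.any(f <= 0):
        raise ValueError("rupture forces must be positive")
    root = np.sqrt(f)
    mean = float(np.mean(root))
    sd = float(np.std(root))
    if sd == 0.0:
        sd = 1.0
    tr = ForceTransform(mean=mean, sd=sd)
    return tr.forward(f), tr


def fit_pathway_gmm(
    forces,
    candidate_components=(1, 2, 3, 4),
    n_init: int = 10,
    seed: int | None = 0,
    min_records: int = 30,
) -> GMMResult:
    """Fit 1-D Gaussian mixtures to transformed rupture forces, select by BIC.

    Components have unequal variances; each candidate count is fitted with
    ``n_init`` restarts and a fixed seed, so the result is deterministic.
    Non-convergence of the selected candidate is reported on the result.
    """
    f = np.asarray(forces, dtype=float)
    if f.size < min_records:
        raise ValueError(
            f"GMM fitting needs >= {min_records} records, got {f.size}"
        )
    z, tr = preprocess_forces(f)
    X = z[:, None]
    scores: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for n in candidate_components:
        gm = GaussianMixture(
            n_components=n,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            max_iter=500,
        )
        gm.fit(X)
        scores[n] = float(gm.bic(X))
        fits[n] = gm
    best_n = min(scores, key=scores.get)
    gm = fits[best_n]
    return GMMResult(
        n_components=best_n,
        weights=gm.weights_.copy(),
        means=gm.means_.ravel().copy(),
        variances=gm.covariances_.reshape(best_n).copy(),
        responsibilities=gm.predict_proba(X),
        transform=tr,
        scores=scores,
        converged=bool(gm.converged_),
    )


def _bhattacharyya(mu1, var1, mu2, var2) -> float:
    """Overlap coefficient of two univariate Gaussians (1 = identical)."""
    vsum = var1 + var2
    dist = 0.25 * (mu1 - mu2) ** 2 / vsum + 0.5 * math.log(
        vsum / (2.0 * math.sqrt(var1 * var2))
    )
    return math.exp(-dist)


def reclassify_fourth_component(
    result: GMMResult, overlap_threshold: float = 0.1
) -> GMMResult:
    """Fold a fourth mixture component back into its overlapping parents.

    A four-component fit is attributed to minor experimental variance: the
    smallest-weight component that overlaps another (Bhattacharyya
    coefficient above ``overlap_threshold``) is removed and its records are
    reassigned by maximum responsibility among the remaining components.
    With no overlapping parent the removal still happens but the result is
    flagged.  Fits with <= 3 components pass through unchanged.
    """
    if result.n_components <= 3:
        return result
    order = np.argsort(result.weights)
    flag = ""
    drop = None
    for cand in order:  # smallest weight first
        overlaps = [
            _bhattacharyya(
                result.means[cand], result.variances[cand],
                result.means[j], result.variances[j],
            )
            for j in range(result.n_components)
            if j != cand
        ]
        if max(overlaps) > overlap_threshold:
            drop = int(cand)
            break
    if drop is None:
        drop = int(order[0])
        flag = "no_overlapping_parent"

    keep = [j for j in range(result.n_components) if j != drop]
    resp = result.responsibilities[:, keep]
    row_sums = resp.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    resp = resp / row_sums
    return GMMResult(
        n_components=3,
        weights=resp.mean(axis=0),
        means=result.means[keep],
        variances=result.variances[keep],
        responsibilities=resp,
        transform=result.transform,
        scores=result.scores,
        converged=result.converged,
        reclassified=True,
        reclassification_flag=flag,
    )


def assign_pathways(result: GMMResult) -> pd.DataFrame:
    """Per-record pathway labels, ordered P0 < P1 < ... by component mean.

    Assignment is by maximum responsibility; exact ties break toward the
    lower-mean component (conservative toward P0).
    """
    order = np.argsort(result.means)
    resp = result.responsibilities[:, order]
    # argmax returns the first maximal index; columns are mean-ascending,
    # so ties already resolve toward the lower-mean pathway
    labels = np.argmax(resp, axis=1)
    return pd.DataFrame(
        {
            "record": np.arange(resp.shape[0]),
            "pathway": [PATHWAY_LABELS[i] for i in labels],
            "posterior": resp[np.arange(resp.shape[0]), labels],
        }
    )


def pathway_proportions(
    assignments: pd.DataFrame,
    pathway_column: str = "pathway",
    speed_column: str = "pulling_speed_nm_s",
    experiment_column: str = "experiment_id",
) -> pd.DataFrame:
    """Mean pathway proportions ± SEM per pulling speed, across experiments.

    Proportions are computed per (experiment, speed) — summing to 1 — then
    averaged over experiments.  With a single experiment the SEM is
    undefined and reported as NaN.
    """
    labels = sorted(assignments[pathway_column].unique())
    rows = []
    per_exp = (
        assignments.groupby([speed_column, experiment_column])[pathway_column]
        .value_counts(normalize=True)
        .rename("proportion")
        .reset_index()
    )
    for speed, grp in per_exp.groupby(speed_column):
        wide = grp.pivot_table(
            index=experiment_column, columns=pathway_column,
            values="proportion", fill_value=0.0,
        )
        for pw in labels:
            vals = wide[pw].to_numpy() if pw in wide else np.zeros(len(wide))
            sem = (
                float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
                if len(vals) > 1
                else math.nan
            )
            rows.append(
                {
                    speed_column: speed,
                    "pathway": pw,
                    "proportion": float(np.mean(vals)),
                    "sem": sem,
                    "n_experiments": len(vals),
                }
            )
    return pd.DataFrame(rows)
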