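"""Transition-law regressions: what drives the transition probabilities?

Each cell T_ij of a subject's transition matrix is regressed on candidate
drivers of the transition i -> j:

* ``distance``  — the Euclidean distance d_ij between the state centroids
  (attractor-like dynamics: transitions fall off with distance),
* ``freq_j``    — the relative frequency f_j of the destination state
  (fully ergodic dynamics: any state reachable regardless of distance),
* ``composite`` — the product f_i * f_j (random-walk-like dynamics: both the
  origin and the destination frequency matter),
* ``full``      — distance and composite frequency together,
  T_ij ~ a * d_ij + b * f_i f_j with standardized coefficients a, b.

All variables are z-scored before ordinary least squares, so coefficients are
standardized ("normalized") betas; for a single regressor the beta equals the
Pearson correlation with the response.  Adjusted R^2 uses
1 - (1 - R^2) (N - 1) / (N - k - 1) with N the number of matrix cells entering
the design.  Matrix cells are treated as independent observations — a
simplification inherited from the modeling tradition this follows; see the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import cdist

from .markov import TransitionMatrix
from .states import ClusterModel


class RegressionError(ValueError):
    pass


MODES = ("distance", "freq_j", "composite", "full")
_MODE_REGRESSORS = {
    "distance": ["x_dist"],
    "freq_j": ["x_freqj"],
    "composite": ["x_comp"],
    "full": ["x_dist", "x_comp"],
}


def centroid_distances(model: ClusterModel | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between state centroids (zero diagonal)."""
    c = model.centroids if isinstance(model, ClusterModel) else np.asarray(model, float)
    return cdist(c, c)


@dataclass
class DesignTable:
    """One row per retained transition-matrix cell (i, j)."""

    frame: pd.DataFrame  # columns: i, j, y, x_dist, x_freqj, x_comp

    @property
    def n_cells(self) -> int:
        return len(self.frame)


def build_design(
    T: TransitionMatrix,
    distances: np.ndarray,
    frequencies: np.ndarray,
    include_diagonal: bool = True,
) -> DesignTable:
    """Assemble the regression table over cells with both states active.

    A state is active when its matrix row is defined (it occurred as a
    transition source).  ``distances`` and ``frequencies`` are indexed on the
    full 1..k space; self-transition cells are kept by default.
    """
    distances = np.asarray(distances, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    if distances.shape != (T.k, T.k) or frequencies.shape != (T.k,):
        raise RegressionError("distances/frequencies not on the matrix state space")
    active = np.nonzero(T.defined_rows)[0]
    p = T.probs
    rows = []
    for i in active:
        for j in active:
            if not include_diagonal and i == j:
                continue
            rows.append(
                {
                    "i": i + 1,
                    "j": j + 1,
                    "y": p[i, j],
                    "x_dist": distances[i, j],
                    "x_freqj": frequencies[j],
                    "x_comp": frequencies[i] * frequencies[j],
                }
            )
    if len(rows) < 5:
        raise RegressionError("fewer than 5 design cells; matrix too sparse")
    return DesignTable(pd.DataFrame(rows))


@dataclass
class RegressionResult:
    """Standardized-coefficient OLS fit of one transition-law mode.

    ``beta_dist`` is the standardized coefficient of centroid distance (None
    when distance is not in the mode); ``beta_comp`` that of the frequency
    regressor (f_j for mode ``freq_j``, f_i*f_j otherwise).  ``beta_ratio`` =
    |beta_comp| / |beta_dist| for the full mode, NaN when undefined.
    """

    mode: str
    beta_dist: float | None
    beta_comp: float | None
    r: float
    r2: float
    adj_r2: float
    p_model: float
    n_cells: int
    k_predictors: int
    beta_ratio: float = float("nan")
    coef_pvalues: dict | None = None
    subject_id: str = ""
    role: str = ""

    def __post_init__(self) -> None:
        if self.mode == "full" and self.beta_dist is not None and self.beta_comp is not None:
            self.beta_ratio = (
                abs(self.beta_comp) / abs(self.beta_dist)
                if self.beta_dist != 0
                else float("nan")
            )


def adjusted_r2(r2: float, n: int, k: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise RegressionError("zero variance in a regression variable")
    return (v - v.mean()) / sd


def fit_model(
    design: DesignTable, mode: str = "full", subject_id: str = "", role: str = ""
) -> RegressionResult:
    """OLS on z-scored response and regressors for one transition-law mode."""
    if mode not in MODES:
        raise RegressionError(f"unknown mode {mode!r}; expected one of {MODES}")
    cols = _MODE_REGRESSORS[mode]
    y = _zscore(design.frame["y"].to_numpy(dtype=float))
    X = np.column_stack([_zscore(design.frame[c].to_numpy(dtype=float)) for c in cols])
    if X.shape[1] == 2:
        rho = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        if abs(rho) > 1 - 1e-12:
            raise RegressionError("collinear regressors; full model unidentifiable")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    betas = dict(zip(cols, fit.params[1:]))
    r2 = float(fit.rsquared)
    result = RegressionResult(
        mode=mode,
        beta_dist=float(betas["x_dist"]) if "x_dist" in betas else None,
        beta_comp=float(betas.get("x_comp", betas.get("x_freqj")))
        if ("x_comp" in betas or "x_freqj" in betas)
        else None,
        r=float(np.sqrt(max(r2, 0.0))),
        r2=r2,
        adj_r2=adjusted_r2(r2, design.n_cells, len(cols)),
        p_model=float(fit.f_pvalue),
        n_cells=design.n_cells,
        k_predictors=len(cols),
        coef_pvalues=dict(zip(cols, (float(p) for p in fit.pvalues[1:]))),
        subject_id=subject_id,
        role=role,
    )
    return result


def compare_modes(
    T: TransitionMatrix,
    distances: np.ndarray,
    frequencies: np.ndarray,
    include_diagonal: bool = True,
    subject_id: str = "",
    role: str = "",
) -> list[RegressionResult]:
    """Fit all four transition-law modes; results ranked by adjusted R^2."""
    design = build_design(T, distances, frequencies, include_diagonal)
    results = [fit_model(design, mode, subject_id, role) for mode in MODES]
    return sorted(results, key=lambda r: r.adj_r2, reverse=True)


@dataclass
class CohortSummary:
    """Per-role arithmetic means of the fitted full-model fields."""

    by_role: dict  # role -> dict of field means
    distance_dependence_ratio: float  # |mean beta_dist(role A)| / |mean beta_dist(role B)|
    ratio_roles: tuple[str, str]


def cohort_summary(
    results_by_role: dict[str, Sequence[RegressionResult]],
    ratio_roles: tuple[str, str] = ("patient", "therapist"),
) -> CohortSummary:
    """Signed means of betas and fit statistics per role, plus the cross-role
    ratio of absolute mean distance coefficients."""
    by_role = {}
    for role, results in results_by_role.items():
        if not results:
            raise RegressionError(f"no results for role {role!r}")
        fields = {}
        for name in ("beta_dist", "beta_comp", "r", "r2", "adj_r2", "beta_ratio"):
            vals = [getattr(res, name) for res in results]
            vals = [v for v in vals if v is not None and np.isfinite(v)]
            fields[name] = float(np.mean(vals)) if vals else float("nan")
        fields["n_subjects"] = len(results)
        by_role[role] = fields
    a, b = ratio_roles
    ratio = float("nan")
    if a in by_role and b in by_role and by_role[b]["beta_dist"] != 0:
        ratio = abs(by_role[a]["beta_dist"]) / abs(by_role[b]["beta_dist"])
    return CohortSummary(by_role=by_role, distance_dependence_ratio=ratio, ratio_roles=ratio_roles)


def results_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Per-subject result table (one row per fitted model)."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "role": r.role,
                "mode": r.mode,
                "beta_dist": r.beta_dist,
                "beta_comp": r.beta_comp,
                "r": r.r,
                "r2": r.r2,
                "adj_r2": r.adj_r2,
                "p_model": r.p_model,
                "beta_ratio": r.beta_ratio,
                "n_cells": r.n_cells,
            }
            for r in results
        ]
    )
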