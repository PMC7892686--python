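"""PCA ranking of differential compounds via squared cosines.

Principal components are extracted from the correlation matrix of the
differential-compound abundances (compounds are the variables, biological
samples the observations).  For correlation-based PCA the squared cosine of
a variable on a factor equals its squared loading (the squared correlation
between variable and factor), so each compound's squared cosines sum to one
over the full factor set and the compound can be attributed to the factor it
cosines most strongly with — separating, in this design, time-driven
compounds from genotype-driven ones.  The Kaiser–Meyer–Olkin (KMO) statistic
quantifies whether the correlation structure is adequate for this kind of
factor attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAReport",
    "FactorAssignment",
    "run_pca",
    "assign_factors",
    "kmo",
    "kmo_from_correlation",
    "heatmap_matrix",
]


@dataclass
class PCAReport:
    """Eigenstructure of the compound correlation matrix."""

    eigenvalues: np.ndarray  # descending, >= 0
    variance_explained: np.ndarray  # percent per factor, sums to 100
    scores: pd.DataFrame  # samples x factors
    loadings: pd.DataFrame  # compounds x factors (variable-factor correlations)
    squared_cosines: pd.DataFrame  # compounds x factors, rows sum to 1
    kmo: float


@dataclass
class FactorAssignment:
    """Argmax-cosine attribution of each compound to a factor."""

    assigned: pd.Series  # compound -> factor label (F1-based)
    margin: pd.Series  # top cosine minus runner-up cosine
    ties: list[str]


def _correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(ddof=1)
    zero = list(sd.index[~(sd > 0)])
    if zero:
        raise ValueError(f"zero-variance compound(s): {zero}")
    return matrix.corr()


def run_pca(matrix: pd.DataFrame, compute_kmo: bool = True) -> PCAReport:
    """Correlation-matrix PCA of a samples x compounds abundance table.

    Compounds are standardized to zero mean and unit variance, so the
    decomposition is scale-free (squared cosines match what a correlation-
    based factor report prints).  More compounds than samples is allowed;
    eigenvalues beyond the data rank are zero.  Factor signs are oriented so
    each factor's largest-magnitude loading is positive.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 compounds")
    if matrix.isna().any().any():
        raise ValueError("missing values must be imputed before PCA")
    corr = _correlation_matrix(matrix)
    evals, evecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    # orient: largest-|loading| entry of each factor positive
    for k in range(evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    factors = [f"F{k + 1}" for k in range(len(evals))]
    loadings = pd.DataFrame(
        evecs * np.sqrt(evals), index=matrix.columns, columns=factors
    )
    z = (matrix - matrix.mean()) / matrix.std(ddof=1)
    scores = pd.DataFrame(z.to_numpy() @ evecs, index=matrix.index, columns=factors)
    cos2 = loadings**2
    return PCAReport(
        eigenvalues=evals,
        variance_explained=evals / evals.sum() * 100.0,
        scores=scores,
        loadings=loadings,
        squared_cosines=cos2,
        kmo=kmo(matrix) if compute_kmo else float("nan"),
    )


def assign_factors(
    cos2: pd.DataFrame | PCAReport, n_factors: int = 2
) -> FactorAssignment:
    """Assign each compound to its argmax squared-cosine factor.

    ``cos2`` may be a PCA report or a compounds x factors squared-cosine
    table (e.g. the printed two-factor table of a published analysis).
    Ties go to the lower factor index and are flagged.
    """
    if isinstance(cos2, PCAReport):
        cos2 = cos2.squared_cosines
    if n_factors > cos2.shape[1]:
        raise ValueError(
            f"requested {n_factors} factors but only {cos2.shape[1]} available"
        )
    sub = cos2.iloc[:, :n_factors]
    assigned = sub.idxmax(axis=1)  # idxmax takes the first (lowest) on ties
    top = sub.max(axis=1)
    if n_factors == 1:
        margin = top
        ties: list[str] = []
    else:
        runner = sub.apply(lambda r: r.nlargest(2).iloc[-1], axis=1)
        margin = top - runner
        ties = list(sub.index[margin == 0])
    return FactorAssignment(assigned, margin, ties)


def kmo(matrix: pd.DataFrame) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy of a data matrix.

    ``sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over off-diagonal elements,
    where ``q`` are the anti-image partial correlations obtained from the
    inverse correlation matrix.
    """
    return kmo_from_correlation(_correlation_matrix(matrix).to_numpy())


def kmo_from_correlation(corr: np.ndarray) -> float:
    """KMO computed directly from a correlation matrix.

    A singular correlation matrix deterministically falls back to the
    Moore–Penrose pseudo-inverse.
    """
    corr = np.asarray(corr, dtype=float)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(corr)
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(corr.shape[0], dtype=bool)
    r2 = (corr[off] ** 2).sum()
    q2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def heatmap_matrix(
    matrix: pd.DataFrame, assignment: FactorAssignment, cos2: pd.DataFrame
) -> pd.DataFrame:
    """Compounds x samples matrix ordered for heatmap display.

    Rows (compounds) are grouped by assigned factor and, within a factor,
    sorted by descending squared cosine; columns follow the design order
    (genotype, time, replicate) when the sample index carries those keys,
    otherwise the existing order.  Serialize with ``DataFrame.to_csv``.
    """
    if matrix.shape[1] == 0:
        raise ValueError("empty differential set")
    top = cos2.max(axis=1)
    order = sorted(
        matrix.columns, key=lambda cpd: (assignment.assigned[cpd], -top[cpd])
    )
    out = matrix[order].T
    if isinstance(matrix.index, pd.MultiIndex):
        out = out.sort_index(axis=1)
    return out
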