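"""Ordination (PCoA, correspondence analysis) and permutation statistics.

PCoA follows the classical-scaling construction: Gower double-centering of the
squared distance matrix, eigendecomposition, coordinates scaled by the square
root of the positive eigenvalues.  Correspondence analysis is the SVD of the
chi-square standardized residuals of a non-negative table.  PERMANOVA and the
environmental-vector fit use label/value permutation nulls with the
``(exceedances + 1) / (permutations + 1)`` convention, so p-values are never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Ordination",
    "PermTestResult",
    "EnvFit",
    "pcoa",
    "correspondence_analysis",
    "permanova",
    "fit_env_vectors",
    "permutational_association",
]

DEFAULT_PERMUTATIONS = 999


@dataclass
class Ordination:
    """Sample coordinates plus eigenvalues from PCoA or CA."""

    coordinates: pd.DataFrame            # samples x axes
    eigenvalues: np.ndarray              # per retained axis, non-increasing
    proportion_explained: np.ndarray
    method: str                          # "pcoa" | "ca"
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    feature_coordinates: pd.DataFrame | None = None   # CA column coords
    source_distance: DistanceMatrix | None = None     # PCoA input, for dispatch

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        pe = np.asarray(self.proportion_explained, dtype=float)
        if pe.sum() > 1 + 1e-9:
            raise ValueError("proportion_explained sums above 1")
        if self.coordinates.shape[1] > max(self.coordinates.shape[0] - 1, 0):
            raise ValueError("more axes than samples - 1")


@dataclass
class PermTestResult:
    statistic: float
    permutations: int
    p_value: float
    name: str = ""


@dataclass
class EnvFit:
    """Least-squares fit of one variable onto ordination axes."""

    variable: str
    direction: np.ndarray     # unit-norm coefficient direction over the axes
    r_squared: float
    p_value: float
    q_value: float = np.nan


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each axis positive (reproducible
    across linear-algebra backends)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pcoa(d: DistanceMatrix | pd.DataFrame | np.ndarray, ids=None) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Negative eigenvalues (non-Euclidean input) are reported in
    ``negative_eigenvalues`` and their axes dropped; ``proportion_explained``
    uses the sum of positive eigenvalues as denominator.
    """
    if isinstance(d, DistanceMatrix):
        D, ids = d.data, list(d.ids)
        source = d
    else:
        D = np.asarray(pd.DataFrame(d), dtype=float)
        if ids is None:
            ids = list(pd.DataFrame(d).index) if isinstance(d, pd.DataFrame) else list(range(D.shape[0]))
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be square symmetric")
        if not np.all(np.isfinite(D)):
            raise ValueError("distance matrix contains non-finite entries")
        source = DistanceMatrix(D, ids=[str(i) for i in ids])
    n = D.shape[0]
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-10
    pos = evals > tol
    neg = evals < -tol
    lam = evals[pos]
    vecs = _fix_signs(evecs[:, pos])
    coords = vecs * np.sqrt(lam)
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    denom = lam.sum() if lam.size else 1.0
    return Ordination(
        coordinates=pd.DataFrame(coords, index=[str(i) for i in ids], columns=axes),
        eigenvalues=lam,
        proportion_explained=lam / denom,
        method="pcoa",
        negative_eigenvalues=np.abs(evals[neg]),
        source_distance=source,
    )


def correspondence_analysis(f: pd.DataFrame | np.ndarray) -> Ordination:
    """Correspondence analysis of a non-negative table (e.g. samples x foods).

    Row principal coordinates are returned in ``coordinates``; column principal
    coordinates in ``feature_coordinates``.  Total inertia (sum of principal
    inertias) equals the independence chi-square statistic divided by the grand
    total.
    """
    F = pd.DataFrame(f).astype(float)
    if (F.to_numpy() < 0).any():
        raise ValueError("correspondence analysis requires non-negative entries")
    zero_rows = F.index[F.sum(axis=1) == 0]
    zero_cols = F.columns[F.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping {len(zero_rows)} all-zero rows / {len(zero_cols)} columns",
            UserWarning,
            stacklevel=2,
        )
        F = F.drop(index=zero_rows, columns=zero_cols)
    total = F.to_numpy().sum()
    if total <= 0:
        raise ValueError("grand total must be positive")
    P = F.to_numpy() / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > max(sv[0], 1.0) * 1e-12 if sv.size else np.array([], bool)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    # sign convention: largest-magnitude row loading positive, mirrored on V
    signs = np.ones(sv.size)
    for j in range(U.shape[1]):
        k = np.argmax(np.abs(U[:, j]))
        signs[j] = 1.0 if U[k, j] >= 0 else -1.0
    U = U * signs
    V = Vt.T * signs
    row_coords = (U * sv) / np.sqrt(r)[:, None]
    col_coords = (V * sv) / np.sqrt(c)[:, None]
    inertias = sv ** 2
    axes = [f"CA{i + 1}" for i in range(row_coords.shape[1])]
    denom = inertias.sum() if inertias.size else 1.0
    return Ordination(
        coordinates=pd.DataFrame(row_coords, index=[str(i) for i in F.index], columns=axes),
        eigenvalues=inertias,
        proportion_explained=inertias / denom,
        method="ca",
        feature_coordinates=pd.DataFrame(col_coords, index=[str(i) for i in F.columns], columns=axes),
    )


def _group_ss(D2: np.ndarray, labels: np.ndarray) -> float:
    """Within-group sum of squares from a squared-distance matrix."""
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss += D2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss


def pseudo_f(D: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F for a distance matrix and group labels."""
    n = D.shape[0]
    groups = np.unique(labels)
    g = groups.size
    D2 = D ** 2
    ss_total = D2.sum() / (2 * n)
    ss_within = _group_ss(D2, labels)
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    d: DistanceMatrix | np.ndarray,
    labels,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
) -> PermTestResult:
    """Permutational MANOVA (pseudo-F ratio, label-permutation null)."""
    D = d.data if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    labels = np.asarray(pd.Series(labels))
    if labels.shape[0] != D.shape[0]:
        raise ValueError("labels must align with the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValueError(f"group(s) of size 1 not allowed: {small}")
    rng = np.random.default_rng(seed)
    f_obs = pseudo_f(D, labels)
    D2 = D ** 2
    n = D.shape[0]
    g = groups.size
    ss_total = D2.sum() / (2 * n)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        ssw = _group_ss(D2, perm)
        f_perm = ((ss_total - ssw) / (g - 1)) / (ssw / (n - g))
        if f_perm >= f_obs:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return PermTestResult(statistic=float(f_obs), permutations=permutations, p_value=p, name="pseudo-F")


def fit_env_vectors(
    ordination: Ordination,
    variables: pd.DataFrame,
    axes: tuple = (0, 1),
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    bh_correct: bool = True,
) -> list[EnvFit]:
    """Fit external continuous variables onto ordination axes (vegan envfit).

    Each variable is regressed (least squares, centered) on the chosen axes'
    coordinates; r-squared is the explained variance fraction, direction the
    unit-norm coefficient vector, and significance a permutation test of
    r-squared.  With two or more variables, Benjamini-Hochberg q-values are
    attached.
    """
    X = ordination.coordinates.iloc[:, list(axes)].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant ordination axis")
    Xc = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(Xc)
    rng = np.random.default_rng(seed)
    results: list[EnvFit] = []
    variables = variables.loc[ordination.coordinates.index]
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError(f"variable {name!r} has non-finite values")
        yc = y - y.mean()
        tot = yc @ yc
        if tot == 0:
            warnings.warn(f"variable {name!r} is constant; r2=0, p=1", UserWarning, stacklevel=2)
            results.append(EnvFit(name, np.zeros(len(axes)), 0.0, 1.0))
            continue
        coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        proj = Q.T @ yc
        r2 = float(proj @ proj / tot)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else coef
        exceed = 0
        for _ in range(permutations):
            yp = rng.permutation(yc)
            pj = Q.T @ yp
            if pj @ pj / tot >= r2 - 1e-15:
                exceed += 1
        p = (exceed + 1) / (permutations + 1)
        results.append(EnvFit(name, direction, r2, p))
    if bh_correct and len(results) >= 2:
        ps = [r.p_value for r in results]
        q = multipletests(ps, method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def permutational_association(
    ordination: Ordination,
    covariate,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    n_axes: int = 3,
) -> PermTestResult:
    """Test a per-sample covariate against ordination structure.

    Continuous covariates dispatch to :func:`fit_env_vectors` on the leading
    axes (permutational correlation test); categorical covariates dispatch to
    :func:`permanova` on the ordination's source distance matrix.
    """
    cov = pd.Series(covariate)
    cov = cov.loc[ordination.coordinates.index] if set(ordination.coordinates.index) <= set(cov.index) else cov
    if pd.api.types.is_numeric_dtype(cov):
        axes = tuple(range(min(n_axes, ordination.coordinates.shape[1])))
        fit = fit_env_vectors(
            ordination, cov.to_frame("covariate"), axes=axes,
            permutations=permutations, seed=seed, bh_correct=False,
        )[0]
        return PermTestResult(fit.r_squared, permutations, fit.p_value, name="envfit-r2")
    if ordination.source_distance is None:
        raise ValueError("categorical dispatch requires the ordination's source distance matrix")
    return permanova(ordination.source_distance, cov.to_numpy(), permutations=permutations, seed=seed)
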