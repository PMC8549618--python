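"""Constrained ordination for multivariate methylation and genotype matrices.

Implements the distance / principal-coordinates / redundancy-analysis stack used
throughout the package:

* Euclidean distance matrices between samples,
* principal coordinates analysis (classical metric scaling, Gower centering),
* axis retention by a minimum relative-eigenvalue rule,
* (partial) redundancy analysis on retained axes -- the db-RDA construction --
  with Ezekiel-adjusted R² and a permutation pseudo-F test,
* greedy forward selection of explanatory terms,
* adjusted-R² variance partitioning between two explanatory sets.

Design matrices for categorical metadata are centered treatment indicators;
interactions are elementwise products of centered indicators.  Because all
encodings are centered, the intercept is handled implicitly by centering the
response.

The permutation scheme for partial models permutes residuals of the reduced
model (the standard choice for constrained ordination).  Permutation p-values
use the add-one rule p = (1 + #{F* >= F}) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.linalg import eigh, qr


__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "RDAResult",
    "VariancePartition",
    "euclidean_distance",
    "pcoa",
    "retain_axes_min_variance",
    "design_matrix",
    "rda",
    "permutation_test",
    "forward_select",
    "partial_rda",
    "variance_partition",
    "adjusted_r2",
    "dbrda",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) > 1e-8):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PCoAResult:
    """Classical-scaling result: eigenvalues (descending, all of them) and
    coordinates on the positive axes, scaled by sqrt(eigenvalue)."""

    eigenvalues: np.ndarray
    coordinates: np.ndarray
    relative_eigenvalues: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class RDAResult:
    r2: float
    adj_r2: float
    f_statistic: float
    permutation_p: float | None
    selected_terms: list[str]
    conditioned_terms: list[str]
    n_samples: int
    rank_x: int
    n_perm: int | None = None


@dataclass
class VariancePartition:
    """Adjusted-R² partition of Y between two explanatory sets.

    ``frac_x1_pure`` is adjR²(X1+X2) − adjR²(X2) (the testable pure fraction),
    ``frac_shared`` the non-testable overlap, ``frac_residual`` what neither
    set explains.  Adjusted fractions can be slightly negative.
    """

    frac_x1_pure: float
    frac_x2_pure: float
    frac_shared: float
    frac_residual: float
    adj_r2_x1: float
    adj_r2_x2: float
    adj_r2_full: float


# ---------------------------------------------------------------------------
# distances and PCoA


def euclidean_distance(matrix: np.ndarray, labels: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Euclidean distances between rows (samples)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    if np.isnan(m).any():
        raise ValueError(
            "feature matrix contains missing cells; apply the complete-case "
            "windowing rule (or impute) before computing distances"
        )
    d = squareform(pdist(m, metric="euclidean"))
    if labels is None:
        labels = [str(i) for i in range(m.shape[0])]
    return DistanceMatrix(labels=list(labels), values=d)


def pcoa(d: DistanceMatrix, eig_tol: float = 1e-10) -> PCoAResult:
    """Principal coordinates analysis via Gower double-centering.

    B = -0.5 * J D^2 J with J = I - 11'/n is eigendecomposed; axes with
    eigenvalue <= ``eig_tol`` x the largest eigenvalue are discarded (negative
    eigenvalues are dropped without correction -- Euclidean input distances
    guarantee non-negativity up to rounding).  Coordinates are eigenvectors
    scaled by sqrt(eigenvalue).
    """
    dm = d.values
    n = dm.shape[0]
    a = -0.5 * dm**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    evals, evecs = eigh(b)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals.size == 0 or evals[0] <= eig_tol:
        warnings.warn("all-zero distance matrix: no positive principal coordinates")
        return PCoAResult(
            eigenvalues=evals,
            coordinates=np.zeros((n, 0)),
            relative_eigenvalues=np.zeros(0),
            labels=list(d.labels),
        )
    keep = evals > eig_tol * evals[0]
    lam = evals[keep]
    coords = evecs[:, keep] * np.sqrt(lam)
    rel = lam / lam.sum()
    return PCoAResult(
        eigenvalues=evals, coordinates=coords, relative_eigenvalues=rel, labels=list(d.labels)
    )


def retain_axes_min_variance(p: PCoAResult, threshold: float = 0.03) -> np.ndarray:
    """Keep principal-coordinate axes representing at least ``threshold`` of
    the variation (inclusive comparison)."""
    if p.n_axes == 0:
        raise ValueError("no positive axes to retain")
    keep = p.relative_eigenvalues >= threshold
    if not keep.any():
        raise ValueError(
            f"no axis reaches the {threshold:.0%} variance threshold; lower the threshold"
        )
    return p.coordinates[:, keep]


# ---------------------------------------------------------------------------
# design matrices


def _centered_indicators(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        raise ValueError(f"factor has a single level: {levels}")
    cols, names = [], []
    for lev in levels[1:]:  # treatment coding, first level as reference
        ind = (values == lev).to_numpy(dtype=float)
        cols.append(ind - ind.mean())
        names.append(str(lev))
    return np.column_stack(cols), names


def design_matrix(
    metadata: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Centered indicator encoding for categorical terms.

    ``terms`` entries are metadata column names or ``a:b`` interactions,
    encoded as elementwise products of the centered main-effect indicators.
    Returns (matrix, column names); no intercept column (everything centered).
    """
    blocks, names = [], []
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            mats = []
            for p in parts:
                m, _ = _centered_indicators(metadata[p])
                mats.append(m)
            inter = mats[0]
            for m in mats[1:]:
                cols = []
                for i in range(inter.shape[1]):
                    for j in range(m.shape[1]):
                        cols.append(inter[:, i] * m[:, j])
                inter = np.column_stack(cols)
            blocks.append(inter)
            names.extend([term] * inter.shape[1])
        else:
            m, levs = _centered_indicators(metadata[term])
            blocks.append(m)
            names.extend([f"{term}[{lv}]" for lv in levs])
    return np.column_stack(blocks), names


# ---------------------------------------------------------------------------
# RDA core


def _center(y: np.ndarray) -> np.ndarray:
    return y - y.mean(axis=0, keepdims=True)


def _orth_basis(x: np.ndarray, tol: float = 1e-9, scale: float | None = None) -> np.ndarray:
    """Orthonormal basis of the column space of ``x`` (aliased columns dropped).

    ``scale`` sets the magnitude against which near-zero columns are judged;
    callers residualizing X on covariates pass the pre-residualization scale
    so a fully aliased X yields an empty basis.
    """
    if x.size == 0:
        return np.zeros((x.shape[0], 0))
    q, r, _ = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0:
        return np.zeros((x.shape[0], 0))
    ref = max(diag[0], scale if scale is not None else 0.0)
    rank = int((diag > tol * ref).sum()) if ref > 0 else 0
    if rank < x.shape[1]:
        warnings.warn(f"rank-deficient design: dropped {x.shape[1] - rank} aliased column(s)")
    return q[:, :rank]


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError("too few samples for the Ezekiel adjustment")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda(y: np.ndarray, x: np.ndarray, term_names: list[str] | None = None) -> RDAResult:
    """Redundancy analysis of response matrix ``y`` on design ``x``.

    R² is the fraction of total (centered) sum of squares captured by the
    least-squares projection of Y onto the column space of X; the adjustment is
    Ezekiel's with p = rank(X).
    """
    y = _center(np.asarray(y, dtype=float))
    x = _center(np.asarray(x, dtype=float))
    n = y.shape[0]
    qx = _orth_basis(x)
    p = qx.shape[1]
    if n <= p + 1:
        raise ValueError("need n_samples > rank(X) + 1")
    ss_tot = float((y**2).sum())
    if ss_tot == 0:
        raise ValueError("response matrix has zero variance")
    ss_x = float(((qx.T @ y) ** 2).sum())
    r2 = ss_x / ss_tot
    f = (ss_x / p) / ((ss_tot - ss_x) / (n - p - 1)) if ss_tot > ss_x else np.inf
    return RDAResult(
        r2=r2,
        adj_r2=adjusted_r2(r2, n, p),
        f_statistic=float(f),
        permutation_p=None,
        selected_terms=list(term_names or []),
        conditioned_terms=[],
        n_samples=n,
        rank_x=p,
    )


def permutation_test(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation pseudo-F test of X (given covariates Z) on multivariate Y.

    F = (SS_X|Z / p) / (SS_resid / (n - p - q - 1)).  With Z present the
    residuals of the reduced model (Y | Z) are row-permuted; the observed and
    permuted statistics share the identity F = f(||Qx'E||², ||Qz'E||²) because
    X is residualized on Z.  Returns (p_value, F_observed).

    The permutation loop is vectorized: all permutations are applied to the
    orthonormal bases (equivalent in distribution to permuting rows of E).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = _center(np.asarray(y, dtype=float))
    x = _center(np.asarray(x, dtype=float))
    n = y.shape[0]
    if z is not None and np.asarray(z).size > 0:
        zc = _center(np.asarray(z, dtype=float))
        qz = _orth_basis(zc)
        e = y - qz @ (qz.T @ y)
        xr = x - qz @ (qz.T @ x)
    else:
        qz = np.zeros((n, 0))
        e = y
        xr = x
    qx = _orth_basis(xr, scale=float(np.linalg.norm(x)))
    p, q = qx.shape[1], qz.shape[1]
    if p == 0:
        raise ValueError("X is fully aliased with Z: zero partial effect")
    df_res = n - p - q - 1
    if df_res <= 0:
        raise ValueError("too few samples for the permutation test")

    ss_e = float((e**2).sum())

    def f_stat(ss_x: np.ndarray, ss_z_regain: np.ndarray) -> np.ndarray:
        ss_res = ss_e - ss_z_regain - ss_x
        return (ss_x / p) / (ss_res / df_res)

    ss_x_obs = float(((qx.T @ e) ** 2).sum())
    f_obs = float(f_stat(np.array(ss_x_obs), np.array(0.0)))

    # permute the basis columns instead of E's rows (same null distribution)
    qall = np.hstack([qz, qx])  # n x (q + p)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    qperm = qall[perms]  # n_perm x n x (q+p)
    proj = np.matmul(qperm.transpose(0, 2, 1), e)  # n_perm x (q+p) x m
    sq = (proj**2).sum(axis=2)
    ss_z_perm = sq[:, :q].sum(axis=1)
    ss_x_perm = sq[:, q:].sum(axis=1)
    f_perm = f_stat(ss_x_perm, ss_z_perm)
    p_value = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_perm)
    return p_value, f_obs


def partial_rda(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray | None,
    term_names: list[str] | None = None,
    conditioned_names: list[str] | None = None,
    n_perm: int | None = 999,
    seed: int | np.random.Generator | None = None,
) -> RDAResult:
    """Partial RDA of Y on X controlling for Z.

    The reported ``r2`` is the semipartial fraction SS_X|Z / SS_total(Y);
    ``adj_r2`` follows the adjusted partitioning convention
    adjR²(X+Z) − adjR²(Z).  With empty Z this reduces exactly to :func:`rda`.
    """
    y = _center(np.asarray(y, dtype=float))
    x = _center(np.asarray(x, dtype=float))
    n = y.shape[0]
    if z is None or np.asarray(z).size == 0:
        res = rda(y, x, term_names)
        if n_perm:
            res.permutation_p, _ = permutation_test(y, x, None, n_perm=n_perm, seed=seed)
            res.n_perm = n_perm
        return res
    zc = _center(np.asarray(z, dtype=float))
    qz = _orth_basis(zc)
    xr = x - qz @ (qz.T @ x)
    qx = _orth_basis(xr, scale=float(np.linalg.norm(x)))
    p, q = qx.shape[1], qz.shape[1]
    ss_tot = float((y**2).sum())
    if p == 0:
        warnings.warn("covariates span X: zero partial effect")
        return RDAResult(0.0, 0.0, 0.0, 1.0, list(term_names or []),
                         list(conditioned_names or []), n, 0, n_perm)
    e = y - qz @ (qz.T @ y)
    ss_x = float(((qx.T @ e) ** 2).sum())
    ss_z = ss_tot - float((e**2).sum())
    ss_res = ss_tot - ss_z - ss_x
    r2_semi = ss_x / ss_tot
    adj_full = adjusted_r2((ss_z + ss_x) / ss_tot, n, p + q)
    adj_z = adjusted_r2(ss_z / ss_tot, n, q)
    f = (ss_x / p) / (ss_res / (n - p - q - 1))
    pv = None
    if n_perm:
        pv, _ = permutation_test(y, x, z, n_perm=n_perm, seed=seed)
    return RDAResult(
        r2=r2_semi,
        adj_r2=adj_full - adj_z,
        f_statistic=float(f),
        permutation_p=pv,
        selected_terms=list(term_names or []),
        conditioned_terms=list(conditioned_names or []),
        n_samples=n,
        rank_x=p,
        n_perm=n_perm,
    )


def forward_select(
    y: np.ndarray,
    candidates: dict[str, np.ndarray],
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Greedy forward selection of explanatory terms by permutation p-value.

    At each step the candidate with the lowest permutation p-value (ties broken
    by larger pseudo-F) is added if p <= alpha; selection stops otherwise.
    """
    if not candidates:
        raise ValueError("need at least one candidate term")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    selected: list[str] = []
    remaining = dict(candidates)
    while remaining:
        z = (
            np.hstack([candidates[t] for t in selected])
            if selected
            else None
        )
        best = None
        for name, xc in remaining.items():
            pv, f = permutation_test(y, xc, z, n_perm=n_perm, seed=rng)
            if best is None or (pv, -f) < (best[1], -best[2]):
                best = (name, pv, f)
        assert best is not None
        if best[1] <= alpha:
            selected.append(best[0])
            del remaining[best[0]]
        else:
            break
    return selected


def variance_partition(
    y: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> VariancePartition:
    """Partition variance of Y between X1 and X2 via adjusted R² of the three
    models [X1], [X2], [X1+X2]."""
    y = np.asarray(y, dtype=float)
    a1 = rda(y, x1).adj_r2
    a2 = rda(y, x2).adj_r2
    afull = rda(y, np.hstack([np.atleast_2d(x1.T).T, np.atleast_2d(x2.T).T])).adj_r2
    pure1 = afull - a2
    pure2 = afull - a1
    shared = a1 + a2 - afull
    return VariancePartition(
        frac_x1_pure=pure1,
        frac_x2_pure=pure2,
        frac_shared=shared,
        frac_residual=1.0 - afull,
        adj_r2_x1=a1,
        adj_r2_x2=a2,
        adj_r2_full=afull,
    )


# ---------------------------------------------------------------------------
# high-level db-RDA


def dbrda(
    features: np.ndarray,
    metadata: pd.DataFrame,
    terms: list[str],
    conditioned: list[str] | None = None,
    axis_threshold: float = 0.03,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    labels: list[str] | None = None,
) -> RDAResult:
    """Distance-based RDA: Euclidean distance -> PCoA -> retain axes with at
    least ``axis_threshold`` of the variation -> (partial) RDA with a
    permutation test."""
    d = euclidean_distance(features, labels=labels)
    p = pcoa(d)
    yaxes = retain_axes_min_variance(p, threshold=axis_threshold)
    x, _ = design_matrix(metadata, terms)
    z = None
    if conditioned:
        z, _ = design_matrix(metadata, conditioned)
    return partial_rda(
        yaxes, x, z, term_names=terms, conditioned_names=conditioned or [],
        n_perm=n_perm, seed=seed,
    )
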