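"""Exploratory factor extraction, oblique target rotation, fit statistics.

The measurement model is an exploratory five-factor structure with a
theory-driven target rotation: cells outside an indicator's intended domain
are rotated toward zero, intended cells are left free. This reproduces the
point-estimate structure of ESEM-with-target-rotation fitted in SEM
software; standard errors and robust corrections are out of scope, which is
the central methodological simplification of this package.

Extraction methods:

- ``ml``     — normal-theory maximum likelihood, profiled over uniquenesses
               (Lawley's eigenvalue form), optimized with L-BFGS-B.
- ``minres`` — ordinary least squares on off-diagonal residual correlations,
               same profile structure.
- ``pca``    — principal components (eigenvector loadings scaled by the
               square-rooted eigenvalue), for unconstrained-structure runs.

Rotation is gradient projection on the orthogonal or oblique manifold
(statsmodels' GPA core) with the partially specified target criterion
``sum of squared loadings over target-zero cells``; seeded random restarts
guard against local minima.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.multivariate.factor_rotation._gpa_rotation import (
    GPA,
    vgQ_partial_target,
)

logger = logging.getLogger("acqstruct.factor")

HEYWOOD_FLOOR = 0.005


@dataclass
class FactorSolution:
    loadings: pd.DataFrame  # k x m, index indicator labels, columns factor names
    phi: pd.DataFrame  # m x m factor correlations (identity if orthogonal)
    uniquenesses: pd.Series  # length k
    rotation: str  # target-oblique | target-orthogonal | none
    criterion_value: float
    method: str  # ml | minres | pca
    converged: bool = True
    heywood: tuple = ()

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    def implied_correlation(self) -> np.ndarray:
        lam = self.loadings.to_numpy()
        phi = self.phi.to_numpy()
        sigma = lam @ phi @ lam.T
        sigma[np.diag_indices_from(sigma)] += self.uniquenesses.to_numpy()
        return sigma


@dataclass
class FitStats:
    chi_square: float | None
    df: int
    cfi: float | None
    tli: float | None
    rmsea: float | None
    srmr: float | None
    bic: float | None
    n_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


# ---------------------------------------------------------------------------
# correlation input

def correlation_matrix(
    indicators: pd.DataFrame, use: str = "listwise"
) -> tuple[pd.DataFrame, int]:
    """Pearson correlation matrix of indicator columns plus the row count
    entering it. ``use`` is 'listwise' (default) or 'pairwise'; with pairwise
    data n_used is the minimum pairwise count."""
    if indicators.shape[1] < 2:
        raise ValueError("need at least 2 indicators")
    if use == "listwise":
        complete = indicators.dropna()
        n_used = len(complete)
        if n_used < 2:
            raise ValueError("fewer than 2 complete rows")
        sd = complete.std(ddof=1)
        dead = list(sd.index[(sd == 0) | sd.isna()])
        if dead:
            raise ValueError(f"zero-variance indicator(s): {dead}")
        return complete.corr(), n_used
    elif use == "pairwise":
        sd = indicators.std(ddof=1)
        dead = list(sd.index[(sd == 0) | sd.isna()])
        if dead:
            raise ValueError(f"zero-variance indicator(s): {dead}")
        notna = indicators.notna().astype(int).to_numpy()
        n_used = int((notna.T @ notna).min())
        if n_used < 2:
            raise ValueError("fewer than 2 overlapping rows for some pair")
        return indicators.corr(), n_used
    raise ValueError(f"unknown use={use!r}")


# ---------------------------------------------------------------------------
# extraction

def model_degrees_of_freedom(k: int, m: int) -> int:
    """df of the exploratory m-factor model on k indicators:
    k(k+1)/2 free moments minus (k*m loadings + k uniquenesses
    - m(m-1)/2 rotational indeterminacies)."""
    return k * (k + 1) // 2 - (k * m + k - m * (m - 1) // 2)


def _prepare_R(R, ridge_warn=True) -> np.ndarray:
    A = np.asarray(R, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    w = np.linalg.eigvalsh(A)
    if w.min() < -1e-8:
        raise ValueError(f"R indefinite (min eigenvalue {w.min():.3g})")
    if w.min() < 1e-6:
        # Within-person centering makes the identity-indicator block exactly
        # singular (the centered identity items sum to zero per respondent),
        # so a floor on the smallest eigenvalue is a structural necessity,
        # not just numerical hygiene.
        if ridge_warn:
            warnings.warn(
                f"R (near-)singular (min eigenvalue {w.min():.3g}); "
                "applying ridge repair"
            )
        A = A + (1e-6 - w.min()) * np.eye(len(A))
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
    return A


def _minres_profile(psi, R, m):
    """Given uniquenesses, loadings from the reduced-correlation eigenspace
    and the off-diagonal residual sum of squares."""
    S = R.copy()
    np.fill_diagonal(S, 1.0 - psi)
    w, v = np.linalg.eigh(S)
    idx = np.argsort(w)[::-1][:m]
    lam = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
    resid = R - lam @ lam.T
    iu = np.triu_indices_from(resid, k=1)
    return lam, float((resid[iu] ** 2).sum())


def _ml_profile(psi, R, m):
    """Lawley's profile: eigenvalues of Psi^-1/2 R Psi^-1/2 give the
    concentrated ML discrepancy and canonical loadings."""
    s = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(s, s)
    w, v = np.linalg.eigh(Rs)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tail = np.clip(w[m:], 1e-12, None)
    f = float(np.sum(tail - np.log(tail) - 1.0))
    lam = (np.sqrt(psi)[:, None]) * v[:, :m] * np.sqrt(np.clip(w[:m] - 1.0, 0, None))
    return lam, f


def extract(R, m: int, method: str = "ml") -> FactorSolution:
    """Unrotated extraction from a correlation matrix.

    Returns a FactorSolution with rotation='none' and factor columns
    F1..Fm; column signs are fixed so each column's largest-magnitude
    loading is positive. Uniquenesses hitting the Heywood floor (0.005)
    are clamped and reported in ``solution.heywood``.
    """
    labels = list(R.index) if isinstance(R, pd.DataFrame) else None
    A = _prepare_R(R)
    k = len(A)
    m_max = k if method == "pca" else k - 1
    if not (1 <= m <= m_max):
        raise ValueError(f"need 1 <= m <= {m_max} for {method} (got m={m}, k={k})")
    if method == "pca":
        w, v = np.linalg.eigh(A)
        order = np.argsort(w)[::-1][:m]
        lam = v[:, order] * np.sqrt(np.clip(w[order], 0, None))
        psi = 1.0 - (lam**2).sum(axis=1)
        converged = True
    elif method in ("ml", "minres"):
        profile = _ml_profile if method == "ml" else _minres_profile
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(A + 1e-10 * np.eye(k)))
        psi0 = np.clip(1.0 - smc, 0.05, 0.95)
        obj = lambda p: profile(p, A, m)[1]
        res = minimize(
            obj,
            psi0,
            method="L-BFGS-B",
            bounds=[(HEYWOOD_FLOOR, 1.0)] * k,
            options={"maxiter": 2000, "ftol": 1e-10, "gtol": 1e-7},
        )
        psi = res.x
        lam, _ = profile(psi, A, m)
        converged = bool(res.success)
        if not converged:
            logger.warning("%s extraction did not fully converge: %s",
                           method, res.message)
    else:
        raise ValueError(f"unknown method {method!r}")

    heywood = tuple(np.flatnonzero(psi <= HEYWOOD_FLOOR + 1e-12))
    if heywood:
        logger.warning("%d Heywood case(s) clamped at uniqueness=%.3f",
                       len(heywood), HEYWOOD_FLOOR)
        psi = np.clip(psi, HEYWOOD_FLOOR, None)

    # deterministic column signs
    for j in range(m):
        i_max = np.argmax(np.abs(lam[:, j]))
        if lam[i_max, j] < 0:
            lam[:, j] = -lam[:, j]

    if labels is None:
        labels = [f"v{i}" for i in range(k)]
    names = [f"F{j + 1}" for j in range(m)]
    if heywood:
        heywood = tuple(labels[i] for i in heywood)
    return FactorSolution(
        loadings=pd.DataFrame(lam, index=labels, columns=names),
        phi=pd.DataFrame(np.eye(m), index=names, columns=names),
        uniquenesses=pd.Series(psi, index=labels, name="uniqueness"),
        rotation="none",
        criterion_value=0.0,
        method=method,
        converged=converged,
        heywood=heywood,
    )


# ---------------------------------------------------------------------------
# target rotation

def target_criterion(loadings, target, weight) -> float:
    """Sum of squared deviations from the target over specified cells."""
    L = np.asarray(loadings, float)
    H = np.asarray(target, float)
    W = np.asarray(weight, float)
    return float((((L - H) ** 2) * W).sum())


def _target_spec(target_mask) -> tuple[np.ndarray, np.ndarray]:
    """Split a partially specified target into (H, W).

    ``target_mask`` entries that are finite are specified target values
    (typically 0); NaN entries are free. Returns the dense target H (free
    cells as 0) and the 0/1 weight matrix W marking specified cells."""
    M = np.asarray(
        target_mask.to_numpy() if isinstance(target_mask, pd.DataFrame) else target_mask,
        float,
    )
    W = np.isfinite(M).astype(float)
    if W.sum() == 0:
        raise ValueError("target specifies no cells")
    H = np.nan_to_num(M, nan=0.0)
    return H, W


def rotate_to_target(
    solution: FactorSolution,
    target_mask,
    oblique: bool = True,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_tries: int = 1000,
) -> FactorSolution:
    """Rotate an unrotated solution toward a partially specified target.

    ``target_mask`` holds target values on specified cells (0 in the usual
    theory-driven style, but any values work, e.g. a known population
    pattern) and NaN on free cells. Minimizes the weighted sum of squared
    deviations from the target by gradient projection on the oblique
    (default) or orthogonal rotation manifold, from the identity start plus
    ``n_restarts`` seeded random orthonormal starts; the best criterion is
    kept. Non-convergence warns, never raises.
    """
    L0 = solution.loadings.to_numpy()
    k, m = L0.shape
    if np.linalg.matrix_rank(L0) < m:
        raise ValueError("unrotated loadings are rank deficient")
    H, W = _target_spec(target_mask)
    if W.shape != (k, m):
        raise ValueError(f"target mask shape {W.shape} != loadings shape {(k, m)}")
    rotation_method = "oblique" if oblique else "orthogonal"
    vgQ = lambda L=None, A=None, T=None: vgQ_partial_target(H, W=W, L=L, A=A, T=T)

    rng = np.random.default_rng(seed)
    starts = [np.eye(m)]
    for _ in range(n_restarts):
        Q, _ = np.linalg.qr(rng.standard_normal((m, m)))
        starts.append(Q)

    best = None
    any_converged = False
    for T0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            L, _, T, table = GPA(
                L0, vgQ=vgQ, T=T0, rotation_method=rotation_method,
                tol=tol, max_tries=max_tries,
            )
        crit = target_criterion(L, H, W)
        converged = len(table) < max_tries
        any_converged = any_converged or converged
        if best is None or crit < best[0]:
            best = (crit, L, T, converged)
    crit, L, T, converged = best
    if not any_converged:
        warnings.warn("target rotation did not converge from any start")
    phi = T.T @ T if oblique else np.eye(m)

    names = list(solution.loadings.columns)
    return FactorSolution(
        loadings=pd.DataFrame(L, index=solution.loadings.index, columns=names),
        phi=pd.DataFrame(phi, index=names, columns=names),
        uniquenesses=solution.uniquenesses.copy(),
        rotation=f"target-{rotation_method}",
        criterion_value=crit,
        method=solution.method,
        converged=converged,
        heywood=solution.heywood,
    )


# ---------------------------------------------------------------------------
# fit statistics

def fit_statistics(R, solution: FactorSolution, n: int) -> FitStats:
    """Normal-theory fit statistics for an ML solution.

    chi^2 = (n-1) * F_ML with F_ML the discrepancy of the model-implied
    correlation matrix; RMSEA, CFI/TLI against the independence baseline,
    SRMR as the root mean square residual over the lower triangle including
    the diagonal, and the chi-square-based BIC = chi^2 - df * ln(n).
    With df <= 0 the model is saturated and the indices are reported as None.
    """
    if solution.method != "ml":
        raise ValueError("fit statistics require an ml solution")
    A = _prepare_R(R, ridge_warn=False)
    k = len(A)
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    df = model_degrees_of_freedom(k, solution.m)
    if df <= 0:
        return FitStats(None, df, None, None, None, None, None, n)

    sigma = solution.implied_correlation()
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    sign_r, logdet_r = np.linalg.slogdet(A)
    if sign_s <= 0 or sign_r <= 0:
        raise ValueError("implied or observed correlation matrix not PD")
    f_ml = max(logdet_s - logdet_r + np.trace(A @ np.linalg.inv(sigma)) - k, 0.0)
    chi2 = (n - 1) * f_ml

    f_base = -logdet_r
    chi2_base = (n - 1) * f_base
    df_base = k * (k - 1) // 2

    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, num, 1e-300)
    cfi = float(1.0 - num / den)
    if chi2_base / df_base > 1:
        tli = float(
            ((chi2_base / df_base) - (chi2 / df)) / ((chi2_base / df_base) - 1.0)
        )
    else:
        tli = None
    resid = A - sigma
    il = np.tril_indices(k)
    srmr = float(np.sqrt((resid[il] ** 2).mean()))
    bic = float(chi2 - df * np.log(n))
    return FitStats(float(chi2), df, cfi, tli, rmsea, srmr, bic, n)


# ---------------------------------------------------------------------------
# alignment

def align_to_blueprint(
    solution: FactorSolution, bp, method: str = "tucker"
) -> FactorSolution:
    """Permute and sign-flip factor columns to best match the blueprint.

    Exhaustive search over all m! permutations x 2^m sign patterns,
    maximizing the sum of diagonal congruence coefficients (Tucker by
    default) against the one-hot domain target; factor correlations are
    transformed consistently and columns are renamed to domain codes.
    """
    from .congruence import ideal_target, _pearson_columns, _tucker_columns

    m = solution.m
    if m > 6:
        raise ValueError("exhaustive alignment limited to m <= 6")
    target = ideal_target(bp, list(solution.loadings.index))
    cols = _tucker_columns if method == "tucker" else _pearson_columns
    C = cols(solution.loadings.to_numpy(), target.to_numpy())
    # C[f, d]: congruence of empirical factor f with domain d; a sign flip
    # of factor f flips the sign of row f, so the best sign per (f, d) cell
    # is |C| and the search reduces to an assignment over permutations.
    best_perm, best_val = None, -np.inf
    for perm in itertools.permutations(range(m)):
        val = sum(abs(C[perm[d], d]) for d in range(m))
        if val > best_val:
            best_val, best_perm = val, perm
    signs = np.array([1.0 if C[best_perm[d], d] >= 0 else -1.0 for d in range(m)])

    lam = solution.loadings.to_numpy()[:, list(best_perm)] * signs
    phi = solution.phi.to_numpy()[np.ix_(list(best_perm), list(best_perm))]
    phi = phi * np.outer(signs, signs)
    names = list(target.columns)
    return FactorSolution(
        loadings=pd.DataFrame(lam, index=solution.loadings.index, columns=names),
        phi=pd.DataFrame(phi, index=names, columns=names),
        uniquenesses=solution.uniquenesses.copy(),
        rotation=solution.rotation,
        criterion_value=solution.criterion_value,
        method=solution.method,
        converged=solution.converged,
        heywood=solution.heywood,
    )


def blueprint_target_mask(bp, indicator_labels) -> pd.DataFrame:
    """Target mask for rotation: 0 outside an indicator's intended domain,
    free (NaN) on the intended cell — the standard ESEM target style."""
    from .congruence import ideal_target

    tgt = ideal_target(bp, indicator_labels)
    mask = tgt.astype(float).where(tgt == 0.0)  # 0 stays 0, 1 -> NaN (free)
    return mask
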