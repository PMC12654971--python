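"""Penalized least squares for sparse term selection: LASSO, SCAD and MCP.

Coordinate descent on standardized columns with an unpenalized intercept,
plus cluster-wise (per-formulation) k-fold cross-validation over a 100-point
log-spaced lambda grid.  Folds never split the repeated measurements of one
formulation, so validation error is measured on held-out formulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .qccp_terms import TermBasis, evaluate_design_matrix

__all__ = ["PenaltyParams", "SelectionResult", "prox", "fit_penalized", "cv_select",
           "DEFAULT_SEED"]

#: Fold-shuffling seed of the shipped pipeline (fixed for reproducibility).
DEFAULT_SEED = 20251101

_KINDS = ("lasso", "scad", "mcp")


@dataclass(frozen=True)
class PenaltyParams:
    """Penalty family and its shape parameters.

    ``gamma`` (> 1) is the MCP concavity; ``a`` (> 2) the SCAD shape.  The
    literature-standard defaults gamma=3 and a=3.7 are used.
    """

    kind: str
    lam: float = 0.0
    gamma: float = 3.0
    a: float = 3.7

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.kind == "mcp" and not self.gamma > 1:
            raise ValueError("MCP needs gamma > 1")
        if self.kind == "scad" and not self.a > 2:
            raise ValueError("SCAD needs a > 2")


def _soft(z, lam):
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def prox(z: float, params: PenaltyParams) -> float:
    """Univariate penalized solution for a standardized coordinate.

    lasso: soft threshold S(z, lam).
    scad:  S(z, lam) for |z| <= 2 lam; ((a-1) z - sign(z) a lam)/(a-2) on the
           middle branch 2 lam < |z| <= a lam; identity beyond a lam.
    mcp:   S(z, lam)/(1 - 1/gamma) for |z| <= gamma lam; identity beyond.
    """
    z = float(z)
    lam = params.lam
    if lam == 0:
        return z
    az = abs(z)
    if params.kind == "lasso":
        return float(_soft(z, lam))
    if params.kind == "scad":
        a = params.a
        if az <= 2 * lam:
            return float(_soft(z, lam))
        if az <= a * lam:
            return ((a - 1) * z - np.sign(z) * a * lam) / (a - 2)
        return z
    gamma = params.gamma
    if az <= gamma * lam:
        return float(_soft(z, lam)) / (1 - 1 / gamma)
    return z


def _standardize(X, y):
    xm = X.mean(axis=0)
    xs = X.std(axis=0)
    keep = xs > 0  # constant columns cannot be standardized or selected
    Xs = (X[:, keep] - xm[keep]) / xs[keep]
    ym = y.mean()
    return Xs, y - ym, xm, xs, ym, keep


_KIND_IDS = {"lasso": 0, "scad": 1, "mcp": 2}


@njit(cache=False)
def _cd_kernel(G, c, n, lams, kind_id, gamma, a, tol, max_sweeps, betas):
    """Cyclic coordinate descent along a lambda path with warm starts.

    Works on the Gram matrix G = Xs'Xs and c = Xs'y of standardized columns
    (covariance updating), so each coordinate update costs O(p).  Returns
    the number of path points that hit the sweep cap.
    """
    p = G.shape[0]
    b = np.zeros(p)
    Gb = np.zeros(p)
    n_unconverged = 0
    for k in range(lams.size):
        lam = lams[k]
        delta = tol
        for _sweep in range(max_sweeps):
            delta = 0.0
            for j in range(p):
                z = b[j] + (c[j] - Gb[j]) / n
                s = 1.0 if z >= 0 else -1.0
                az = abs(z)
                if lam == 0.0:
                    new = z
                elif kind_id == 0:  # lasso: soft threshold
                    new = s * max(az - lam, 0.0)
                elif kind_id == 1:  # scad: three branches
                    if az <= 2.0 * lam:
                        new = s * max(az - lam, 0.0)
                    elif az <= a * lam:
                        new = ((a - 1.0) * z - s * a * lam) / (a - 2.0)
                    else:
                        new = z
                else:  # mcp: firm threshold
                    if az <= gamma * lam:
                        new = s * max(az - lam, 0.0) / (1.0 - 1.0 / gamma)
                    else:
                        new = z
                if new != b[j]:
                    diff = new - b[j]
                    for i in range(p):
                        Gb[i] += G[i, j] * diff
                    if abs(diff) > delta:
                        delta = abs(diff)
                    b[j] = new
            if delta < tol:
                break
        if delta >= tol:
            n_unconverged += 1
        betas[k] = b
    return n_unconverged


def _cd_path(Xs, yc, kind, lams, gamma, a, tol=1e-7, max_sweeps=10_000):
    """Solution path on standardized data; warns (once) on non-convergence."""
    n, p = Xs.shape
    lams = np.asarray(lams, dtype=float)
    betas = np.zeros((lams.size, p))
    G = Xs.T @ Xs
    c = Xs.T @ yc
    bad = _cd_kernel(G, c, float(n), lams, _KIND_IDS[kind], float(gamma),
                     float(a), float(tol), max_sweeps, betas)
    if bad:
        warnings.warn(
            f"coordinate descent hit the sweep cap at {bad} of {lams.size} "
            f"lambda values ({kind})")
    return betas


def fit_penalized(
    design: np.ndarray,
    response: np.ndarray,
    params: PenaltyParams,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Penalized least squares; returns (intercept, coefficients) de-standardized.

    Columns are standardized to mean 0 / unit variance internally; the
    intercept is unpenalized.  Returns an array of length p+1 whose first
    entry is the intercept on the original scale.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("design must have at least one column")
    if len(y) != X.shape[0]:
        raise ValueError("response length does not match design rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or response")

    Xs, yc, xm, xs, ym, keep = _standardize(X, y)
    bs = _cd_path(Xs, yc, params.kind, [params.lam], params.gamma, params.a,
                  tol=tol, max_sweeps=max_sweeps)[0]
    beta = np.zeros(X.shape[1])
    beta[keep] = bs / xs[keep]
    intercept = ym - xm @ beta
    return np.concatenate([[intercept], beta])


@dataclass
class SelectionResult:
    """Outcome of cross-validated penalized selection."""

    kind: str
    term_labels: list
    coefficients: np.ndarray  # length p+1: intercept first
    chosen_lambda: float
    lambda_path: pd.DataFrame  # lambda, cv_error, n_nonzero
    folds: int
    seed: int

    @property
    def selected_labels(self) -> list:
        return [lab for lab, b in zip(self.term_labels, self.coefficients[1:]) if b != 0]

    def coefficient_table(self) -> pd.DataFrame:
        labs = ["intercept"] + list(self.term_labels)
        return pd.DataFrame(
            {"term": labs, "coefficient": self.coefficients,
             "selected": [True] + [b != 0 for b in self.coefficients[1:]]}
        )


def _make_folds(n_clusters, folds, rng):
    order = rng.permutation(n_clusters)
    return [order[i::folds] for i in range(folds)]


def cv_select(
    dataset,
    basis: TermBasis,
    kind: str,
    folds: int = 10,
    seed: int = DEFAULT_SEED,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.001,
    gamma: float = 3.0,
    a: float = 3.7,
) -> SelectionResult:
    """Cross-validated penalized selection on the long-format study data.

    Folds partition formulations (clusters), never individual time rows.
    The lambda grid runs log-spaced from lambda_max (the smallest lambda
    zeroing every penalized term) down to ``lambda_min_ratio * lambda_max``;
    ties in CV error resolve toward the larger lambda (sparser model).
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if dataset.n_formulations < folds:
        raise ValueError("fewer formulations than folds")

    dm = evaluate_design_matrix(basis, dataset)
    labels = [lab for lab in dm["labels"] if lab != "intercept"]
    cols = [j for j, lab in enumerate(dm["labels"]) if lab != "intercept"]
    X, y, cluster = dm["X"][:, cols], dm["y"], dm["cluster"]

    Xs, yc, xm, xs, ym, keep = _standardize(X, y)
    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ yc) / n)
    lams = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)

    rng = np.random.default_rng(seed)
    fold_ids = _make_folds(dataset.n_formulations, folds, rng)
    for f in fold_ids:
        if len(f) == 0:
            raise ValueError("empty CV fold")

    cv_err = np.zeros(n_lambda)
    for f in fold_ids:
        test = np.isin(cluster, f)
        train = ~test
        Xs_tr, yc_tr, xm_tr, xs_tr, ym_tr, keep_tr = _standardize(X[train], y[train])
        betas = _cd_path(Xs_tr, yc_tr, kind, lams, gamma, a)
        # de-standardize the whole path, then validate on held-out formulations
        B = np.zeros((n_lambda, X.shape[1]))
        B[:, keep_tr] = betas / xs_tr[keep_tr]
        icpt = ym_tr - B @ xm_tr
        pred = X[test] @ B.T + icpt
        cv_err += ((y[test, None] - pred) ** 2).sum(axis=0)
    cv_err /= n

    best = int(np.argmin(cv_err))  # grid is descending: first minimum = largest lambda
    chosen = float(lams[best])

    betas = _cd_path(Xs, yc, kind, lams, gamma, a)
    n_nonzero = (betas != 0).sum(axis=1)
    beta = np.zeros(X.shape[1])
    beta[keep] = betas[best] / xs[keep]
    coefficients = np.concatenate([[ym - xm @ beta], beta])

    path = pd.DataFrame({"lambda": lams, "cv_error": cv_err, "n_nonzero": n_nonzero})
    return SelectionResult(
        kind=kind,
        term_labels=labels,
        coefficients=coefficients,
        chosen_lambda=chosen,
        lambda_path=path,
        folds=folds,
        seed=seed,
    )
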