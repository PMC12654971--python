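"""Entropy-weight TOPSIS ranking of candidate formulations.

The entropy weight method (EWM) derives objective criterion weights from the
information entropy of the normalized decision matrix; TOPSIS then ranks
alternatives by relative closeness C = D- / (D+ + D-) to the positive and
negative ideal solutions in the weighted normalized space.

Dialect.  The default pipeline follows the SPSS entropy-method convention:
benefit criteria are first min-max normalized, probabilities are the column
shares of that normalized matrix, and the TOPSIS matrix is the min-max
matrix rescaled to unit column L2 norm before weighting.  Because cumulative
release is a pure benefit indicator, the negative ideal defaults to the zero
vector.  On the reference 45-candidate release matrix this dialect
reproduces the published ranking and all printed D+/D-/C values to three
decimals, and gives the intermediate (8 h) release the largest weight.  The
classical raw-matrix dialect (column-sum probabilities, vector normalization
of the raw values) is available with ``preprocess=None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = ["EntropyWeights", "TopsisResult", "entropy_weights", "topsis",
           "rank_candidates", "rank_report"]


@dataclass
class EntropyWeights:
    """Per-criterion entropy e_j and normalized weight w_j (sums to 1)."""

    entropy: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.entropy = np.asarray(self.entropy, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1) > 1e-9:
            raise ValueError("weights must sum to 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"entropy": [float(e) for e in self.entropy],
                 "weights": [float(w) for w in self.weights]}, fh)


def _minmax(M: np.ndarray) -> np.ndarray:
    lo = M.min(axis=0)
    span = M.max(axis=0) - lo
    out = np.zeros_like(M, dtype=float)
    np.divide(M - lo, span, out=out, where=span > 0)
    return out


def entropy_weights(matrix, preprocess: str | None = "minmax") -> EntropyWeights:
    """Objective weights from the information entropy of benefit criteria.

    ``preprocess="minmax"`` (default) rescales each column to [0, 1] before
    forming column-share probabilities; ``None`` uses the raw values (which
    must then be strictly positive).  Entropy e_j = -(1/ln n) sum_i P_ij ln
    P_ij with 0 ln 0 := 0; weights w_j = (1 - e_j) / sum_k (1 - e_k).
    Constant columns carry no information and receive weight 0.
    """
    M = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, m = M.shape
    if n < 2:
        raise ValueError("need at least 2 alternatives")
    if preprocess == "minmax":
        V = _minmax(M)
    elif preprocess is None:
        if np.any(M <= 0):
            raise ValueError("raw-dialect entropy needs strictly positive entries")
        V = M
    else:
        raise ValueError("preprocess must be 'minmax' or None")

    colsum = V.sum(axis=0)
    constant = colsum == 0
    e = np.ones(m)
    for j in np.flatnonzero(~constant):
        P = V[:, j] / colsum[j]
        Plog = np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)
        e[j] = -Plog.sum() / np.log(n)
    info = 1 - e
    if np.all(info <= 1e-15):
        raise ValueError("every criterion is constant; weights undefined")
    w = info / info.sum()
    return EntropyWeights(entropy=e, weights=np.clip(w, 0.0, None))


@dataclass
class TopsisResult:
    """Distances to the ideal solutions, relative closeness and ranks."""

    d_plus: np.ndarray
    d_minus: np.ndarray
    closeness: np.ndarray
    rank: np.ndarray  # 1 = best; ties broken by input order (stable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d_plus": self.d_plus, "d_minus": self.d_minus,
             "closeness": self.closeness, "rank": self.rank})


def topsis(
    matrix,
    weights: EntropyWeights,
    preprocess: str | None = "minmax",
    zero_negative_ideal: bool = True,
) -> TopsisResult:
    """Rank alternatives by relative closeness to the ideal solutions.

    The (optionally min-max preprocessed) matrix is rescaled to unit column
    L2 norm, weighted, and compared against the positive ideal (column-wise
    maximum) and the negative ideal (the zero vector for pure benefit
    criteria, else the column-wise minimum) in Euclidean distance.
    """
    M = np.atleast_2d(np.asarray(matrix, dtype=float))
    if np.any(M < 0):
        raise ValueError("matrix entries must be non-negative")
    if len(weights.weights) != M.shape[1]:
        raise ValueError("weight count does not match criterion count")
    if preprocess == "minmax":
        if M.shape[0] < 2:
            raise ValueError("min-max preprocessing needs at least 2 alternatives")
        V = _minmax(M)
    elif preprocess is None:
        V = M
    else:
        raise ValueError("preprocess must be 'minmax' or None")

    norm = np.sqrt((V**2).sum(axis=0))
    if np.any(norm == 0) and preprocess is None:
        raise ValueError("zero-norm criterion column")
    r = np.divide(V, norm, out=np.zeros_like(V), where=norm > 0)
    v = weights.weights * r
    v_plus = v.max(axis=0)
    v_minus = np.zeros_like(v_plus) if zero_negative_ideal else v.min(axis=0)
    d_plus = np.sqrt(((v - v_plus) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - v_minus) ** 2).sum(axis=1))
    closeness = np.divide(d_minus, d_plus + d_minus,
                          out=np.zeros_like(d_minus), where=(d_plus + d_minus) > 0)
    order = np.argsort(-closeness, kind="stable")
    rank = np.empty(len(closeness), dtype=int)
    rank[order] = np.arange(1, len(closeness) + 1)
    return TopsisResult(d_plus=d_plus, d_minus=d_minus, closeness=closeness, rank=rank)


def rank_candidates(
    candidates: pd.DataFrame,
    release_columns=("Y_2", "Y_8", "Y_24"),
    preprocess: str | None = "minmax",
    zero_negative_ideal: bool = True,
) -> tuple:
    """Entropy-weight TOPSIS on a candidate table's release matrix.

    Returns ``(TopsisResult, EntropyWeights)``; row order follows the input.
    """
    M = candidates.loc[:, list(release_columns)].to_numpy(dtype=float)
    w = entropy_weights(M, preprocess=preprocess)
    res = topsis(M, w, preprocess=preprocess, zero_negative_ideal=zero_negative_ideal)
    return res, w


def rank_report(result: TopsisResult, candidates: pd.DataFrame,
                round_to: int = 3) -> pd.DataFrame:
    """Candidate table joined with D+/D-/C and sorted by rank (printed style)."""
    if len(candidates) != len(result.rank):
        raise ValueError("result and candidate row counts differ")
    out = candidates.copy().reset_index(drop=True)
    out["d_plus"] = np.round(result.d_plus, round_to)
    out["d_minus"] = np.round(result.d_minus, round_to)
    out["closeness"] = np.round(result.closeness, round_to)
    out["rank"] = result.rank
    return out.sort_values("rank").reset_index(drop=True)
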