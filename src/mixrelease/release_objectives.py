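"""Fitted release model -> penalized objective functions and feasibility filter.

The mixture design imposes the equality constraint sum(X) = 82.8 % on the
five excipient percentages.  An exterior quadratic penalty sigma*(sum x -
total)^2 with sigma = 1000 converts the constrained maximization of predicted
release at each time point into three unconstrained minimization objectives

    Q_k(x) = -Yhat(x, t_k) + sigma * (sum x - total)^2,   t_k in {2, 8, 24} h.

Pharmacopoeia acceptance intervals for glipizide preparations (15-25 % at
2 h, 55-65 % at 8 h, 80-110 % at 24 h) act as a post-hoc feasibility filter
on optimizer output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .qccp_terms import TermBasis, evaluate_terms_batch

__all__ = [
    "ReleaseModel",
    "PenaltyConfig",
    "ReleaseLimits",
    "predict_release",
    "penalty_term",
    "build_objectives",
    "ReleaseObjectives",
    "pharmacopoeia_filter",
    "DEFAULT_LIMITS",
]


@dataclass
class ReleaseModel:
    """A term basis plus fitted coefficients mapping (composition, time) to
    predicted cumulative release (%)."""

    basis: TermBasis
    coefficients: dict
    total: float = 82.8

    def __post_init__(self):
        missing = set(self.coefficients) - set(self.basis.labels)
        if missing:
            raise ValueError(f"coefficient labels not in basis: {sorted(missing)}")

    @classmethod
    def from_fit(cls, basis: TermBasis, fit, total: float = 82.8) -> "ReleaseModel":
        """Wrap a QIF (or any) fit exposing ``coefficients()``."""
        return cls(basis=basis.subset(fit.term_labels), coefficients=fit.coefficients(),
                   total=total)

    def _beta(self) -> np.ndarray:
        return np.array([self.coefficients.get(lab, 0.0) for lab in self.basis.labels])

    def predict(self, x, t: float) -> np.ndarray:
        """Predicted release for one composition or a batch at time ``t``."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        cols = evaluate_terms_batch(self.basis, x, t)
        out = cols @ self._beta()
        return float(out[0]) if single else out

    def predict_profile(self, x, times=(2.0, 8.0, 24.0)) -> np.ndarray:
        """Release at each time point; rows = compositions, cols = times."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        prof = np.column_stack([self.predict(X, t) for t in times])
        return prof[0] if single else prof

    def to_yaml(self, path) -> None:
        payload = {
            "total": float(self.total),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "q": int(self.basis.q),
            "terms": [
                {"component_indices": list(t.component_indices),
                 "time_power": int(t.time_power)}
                for t in self.basis.terms
            ],
            "centered": bool(self.basis.centered),
            "centering_offsets": None if self.basis.centering_offsets is None
            else [float(v) for v in self.basis.centering_offsets],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ReleaseModel":
        from .qccp_terms import Term

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        off = payload.get("centering_offsets")
        basis = TermBasis(
            q=payload["q"],
            terms=[Term(tuple(d["component_indices"]), d["time_power"])
                   for d in payload["terms"]],
            centered=payload.get("centered", False),
            centering_offsets=None if off is None else np.asarray(off, dtype=float),
        )
        return cls(basis=basis, coefficients=payload["coefficients"],
                   total=payload["total"])


def predict_release(model: ReleaseModel, x, t: float):
    """Module-level alias for :meth:`ReleaseModel.predict`."""
    return model.predict(x, t)


@dataclass(frozen=True)
class PenaltyConfig:
    """Exterior-penalty settings for the constant-sum equality constraint."""

    sigma: float = 1000.0
    total: float = 82.8
    exponent: int = 2

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.exponent < 2 or self.exponent % 2:
            raise ValueError("exponent must be even and >= 2")


def penalty_term(x, config: PenaltyConfig):
    """sigma * (sum x - total)^exponent, vectorized over rows."""
    x = np.asarray(x, dtype=float)
    s = x.sum(axis=-1)
    return config.sigma * (s - config.total) ** config.exponent


@dataclass
class ReleaseObjectives:
    """The three penalized release objectives Q1, Q2, Q3 (all minimized).

    Callable row-wise on a single composition or a batch; also exposes the
    unpenalized release profile for candidate reporting.
    """

    model: ReleaseModel
    penalty: PenaltyConfig
    times: tuple = (2.0, 8.0, 24.0)

    def __post_init__(self):
        if abs(self.model.total - self.penalty.total) > 1e-9:
            raise ValueError("model and penalty disagree on the constant sum")

    @property
    def n_objectives(self) -> int:
        return len(self.times)

    def releases(self, x) -> np.ndarray:
        return self.model.predict_profile(x, self.times)

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        pen = penalty_term(x, self.penalty)
        prof = self.releases(x)
        return -prof + (pen[..., None] if x.ndim == 2 else pen)

    def as_callables(self) -> list:
        """Three scalar functions of a single composition vector."""
        return [
            (lambda x, k=k: float(self(np.asarray(x, dtype=float))[k]))
            for k in range(self.n_objectives)
        ]


def build_objectives(
    model: ReleaseModel,
    config: PenaltyConfig | None = None,
    times=(2.0, 8.0, 24.0),
) -> ReleaseObjectives:
    """Penalty-transformed objective set for the three release stages."""
    if config is None:
        config = PenaltyConfig(total=model.total)
    return ReleaseObjectives(model=model, penalty=config, times=tuple(times))


@dataclass(frozen=True)
class ReleaseLimits:
    """Closed acceptance intervals for the release at each time point (%)."""

    intervals: tuple = ((15.0, 25.0), (55.0, 65.0), (80.0, 110.0))

    def __post_init__(self):
        for lo, hi in self.intervals:
            if not lo < hi:
                raise ValueError("each interval needs lo < hi")

    def contains(self, releases) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(releases, dtype=float))
        ok = np.ones(len(Y), dtype=bool)
        for j, (lo, hi) in enumerate(self.intervals):
            ok &= (Y[:, j] >= lo) & (Y[:, j] <= hi)
        return ok


#: The pharmacopoeia limits for glipizide sustained-release preparations.
DEFAULT_LIMITS = ReleaseLimits()


def pharmacopoeia_filter(candidates: pd.DataFrame, limits: ReleaseLimits = DEFAULT_LIMITS,
                         release_columns=("Y_2", "Y_8", "Y_24")) -> pd.DataFrame:
    """Rows whose releases fall inside every acceptance interval (closed bounds)."""
    if len(candidates) == 0:
        return candidates.copy()
    Y = candidates.loc[:, list(release_columns)].to_numpy(dtype=float)
    return candidates.loc[limits.contains(Y)].copy()
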