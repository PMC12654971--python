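"""Mixture-polynomial candidate terms and design-matrix evaluation.

The candidate model for a q-component mixture with repeated release
measurements contains all main effects X1..Xq, all product interactions up
to a chosen order (X24 = X2*X4, X135 = X1*X3*X5, ...), the component-by-time
terms Xi*t, the pure time terms t and t^2, and an intercept.  Term labels
concatenate ascending component indices ("X24", "X12345", "X3t").

Centering is optional: when enabled, component columns are shifted by their
training means before products are formed, and the offsets are stored on the
basis for prediction-time reuse.  The default is raw (Scheffe-type) products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import yaml

__all__ = ["Term", "TermBasis", "generate_term_basis", "evaluate_design_matrix",
           "evaluate_terms_batch"]


@dataclass(frozen=True)
class Term:
    """One polynomial term, identified by its component indices and time power.

    ``component_indices`` are 1-based and sorted.  ``time_power`` is 0, 1 or 2;
    component-by-time terms carry exactly one component index and time power 1.
    The intercept has no indices and time power 0.
    """

    component_indices: tuple
    time_power: int = 0

    @property
    def label(self) -> str:
        if not self.component_indices:
            if self.time_power == 0:
                return "intercept"
            return "t" if self.time_power == 1 else "t2"
        base = "X" + "".join(str(i) for i in self.component_indices)
        return base + "t" * self.time_power

    def __post_init__(self):
        idx = tuple(sorted(self.component_indices))
        object.__setattr__(self, "component_indices", idx)
        if self.time_power not in (0, 1, 2):
            raise ValueError("time_power must be 0, 1 or 2")
        if self.time_power >= 1 and len(idx) > 1:
            raise ValueError("component-by-time terms take a single component")
        if self.time_power == 2 and idx:
            raise ValueError("squared time does not combine with components")


@dataclass
class TermBasis:
    """Ordered term set for a q-component mixture model.

    Ordering: main effects, interactions by order then lexicographically,
    component-by-time terms, t, t^2, intercept last.
    """

    q: int
    terms: list
    centered: bool = False
    centering_offsets: np.ndarray | None = field(default=None)

    def __post_init__(self):
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate term labels")

    @property
    def labels(self) -> list:
        return [t.label for t in self.terms]

    def subset(self, labels) -> "TermBasis":
        """A basis restricted to ``labels`` (original order preserved)."""
        keep = set(labels)
        missing = keep - set(self.labels)
        if missing:
            raise KeyError(f"labels not in basis: {sorted(missing)}")
        return TermBasis(
            q=self.q,
            terms=[t for t in self.terms if t.label in keep],
            centered=self.centered,
            centering_offsets=None if self.centering_offsets is None
            else np.array(self.centering_offsets),
        )

    def to_yaml(self, path) -> None:
        payload = {
            "q": int(self.q),
            "terms": [
                {"component_indices": list(t.component_indices), "time_power": int(t.time_power)}
                for t in self.terms
            ],
            "centered": bool(self.centered),
            "centering_offsets": None
            if self.centering_offsets is None
            else [float(v) for v in self.centering_offsets],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "TermBasis":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        terms = [
            Term(tuple(d["component_indices"]), d["time_power"]) for d in payload["terms"]
        ]
        off = payload.get("centering_offsets")
        return cls(
            q=payload["q"],
            terms=terms,
            centered=payload.get("centered", False),
            centering_offsets=None if off is None else np.asarray(off, dtype=float),
        )


def generate_term_basis(
    q: int,
    max_interaction_order: int | None = None,
    include_time_terms: bool = True,
    centered: bool = False,
) -> TermBasis:
    """Full candidate term set for a q-component mixture release model."""
    if q < 2:
        raise ValueError("need at least 2 components")
    if max_interaction_order is None:
        max_interaction_order = q
    if not (2 <= max_interaction_order <= q):
        raise ValueError("max_interaction_order must be in [2, q]")

    terms = [Term((i,)) for i in range(1, q + 1)]
    for order in range(2, max_interaction_order + 1):
        for idx in combinations(range(1, q + 1), order):
            terms.append(Term(idx))
    if include_time_terms:
        terms.extend(Term((i,), time_power=1) for i in range(1, q + 1))
        terms.append(Term((), time_power=1))
        terms.append(Term((), time_power=2))
    terms.append(Term(()))  # intercept last
    return TermBasis(q=q, terms=terms, centered=centered)


def _term_columns(basis: TermBasis, comp: np.ndarray, t: float) -> np.ndarray:
    """Evaluate every term at composition rows ``comp`` and scalar time ``t``."""
    n = comp.shape[0]
    cols = np.empty((n, len(basis.terms)))
    for j, term in enumerate(basis.terms):
        if term.component_indices:
            col = np.ones(n)
            for i in term.component_indices:
                col = col * comp[:, i - 1]
            if term.time_power == 1:
                col = col * t
            cols[:, j] = col
        else:
            cols[:, j] = {0: 1.0, 1: t, 2: t * t}[term.time_power]
    return cols


def evaluate_terms_batch(basis: TermBasis, composition: np.ndarray, t: float) -> np.ndarray:
    """Design rows for a batch of compositions at one time point.

    Honors stored centering offsets (fails if centering is enabled but the
    offsets have not been fitted).
    """
    comp = np.atleast_2d(np.asarray(composition, dtype=float))
    if comp.shape[1] != basis.q:
        raise ValueError(f"expected {basis.q} components, got {comp.shape[1]}")
    if basis.centered:
        if basis.centering_offsets is None:
            raise ValueError("centered basis has no fitted offsets")
        comp = comp - basis.centering_offsets
    return _term_columns(basis, comp, float(t))


def evaluate_design_matrix(basis: TermBasis, dataset) -> dict:
    """Long-format design for a repeated-measures mixture study.

    Stacks the m time points of each formulation contiguously (time-major
    within formulation).  With centering enabled the component means over the
    formulations are stored on the basis for later prediction.

    Returns a dict with ``X`` (n*m, p), ``y`` (n*m,), ``labels``,
    ``cluster`` (formulation index per row) and ``time`` per row.
    """
    if dataset.q != basis.q:
        raise ValueError("dataset component count does not match basis q")
    comp = dataset.composition
    if basis.centered:
        basis.centering_offsets = comp.mean(axis=0)
        comp = comp - basis.centering_offsets

    n, m = dataset.n_formulations, dataset.n_times
    p = len(basis.terms)
    X = np.empty((n * m, p))
    y = np.empty(n * m)
    cluster = np.repeat(np.arange(n), m)
    time = np.tile(np.asarray(dataset.times, dtype=float), n)
    for j, t in enumerate(dataset.times):
        rows = np.arange(n) * m + j
        X[rows] = _term_columns(basis, comp, float(t))
        y[rows] = dataset.responses[:, j]
    return {"X": X, "y": y, "labels": basis.labels, "cluster": cluster, "time": time}
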