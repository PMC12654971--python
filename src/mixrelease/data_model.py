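"""Domain types, fixtures, validation and the synthetic mixture-study generator.

A mixture-design release study is a table of formulations: each row holds the
percentages of ``q`` excipients (constant-sum composition, here summing to
82.8 % w/w of the tablet) and the cumulative drug release observed at an
ordered set of dissolution time points (here 2, 8 and 24 h).  The reference
study is a 25-run D-optimal design for glipizide sustained-release matrix
tablets with five excipients: HPMC K4M (X1), HPMC K100LV (X2), MgO (X3),
lactose (X4) and anhydrous CaHPO4 (X5).

All percentages are handled on the 0-100 scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "MixtureDataset",
    "SyntheticConfig",
    "GroundTruth",
    "ValidationReport",
    "COMPONENT_NAMES",
    "DEFAULT_TOTAL",
    "DEFAULT_BOUNDS",
    "load_reference_dataset",
    "load_candidate_table",
    "load_topsis_reference",
    "load_comparison_reference",
    "read_dataset_csv",
    "write_dataset_csv",
    "validate_constant_sum",
    "response_correlations",
    "pearson_correlations",
    "simulate_mixture_study",
]

#: Excipient names of the reference study, indexed X1..X5.
COMPONENT_NAMES = ("HPMC K4M", "HPMC K100LV", "MgO", "Lactose", "Anhydrous CaHPO4")

#: Constant sum of the five excipient percentages in the reference design.
DEFAULT_TOTAL = 82.8

#: Observed per-component ranges of the reference design (% w/w), used as the
#: default box bounds for simulation and optimization.
DEFAULT_BOUNDS = (
    (25.0, 47.8),
    (10.0, 27.8),
    (2.0, 10.0),
    (15.0, 22.8),
    (5.0, 12.8),
)


@dataclass
class MixtureDataset:
    """Formulations with constant-sum compositions and repeated release responses.

    Parameters
    ----------
    formulation_ids
        One label per formulation (row).
    composition
        ``(n, q)`` array of component percentages.
    times
        Strictly increasing dissolution time points in hours.
    responses
        ``(n, m)`` array of cumulative release (%) at each time point.
    """

    formulation_ids: list
    composition: np.ndarray
    times: np.ndarray
    responses: np.ndarray
    component_labels: list = field(default=None)

    def __post_init__(self):
        self.composition = np.asarray(self.composition, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.formulation_ids = list(self.formulation_ids)
        n, q = self.composition.shape
        if self.component_labels is None:
            self.component_labels = [f"X{i + 1}" for i in range(q)]
        if len(self.formulation_ids) != n:
            raise ValueError("formulation_ids length does not match composition rows")
        if self.responses.shape != (n, len(self.times)):
            raise ValueError("responses shape does not match (n formulations, m times)")
        if np.any(self.composition < 0):
            raise ValueError("composition entries must be non-negative")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.responses)) or np.any(self.responses < 0):
            raise ValueError("responses must be finite and non-negative")

    @property
    def n_formulations(self) -> int:
        return self.composition.shape[0]

    @property
    def q(self) -> int:
        return self.composition.shape[1]

    @property
    def n_times(self) -> int:
        return len(self.times)

    def response_labels(self) -> list:
        return [_fmt_time_label(t) for t in self.times]

    def to_frame(self) -> pd.DataFrame:
        """Wide-format table: formulation, X1..Xq, Y_<t> columns."""
        df = pd.DataFrame(self.composition, columns=self.component_labels)
        for j, lab in enumerate(self.response_labels()):
            df[lab] = self.responses[:, j]
        df.insert(0, "formulation", self.formulation_ids)
        return df


def _fmt_time_label(t: float) -> str:
    return f"Y_{int(t)}" if float(t).is_integer() else f"Y_{t}"


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic mixture-study generator.

    The generator emulates the reference design: ``n_formulations``
    constant-sum compositions sampled inside per-component box bounds, with
    responses from a sparse mixture polynomial plus AR(1)-correlated Gaussian
    noise across the within-formulation time points.
    """

    n_formulations: int = 25
    component_bounds: Sequence = DEFAULT_BOUNDS
    total: float = DEFAULT_TOTAL
    times: Sequence = (2.0, 8.0, 24.0)
    # Sparse truth whose mean releases on the reference design space follow a
    # typical sustained-release profile (~20/60/95 % at 2/8/24 h): a concave
    # time trend plus mild filler-interaction and matrix-by-time effects.
    true_coefficients: Mapping = field(
        default_factory=lambda: {
            "intercept": 7.0,
            "X24": -0.01,
            "X3t": 0.02,
            "t": 8.70,
            "t2": -0.2036,
        }
    )
    noise_sd: float = 2.0
    rho: float = 0.3
    seed: int = 0

    def __post_init__(self):
        bounds = np.asarray(self.component_bounds, dtype=float)
        if bounds.ndim != 2 or bounds.shape[1] != 2:
            raise ValueError("component_bounds must be a (q, 2) array of [lo, hi]")
        if np.any(bounds[:, 0] > bounds[:, 1]):
            raise ValueError("each component bound needs lo <= hi")
        if not (bounds[:, 0].sum() <= self.total <= bounds[:, 1].sum()):
            raise ValueError("total is infeasible for the given bounds")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.component_bounds = bounds

    @property
    def q(self) -> int:
        return len(self.component_bounds)

    def to_yaml(self, path) -> None:
        payload = {
            "n_formulations": int(self.n_formulations),
            "component_bounds": [[float(a), float(b)] for a, b in self.component_bounds],
            "total": float(self.total),
            "times": [float(t) for t in self.times],
            "true_coefficients": {k: float(v) for k, v in self.true_coefficients.items()},
            "noise_sd": float(self.noise_sd),
            "rho": float(self.rho),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


@dataclass
class GroundTruth:
    """The generating truth of a simulated study (for recovery checks)."""

    true_coefficients: Mapping
    rho: float
    noise_sd: float


@dataclass
class ValidationReport:
    """Per-row constant-sum deviations and the dataset-level verdict."""

    table: pd.DataFrame
    total: float
    tol: float

    @property
    def passed(self) -> bool:
        return bool(self.table["ok"].all())


def _fixture_frame(name: str) -> pd.DataFrame:
    with resources.files("mixrelease.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, float_precision="round_trip")


def load_reference_dataset() -> MixtureDataset:
    """The 25-formulation glipizide sustained-release study (5 excipients,
    cumulative release at 2/8/24 h), exactly as printed."""
    df = _fixture_frame("table1_reference.csv")
    comp_cols = ["X1", "X2", "X3", "X4", "X5"]
    resp_cols = ["Y_2", "Y_8", "Y_24"]
    return MixtureDataset(
        formulation_ids=df["formulation"].tolist(),
        composition=df[comp_cols].to_numpy(),
        times=np.array([2.0, 8.0, 24.0]),
        responses=df[resp_cols].to_numpy(),
    )


def load_candidate_table() -> pd.DataFrame:
    """The 45 pooled Pareto candidates (15 per optimizer) with their
    compositions and predicted releases, exactly as printed."""
    return _fixture_frame("table5_candidates.csv")


def load_topsis_reference() -> pd.DataFrame:
    """The printed entropy-weight TOPSIS ranking of the top 15 candidates."""
    return _fixture_frame("table6_topsis.csv")


def load_comparison_reference() -> pd.DataFrame:
    """The printed baseline-vs-optimum comparison (composition and releases
    of the original formulation, the top candidate, changes and rates)."""
    return _fixture_frame("table7_comparison.csv")


def read_dataset_csv(path, times: Sequence | None = None) -> MixtureDataset:
    """Read a wide-format study CSV (formulation, X1..Xq, Y_<t> columns)."""
    df = pd.read_csv(path, float_precision="round_trip")
    comp_cols = [c for c in df.columns if c.startswith("X")]
    resp_cols = [c for c in df.columns if c.startswith("Y_")]
    if times is None:
        times = [float(c.split("_", 1)[1]) for c in resp_cols]
    ids = df["formulation"].tolist() if "formulation" in df.columns else list(range(1, len(df) + 1))
    return MixtureDataset(
        formulation_ids=ids,
        composition=df[comp_cols].to_numpy(),
        times=np.asarray(times, dtype=float),
        responses=df[resp_cols].to_numpy(),
    )


def write_dataset_csv(dataset: MixtureDataset, path) -> None:
    # %.17g guarantees bit-for-bit float round-trips through the CSV dialect
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def validate_constant_sum(
    dataset: MixtureDataset, total: float = DEFAULT_TOTAL, tol: float = 0.25
) -> ValidationReport:
    """Check every formulation's component sum against the design total.

    ``tol`` defaults to 0.25 percentage points: five components printed to
    one decimal can each be off by up to 0.05, so their sum can deviate by
    up to 0.25 from the design total without any underlying violation (the
    reference table contains rows at 0.1 and 0.2).  Generated data should
    pass at machine tolerance.
    """
    if dataset.n_formulations == 0:
        raise ValueError("dataset is empty")
    if tol <= 0:
        raise ValueError("tol must be positive")
    sums = dataset.composition.sum(axis=1)
    dev = np.abs(sums - total)
    # small epsilon so a deviation printed as exactly tol (e.g. 0.1 from
    # table rounding) is not rejected by floating-point representation
    ok = dev <= tol + 1e-9
    table = pd.DataFrame(
        {
            "formulation": dataset.formulation_ids,
            "sum": sums,
            "deviation": dev,
            "ok": ok,
        }
    )
    return ValidationReport(table=table, total=total, tol=tol)


def response_correlations(dataset: MixtureDataset, method: str = "pearson") -> pd.DataFrame:
    """Correlation matrix of the release responses across time points.

    ``method`` is ``"pearson"`` or ``"spearman"``.  Computed over
    formulations for each pair of time points; raises if a response column is
    constant (correlation undefined).
    """
    if dataset.n_formulations < 3:
        raise ValueError("need at least 3 formulations")
    if dataset.n_times < 2:
        raise ValueError("need at least 2 time points")
    Y = dataset.responses
    if np.any(Y.std(axis=0) == 0):
        raise ValueError("a response column is constant; correlation undefined")
    if method == "pearson":
        mat = np.corrcoef(Y.T)
    elif method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 0, Y)
        mat = np.corrcoef(ranks.T)
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = dataset.response_labels()
    return pd.DataFrame(mat, index=labels, columns=labels)


def pearson_correlations(dataset: MixtureDataset) -> pd.DataFrame:
    """Pearson correlation matrix of the responses (see ``response_correlations``)."""
    return response_correlations(dataset, method="pearson")


def _sample_compositions(rng: np.random.Generator, config: SyntheticConfig) -> np.ndarray:
    """Uniform box sampling projected onto the constant-sum hyperplane.

    The orthogonal projection adds the same correction to every component;
    draws whose projection exits the box are rejected.
    """
    bounds = np.asarray(config.component_bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]
    q = config.q
    out = np.empty((config.n_formulations, q))
    filled = 0
    attempts = 0
    max_attempts = 2000 * config.n_formulations + 10000
    while filled < config.n_formulations:
        chunk = max(config.n_formulations - filled, 64)
        x = rng.uniform(lo, hi, size=(chunk, q))
        x = x + (config.total - x.sum(axis=1, keepdims=True)) / q
        keep = np.all((x >= lo) & (x <= hi), axis=1)
        kept = x[keep]
        take = min(len(kept), config.n_formulations - filled)
        out[filled : filled + take] = kept[:take]
        filled += take
        attempts += chunk
        if attempts > max_attempts:
            raise RuntimeError(
                "constant-sum projection kept leaving the box bounds; "
                "bounds and total are jointly too tight"
            )
    return out


def simulate_mixture_study(config: SyntheticConfig) -> tuple:
    """Generate a synthetic mixture study and its ground truth.

    Responses are ``true polynomial + AR(1) noise``: within each formulation
    the residuals at consecutive time points follow a stationary AR(1)
    process with lag-1 correlation ``rho`` and marginal standard deviation
    ``noise_sd``.  Identical seeds give identical output.
    """
    from .qccp_terms import generate_term_basis, evaluate_terms_batch

    rng = np.random.default_rng(config.seed)
    comp = _sample_compositions(rng, config)
    n, m = config.n_formulations, len(config.times)

    basis = generate_term_basis(config.q, max_interaction_order=config.q, include_time_terms=True)
    labels = [t.label for t in basis.terms]
    unknown = set(config.true_coefficients) - set(labels)
    if unknown:
        raise ValueError(f"unknown true-coefficient labels: {sorted(unknown)}")
    beta = np.array([config.true_coefficients.get(lab, 0.0) for lab in labels])

    times = np.asarray(config.times, dtype=float)
    mean = np.empty((n, m))
    for j, t in enumerate(times):
        mean[:, j] = evaluate_terms_batch(basis, comp, t) @ beta

    eps = np.empty((n, m))
    eps[:, 0] = rng.normal(0.0, 1.0, n)
    for j in range(1, m):
        eps[:, j] = config.rho * eps[:, j - 1] + np.sqrt(1 - config.rho**2) * rng.normal(0.0, 1.0, n)
    responses = np.clip(mean + config.noise_sd * eps, 0.0, None)

    dataset = MixtureDataset(
        formulation_ids=list(range(1, n + 1)),
        composition=comp,
        times=times,
        responses=responses,
    )
    truth = GroundTruth(
        true_coefficients=dict(config.true_coefficients),
        rho=config.rho,
        noise_sd=config.noise_sd,
    )
    return dataset, truth
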