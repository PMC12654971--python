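"""End-to-end orchestration: data -> terms -> selection -> QIF -> objectives
-> optimization -> ranking -> comparison.

The pipeline is a pure function of (input data, configuration, master seed):
the master seed is fanned out deterministically to the optimizer runs, the
CV fold seed is fixed in the configuration, and every stage's inputs,
outputs and seeds are logged.  Artifacts (CSV tables, YAML model, fitness
histories, run log) are written to the configured output directory.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_model, mcdm_rank, mo_optimizers, qccp_terms, qif_fit, sparse_select
from .release_objectives import (DEFAULT_LIMITS, PenaltyConfig, ReleaseModel,
                                 build_objectives)

__all__ = ["PipelineConfig", "PipelineResult", "ComparisonReport", "run_pipeline",
           "compare_to_baseline"]


@dataclass
class PipelineConfig:
    """Configuration of the full optimization workflow.

    ``dataset`` is ``"reference"``, a CSV path, or a
    :class:`~mixrelease.data_model.SyntheticConfig`.  ``candidates`` may name
    a ready-made candidate table (``"reference"`` or a CSV path) to skip the
    optimizer stage, e.g. when only re-ranking published candidates.
    """

    dataset: object = "reference"
    selection_kinds: tuple = ("lasso", "scad", "mcp")
    final_kind: str = "mcp"
    folds: int = 10
    selection_seed: int = sparse_select.DEFAULT_SEED
    qif_basis: str = "ar1"  # or "exchangeable"
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    optimizer: mo_optimizers.OptimizerConfig = field(
        default_factory=mo_optimizers.OptimizerConfig)
    candidates: object = None
    outdir: object = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "penalty" in payload:
            payload["penalty"] = PenaltyConfig(**payload["penalty"])
        if "optimizer" in payload:
            payload["optimizer"] = mo_optimizers.OptimizerConfig(**payload["optimizer"])
        if "selection_kinds" in payload:
            payload["selection_kinds"] = tuple(payload["selection_kinds"])
        return cls(**payload)


@dataclass
class ComparisonReport:
    """Baseline-vs-candidate changes in composition and release."""

    labels: list
    baseline: np.ndarray
    candidate: np.ndarray

    @property
    def change(self) -> np.ndarray:
        return self.candidate - self.baseline

    @property
    def rate_pct(self) -> np.ndarray:
        return 100.0 * self.change / self.baseline

    def to_frame(self, round_to: int = 3) -> pd.DataFrame:
        df = pd.DataFrame(
            [self.baseline, self.candidate, self.change, self.rate_pct],
            index=["baseline", "candidate", "change", "rate_pct"],
            columns=self.labels,
        )
        return df.round(round_to)


def compare_to_baseline(candidate, baseline) -> ComparisonReport:
    """Element-wise change and percentage rate of change vs the baseline.

    ``candidate`` and ``baseline`` are mappings (or Series) sharing the same
    composition and release keys, e.g. X1..X5, Y_2, Y_8, Y_24.
    """
    cand = pd.Series(dict(candidate), dtype=float)
    base = pd.Series(dict(baseline), dtype=float)
    labels = [k for k in base.index if k in cand.index]
    if not labels:
        raise ValueError("candidate and baseline share no keys")
    return ComparisonReport(
        labels=labels,
        baseline=base[labels].to_numpy(),
        candidate=cand[labels].to_numpy(),
    )


def reference_baseline() -> pd.Series:
    """The original (pre-optimization) formulation and its releases."""
    t7 = data_model.load_comparison_reference()
    row = t7.loc[t7["row"] == "baseline"].iloc[0]
    return row.drop("row").astype(float)


@dataclass
class PipelineResult:
    """Artifact bundle of one pipeline execution."""

    dataset: object
    basis: object
    selections: dict
    fits: dict
    final_kind: str
    model: ReleaseModel
    archives: dict
    candidates: pd.DataFrame
    topsis: mcdm_rank.TopsisResult
    weights: mcdm_rank.EntropyWeights
    ranking: pd.DataFrame
    comparison: ComparisonReport
    log: list


def _stage(log, name):
    log.append(f"[{time.strftime('%H:%M:%S')}] stage {name}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order; fails fast with a stage-labeled error."""
    log: list = [f"master seed {config.seed}"]
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # --- data -------------------------------------------------------------
    _stage(log, "data")
    try:
        if isinstance(config.dataset, data_model.SyntheticConfig):
            dataset, _truth = data_model.simulate_mixture_study(config.dataset)
        elif config.dataset == "reference":
            dataset = data_model.load_reference_dataset()
        else:
            dataset = data_model.read_dataset_csv(config.dataset)
        report = data_model.validate_constant_sum(dataset)
        log.append(f"dataset: {dataset.n_formulations} formulations, "
                   f"constant-sum pass={report.passed}")
    except Exception as exc:  # noqa: BLE001
        fail("data", exc)

    # --- terms + selection --------------------------------------------------
    _stage(log, "selection")
    try:
        basis = qccp_terms.generate_term_basis(dataset.q)
        selections = {
            kind: sparse_select.cv_select(dataset, basis, kind,
                                          folds=config.folds,
                                          seed=config.selection_seed)
            for kind in config.selection_kinds
        }
        for kind, sel in selections.items():
            log.append(f"{kind}: {len(sel.selected_labels)} terms at "
                       f"lambda={sel.chosen_lambda:.5g} (seed {sel.seed})")
    except Exception as exc:  # noqa: BLE001
        fail("selection", exc)

    # --- QIF fits ------------------------------------------------------------
    _stage(log, "qif")
    try:
        bset = (qif_fit.ar1_basis(dataset.n_times) if config.qif_basis == "ar1"
                else qif_fit.exchangeable_basis(dataset.n_times))
        fits = {}
        for kind, sel in selections.items():
            labels = sel.selected_labels + ["intercept"]
            fits[kind] = qif_fit.fit_qif(dataset, basis, labels, bset)
            log.append(f"QIF[{kind}]: p={fits[kind].p} "
                       f"AIC={fits[kind].aic:.4f} BIC={fits[kind].bic:.4f}")
        final_fit = fits[config.final_kind]
    except Exception as exc:  # noqa: BLE001
        fail("qif", exc)

    # --- objectives -----------------------------------------------------------
    _stage(log, "objectives")
    try:
        model = ReleaseModel.from_fit(basis, final_fit, total=config.penalty.total)
        objectives = build_objectives(model, config.penalty,
                                      times=tuple(dataset.times))
    except Exception as exc:  # noqa: BLE001
        fail("objectives", exc)

    # --- optimization ----------------------------------------------------------
    _stage(log, "optimize")
    try:
        if config.candidates is not None:
            archives = {}
            if config.candidates == "reference":
                candidates = data_model.load_candidate_table()
            else:
                candidates = pd.read_csv(config.candidates)
            log.append(f"optimizer stage skipped; {len(candidates)} candidates supplied")
        else:
            archives = mo_optimizers.run_all(objectives, config.optimizer, config.seed)
            # rank at full precision; Table-style rounding happens at write time
            candidates = mo_optimizers.pool_candidates(archives, DEFAULT_LIMITS,
                                                       round_to=None)
            log.append(f"pooled {len(candidates)} candidates from "
                       f"{sum(len(v) for v in archives.values())} runs")
    except Exception as exc:  # noqa: BLE001
        fail("optimize", exc)

    # --- ranking ---------------------------------------------------------------
    _stage(log, "rank")
    try:
        try:
            topsis_res, weights = mcdm_rank.rank_candidates(candidates)
        except ValueError:
            # every release criterion constant across candidates (e.g. a
            # composition-independent model): no information to weight, so
            # rank with equal weights; candidates are all equivalent
            M = candidates[["Y_2", "Y_8", "Y_24"]].to_numpy(dtype=float)
            weights = mcdm_rank.EntropyWeights(
                entropy=np.ones(M.shape[1]),
                weights=np.full(M.shape[1], 1.0 / M.shape[1]))
            topsis_res = mcdm_rank.topsis(M, weights, preprocess=None)
            log.append("release criteria carry no information across candidates; "
                       "equal weights used and ties broken by input order")
        ranking = mcdm_rank.rank_report(topsis_res, candidates)
        log.append(f"entropy weights {np.round(weights.weights, 4).tolist()}; "
                   f"top candidate scheme {ranking.iloc[0]['scheme']}")
    except Exception as exc:  # noqa: BLE001
        fail("rank", exc)

    # --- comparison -------------------------------------------------------------
    _stage(log, "compare")
    try:
        top = ranking.iloc[0]
        keys = [c for c in candidates.columns if c.startswith(("X", "Y_"))]
        comparison = compare_to_baseline(top[keys], reference_baseline())
    except Exception as exc:  # noqa: BLE001
        fail("compare", exc)

    result = PipelineResult(
        dataset=dataset, basis=basis, selections=selections, fits=fits,
        final_kind=config.final_kind, model=model, archives=archives,
        candidates=candidates, topsis=topsis_res, weights=weights,
        ranking=ranking, comparison=comparison, log=log,
    )
    if outdir:
        _write_artifacts(result, outdir)
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    for kind, sel in result.selections.items():
        sel.coefficient_table().to_csv(outdir / f"selection_{kind}.csv", index=False)
        sel.lambda_path.to_csv(outdir / f"lambda_path_{kind}.csv", index=False)
    qif_fit.inference_table(result.fits[result.final_kind]).to_csv(
        outdir / "inference_table.csv", index=False)
    result.model.to_yaml(outdir / "model.yaml")
    result.candidates.to_csv(outdir / "candidates_raw.csv", index=False)
    rounded = result.candidates.copy()
    num = rounded.select_dtypes("number").columns.drop("scheme", errors="ignore")
    rounded[num] = rounded[num].round(3)
    rounded.to_csv(outdir / "candidates.csv", index=False)
    result.ranking.to_csv(outdir / "ranking.csv", index=False)
    result.weights.to_yaml(outdir / "entropy_weights.yaml")
    result.comparison.to_frame().to_csv(outdir / "comparison.csv")
    for alg, archives in result.archives.items():
        for i, arch in enumerate(archives):
            arch.history.to_csv(
                outdir / f"history_{alg.replace('-', '').lower()}_run{i + 1}.csv",
                index=False)
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")
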