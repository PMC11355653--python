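"""End-to-end workflow: preprocess -> PLS -> VIP -> k-sweep CV -> baseline stats."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import CohortTable, read_cohort
from .crossval import (
    CVConfig,
    CVReport,
    SCHEMES,
    accuracy_sweep,
    best_k,
)
from .pls import (
    PLSModel,
    VIPResult,
    auto_components,
    cumulative_explained_variance,
    fit_pls,
    vip_scores,
)
from .preprocess import DEFAULT_IMPUTATION_VALUE, build_design_matrix
from .report import cv_report_to_dict, vip_result_to_dict, write_report
from .stats import baseline_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis choices in one reproducible record.

    ``components=None`` means automatic: the smallest count whose cumulative
    explained y-variance reaches ``explained_y_target``, capped at
    min(n-1, p).  The trichotomous half-width, imputation value and k-range
    default to the standard analysis constants (0.1, 1e-6, 1..10).
    """

    components: int | None = None
    k_min: int = 1
    k_max: int = 10
    schemes: tuple[str, ...] = SCHEMES
    selection_mode: str = "two_stage"
    normalization_mode: str = "global"
    imputation_value: float = DEFAULT_IMPUTATION_VALUE
    classification_halfwidth: float = 0.1
    explained_y_target: float = 0.9
    seed: int = 0
    rounding_decimals: int = 1

    def __post_init__(self) -> None:
        if self.classification_halfwidth < 0:
            raise ValueError("classification_halfwidth must be >= 0")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")

    def cv_config(self) -> CVConfig:
        return CVConfig(
            normalization=self.normalization_mode,
            selection=self.selection_mode,
            imputation_value=self.imputation_value,
            classification_halfwidth=self.classification_halfwidth,
            explained_y_target=self.explained_y_target,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "schemes" in payload:
            payload["schemes"] = tuple(payload["schemes"])
        return cls(**payload)


@dataclass
class PipelineResult:
    config: PipelineConfig
    initial_model: PLSModel
    cumulative_explvar_X: np.ndarray
    cumulative_explvar_Y: np.ndarray
    vip: VIPResult
    reports: dict[tuple[int, str], CVReport]
    best_k_per_scheme: dict[str, int]
    baseline: object  # pandas DataFrame, or None when the cohort has no baseline data

    def summary(self) -> dict:
        out = {
            "config": self.config.to_dict(),
            "initial_components": self.initial_model.A,
            "cumulative_explained_variance_Y": self.cumulative_explvar_Y.tolist(),
            "n_vip_above_1": self.vip.n_above_1,
            "n_vip_above_1_5": self.vip.n_above_1_5,
            "n_vip_above_2": self.vip.n_above_2,
            "best_k_per_scheme": self.best_k_per_scheme,
            "accuracy_by_k_scheme": {
                f"k={k},{scheme}": round(
                    100 * rep.accuracy_fraction, self.config.rounding_decimals
                )
                for (k, scheme), rep in sorted(self.reports.items())
            },
        }
        for scheme, k in self.best_k_per_scheme.items():
            rep = self.reports[(k, scheme)]
            out[f"best_{scheme}"] = {
                "k": k,
                **rep.tallies,
                **rep.percentages(self.config.rounding_decimals),
            }
        return out


def run_full_pipeline(
    cohort: CohortTable | str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the complete analysis on a cohort (object or CSV path).

    Steps: normalize + impute all measurements, fit the initial PLS, rank
    variables by VIP, sweep k over the configured range under both
    cross-validation schemes, pick the best k per scheme, and compare
    baseline characteristics between outcome groups.  The analysis itself is
    deterministic; identical input and config give identical outputs.  When
    ``out_dir`` is given, every artifact is written there together with an
    echo of the configuration.
    """
    if not isinstance(cohort, CohortTable):
        cohort = read_cohort(cohort)

    design = build_design_matrix(cohort, imputation_value=config.imputation_value)
    A = (
        config.components
        if config.components is not None
        else auto_components(design, config.explained_y_target)
    )
    model = fit_pls(design, A)
    cum_x, cum_y = cumulative_explained_variance(model)
    vip = vip_scores(model)

    k_max = min(config.k_max, design.p)
    reports = accuracy_sweep(
        cohort,
        vip=vip if config.selection_mode == "two_stage" else None,
        k_range=range(config.k_min, k_max + 1),
        schemes=config.schemes,
        n_components=config.components,
        config=config.cv_config(),
    )
    best = {scheme: best_k(reports, scheme) for scheme in config.schemes}

    baseline = baseline_table(cohort) if len(cohort.baseline.columns) else None

    result = PipelineResult(
        config=config,
        initial_model=model,
        cumulative_explvar_X=cum_x,
        cumulative_explvar_Y=cum_y,
        vip=vip,
        reports=reports,
        best_k_per_scheme=best,
        baseline=baseline,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(vip, out_dir / "vip.json")
        for (k, scheme), rep in reports.items():
            write_report(rep, out_dir / f"cv_k{k}_{scheme}.json")
        if baseline is not None:
            baseline.to_csv(out_dir / "baseline.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(result.summary(), indent=2))
        (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
        logger.info("pipeline artifacts written to %s", out_dir)
    return result
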