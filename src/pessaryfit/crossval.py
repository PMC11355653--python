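"""Variable selection, exhaustive cross-validation and trichotomous calls.

The validation stage takes the top-k variables by VIP, refits a PLS model,
and evaluates it by exhaustive leave-one-out and leave-two-out resampling.
Continuous predictions are called trichotomously: above +0.1 fitting, below
-0.1 non-fitting, the closed middle band unknown.  Leave-two-out produces
n(n-1) predictions for n participants (each participant is predicted once
per possible co-held-out partner), recorded in an n x n heatmap with an
empty diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, FITTING, NON_FITTING
from .grid import VariableKey
from .pls import VIPResult, auto_components, fit_pls, predict, vip_scores
from .preprocess import (
    DEFAULT_IMPUTATION_VALUE,
    DesignMatrix,
    build_design_matrix,
    code_response,
    impute_missing,
    zscore_normalize,
)

UNKNOWN = "unknown"

LEAVE_ONE_OUT = "leave_one_out"
LEAVE_TWO_OUT = "leave_two_out"
SCHEMES = (LEAVE_ONE_OUT, LEAVE_TWO_OUT)

_CALL_CODE = {FITTING: 1.0, NON_FITTING: -1.0, UNKNOWN: 0.0}


@dataclass(frozen=True)
class CVConfig:
    """Knobs of the cross-validation stage.

    normalization
        ``"global"``: z-score and impute the full matrix once, then fold
        (the stated order of operations of the analysis); ``"fold"``:
        recompute normalization statistics within each training fold and
        project the held-out rows onto them.
    selection
        ``"two_stage"``: VIP selection once on the full cohort before CV;
        ``"nested"``: re-select the top-k within every training fold
        (avoids selection bias at the cost of varying variable sets).
    degenerate_folds
        What to do when a training fold cannot support a fit (a single
        outcome class, or predictors with no usable variation):
        ``"error"`` raises, ``"unknown"`` records the fold's predictions as
        unknown calls so exhaustive-resampling bookkeeping stays intact.
    """

    normalization: str = "global"
    selection: str = "two_stage"
    imputation_value: float = DEFAULT_IMPUTATION_VALUE
    classification_halfwidth: float = 0.1
    explained_y_target: float = 0.9
    degenerate_folds: str = "error"

    def __post_init__(self) -> None:
        if self.normalization not in ("global", "fold"):
            raise ValueError("normalization must be 'global' or 'fold'")
        if self.selection not in ("two_stage", "nested"):
            raise ValueError("selection must be 'two_stage' or 'nested'")
        if self.classification_halfwidth < 0:
            raise ValueError("classification_halfwidth must be >= 0")
        if self.degenerate_folds not in ("error", "unknown"):
            raise ValueError("degenerate_folds must be 'error' or 'unknown'")


@dataclass
class PredictionRecord:
    predicted_participant: str
    co_held_out_participant: str | None
    continuous_response: float
    call: str
    truth: str
    correct: bool | None  # None when the call is unknown


@dataclass
class CVReport:
    scheme: str
    k_variables: int
    selected_keys: list[VariableKey]
    predictions: list[PredictionRecord]
    tallies: dict[str, int]
    accuracy_fraction: float
    heatmap: np.ndarray  # (n,) for leave-one-out, (n, n) with NaN diagonal for leave-two-out
    participant_ids: list[str] = field(default_factory=list)

    def percentages(self, decimals: int = 1) -> dict[str, float]:
        """Correct/incorrect/unknown shares in percent, rounded for reporting."""
        total = self.tallies["n_total"]
        return {
            "correct_pct": round(100 * self.tallies["n_correct"] / total, decimals),
            "incorrect_pct": round(100 * self.tallies["n_incorrect"] / total, decimals),
            "unknown_pct": round(100 * self.tallies["n_unknown"] / total, decimals),
        }


def classify_response(yhat: float, halfwidth: float = 0.1) -> str:
    """Trichotomous call: fitting above +halfwidth, non-fitting below
    -halfwidth, unknown in the closed middle band (boundaries included)."""
    if not np.isfinite(yhat):
        raise ValueError(f"non-finite prediction response: {yhat}")
    if yhat > halfwidth:
        return FITTING
    if yhat < -halfwidth:
        return NON_FITTING
    return UNKNOWN


def select_top_k(vip: VIPResult, k: int) -> list[VariableKey]:
    """First k keys of the VIP ranking (descending score, canonical tie-break)."""
    if not 1 <= k <= len(vip.ranking):
        raise ValueError(f"k must be in [1, {len(vip.ranking)}], got {k}")
    return list(vip.ranking[:k])


def _check_fold_classes(outcomes: list[str], train_idx: np.ndarray) -> None:
    train_out = {outcomes[i] for i in train_idx}
    if len(train_out) < 2:
        raise ValueError("training fold contains a single outcome class")


def _fold_matrices(
    cohort: CohortTable,
    keys: list[VariableKey],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: CVConfig,
    global_X: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Training and held-out predictor blocks for one fold."""
    if config.normalization == "global":
        assert global_X is not None
        return global_X[train_idx], global_X[test_idx]
    cols = [k.column for k in keys]
    raw = cohort.measurements[cols].to_numpy(dtype=float)
    Z_train, means, sds = zscore_normalize(raw[train_idx])
    safe = np.where(sds == 0, 1.0, sds)
    raw_test = raw[test_idx]
    Z_test = (raw_test - means) / safe
    const = sds == 0
    if const.any():
        Z_test[:, const] = np.where(np.isnan(raw_test[:, const]), np.nan, 0.0)
    return (
        impute_missing(Z_train, value=config.imputation_value),
        impute_missing(Z_test, value=config.imputation_value),
    )


def _nested_select(
    cohort: CohortTable, train_idx: np.ndarray, k: int, config: CVConfig
) -> list[VariableKey]:
    train = cohort.subset_rows(train_idx)
    design = build_design_matrix(train, imputation_value=config.imputation_value)
    A = auto_components(design, config.explained_y_target)
    return select_top_k(vip_scores(fit_pls(design, A)), k)


def _run_folds(
    cohort: CohortTable,
    folds: list[tuple[np.ndarray, np.ndarray]],
    selected: list[VariableKey] | None,
    k: int | None,
    n_components: int | None,
    config: CVConfig,
    scheme: str,
) -> CVReport:
    n = cohort.n
    if selected is None and config.selection != "nested":
        raise ValueError("selected keys required unless selection='nested'")
    if config.selection == "nested" and k is None:
        k = len(selected) if selected is not None else None
        if k is None:
            raise ValueError("nested selection requires k")

    global_X = None
    A_star = None
    if selected is not None:
        design_sel = build_design_matrix(
            cohort, selected, imputation_value=config.imputation_value
        )
        if config.normalization == "global":
            global_X = design_sel.X
        A_star = (
            n_components
            if n_components is not None
            else auto_components(design_sel, config.explained_y_target)
        )

    y_all = code_response(cohort.outcomes)
    records: list[PredictionRecord] = []
    heatmap = (
        np.full(n, np.nan) if scheme == LEAVE_ONE_OUT else np.full((n, n), np.nan)
    )

    for train_idx, test_idx in folds:
        try:
            _check_fold_classes(cohort.outcomes, train_idx)
            if config.selection == "nested":
                fold_keys = _nested_select(cohort, train_idx, k, config)
                fold_global_X = None
                if config.normalization == "global":
                    fold_design = build_design_matrix(
                        cohort, fold_keys, imputation_value=config.imputation_value
                    )
                    fold_global_X = fold_design.X
            else:
                fold_keys = selected
                fold_global_X = global_X
            Xtr, Xte = _fold_matrices(
                cohort, fold_keys, train_idx, test_idx, config, fold_global_X
            )
            n_train = len(train_idx)
            A_req = A_star if A_star is not None else len(fold_keys)
            A = max(1, min(A_req, len(fold_keys), n_train - 1))
            fold_design = _as_design(Xtr, y_all[train_idx], fold_keys)
            model = fit_pls(fold_design, A)
            yhat = predict(model, Xte)
        except ValueError:
            if config.degenerate_folds != "unknown":
                raise
            # an unfittable fold yields unknown calls, keeping the
            # exhaustive-resampling tallies complete
            yhat = np.zeros(len(test_idx))
        for row, i in enumerate(test_idx):
            call = classify_response(float(yhat[row]), config.classification_halfwidth)
            truth = cohort.outcomes[i]
            correct = None if call == UNKNOWN else call == truth
            co = None
            if scheme == LEAVE_TWO_OUT:
                j = int(test_idx[1 - row])
                co = cohort.participant_ids[j]
                heatmap[i, j] = _CALL_CODE[call]
            else:
                heatmap[i] = _CALL_CODE[call]
            records.append(
                PredictionRecord(
                    predicted_participant=cohort.participant_ids[i],
                    co_held_out_participant=co,
                    continuous_response=float(yhat[row]),
                    call=call,
                    truth=truth,
                    correct=correct,
                )
            )

    n_correct = sum(1 for r in records if r.correct is True)
    n_incorrect = sum(1 for r in records if r.correct is False)
    n_unknown = sum(1 for r in records if r.correct is None)
    n_total = len(records)
    return CVReport(
        scheme=scheme,
        k_variables=len(selected) if selected is not None else int(k),
        selected_keys=list(selected) if selected is not None else [],
        predictions=records,
        tallies={
            "n_correct": n_correct,
            "n_incorrect": n_incorrect,
            "n_unknown": n_unknown,
            "n_total": n_total,
        },
        accuracy_fraction=n_correct / n_total,
        heatmap=heatmap,
        participant_ids=list(cohort.participant_ids),
    )


def _as_design(X: np.ndarray, y: np.ndarray, keys: list[VariableKey]) -> DesignMatrix:
    return DesignMatrix(
        X=X,
        y=y,
        column_keys=list(keys),
        column_means=np.zeros(X.shape[1]),
        column_sds=np.ones(X.shape[1]),
        missing_mask=np.zeros_like(X, dtype=bool),
    )


def leave_one_out_cv(
    cohort: CohortTable,
    selected: list[VariableKey] | None = None,
    n_components: int | None = None,
    config: CVConfig = CVConfig(),
    k: int | None = None,
) -> CVReport:
    """Exhaustive leave-one-out validation: n folds, one prediction each."""
    n = cohort.n
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 participants")
    folds = [
        (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
    ]
    return _run_folds(cohort, folds, selected, k, n_components, config, LEAVE_ONE_OUT)


def leave_two_out_cv(
    cohort: CohortTable,
    selected: list[VariableKey] | None = None,
    n_components: int | None = None,
    config: CVConfig = CVConfig(),
    k: int | None = None,
) -> CVReport:
    """Exhaustive leave-two-out validation over all unordered participant
    pairs: n(n-1) predictions, each participant predicted n-1 times."""
    n = cohort.n
    if n < 5:
        raise ValueError("leave-two-out needs at least 5 participants")
    folds = []
    for i in range(n):
        for j in range(i + 1, n):
            test = np.array([i, j])
            folds.append((np.delete(np.arange(n), test), test))
    return _run_folds(cohort, folds, selected, k, n_components, config, LEAVE_TWO_OUT)


def accuracy_sweep(
    cohort: CohortTable,
    vip: VIPResult | None = None,
    k_range: range = range(1, 11),
    schemes: tuple[str, ...] = SCHEMES,
    n_components: int | None = None,
    config: CVConfig = CVConfig(),
) -> dict[tuple[int, str], CVReport]:
    """Run every (k, scheme) combination of the validation stage.

    With ``selection='two_stage'`` the VIP ranking must be supplied (or is
    computed once from the full cohort); with ``'nested'`` each fold
    re-selects its own top-k.
    """
    bad = set(schemes) - set(SCHEMES)
    if bad:
        raise ValueError(f"unknown schemes: {sorted(bad)}")
    if vip is None and config.selection == "two_stage":
        design = build_design_matrix(cohort, imputation_value=config.imputation_value)
        A = auto_components(design, config.explained_y_target)
        vip = vip_scores(fit_pls(design, A))

    runners = {LEAVE_ONE_OUT: leave_one_out_cv, LEAVE_TWO_OUT: leave_two_out_cv}
    reports: dict[tuple[int, str], CVReport] = {}
    for k in k_range:
        selected = select_top_k(vip, k) if config.selection == "two_stage" else None
        for scheme in schemes:
            reports[(k, scheme)] = runners[scheme](
                cohort, selected, n_components=n_components, config=config, k=k
            )
    return reports


def best_k(reports: dict[tuple[int, str], CVReport], scheme: str) -> int:
    """k with the highest accuracy for a scheme (smallest k wins ties)."""
    candidates = sorted(
        (key for key in reports if key[1] == scheme),
        key=lambda key: (-reports[key].accuracy_fraction, key[0]),
    )
    if not candidates:
        raise ValueError(f"no reports for scheme {scheme!r}")
    return candidates[0][0]
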