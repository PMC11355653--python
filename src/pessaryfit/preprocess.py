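"""Preprocessing: z-score normalization, +/-1 response coding, imputation.

The pipeline normalizes every measurement column to mean 0 / SD 1 over the
observed entries, codes the fitting outcome as +1 and non-fitting as -1,
and only then replaces missing entries with a value close to zero (1e-6 by
default) so they barely perturb the fitted directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable, FITTING, NON_FITTING
from .grid import VariableKey

logger = logging.getLogger(__name__)

#: Post-normalization replacement for missing entries.
DEFAULT_IMPUTATION_VALUE = 1e-6


@dataclass
class DesignMatrix:
    """Normalized, imputed predictor matrix with its provenance.

    ``X`` is z-scored per column over observed entries (sample SD, n-1
    denominator) and imputed at masked positions; ``y`` is the +/-1 coded
    outcome.  ``column_means``/``column_sds`` are in the original units so
    new observations can be projected onto the same scale.
    """

    X: np.ndarray
    y: np.ndarray
    column_keys: list[VariableKey]
    column_means: np.ndarray
    column_sds: np.ndarray
    missing_mask: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def code_response(outcomes: list[str]) -> np.ndarray:
    """Code outcomes as +1 (fitting) / -1 (non-fitting), order preserved."""
    if len(outcomes) == 0:
        raise ValueError("cannot code an empty outcome list")
    mapping = {FITTING: 1.0, NON_FITTING: -1.0}
    try:
        return np.array([mapping[o] for o in outcomes])
    except KeyError as exc:
        raise ValueError(f"unknown outcome label: {exc.args[0]!r}") from None


def decode_response(y: np.ndarray) -> list[str]:
    """Inverse of :func:`code_response` for exactly coded values."""
    out = []
    for v in np.asarray(y, dtype=float):
        if v == 1.0:
            out.append(FITTING)
        elif v == -1.0:
            out.append(NON_FITTING)
        else:
            raise ValueError(f"not a coded response value: {v}")
    return out


def zscore_normalize(
    raw: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scores over observed entries only.

    Parameters
    ----------
    raw
        (n, p) matrix in original units; NaN entries are treated as missing.
    mask
        Optional (n, p) boolean mask of missing entries; merged with NaNs.

    Returns
    -------
    Z, means, sds
        ``Z`` has observed entries standardized with the sample SD
        (n-1 denominator) and NaN at missing positions.  A constant column
        maps to all-zero z-scores with a logged warning (its sd is reported
        as 0).

    Raises
    ------
    ValueError
        If any column has fewer than 2 observed values, or n < 2.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 rows to normalize")
    miss = np.isnan(raw)
    if mask is not None:
        miss = miss | np.asarray(mask, dtype=bool)

    n_obs = (~miss).sum(axis=0)
    if (n_obs < 2).any():
        bad = np.nonzero(n_obs < 2)[0].tolist()
        raise ValueError(f"columns with fewer than 2 observed values: {bad}")

    work = np.where(miss, np.nan, raw)
    means = np.nanmean(work, axis=0)
    sds = np.nanstd(work, axis=0, ddof=1)

    constant = sds == 0
    if constant.any():
        logger.warning(
            "constant columns mapped to all-zero z-scores: %s",
            np.nonzero(constant)[0].tolist(),
        )
    safe_sds = np.where(constant, 1.0, sds)
    Z = (work - means) / safe_sds
    Z[:, constant] = np.where(miss[:, constant], np.nan, 0.0)
    return Z, means, sds


def impute_missing(
    Z: np.ndarray,
    mask: np.ndarray | None = None,
    value: float = DEFAULT_IMPUTATION_VALUE,
) -> np.ndarray:
    """Replace masked/NaN entries of a normalized matrix with ``value``."""
    Z = np.asarray(Z, dtype=float)
    miss = np.isnan(Z)
    if mask is not None:
        miss = miss | np.asarray(mask, dtype=bool)
    X = Z.copy()
    X[miss] = value
    return X


def build_design_matrix(
    cohort: CohortTable,
    keys: list[VariableKey] | None = None,
    imputation_value: float = DEFAULT_IMPUTATION_VALUE,
) -> DesignMatrix:
    """Normalize and impute a cohort's measurements into a DesignMatrix.

    ``keys`` restricts (and orders) the columns; by default all measurement
    columns of the cohort are used in their stored order.
    """
    if keys is None:
        keys = cohort.variable_keys
    cols = [k.column for k in keys]
    missing_cols = [c for c in cols if c not in cohort.measurements.columns]
    if missing_cols:
        raise ValueError(f"selected keys absent from cohort: {missing_cols}")
    raw = cohort.measurements[cols].to_numpy(dtype=float)
    mask = np.isnan(raw)
    n_imputed = int(mask.sum())
    if n_imputed:
        logger.info("imputing %d missing cells at %g", n_imputed, imputation_value)
    Z, means, sds = zscore_normalize(raw)
    X = impute_missing(Z, value=imputation_value)
    y = code_response(cohort.outcomes)
    return DesignMatrix(
        X=X,
        y=y,
        column_keys=list(keys),
        column_means=means,
        column_sds=sds,
        missing_mask=mask,
    )
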