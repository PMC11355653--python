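"""Synthetic cohort generator.

Emulates the statistical structure of a small pessary-fitting cohort: two
outcome groups, anatomical variables that are correlated across the
manoeuvre/pessary conditions of the same parameter, a designated set of
informative variables whose group means differ by a configurable
standardized effect, and missing-at-random cells.  It exists so that every
downstream stage (normalization, PLS, VIP selection, cross-validation,
baseline statistics) is testable without clinical data.

Correlation is modelled per anatomical parameter with an exchangeable
(compound-symmetry) structure across that parameter's 3-12 conditions:
repeated measurements of the same structure under different manoeuvres and
pessaries share a participant-level component.  The construction

    x_cond = mean + sd * (sqrt(rho) * z_participant + sqrt(1 - rho) * z_cond)

realizes correlation rho exactly and is positive definite for rho in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AVULSION_LEVELS, CohortTable, FITTING, NON_FITTING
from .grid import Parameter, Pessary, Manoeuvre, VariableKey, conditions_for, variable_grid

#: Per-parameter base means in original units (cm, cm^2, degrees); the TVL
#: mean on dynamic MRI is about 7.3 cm at rest, shorter than the 8.4 cm
#: measured on physical examination.
DEFAULT_BASE_MEANS: dict[Parameter, float] = {
    Parameter.PCL_LENGTH: 10.5,
    Parameter.TVL: 7.3,
    Parameter.CL: 2.6,
    Parameter.PUBOCOCCYGEAL_ANGLE: 25.0,
    Parameter.SACROCOCCYGEAL_ANGLE: 110.0,
    Parameter.SACROCOCCYGEAL_STRAIGHT_LENGTH: 10.0,
    Parameter.PUBOCOCCYGEAL_SACRAL_ANGLE: 100.0,
    Parameter.LHA: 25.0,
}

DEFAULT_BASE_SDS: dict[Parameter, float] = {
    Parameter.PCL_LENGTH: 1.0,
    Parameter.TVL: 1.2,
    Parameter.CL: 0.8,
    Parameter.PUBOCOCCYGEAL_ANGLE: 8.0,
    Parameter.SACROCOCCYGEAL_ANGLE: 12.0,
    Parameter.SACROCOCCYGEAL_STRAIGHT_LENGTH: 1.5,
    Parameter.PUBOCOCCYGEAL_SACRAL_ANGLE: 12.0,
    Parameter.LHA: 6.0,
}


@dataclass
class EffectProfile:
    """What separates (or does not separate) the two outcome groups.

    ``standardized_effect`` is the fitting-minus-non-fitting difference of
    group means in SD units, applied to every key in ``informative_keys``
    (positive sign = larger in the fitting group).
    ``within_participant_correlation`` is the exchangeable correlation across
    the conditions of one parameter.
    """

    informative_keys: frozenset[VariableKey] = frozenset()
    standardized_effect: float = 0.0
    base_means: dict[Parameter, float] = field(default_factory=lambda: dict(DEFAULT_BASE_MEANS))
    base_sds: dict[Parameter, float] = field(default_factory=lambda: dict(DEFAULT_BASE_SDS))
    within_participant_correlation: float = 0.5
    missing_rate: float = 0.0
    bmi_mean_fitting: float = 27.8
    bmi_mean_nonfitting: float = 23.9

    def __post_init__(self) -> None:
        grid = set(variable_grid())
        stray = self.informative_keys - grid
        if stray:
            raise ValueError(f"informative keys outside the grid: {sorted(map(str, stray))}")
        if not np.isfinite(self.standardized_effect):
            raise ValueError("standardized_effect must be finite")
        if not 0 <= self.within_participant_correlation < 1:
            raise ValueError("within_participant_correlation must lie in [0, 1)")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")


def default_effect_profile(
    standardized_effect: float = 1.5,
    within_participant_correlation: float = 0.5,
    missing_rate: float = 0.02,
) -> EffectProfile:
    """The default study profile: the six top-VIP variables are informative.

    The informative set is total vaginal length during Valsalva and at rest
    without a pessary and at rest with a ring, cervical length at rest with
    ring-with-support, the sacrococcygeal angle during Valsalva with
    ring-with-support, and the pubococcygeal angle at rest with a ring.
    """
    informative = frozenset(
        {
            VariableKey(Parameter.TVL, Manoeuvre.VALSALVA, Pessary.NONE),
            VariableKey(Parameter.TVL, Manoeuvre.REST, Pessary.NONE),
            VariableKey(Parameter.CL, Manoeuvre.REST, Pessary.RING_SUPPORT),
            VariableKey(Parameter.SACROCOCCYGEAL_ANGLE, Manoeuvre.VALSALVA, Pessary.RING_SUPPORT),
            VariableKey(Parameter.TVL, Manoeuvre.REST, Pessary.RING),
            VariableKey(Parameter.PUBOCOCCYGEAL_ANGLE, Manoeuvre.REST, Pessary.RING),
        }
    )
    return EffectProfile(
        informative_keys=informative,
        standardized_effect=standardized_effect,
        within_participant_correlation=within_participant_correlation,
        missing_rate=missing_rate,
    )


def generate_cohort(
    n_fitting: int = 9,
    n_nonfitting: int = 6,
    profile: EffectProfile | None = None,
    seed: int = 0,
) -> CohortTable:
    """Draw a reproducible synthetic cohort.

    Group sizes default to the 9 fitting / 6 non-fitting split of a
    15-participant study.  Within each parameter the conditions share an
    exchangeable correlation; informative keys get a group-mean shift of
    ``standardized_effect * sd``; cells go missing independently at
    ``missing_rate``.  Baseline characteristics are drawn from documented
    distributions (age ~ Normal(70, 8.5) years, group-specific BMI means,
    etc.) but are not consumed by the PLS pipeline.
    """
    if n_fitting < 2 or n_nonfitting < 2:
        raise ValueError("need at least 2 participants per outcome group")
    profile = profile or EffectProfile()
    rng = np.random.default_rng(seed)
    n = n_fitting + n_nonfitting
    outcomes = [FITTING] * n_fitting + [NON_FITTING] * n_nonfitting
    fitting_rows = np.arange(n) < n_fitting

    rho = profile.within_participant_correlation
    grid = variable_grid()
    data = pd.DataFrame(index=range(n), columns=[k.column for k in grid], dtype=float)
    for parameter in Parameter:
        keys = conditions_for(parameter)
        m = len(keys)
        mean = profile.base_means[parameter]
        sd = profile.base_sds[parameter]
        shared = rng.standard_normal((n, 1))
        idio = rng.standard_normal((n, m))
        block = mean + sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * idio)
        for j, key in enumerate(keys):
            col = block[:, j]
            if key in profile.informative_keys:
                col = col + np.where(fitting_rows, profile.standardized_effect * sd, 0.0)
            data[key.column] = col

    if profile.missing_rate > 0:
        miss = rng.random(data.shape) < profile.missing_rate
        data = data.mask(miss)

    baseline = pd.DataFrame(
        {
            "age_years": rng.normal(70.0, 8.5, n).round(1),
            "bmi_kg_m2": np.where(
                fitting_rows,
                rng.normal(profile.bmi_mean_fitting, 3.8, n),
                rng.normal(profile.bmi_mean_nonfitting, 3.2, n),
            ).round(1),
            "parity": rng.choice([1, 2, 3], size=n, p=[0.25, 0.5, 0.25]),
            "family_history_pop": rng.random(n) < 0.4,
            "hysterectomy": rng.random(n) < 0.13,
            "popq_stage": rng.choice([2, 3, 4], size=n, p=[0.42, 0.53, 0.05]),
            "tvl_exam_cm": rng.normal(8.4, 1.2, n).round(1),
            "postmenopausal": rng.random(n) < 0.93,
            "avulsion": rng.choice(AVULSION_LEVELS, size=n, p=[0.47, 0.13, 0.40]),
        }
    )

    return CohortTable(
        participant_ids=[f"P{i + 1:02d}" for i in range(n)],
        outcomes=outcomes,
        measurements=data,
        baseline=baseline,
    )
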