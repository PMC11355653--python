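"""The measurement grid: anatomical parameter x manoeuvre x pessary condition.

Eight pelvic-floor parameters are measured on dynamic MRI at three
manoeuvres (rest, contraction, Valsalva).  Six of them are measured under
four pessary conditions (no pessary, ring, ring with support, Falk); the
sacrococcygeal straight length and the pubococcygeal-sacral angle are
measured only without a pessary.  The full grid therefore holds
6 * 3 * 4 + 2 * 3 * 1 = 78 distinct variables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache


class Parameter(str, enum.Enum):
    PCL_LENGTH = "PCL_length"
    TVL = "TVL"
    CL = "CL"
    PUBOCOCCYGEAL_ANGLE = "pubococcygeal_angle"
    SACROCOCCYGEAL_ANGLE = "sacrococcygeal_angle"
    SACROCOCCYGEAL_STRAIGHT_LENGTH = "sacrococcygeal_straight_length"
    PUBOCOCCYGEAL_SACRAL_ANGLE = "pubococcygeal_sacral_angle"
    LHA = "LHA"


class Manoeuvre(str, enum.Enum):
    REST = "rest"
    CONTRACTION = "contraction"
    VALSALVA = "valsalva"


class Pessary(str, enum.Enum):
    NONE = "none"
    RING = "ring"
    RING_SUPPORT = "ring_support"
    FALK = "falk"


#: Parameters assessed only without a pessary.
NO_PESSARY_ONLY = frozenset(
    {Parameter.SACROCOCCYGEAL_STRAIGHT_LENGTH, Parameter.PUBOCOCCYGEAL_SACRAL_ANGLE}
)

#: Angle-valued parameters (degrees); the rest are lengths (cm) except LHA (cm^2).
ANGLE_PARAMETERS = frozenset(
    {
        Parameter.PUBOCOCCYGEAL_ANGLE,
        Parameter.SACROCOCCYGEAL_ANGLE,
        Parameter.PUBOCOCCYGEAL_SACRAL_ANGLE,
    }
)

#: Column-name separator for `parameter__manoeuvre__pessary`; double underscore
#: so multi-word parameter names parse unambiguously.
SEP = "__"


@dataclass(frozen=True, order=False)
class VariableKey:
    """Identity of one measurement: parameter x manoeuvre x pessary condition."""

    parameter: Parameter
    manoeuvre: Manoeuvre
    pessary: Pessary

    def __post_init__(self) -> None:
        if self.parameter in NO_PESSARY_ONLY and self.pessary is not Pessary.NONE:
            raise ValueError(
                f"{self.parameter.value} is assessed only without a pessary, "
                f"got pessary={self.pessary.value!r}"
            )

    @property
    def column(self) -> str:
        """Canonical CSV column name, `parameter__manoeuvre__pessary`."""
        return SEP.join(
            (self.parameter.value, self.manoeuvre.value, self.pessary.value)
        )

    @classmethod
    def from_column(cls, name: str) -> "VariableKey":
        parts = name.split(SEP)
        if len(parts) != 3:
            raise ValueError(f"malformed variable column name: {name!r}")
        try:
            return cls(Parameter(parts[0]), Manoeuvre(parts[1]), Pessary(parts[2]))
        except ValueError as exc:
            raise ValueError(f"invalid variable column name {name!r}: {exc}") from exc

    def sort_index(self) -> tuple[int, int, int]:
        params = list(Parameter)
        mans = list(Manoeuvre)
        pess = list(Pessary)
        return (
            params.index(self.parameter),
            mans.index(self.manoeuvre),
            pess.index(self.pessary),
        )

    def __lt__(self, other: "VariableKey") -> bool:
        return self.sort_index() < other.sort_index()

    def __str__(self) -> str:
        return self.column


@lru_cache(maxsize=1)
def variable_grid() -> tuple[VariableKey, ...]:
    """Every valid measurement key exactly once, in canonical order.

    Canonical order is (parameter, manoeuvre, pessary), each in enum
    declaration order.  The grid has exactly 78 members.
    """
    keys: list[VariableKey] = []
    for parameter in Parameter:
        pessaries = (Pessary.NONE,) if parameter in NO_PESSARY_ONLY else tuple(Pessary)
        for manoeuvre in Manoeuvre:
            for pessary in pessaries:
                keys.append(VariableKey(parameter, manoeuvre, pessary))
    return tuple(keys)


def conditions_for(parameter: Parameter) -> tuple[VariableKey, ...]:
    """All grid keys belonging to one anatomical parameter (3 or 12 keys)."""
    return tuple(k for k in variable_grid() if k.parameter is parameter)
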