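"""Closed-form assay quantifications: 2^-ddCt qPCR and dual-luciferase ratios."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .errors import InputError

__all__ = [
    "QpcrSample",
    "RelativeExpression",
    "LuciferaseReading",
    "ddct_fold_change",
    "luciferase_relative_activity",
]


@dataclass(frozen=True)
class QpcrSample:
    """One well: target and reference Ct (cycle-threshold) values."""

    ct_target: float
    ct_reference: float
    group: str = ""

    def __post_init__(self) -> None:
        import math

        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(ct):
                raise InputError(f"{name} must be finite, got {ct}")
            if not 0 < ct < 45:
                warnings.warn(
                    f"{name}={ct} outside the typical qPCR range (0, 45)",
                    stacklevel=3,
                )


@dataclass(frozen=True)
class RelativeExpression:
    delta_ct_treatment: float
    delta_ct_control: float
    delta_delta_ct: float
    fold_change: float


@dataclass(frozen=True)
class LuciferaseReading:
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.firefly <= 0:
            raise InputError(f"firefly luminescence must be positive, got {self.firefly}")
        if self.renilla <= 0:
            raise InputError(f"renilla luminescence must be positive, got {self.renilla}")


def _mean(values: list[float]) -> float:
    return sum(values) / len(values)


def ddct_fold_change(
    treatment: Iterable[QpcrSample], control: Iterable[QpcrSample]
) -> RelativeExpression:
    """Relative quantification by the 2^-ddCt rule.

    Per group, dCt = mean(target Ct) - mean(reference Ct); ddCt is the
    treatment-minus-control difference of the group dCt values and the fold
    change is ``2 ** (-ddCt)`` (amplification efficiency fixed at 2).
    """
    treatment = list(treatment)
    control = list(control)
    if not treatment or not control:
        raise InputError("both treatment and control need at least one sample")
    d_treat = _mean([s.ct_target for s in treatment]) - _mean(
        [s.ct_reference for s in treatment]
    )
    d_ctrl = _mean([s.ct_target for s in control]) - _mean(
        [s.ct_reference for s in control]
    )
    ddct = d_treat - d_ctrl
    return RelativeExpression(
        delta_ct_treatment=d_treat,
        delta_ct_control=d_ctrl,
        delta_delta_ct=ddct,
        fold_change=2.0 ** (-ddct),
    )


def luciferase_relative_activity(
    sample: LuciferaseReading, reference: LuciferaseReading
) -> float:
    """Firefly/Renilla ratio of `sample`, normalized to that of `reference`."""
    return (sample.firefly / sample.renilla) / (reference.firefly / reference.renilla)
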