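"""Relative qPCR quantification: 2^-ddCt expression and ChIP fold enrichment.

Both utilities assume a doubling per cycle (amplification efficiency 2, the
Livak assumption); efficiency-corrected variants are out of scope. Because
everything is a power of two in Ct differences, adding a constant to every
Ct value of a plate leaves the results unchanged, and log2 of every output
is exactly linear in Ct differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "QpcrSample",
    "ChipMeasurement",
    "DdctResult",
    "QuantificationError",
    "ddct_fold_change",
    "chip_fold_enrichment",
    "chip_percent_input",
]


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class QpcrSample:
    """One qPCR well pair: target-gene Ct and reference-gene Ct.

    The reference gene (e.g. beta-actin) normalizes loading; ``group_label``
    distinguishes the treated and control conditions.
    """

    ct_target: float
    ct_reference: float
    group_label: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("ct_target", self.ct_target),
            ("ct_reference", self.ct_reference),
        ):
            if not math.isfinite(v) or v <= 0:
                raise QuantificationError(
                    f"{name} must be positive and finite, got {v}"
                )

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class ChipMeasurement:
    """One ChIP-qPCR promoter measurement: IP Ct against a control Ct.

    ``control_kind`` records whether the control well is the IgG mock
    pulldown or a diluted input sample; ``promoter_label`` names the assayed
    promoter (e.g. p21, MyoG, Myh4).
    """

    ct_ip: float
    ct_control: float
    control_kind: str = "igg"
    promoter_label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_ip) and math.isfinite(self.ct_control)):
            raise QuantificationError("ChIP Ct values must be finite")
        if self.control_kind not in ("igg", "input"):
            raise QuantificationError(
                f"control_kind must be 'igg' or 'input', "
                f"got {self.control_kind!r}"
            )


@dataclass(frozen=True)
class DdctResult:
    fold_change: float
    ddct: float
    treatment_delta_ct_mean: float
    control_delta_ct_mean: float
    per_replicate_folds: tuple[float, ...]


def ddct_fold_change(
    treatment: Sequence[QpcrSample], control: Sequence[QpcrSample]
) -> DdctResult:
    """Relative expression of the treatment group by the 2^-ddCt method.

    dCt = ct_target - ct_reference per sample; ddCt is the difference of
    group-mean dCt values (treatment minus control); the fold change is
    2^-ddCt. Per-replicate folds 2^-(dCt_i - mean dCt control) are returned
    so callers can report dispersion.
    """
    if not treatment or not control:
        raise QuantificationError("both groups need at least one replicate")
    t_dct = np.array([s.delta_ct for s in treatment])
    c_dct = np.array([s.delta_ct for s in control])
    ddct = float(t_dct.mean() - c_dct.mean())
    per_rep = tuple(float(2.0 ** -(d - c_dct.mean())) for d in t_dct)
    return DdctResult(
        fold_change=float(2.0 ** -ddct),
        ddct=ddct,
        treatment_delta_ct_mean=float(t_dct.mean()),
        control_delta_ct_mean=float(c_dct.mean()),
        per_replicate_folds=per_rep,
    )


def chip_fold_enrichment(m: ChipMeasurement) -> float:
    """Fold enrichment of the IP over its control well: 2^(ct_control - ct_ip).

    Values above 1 mean the IP recovered more promoter DNA than the control
    pulldown; log2 of the result is exactly the Ct difference.
    """
    return float(2.0 ** (m.ct_control - m.ct_ip))


def chip_percent_input(m: ChipMeasurement, input_fraction: float = 0.01) -> float:
    """Percent-input alternative: 100 x 2^(adjusted input Ct - IP Ct).

    ``input_fraction`` is the fraction of chromatin the input well
    represents (1% by default); its Ct is first shifted down by
    log2(1/input_fraction) to stand for undiluted input.
    """
    if m.control_kind != "input":
        raise QuantificationError(
            "percent-input needs a measurement with control_kind='input'"
        )
    if not 0 < input_fraction <= 1:
        raise QuantificationError("input_fraction must be in (0, 1]")
    adjusted = m.ct_control - math.log2(1.0 / input_fraction)
    return float(100.0 * 2.0 ** (adjusted - m.ct_ip))
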