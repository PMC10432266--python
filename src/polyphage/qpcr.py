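"""Scalar quantitation formulas: comparative-CT, viral load, RLU, screen calls.

The comparative-CT (delta-delta-Ct) model assumes an amplification efficiency
of exactly 2 per cycle (no standard-curve correction), so a one-cycle shift
corresponds to a twofold change in template.  Technical replicates are
averaged on the Ct scale before exponentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CtRecord",
    "ReporterReading",
    "mean_ct",
    "fold_change_ddct",
    "relative_viral_load",
    "induction_ratio",
    "rlu",
    "screen_hit_call",
]


@dataclass(frozen=True)
class CtRecord:
    sample: str
    target: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"Ct must be finite and > 0, got {self.ct}")


@dataclass(frozen=True)
class ReporterReading:
    condition: str
    bioluminescence: float
    od600: float


def mean_ct(cts: Iterable[float] | float) -> float:
    """Average replicate Ct values on the Ct scale (a scalar passes through)."""
    arr = np.atleast_1d(np.asarray(cts, dtype=float))
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValueError("Ct values must be finite and non-empty")
    return float(arr.mean())


def fold_change_ddct(
    ct_target_trt: float | Sequence[float],
    ct_ref_trt: float | Sequence[float],
    ct_target_ctl: float | Sequence[float],
    ct_ref_ctl: float | Sequence[float],
) -> float:
    """Comparative-CT fold change, 2**(-ddCt).

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control);
    replicate Ct lists are averaged before exponentiation.  The reference is
    typically a housekeeping gene such as rpoB.
    """
    ddct = (mean_ct(ct_target_trt) - mean_ct(ct_ref_trt)) - (
        mean_ct(ct_target_ctl) - mean_ct(ct_ref_ctl)
    )
    return float(2.0 ** (-ddct))


def relative_viral_load(
    ct_induced: float | Sequence[float], ct_uninduced: float | Sequence[float]
) -> float:
    """Fold change of phage DNA in an induced vs an uninduced sample.

    2**(Ct_uninduced - Ct_induced) with the same primer set on both samples;
    an induced sample amplifying 7.13 cycles earlier is a ~140-fold increase.
    """
    return float(2.0 ** (mean_ct(ct_uninduced) - mean_ct(ct_induced)))


def induction_ratio(load_a: float, load_b: float) -> float:
    """Ratio of two relative viral loads (e.g. one phage under two inducers)."""
    if load_a <= 0 or load_b <= 0:
        raise ValueError("viral loads must be positive")
    return load_a / load_b


def rlu(reading: ReporterReading) -> float:
    """Relative light units: bioluminescence divided by OD600."""
    if reading.od600 <= 0:
        raise ValueError(f"od600 must be positive, got {reading.od600}")
    return reading.bioluminescence / reading.od600


def screen_hit_call(
    target_fold: float,
    lambda_fold: float,
    growth_decline_target: bool = False,
    growth_decline_lambda: bool = False,
    threshold: float = 2.0,
) -> str:
    """Classify a screening compound by the twofold specificity rule.

    A compound is a ``specific_hit`` when it triggers the target-phage arm
    (reporter fold > threshold, or growth decline in the target strain) but
    not the lambda control arm; ``nonspecific`` when both arms trigger;
    ``none`` otherwise.
    """
    if target_fold < 0 or lambda_fold < 0:
        raise ValueError("fold changes must be non-negative")
    target_arm = target_fold > threshold or growth_decline_target
    lambda_arm = lambda_fold > threshold or growth_decline_lambda
    if target_arm and not lambda_arm:
        return "specific_hit"
    if target_arm and lambda_arm:
        return "nonspecific"
    return "none"
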