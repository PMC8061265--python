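"""Copy-number estimation from droplet digital PCR partition counts.

A ddPCR reaction partitions the template into ~20,000 nanoliter droplets.
Under Poisson occupancy the fraction of negative droplets is exp(-lambda),
so the mean copies per droplet is recovered from the zero class:

    lambda = -ln(n_negative / (n_positive + n_negative))

CNV is the target/control concentration ratio of a sample divided by the
same ratio in the calibrator line, cancelling droplet volume and template
mass. Cross-platform agreement (qPCR vs ddPCR vs TaqMan) is measured by
Pearson correlation on log2 folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    CceampError,
    EmptyWellError,
    NoControlSignalError,
    SaturationError,
)


@dataclass(frozen=True)
class DropletCount:
    """Positive/negative droplet counts for one well."""

    sample_id: str
    gene_id: str
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise CceampError("droplet counts must be non-negative")


@dataclass(frozen=True)
class PoissonEstimate:
    """Mean copies per droplet with a 95% confidence interval."""

    lam: float
    ci_low: float
    ci_high: float


def estimate_lambda(count: DropletCount) -> PoissonEstimate:
    """Poisson zero-class estimate of copies per droplet.

    The 95% CI is a Wilson score interval on the negative fraction pushed
    through -ln, which keeps the interval inside [0, inf) and behaves well
    at the extremes (all-negative wells give ci_low = lambda = 0).
    """
    total = count.n_positive + count.n_negative
    if total == 0:
        raise EmptyWellError(f"{count.sample_id}/{count.gene_id}: no droplets")
    if count.n_negative == 0:
        raise SaturationError(
            f"{count.sample_id}/{count.gene_id}: all droplets positive, "
            "too concentrated to quantify"
        )
    neg_frac = count.n_negative / total
    lam = float(max(-np.log(neg_frac), 0.0))
    lo_neg, hi_neg = proportion_confint(count.n_negative, total, method="wilson")
    # high negative fraction -> low lambda
    ci_low = -np.log(min(hi_neg, 1.0)) if hi_neg > 0 else np.inf
    ci_high = -np.log(lo_neg) if lo_neg > 0 else np.inf
    ci_low = min(max(float(ci_low), 0.0), lam)
    ci_high = max(float(ci_high), lam)
    return PoissonEstimate(lam, ci_low, ci_high)


def cnv_from_droplets(
    sample_target: DropletCount,
    sample_control: DropletCount,
    calibrator_target: DropletCount,
    calibrator_control: DropletCount,
) -> float:
    """Relative copy number of target vs control, normalized to calibrator.

    fold = (lambda_target/lambda_control)_sample
         / (lambda_target/lambda_control)_calibrator
    """
    lam = {
        "sample_target": estimate_lambda(sample_target).lam,
        "sample_control": estimate_lambda(sample_control).lam,
        "calibrator_target": estimate_lambda(calibrator_target).lam,
        "calibrator_control": estimate_lambda(calibrator_control).lam,
    }
    if lam["sample_control"] == 0 or lam["calibrator_control"] == 0:
        raise NoControlSignalError("control well has zero estimated concentration")
    if lam["calibrator_target"] == 0:
        raise NoControlSignalError("calibrator target well has zero concentration")
    sample_ratio = lam["sample_target"] / lam["sample_control"]
    calib_ratio = lam["calibrator_target"] / lam["calibrator_control"]
    return float(sample_ratio / calib_ratio)


def concordance(
    folds_a: Sequence[float], folds_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of two fold vectors paired by individual.

    Computed on log2-transformed folds: copy numbers span more than an
    order of magnitude and a raw-scale correlation would be dominated by
    the few highest-copy individuals.

    Returns (r, two-sided p-value).
    """
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if a.shape != b.shape:
        raise CceampError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise CceampError(f"need >= 3 pairs, got {a.size}")
    if np.any(a <= 0) or np.any(b <= 0):
        raise CceampError("folds must be positive for log2 transform")
    r, p = stats.pearsonr(np.log2(a), np.log2(b))
    return float(r), float(p)
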