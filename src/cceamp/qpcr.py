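"""Efficiency-corrected relative quantification of gene copy number by qPCR.

Copy-number variation (CNV) is expressed as relative genomic DNA quantity of
a target gene versus single-copy reference genes, normalized to a fully
susceptible calibrator line. The fold change for one reference gene is the
efficiency-corrected ratio

    fold = E_target ** dCq_target / E_ref ** dCq_ref

where ``dCq = Cq(calibrator) - Cq(sample)`` and ``E`` is the per-gene
amplification efficiency (fold of template per cycle, 2.0 = perfect
doubling) estimated from a dilution series. Folds against multiple
reference genes are combined by geometric mean.

The module also supports dual-color TaqMan duplex wells (FAM target probe +
HEX control probe in one reaction) and Cq calling from raw amplification
traces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CceampError,
    FailedWellError,
    InsufficientCurveError,
    InvalidEfficiencyError,
    InvalidThresholdError,
    InvertedSeriesError,
    NoReferenceError,
    TableFormatError,
)

logger = logging.getLogger(__name__)

#: Valid range for amplification efficiency, fold per cycle. The upper bound
#: tolerates slightly >100% apparent efficiency from pipetting artifacts.
EFFICIENCY_RANGE = (1.0, 2.2)

#: Efficiency assumed when no standard curve is available for a gene.
DEFAULT_EFFICIENCY = 2.0

CQ_COLUMNS = ["sample_id", "gene_id", "gene_role", "dye", "replicate", "cq"]


@dataclass(frozen=True)
class StandardCurve:
    """Serial-dilution calibration series for one amplicon.

    ``points`` are ``(log10_dilution, cq)`` pairs; log10_dilution is 0 for
    the undiluted pool and negative for dilutions.
    """

    gene_id: str
    points: Sequence[tuple[float, float]]


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Amplification efficiency fitted from a standard curve."""

    gene_id: str
    slope: float  # cycles per log10 dilution unit, negative
    efficiency: float  # fold per cycle, in (1.0, 2.2]
    r_squared: float


@dataclass(frozen=True)
class DuplexResult:
    """Outcome of a single TaqMan duplex well."""

    fold: float
    flag: str | None = None


def _check_efficiency(e: float, label: str = "efficiency") -> None:
    lo, hi = EFFICIENCY_RANGE
    if not (lo < e <= hi):
        raise InvalidEfficiencyError(
            f"{label} {e!r} outside plausible range ({lo}, {hi}]"
        )


def fit_standard_curve(curve: StandardCurve) -> EfficiencyEstimate:
    """Fit Cq ~ log10(dilution) by least squares and derive efficiency.

    Efficiency is ``10 ** (-1/slope)``; a perfectly doubling assay has slope
    -log2(10) = -3.3219 cycles per decade and efficiency 2.0.

    Raises
    ------
    InsufficientCurveError
        Fewer than three distinct dilution levels.
    InvertedSeriesError
        Non-negative fitted slope (Cq must increase with dilution).
    """
    pts = np.asarray(curve.points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InsufficientCurveError("curve points must be (log10_dilution, cq) pairs")
    levels = np.unique(pts[:, 0])
    if levels.size < 3:
        raise InsufficientCurveError(
            f"{curve.gene_id}: {levels.size} distinct dilution levels, need >= 3"
        )
    fit = stats.linregress(pts[:, 0], pts[:, 1])
    if fit.slope >= 0:
        raise InvertedSeriesError(
            f"{curve.gene_id}: non-negative slope {fit.slope:.3f}; "
            "Cq should rise as template is diluted"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope)
    return EfficiencyEstimate(
        gene_id=curve.gene_id,
        slope=float(fit.slope),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue) ** 2,
    )


def pfaffl_fold(
    e_target: float, dcq_target: float, e_reference: float, dcq_reference: float
) -> float:
    """Efficiency-corrected relative fold for one target/reference pair.

    ``dcq`` is Cq(calibrator) - Cq(sample): positive when the sample carries
    more template than the calibrator.
    """
    _check_efficiency(e_target, "target efficiency")
    _check_efficiency(e_reference, "reference efficiency")
    return e_target**dcq_target / e_reference**dcq_reference


def combine_references(folds_per_reference: Sequence[float]) -> float:
    """Geometric mean of per-reference folds (multi-reference normalization)."""
    if len(folds_per_reference) == 0:
        raise NoReferenceError("no reference fold to combine")
    arr = np.asarray(folds_per_reference, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise NoReferenceError(f"folds must be positive finite, got {list(arr)}")
    return float(np.exp(np.mean(np.log(arr))))


def _efficiency_of(efficiencies: Mapping[str, object] | None, gene: str) -> float:
    if efficiencies is not None and gene in efficiencies:
        est = efficiencies[gene]
        e = est.efficiency if isinstance(est, EfficiencyEstimate) else float(est)
    else:
        logger.warning(
            "no standard curve for gene %s: assuming efficiency %.1f",
            gene,
            DEFAULT_EFFICIENCY,
        )
        e = DEFAULT_EFFICIENCY
    _check_efficiency(e, f"efficiency of {gene}")
    return e


def quantify(
    measurements: pd.DataFrame,
    efficiencies: Mapping[str, object] | None,
    calibrator_samples: Iterable[str],
    targets: Iterable[str],
    references: Iterable[str],
) -> pd.DataFrame:
    """Relative quantification of each sample x target versus the calibrator.

    Technical replicates are averaged on the Cq scale. The calibrator Cq for
    each gene is the mean over calibrator samples. Per sample and target the
    fold is the geometric mean over reference genes of the
    efficiency-corrected ratio. On noiseless input the fold equals the
    generating truth exactly.

    Parameters
    ----------
    measurements
        Long table with columns sample_id, gene_id, gene_role, dye,
        replicate, cq (NaN = undetermined).
    efficiencies
        Mapping gene_id -> EfficiencyEstimate or float; missing genes fall
        back to efficiency 2.0 with a logged warning.
    calibrator_samples, targets, references
        Sample and gene id sets defining the design.

    Returns
    -------
    DataFrame with columns sample_id, gene_id, fold, n_replicates, cv, flag.
    Samples lacking every reference gene are skipped with a logged warning.
    Targets with no determined Cq in a non-calibrator sample are reported as
    fold 0 flagged ``no-target-amplification``.
    """
    missing = [c for c in CQ_COLUMNS if c not in measurements.columns]
    if missing:
        raise TableFormatError(f"Cq table missing columns: {missing}")
    calibrators = set(calibrator_samples)
    targets = list(targets)
    references = list(references)
    if not calibrators:
        raise NoReferenceError("calibrator sample set is empty")
    if not references:
        raise NoReferenceError("reference gene set is empty")

    det = measurements.dropna(subset=["cq"])
    # mean Cq per sample x gene over determined replicates
    mean_cq = det.groupby(["sample_id", "gene_id"])["cq"].agg(["mean", "count"])

    cal_cq: dict[str, float] = {}
    for gene in targets + references:
        vals = [
            mean_cq.loc[(s, gene), "mean"]
            for s in calibrators
            if (s, gene) in mean_cq.index
        ]
        if not vals:
            raise NoReferenceError(f"no calibrator Cq for gene {gene}")
        cal_cq[gene] = float(np.mean(vals))

    eff = {g: _efficiency_of(efficiencies, g) for g in targets + references}

    rows = []
    for sample in measurements["sample_id"].unique():
        ref_dcq = {}
        for ref in references:
            if (sample, ref) in mean_cq.index:
                ref_dcq[ref] = cal_cq[ref] - mean_cq.loc[(sample, ref), "mean"]
        if not ref_dcq:
            logger.warning(
                "sample %s has no determined Cq for any reference gene: skipped",
                sample,
            )
            continue
        for gene in targets:
            flag = None
            if (sample, gene) not in mean_cq.index:
                if sample in calibrators:
                    continue
                rows.append((sample, gene, 0.0, 0, np.nan, "no-target-amplification"))
                continue
            cq_t, n_rep = mean_cq.loc[(sample, gene)]
            dcq_t = cal_cq[gene] - cq_t
            per_ref = [
                pfaffl_fold(eff[gene], dcq_t, eff[ref], dcq)
                for ref, dcq in ref_dcq.items()
            ]
            fold = combine_references(per_ref)
            # replicate-level dispersion: fold recomputed per target replicate
            rep_cqs = det.loc[
                (det["sample_id"] == sample) & (det["gene_id"] == gene), "cq"
            ].to_numpy()
            if rep_cqs.size >= 2:
                rep_folds = [
                    combine_references(
                        [
                            pfaffl_fold(eff[gene], cal_cq[gene] - c, eff[r], d)
                            for r, d in ref_dcq.items()
                        ]
                    )
                    for c in rep_cqs
                ]
                cv = float(np.std(rep_folds, ddof=1) / np.mean(rep_folds))
            else:
                cv = np.nan
            rows.append((sample, gene, float(fold), int(n_rep), cv, flag))
    return pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "fold", "n_replicates", "cv", "flag"]
    )


def duplex_quantify(
    fam_cq: float,
    hex_cq: float,
    e_fam: float,
    e_hex: float,
    calibrator_fam_cq: float,
    calibrator_hex_cq: float,
) -> DuplexResult:
    """Relative fold from a single dual-color TaqMan duplex well.

    FAM reads the target probe, HEX the single-copy control probe. An
    undetermined FAM signal with determined HEX is a valid negative well
    (fold 0, flagged); an undetermined HEX signal means the reaction failed.
    """
    if hex_cq is None or (isinstance(hex_cq, float) and math.isnan(hex_cq)):
        raise FailedWellError("undetermined HEX (control) signal: failed well")
    if fam_cq is None or (isinstance(fam_cq, float) and math.isnan(fam_cq)):
        return DuplexResult(0.0, "no-target-amplification")
    fold = pfaffl_fold(
        e_fam, calibrator_fam_cq - fam_cq, e_hex, calibrator_hex_cq - hex_cq
    )
    return DuplexResult(float(fold), None)


def call_cq(
    trace: Sequence[float],
    baseline_window: tuple[int, int] = (3, 15),
    threshold: float | None = None,
) -> float | None:
    """Quantification cycle from a raw amplification trace.

    The baseline (mean fluorescence over ``baseline_window``, cycles
    1-based inclusive) is subtracted; the default threshold is 10 standard
    deviations of the baseline noise. Cq is the linearly interpolated cycle
    of the first upward threshold crossing, or None (undetermined) if the
    trace never crosses.
    """
    f = np.asarray(trace, dtype=float)
    if f.size < 40:
        raise CceampError(f"trace has {f.size} cycles, need >= 40")
    lo, hi = baseline_window
    if not (1 <= lo < hi <= f.size):
        raise InvalidThresholdError(f"baseline window {baseline_window} out of range")
    base = f[lo - 1 : hi]
    base_mean = float(np.mean(base))
    base_sd = float(np.std(base, ddof=1))
    signal = f - base_mean
    thr = 10.0 * base_sd if threshold is None else float(threshold)
    if thr <= base_sd:
        raise InvalidThresholdError(
            f"threshold {thr:g} is at or below baseline noise (SD {base_sd:g})"
        )
    for i in range(1, signal.size):
        if signal[i - 1] < thr <= signal[i] and signal[i] > signal[i - 1]:
            frac = (thr - signal[i - 1]) / (signal[i] - signal[i - 1])
            return float(i + frac)  # cycle numbers are 1-based
    return None
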