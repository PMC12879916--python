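"""Species-unspecific online isotope dilution: ratio traces to Se mass flow.

A constant flow of isotopically enriched spike (here 99.9 % ⁷⁴Se) is merged
with the column effluent before the nebulizer.  Any natural-composition Se
species eluting at time *t* perturbs the measured reference/spike intensity
ratio R_m(t) = I₇₈/I₇₄ away from the pure-spike ratio, and the sample mass
flow follows from the online IDA equation

    MF_s(t) = MF_sp · (Aw_nat/Aw_sp) · (a_sp,74/a_nat,78)
              · (R_m(t) − R_sp) / (1 − R_m(t)·R_nat)

with R_sp = a_sp,78/a_sp,74 and R_nat = a_nat,74/a_nat,78.  The ratio is
insensitive to drift and matrix effects because both channels scale
together; MF_s vanishes exactly at R_m = R_sp (no analyte) and has a pole
at R_m = 1/R_nat (spike fully diluted), where points are masked rather than
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chrom_io import IDAParameters, IsotopeChromatogram

#: Points where |1 − R_m·R_nat| falls below this are masked as at-the-pole.
DENOMINATOR_TOL = 1e-9

#: ⁷⁴Se channel counts-per-second floor below which the ratio is undefined.
DEFAULT_COUNT_THRESHOLD = 10.0


@dataclass
class RatioTrace:
    """⁷⁸Se/⁷⁴Se intensity ratio versus time with a validity mask."""

    time_s: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.time_s.shape == self.ratio.shape == self.valid.shape):
            raise ValueError("time, ratio and mask must have equal length")

    @property
    def time_min(self) -> np.ndarray:
        return self.time_s / 60.0


@dataclass
class MassFlowTrace:
    """Natural-composition sample Se mass flow (ng/min) versus time."""

    time_s: np.ndarray
    mass_flow_ng_min: np.ndarray
    valid: np.ndarray
    pole_points: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.mass_flow_ng_min = np.asarray(self.mass_flow_ng_min, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (
            self.time_s.shape == self.mass_flow_ng_min.shape == self.valid.shape
        ):
            raise ValueError("time, mass flow and mask must have equal length")

    @property
    def time_min(self) -> np.ndarray:
        return self.time_s / 60.0


def _moving_average(x: np.ndarray, points: int) -> np.ndarray:
    if points <= 1:
        return x
    if points % 2 == 0:
        raise ValueError("smoothing_points must be odd so the window is centered")
    kernel = np.ones(points) / points
    # reflect-pad so the trace keeps its length and edges stay unbiased
    half = points // 2
    padded = np.concatenate([x[half:0:-1], x, x[-2 : -2 - half : -1]])
    return np.convolve(padded, kernel, mode="valid")


def ratio_trace(
    chrom: IsotopeChromatogram,
    smoothing_points: int = 1,
    count_threshold: float = DEFAULT_COUNT_THRESHOLD,
    reference_isotope: int = 78,
    spike_isotope: int = 74,
) -> RatioTrace:
    """Pointwise reference/spike intensity ratio with optional smoothing.

    Both channels are smoothed with the same centered moving average before
    dividing; ``smoothing_points=1`` is the raw pointwise ratio.  Points
    where the spike channel sits below ``count_threshold`` cps are masked.
    """
    i_ref = chrom.intensities[reference_isotope]
    i_spk = chrom.intensities[spike_isotope]
    i_ref = _moving_average(i_ref, smoothing_points)
    i_spk = _moving_average(i_spk, smoothing_points)
    valid = i_spk > count_threshold
    if not valid.any():
        raise ValueError(
            "no spike signal: every point of the spike channel is below "
            f"{count_threshold} cps"
        )
    ratio = np.divide(i_ref, i_spk, out=np.zeros_like(i_ref), where=valid)
    return RatioTrace(time_s=chrom.time_s, ratio=ratio, valid=valid)


def mass_bias_correct(trace: RatioTrace, factor_per_amu: float) -> RatioTrace:
    """Undo a linear mass-bias of ``factor_per_amu`` across the Δm = 4 gap.

    A detector bias multiplying the measured ratio by (1 + f·Δm) is removed
    by dividing it back out; factor 0 is the identity.
    """
    if not np.isfinite(factor_per_amu):
        raise ValueError("mass-bias factor must be finite")
    scale = 1.0 / (1.0 + factor_per_amu * 4.0)
    return RatioTrace(
        time_s=trace.time_s, ratio=trace.ratio * scale, valid=trace.valid.copy()
    )


def mass_flow(
    trace: RatioTrace,
    ida: IDAParameters,
    denominator_tol: float = DENOMINATOR_TOL,
) -> MassFlowTrace:
    """Convert a ratio trace into a sample-Se mass-flow chromatogram.

    Invalid ratio points propagate as masked.  Points at the natural-ratio
    pole (denominator within ``denominator_tol`` of zero) are masked and
    counted on the result rather than silently zeroed.
    """
    r_sp = ida.ratio_spike
    r_nat = ida.ratio_natural_inverse
    prefactor = (
        ida.spike_mass_flow_ng_min
        * (ida.atomic_weight_natural / ida.atomic_weight_spike)
        * (
            ida.spike_abundances[ida.spike_isotope]
            / ida.natural_abundances[ida.reference_isotope]
        )
    )
    denom = 1.0 - trace.ratio * r_nat
    at_pole = trace.valid & (np.abs(denom) < denominator_tol)
    valid = trace.valid & ~at_pole
    mf = np.zeros_like(trace.ratio)
    np.divide(trace.ratio - r_sp, denom, out=mf, where=valid)
    mf[valid] *= prefactor
    return MassFlowTrace(
        time_s=trace.time_s,
        mass_flow_ng_min=mf,
        valid=valid,
        pole_points=int(at_pole.sum()),
    )


def quantify_chromatogram(
    chrom: IsotopeChromatogram,
    ida: IDAParameters,
    smoothing_points: int = 1,
    mass_bias_per_amu: float = 0.0,
) -> MassFlowTrace:
    """Chromatogram -> ratio -> (optional bias correction) -> mass flow."""
    trace = ratio_trace(
        chrom,
        smoothing_points=smoothing_points,
        reference_isotope=ida.reference_isotope,
        spike_isotope=ida.spike_isotope,
    )
    if mass_bias_per_amu != 0.0:
        trace = mass_bias_correct(trace, mass_bias_per_amu)
    return mass_flow(trace, ida)


__all__ = [
    "RatioTrace",
    "MassFlowTrace",
    "ratio_trace",
    "mass_bias_correct",
    "mass_flow",
    "quantify_chromatogram",
    "DENOMINATOR_TOL",
    "DEFAULT_COUNT_THRESHOLD",
]
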