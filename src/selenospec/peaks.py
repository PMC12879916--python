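"""Baseline handling and window integration of mass-flow chromatograms.

Peak areas of a mass-flow trace are absolute Se masses, so quantification
reduces to a baseline estimate over a blank region and a trapezoidal
integral of (mass flow − baseline) over each fixed retention window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chrom_io import SpeciesWindows
from .ida_quant import MassFlowTrace

#: Blank region of the 50-min run used for the baseline: after the
#: selenoalbumin peak, before re-equilibration.
DEFAULT_BLANK_WINDOW_MIN = (40.0, 48.0)

#: A window with more than this fraction of masked points is unreliable.
MASKED_FRACTION_LIMIT = 0.20


@dataclass(frozen=True)
class SpeciesAmount:
    """Integrated Se mass of one species in one injection."""

    species_name: str
    se_mass_ng: float
    window_min: tuple[float, float]
    baseline_ng_min: float
    raw_se_mass_ng: float
    clipped: bool = False
    unreliable: bool = False

    @property
    def flags(self) -> str:
        parts = [f for f, on in (("clipped", self.clipped), ("unreliable", self.unreliable)) if on]
        return ";".join(parts)


def estimate_baseline(
    mf: MassFlowTrace, blank_window_min: tuple[float, float] = DEFAULT_BLANK_WINDOW_MIN
) -> float:
    """Median mass flow (ng/min) over a blank window; robust to outliers."""
    lo, hi = blank_window_min
    sel = (mf.time_min >= lo) & (mf.time_min <= hi) & mf.valid
    if sel.sum() < 5:
        raise ValueError(
            f"blank window {lo}-{hi} min holds only {int(sel.sum())} valid points "
            "(need >= 5)"
        )
    return float(np.median(mf.mass_flow_ng_min[sel]))


def integrate_windows(
    mf: MassFlowTrace,
    windows: SpeciesWindows,
    baseline_ng_min: float = 0.0,
) -> list[SpeciesAmount]:
    """Trapezoidal Se mass (ng) per retention window after baseline removal.

    Negative integrals are clipped to zero at reporting, with the raw value
    retained and a flag set; windows where more than 20 % of points are
    masked are flagged unreliable.
    """
    t_min = mf.time_min
    start, end = windows.span
    if start < t_min[0] - 1e-9 or end > t_min[-1] + 1e-9:
        raise ValueError(
            f"windows span {start}-{end} min but trace covers "
            f"{t_min[0]:.2f}-{t_min[-1]:.2f} min"
        )
    amounts = []
    for name, lo, hi in windows:
        sel = (t_min >= lo) & (t_min <= hi)
        n_sel = int(sel.sum())
        masked_frac = 1.0 - (mf.valid[sel].sum() / n_sel) if n_sel else 1.0
        y = np.where(mf.valid, mf.mass_flow_ng_min, 0.0)[sel] - baseline_ng_min
        raw = float(np.trapezoid(y, t_min[sel]))
        clipped = raw < 0
        amounts.append(
            SpeciesAmount(
                species_name=name,
                se_mass_ng=max(raw, 0.0),
                window_min=(lo, hi),
                baseline_ng_min=baseline_ng_min,
                raw_se_mass_ng=raw,
                clipped=clipped,
                unreliable=masked_frac > MASKED_FRACTION_LIMIT,
            )
        )
    return amounts


def to_concentration(
    amounts: list[SpeciesAmount], sample_mass_g: float
) -> dict[str, float]:
    """ng Se/mL per species: mass normalised to sample mass, density 1 g/mL."""
    if not sample_mass_g > 0:
        raise ValueError("sample mass must be positive")
    return {a.species_name: a.se_mass_ng / sample_mass_g for a in amounts}


def amounts_frame(sample_id: str, amounts: list[SpeciesAmount], sample_mass_g: float) -> pd.DataFrame:
    """Per-sample species table row set: ``sample_id,species,se_ng,conc_ng_per_ml,flags``."""
    conc = to_concentration(amounts, sample_mass_g)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "species": [a.species_name for a in amounts],
            "se_ng": [a.se_mass_ng for a in amounts],
            "conc_ng_per_ml": [conc[a.species_name] for a in amounts],
            "flags": [a.flags for a in amounts],
        }
    )


__all__ = [
    "SpeciesAmount",
    "estimate_baseline",
    "integrate_windows",
    "to_concentration",
    "amounts_frame",
    "DEFAULT_BLANK_WINDOW_MIN",
    "MASKED_FRACTION_LIMIT",
]
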