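"""Chromatogram, retention-window and IDA-parameter I/O.

One text dialect is supported for chromatograms: comma-delimited with a
``time_s`` column followed by one column per monitored Se isotope mass
number (``time_s,74,76,77,78,80``).  Retention windows and isotope-dilution
parameters travel as YAML mappings.  Vendor exports are expected to be
pre-converted to this dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .constants import (
    MONITORED_ISOTOPES,
    SE_ATOMIC_WEIGHT,
    SE_ISOTOPE_MASSES,
    SE_NATURAL_ABUNDANCES,
)

logger = logging.getLogger(__name__)

_ABUNDANCE_TOL = 1e-6


@dataclass
class IsotopeChromatogram:
    """Multi-isotope ICP-MS time traces from one injection.

    Parameters
    ----------
    time_s
        Acquisition time in seconds, strictly increasing.
    intensities
        Mapping isotope mass number -> counts-per-second trace, all the
        same length as ``time_s``.
    sample_id
        Free-form identifier of the injection.
    injected_volume_ml
        Volume of serum injected (mL).
    sample_mass_g
        Mass of sample the final concentrations are normalised to (g).
    """

    time_s: np.ndarray
    intensities: dict[int, np.ndarray]
    sample_id: str = ""
    injected_volume_ml: float = 0.1
    sample_mass_g: float = 0.1000
    clamped_points: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.time_s.ndim != 1 or len(self.time_s) < 2:
            raise ValueError("time axis must be a 1-D array with >= 2 points")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time axis must be strictly increasing")
        missing = {74, 78} - set(self.intensities)
        if missing:
            raise ValueError(
                f"chromatogram must include the ratio isotopes 74 and 78; missing {sorted(missing)}"
            )
        self.intensities = {
            int(k): np.asarray(v, dtype=float) for k, v in self.intensities.items()
        }
        for iso, trace in self.intensities.items():
            if trace.shape != self.time_s.shape:
                raise ValueError(f"isotope {iso} trace length != time axis length")

    @property
    def isotopes(self) -> tuple[int, ...]:
        return tuple(sorted(self.intensities))

    @property
    def time_min(self) -> np.ndarray:
        return self.time_s / 60.0


@dataclass(frozen=True)
class SpeciesWindows:
    """Ordered, non-overlapping retention windows, minutes."""

    windows: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_name = None
        for name, start, end in self.windows:
            if not start < end:
                raise ValueError(f"window {name!r}: start {start} must precede end {end}")
            if start < prev_end:
                raise ValueError(
                    f"windows {prev_name!r} and {name!r} overlap ({start} < {prev_end})"
                )
            prev_end, prev_name = end, name

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.windows)

    @property
    def span(self) -> tuple[float, float]:
        return self.windows[0][1], self.windows[-1][2]


@dataclass(frozen=True)
class IDAParameters:
    """Everything the species-unspecific IDA mass-flow equation needs.

    Abundance vectors are atom fractions over isotope mass numbers and must
    each sum to one.  The spike atomic weight is recomputed from its
    abundances and checked against the declared value.
    """

    spike_concentration_ng_ml: float
    spike_flow_ml_min: float
    spike_abundances: dict[int, float]
    natural_abundances: dict[int, float] = field(
        default_factory=lambda: dict(SE_NATURAL_ABUNDANCES)
    )
    atomic_weight_natural: float = SE_ATOMIC_WEIGHT
    atomic_weight_spike: float | None = None
    reference_isotope: int = 78
    spike_isotope: int = 74

    def __post_init__(self) -> None:
        for label, vec in (
            ("spike", self.spike_abundances),
            ("natural", self.natural_abundances),
        ):
            total = sum(vec.values())
            if abs(total - 1.0) > _ABUNDANCE_TOL:
                raise ValueError(f"{label} abundances sum to {total}, expected 1")
        for iso in (self.reference_isotope, self.spike_isotope):
            if iso not in SE_ISOTOPE_MASSES:
                raise ValueError(f"unknown selenium isotope {iso}")
        implied = sum(
            a * SE_ISOTOPE_MASSES[iso] for iso, a in self.spike_abundances.items()
        )
        if self.atomic_weight_spike is None:
            object.__setattr__(self, "atomic_weight_spike", implied)
        elif abs(self.atomic_weight_spike - implied) > 0.01:
            raise ValueError(
                f"declared spike atomic weight {self.atomic_weight_spike} inconsistent "
                f"with abundances (implied {implied:.4f})"
            )

    @property
    def spike_mass_flow_ng_min(self) -> float:
        """Constant post-column spike mass flow, ng Se/min."""
        return self.spike_concentration_ng_ml * self.spike_flow_ml_min

    @property
    def ratio_spike(self) -> float:
        """Reference/spike-isotope ratio of the pure spike (R_sp)."""
        return (
            self.spike_abundances.get(self.reference_isotope, 0.0)
            / self.spike_abundances[self.spike_isotope]
        )

    @property
    def ratio_natural_inverse(self) -> float:
        """Spike/reference-isotope ratio of natural Se (R_nat = a74/a78)."""
        return (
            self.natural_abundances[self.spike_isotope]
            / self.natural_abundances[self.reference_isotope]
        )


def default_windows() -> SpeciesWindows:
    """Retention windows of the optimized 50-min serum separation.

    Elution order: glutathione peroxidase and unretained selenometabolites
    early (~3 and ~5 min), SELENOP at ~20 min, the SELENOW-containing
    fraction at ~25 min, selenoalbumin at ~31 min.
    """
    return SpeciesWindows(
        (
            ("GPx", 2.0, 4.0),
            ("SMT", 4.0, 8.0),
            ("SELENOP", 15.0, 23.0),
            ("SELENOW_plus_others", 23.0, 28.0),
            ("SeAlb", 28.0, 35.0),
        )
    )


def default_ida() -> IDAParameters:
    """Default online-IDA configuration: 99.9 % enriched ⁷⁴Se spike.

    The spike mass flow (100 ng/mL at 0.1 mL/min = 10 ng Se/min) keeps the
    ⁷⁴Se spike baseline within an order of magnitude of the tallest natural
    ⁷⁸Se peak for serum-level selenoprotein loads.
    """
    return IDAParameters(
        spike_concentration_ng_ml=100.0,
        spike_flow_ml_min=0.1,
        spike_abundances={74: 0.999, 78: 0.001},
    )


# --- chromatogram CSV -------------------------------------------------------


def read_chromatogram(path) -> IsotopeChromatogram:
    """Read a ``time_s,74,76,...`` CSV into a validated chromatogram.

    Negative intensities are clamped to zero; the number of clamped points
    is logged and kept on the returned object.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    iso_cols = [c for c in df.columns if c != "time_s" and str(c).strip().isdigit()]
    intensities = {}
    clamped = 0
    for col in iso_cols:
        trace = df[col].to_numpy(dtype=float)
        neg = trace < 0
        clamped += int(neg.sum())
        intensities[int(str(col).strip())] = np.where(neg, 0.0, trace)
    if clamped:
        logger.warning("%s: clamped %d negative intensity points to 0", path, clamped)
    time = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.diff(time) > 0):
        raise ValueError(f"{path}: time axis is not strictly increasing")
    return IsotopeChromatogram(
        time_s=time, intensities=intensities, sample_id=str(path), clamped_points=clamped
    )


def write_chromatogram(chrom: IsotopeChromatogram, path) -> None:
    cols = {"time_s": chrom.time_s}
    for iso in MONITORED_ISOTOPES:
        if iso in chrom.intensities:
            cols[str(iso)] = chrom.intensities[iso]
    for iso in chrom.isotopes:  # any extra monitored isotope
        cols.setdefault(str(iso), chrom.intensities[iso])
    pd.DataFrame(cols).to_csv(path, index=False)


# --- YAML configs -----------------------------------------------------------


def load_windows(path) -> SpeciesWindows:
    """Load retention windows from YAML: ``windows: [{species, start_min, end_min}]``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["windows"] if isinstance(doc, dict) else doc
    return SpeciesWindows(
        tuple(
            (str(e["species"]), float(e["start_min"]), float(e["end_min"]))
            for e in entries
        )
    )


def save_windows(windows: SpeciesWindows, path) -> None:
    doc = {
        "windows": [
            {"species": n, "start_min": s, "end_min": e} for n, s, e in windows
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_ida(path) -> IDAParameters:
    """Load IDA parameters from YAML (keys mirror :class:`IDAParameters`)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kwargs = dict(
        spike_concentration_ng_ml=float(doc["spike_concentration_ng_ml"]),
        spike_flow_ml_min=float(doc["spike_flow_ml_min"]),
        spike_abundances={int(k): float(v) for k, v in doc["spike_abundances"].items()},
    )
    if "natural_abundances" in doc:
        kwargs["natural_abundances"] = {
            int(k): float(v) for k, v in doc["natural_abundances"].items()
        }
    for key in ("atomic_weight_natural", "atomic_weight_spike"):
        if key in doc:
            kwargs[key] = float(doc[key])
    for key in ("reference_isotope", "spike_isotope"):
        if key in doc:
            kwargs[key] = int(doc[key])
    return IDAParameters(**kwargs)


def save_ida(ida: IDAParameters, path) -> None:
    doc = {
        "spike_concentration_ng_ml": ida.spike_concentration_ng_ml,
        "spike_flow_ml_min": ida.spike_flow_ml_min,
        "spike_abundances": {int(k): float(v) for k, v in ida.spike_abundances.items()},
        "natural_abundances": {
            int(k): float(v) for k, v in ida.natural_abundances.items()
        },
        "atomic_weight_natural": ida.atomic_weight_natural,
        "atomic_weight_spike": ida.atomic_weight_spike,
        "reference_isotope": ida.reference_isotope,
        "spike_isotope": ida.spike_isotope,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


__all__ = [
    "IsotopeChromatogram",
    "SpeciesWindows",
    "IDAParameters",
    "default_windows",
    "default_ida",
    "read_chromatogram",
    "write_chromatogram",
    "load_windows",
    "save_windows",
    "load_ida",
    "save_ida",
]
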