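"""Forward model of online-IDA multi-isotope ICP-MS chromatograms.

Fabricates the raw counts a triple-quadrupole ICP-MS would record during a
50-min serum selenoprotein separation with a constant post-column flow of
⁷⁴Se-enriched spike: each Se species elutes as a (by default Gaussian)
mass-flow peak of known integral, the spike adds a flat mass flow of
enriched composition, and each monitored isotope channel sees the sum
weighted by its abundance, scaled by detector sensitivity and an optional
linear mass bias, with optional Poisson counting noise.  Ground truth is
returned alongside, so the whole quantification chain is testable without
any instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .chrom_io import IDAParameters, IsotopeChromatogram, default_ida
from .constants import MONITORED_ISOTOPES, SE_ISOTOPE_MASSES
from .speciation import SPECIES_COLUMNS, reference_cohort


@dataclass(frozen=True)
class SpeciesPeakSpec:
    """One eluting Se species: position, width and injected Se mass."""

    species_name: str
    retention_time_min: float
    peak_sigma_min: float
    se_mass_ng: float
    #: exponential tail constant for the EMG option, minutes; 0 = pure Gaussian
    emg_tau_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.retention_time_min > 0:
            raise ValueError(f"{self.species_name}: retention time must be positive")
        if not self.peak_sigma_min > 0:
            raise ValueError(f"{self.species_name}: peak sigma must be positive")
        if self.se_mass_ng < 0:
            raise ValueError(f"{self.species_name}: injected Se mass must be >= 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one simulated injection.

    ``sensitivity_cps_per_ng_min`` converts Se mass flow (ng/min, isotope-
    abundance-weighted) into detector counts per second; the per-channel
    sensitivity additionally carries the linear mass-bias factor
    (1 + mass_bias_per_amu·(m_j − m_78)).  All isotope channels share one
    time grid with spacing ``dwell_time_s`` × number of channels (the
    sub-second quadrupole stagger is negligible against minute-wide peaks).
    """

    species: tuple[SpeciesPeakSpec, ...]
    run_length_min: float = 50.0
    dwell_time_s: float = 0.3
    ida: IDAParameters = field(default_factory=default_ida)
    sensitivity_cps_per_ng_min: float = 1.0e6
    mass_bias_per_amu: float = 0.0
    baseline_counts: float = 0.0
    noise_model: str = "none"
    seed: int = 0
    injected_volume_ml: float = 0.1
    sample_mass_g: float = 0.1000
    isotopes: tuple[int, ...] = MONITORED_ISOTOPES

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not self.dwell_time_s > 0:
            raise ValueError("dwell time must be positive")
        if not self.sensitivity_cps_per_ng_min > 0:
            raise ValueError("sensitivity must be positive")
        for sp in self.species:
            latest = sp.retention_time_min + 5.0 * sp.peak_sigma_min + 5.0 * sp.emg_tau_min
            if latest > self.run_length_min:
                raise ValueError(
                    f"run of {self.run_length_min} min too short for species "
                    f"{sp.species_name!r} eluting through {latest:.1f} min"
                )


@dataclass(frozen=True)
class GroundTruth:
    """What was actually injected, for closing the loop in tests."""

    se_mass_ng: dict[str, float]
    injected_volume_ml: float
    sample_mass_g: float

    def __post_init__(self) -> None:
        if not self.sample_mass_g > 0:
            raise ValueError("sample mass must be positive")

    @property
    def concentration_ng_ml(self) -> dict[str, float]:
        """ng Se/mL under the unit serum density convention (0.1 g ≡ 0.1 mL)."""
        return {k: v / self.sample_mass_g for k, v in self.se_mass_ng.items()}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "se_mass_ng": {k: float(v) for k, v in self.se_mass_ng.items()},
                    "injected_volume_ml": self.injected_volume_ml,
                    "sample_mass_g": self.sample_mass_g,
                },
                fh,
                sort_keys=False,
            )


def load_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return GroundTruth(
        se_mass_ng={str(k): float(v) for k, v in doc["se_mass_ng"].items()},
        injected_volume_ml=float(doc["injected_volume_ml"]),
        sample_mass_g=float(doc["sample_mass_g"]),
    )


#: Default elution profile of the optimized separation: retention time and
#: peak width per fraction, minutes.  Early unretained species are narrow;
#: the affinity-retained proteins are broader.
DEFAULT_ELUTION: dict[str, tuple[float, float]] = {
    "GPx": (3.0, 0.25),
    "SMT": (5.0, 0.25),
    "SELENOP": (20.0, 0.5),
    "SELENOW_plus_others": (25.0, 0.5),
    "SeAlb": (31.0, 0.5),
}


def _peak_profile(t_min: np.ndarray, sp: SpeciesPeakSpec) -> np.ndarray:
    """Unit-area elution profile (1/min) at the grid times."""
    mu, sigma, tau = sp.retention_time_min, sp.peak_sigma_min, sp.emg_tau_min
    z = (t_min - mu) / sigma
    if tau <= 0:
        return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))
    # exponentially modified Gaussian, two-branch stable evaluation:
    # erfcx form on the leading edge, decaying-exponential form on the tail
    from scipy.special import erfc, erfcx

    arg = (sigma / tau - z) / np.sqrt(2.0)
    lead = arg >= 0
    out = np.empty_like(z)
    out[lead] = (0.5 / tau) * np.exp(-0.5 * z[lead] ** 2) * erfcx(arg[lead])
    tail_exp = np.clip(
        0.5 * (sigma / tau) ** 2 - (t_min[~lead] - mu) / tau, None, 700.0
    )
    out[~lead] = (0.5 / tau) * np.exp(tail_exp) * erfc(arg[~lead])
    return out


def natural_mass_flow(spec: SimulationSpec, t_min: np.ndarray) -> np.ndarray:
    """Ground-truth natural-Se mass flow (ng/min) at the grid times."""
    mf = np.zeros_like(t_min)
    for sp in spec.species:
        if sp.se_mass_ng > 0:
            mf += sp.se_mass_ng * _peak_profile(t_min, sp)
    return mf


def simulate_chromatogram(
    spec: SimulationSpec,
) -> tuple[IsotopeChromatogram, GroundTruth]:
    """Simulate one injection; deterministic for a given spec (incl. seed).

    Expected counts per second on isotope channel *j*:

        I_j(t) = S·(1 + b·(m_j − m_78)) ·
                 [ MF_nat(t)·a_nat,j/Aw_nat + MF_sp·a_sp,j/Aw_sp ]
                 + baseline_counts

    with Poisson noise applied to the expected counts per dwell period
    when requested.
    """
    cycle_s = spec.dwell_time_s * len(spec.isotopes)
    n_points = int(np.floor(spec.run_length_min * 60.0 / cycle_s)) + 1
    time_s = np.arange(n_points) * cycle_s
    t_min = time_s / 60.0

    ida = spec.ida
    mf_nat = natural_mass_flow(spec, t_min)
    mf_spike = ida.spike_mass_flow_ng_min
    m78 = SE_ISOTOPE_MASSES[78]

    rng = np.random.default_rng(spec.seed)
    intensities: dict[int, np.ndarray] = {}
    for iso in spec.isotopes:
        sens = spec.sensitivity_cps_per_ng_min * (
            1.0 + spec.mass_bias_per_amu * (SE_ISOTOPE_MASSES[iso] - m78)
        )
        expected_cps = (
            sens
            * (
                mf_nat * ida.natural_abundances.get(iso, 0.0) / ida.atomic_weight_natural
                + mf_spike * ida.spike_abundances.get(iso, 0.0) / ida.atomic_weight_spike
            )
            + spec.baseline_counts
        )
        if spec.noise_model == "poisson":
            counts = rng.poisson(expected_cps * spec.dwell_time_s)
            intensities[iso] = counts / spec.dwell_time_s
        else:
            intensities[iso] = expected_cps

    chrom = IsotopeChromatogram(
        time_s=time_s,
        intensities=intensities,
        sample_id=f"sim-seed{spec.seed}",
        injected_volume_ml=spec.injected_volume_ml,
        sample_mass_g=spec.sample_mass_g,
    )
    truth = GroundTruth(
        se_mass_ng={sp.species_name: sp.se_mass_ng for sp in spec.species},
        injected_volume_ml=spec.injected_volume_ml,
        sample_mass_g=spec.sample_mass_g,
    )
    return chrom, truth


def spec_from_concentrations(
    conc_ng_ml: dict[str, float],
    noise_model: str = "none",
    seed: int = 0,
    injected_volume_ml: float = 0.1,
    **overrides,
) -> SimulationSpec:
    """Build a SimulationSpec from per-species serum concentrations (ng/mL).

    Injected mass per species is concentration × injected volume; elution
    positions/widths come from :data:`DEFAULT_ELUTION`.
    """
    species = tuple(
        SpeciesPeakSpec(
            species_name=name,
            retention_time_min=DEFAULT_ELUTION[name][0],
            peak_sigma_min=DEFAULT_ELUTION[name][1],
            se_mass_ng=conc * injected_volume_ml,
        )
        for name, conc in conc_ng_ml.items()
    )
    return SimulationSpec(
        species=species,
        noise_model=noise_model,
        seed=seed,
        injected_volume_ml=injected_volume_ml,
        **overrides,
    )


def make_reference_cohort(
    noise_model: str = "none", seed: int = 0
) -> list[tuple[IsotopeChromatogram, GroundTruth]]:
    """Simulate the 13-injection cohort behind the published serum table.

    Ground-truth concentrations are the printed per-sample rows; each
    injection loads concentration × 0.1 mL of Se per species on column.
    Seeds of the individual injections are derived from ``seed`` so the
    cohort is reproducible as a whole.
    """
    cohort = []
    table = reference_cohort()
    for i, (sample, row) in enumerate(table.iterrows()):
        spec = spec_from_concentrations(
            {sp: float(row[sp]) for sp in SPECIES_COLUMNS},
            noise_model=noise_model,
            seed=(seed * 1009 + i) % (2**31),
        )
        chrom, truth = simulate_chromatogram(spec)
        chrom.sample_id = sample
        cohort.append((chrom, truth))
    return cohort


__all__ = [
    "SpeciesPeakSpec",
    "SimulationSpec",
    "GroundTruth",
    "load_ground_truth",
    "DEFAULT_ELUTION",
    "natural_mass_flow",
    "simulate_chromatogram",
    "spec_from_concentrations",
    "make_reference_cohort",
]
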