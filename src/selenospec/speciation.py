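"""Cohort speciation table, aggregate statistics and protein conversion.

Assembles per-sample Se concentrations of the five serum fractions
(glutathione peroxidase, selenometabolites, SELENOP, the SELENOW-containing
fraction, selenoalbumin) into the cohort table, computes the report
statistics (mean, sample SD, SEM, max, min), percent composition, and the
Se-atom-stoichiometry conversion from ng Se/mL to mg protein/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .constants import SE_ATOMIC_WEIGHT

#: Canonical column order of the speciation table.
SPECIES_COLUMNS = ("GPx", "SMT", "SELENOP", "SELENOW_plus_others", "SeAlb")
SUM_COLUMN = "sum_of_species"

#: Fractions without a fixed Se:protein stoichiometry — protein conversion
#: is refused for these: selenoalbumin carries selenomethionine
#: nonspecifically, and the SELENOW fraction co-elutes with unresolved
#: Se species.
NON_STOICHIOMETRIC = frozenset({"SeAlb", "SELENOW_plus_others"})

#: Se atoms per protein for the stoichiometric species (selenocysteine
#: residues: 13 in chicken SELENOP, 1 per GPx subunit).
SE_ATOMS = {"SELENOP": 13, "GPx": 1}

#: Molar masses (g/mol) back-derived from the reported cohort averages and
#: mg/L conversions; synthetic regression fixtures, not literature values.
IMPLIED_MOLAR_MASS = {"SELENOP": 49943.8, "GPx": 26981.8}

# Published 13-sample cohort: ng Se per mL serum, per fraction, plus the
# printed sum-of-species column (which differs from the component sum by
# up to 0.01 through rounding of the printed components).
_COHORT_ROWS = [
    # GPx,  SMT,  SELENOP, SELENOW+, SeAlb, sum
    (2.73, 3.70, 50.78, 31.37, 1.92, 90.51),
    (3.01, 3.80, 60.84, 37.77, 2.34, 107.76),
    (3.47, 6.88, 70.00, 24.64, 1.69, 106.67),
    (3.50, 2.22, 63.93, 30.59, 1.90, 102.14),
    (3.51, 4.09, 78.80, 24.89, 1.37, 112.66),
    (3.58, 4.66, 81.42, 34.68, 2.46, 126.81),
    (3.60, 5.28, 46.96, 34.21, 1.89, 91.93),
    (3.66, 1.94, 53.77, 33.40, 1.80, 94.57),
    (3.69, 4.79, 37.20, 38.64, 2.18, 86.50),
    (3.80, 3.57, 63.31, 44.27, 2.48, 117.44),
    (3.83, 2.27, 46.62, 40.18, 2.70, 95.60),
    (3.88, 6.77, 46.96, 35.69, 1.90, 95.20),
    (3.89, 3.06, 68.38, 33.75, 2.49, 111.57),
]


def reference_cohort() -> pd.DataFrame:
    """The published 13-sample chicken-serum speciation table, ng Se/mL.

    Index ``sample 1`` .. ``sample 13``; columns the five species plus
    ``sum_of_species`` as printed.
    """
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=list(SPECIES_COLUMNS) + [SUM_COLUMN],
        index=[f"sample {i}" for i in range(1, 14)],
    )


def make_table(per_sample: pd.DataFrame, sum_tol: float = 0.02) -> pd.DataFrame:
    """Validate/complete a per-sample species table into a SpeciesQuantTable.

    ``per_sample`` has one row per sample and the five species columns;
    ``sum_of_species`` is added (or checked against the row sum within
    ``sum_tol`` ng/mL, the slack printed tables accumulate by rounding).
    """
    missing = [c for c in SPECIES_COLUMNS if c not in per_sample.columns]
    if missing:
        raise ValueError(f"missing species columns: {missing}")
    table = per_sample.copy()
    rowsum = table[list(SPECIES_COLUMNS)].sum(axis=1)
    if SUM_COLUMN in table.columns:
        bad = (table[SUM_COLUMN] - rowsum).abs() > sum_tol
        if bad.any():
            raise ValueError(
                f"sum_of_species deviates from component sum by more than {sum_tol} "
                f"in rows {list(table.index[bad])}"
            )
    else:
        table[SUM_COLUMN] = rowsum
    return table[list(SPECIES_COLUMNS) + [SUM_COLUMN]]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, as report tables conventionally do.

    Values are pre-quantised at 9 decimals so binary floating-point noise
    around an exact decimal tie (e.g. a column mean of exactly 3.55)
    cannot flip the rounded figure.
    """
    q = Decimal(repr(float(x))).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    return float(q.quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AggregateStats:
    """Per-column cohort statistics, full precision and report-rounded."""

    n: int
    mean: pd.Series
    sd: pd.Series
    sem: pd.Series
    maximum: pd.Series
    minimum: pd.Series

    def rounded(self, ndigits: int = 1) -> pd.DataFrame:
        """Statistic rows rounded half-away-from-zero for the report table."""
        rows = {
            "average": self.mean,
            "SD": self.sd,
            "SEM": self.sem,
            "maximum": self.maximum,
            "minimum": self.minimum,
        }
        return pd.DataFrame(
            {
                name: {c: round_half_away(v, ndigits) for c, v in ser.items()}
                for name, ser in rows.items()
            }
        ).T[list(self.mean.index)]


def aggregate(table: pd.DataFrame) -> AggregateStats:
    """Column statistics of a speciation table (SD with n−1 denominator)."""
    n = len(table)
    if n < 2:
        raise ValueError("aggregate statistics need at least 2 samples")
    sd = table.std(ddof=1)
    return AggregateStats(
        n=n,
        mean=table.mean(),
        sd=sd,
        sem=sd / np.sqrt(n),
        maximum=table.max(),
        minimum=table.min(),
    )


def percent_composition(stats: AggregateStats) -> dict[str, int]:
    """Integer percent of total Se per species, from full-precision means."""
    total = stats.mean[SUM_COLUMN]
    if not total > 0:
        raise ValueError("sum-of-species average must be positive")
    return {
        sp: int(round_half_away(100.0 * stats.mean[sp] / total, 0))
        for sp in SPECIES_COLUMNS
        if sp in stats.mean.index
    }


def se_to_protein(
    conc_ng_ml: float, species: str, n_se_atoms: int | None = None,
    molar_mass: float | None = None,
) -> float:
    """Convert a Se concentration (ng/mL ≡ µg/L) to protein mg/L.

    mg/L = conc · M / (n_Se · 78.971) / 1000.  Refused for fractions with
    no fixed Se:protein stoichiometry (selenoalbumin, the unresolved
    SELENOW-containing fraction).
    """
    if species in NON_STOICHIOMETRIC:
        raise ValueError(
            f"cannot convert {species}: no fixed Se:protein stoichiometry "
            "(Se is nonspecifically incorporated or the fraction contains "
            "multiple unresolved Se species)"
        )
    if n_se_atoms is None:
        n_se_atoms = SE_ATOMS[species]
    if molar_mass is None:
        molar_mass = IMPLIED_MOLAR_MASS[species]
    if not molar_mass > 0:
        raise ValueError("molar mass must be positive")
    if n_se_atoms < 1:
        raise ValueError("a selenoprotein carries at least one Se atom")
    return conc_ng_ml * molar_mass / (n_se_atoms * SE_ATOMIC_WEIGHT) / 1000.0


def validation_stats(
    measured: float, certified: float, blank_amounts
) -> dict[str, float]:
    """Recovery against a certified value plus 3σ/10σ blank-based limits.

    Returns ``recovery_percent``, ``lod`` and ``loq`` in the units of the
    blank amounts.  Needs at least 3 blank replicates.
    """
    blanks = np.asarray(list(blank_amounts), dtype=float)
    if blanks.size < 3:
        raise ValueError("LOD/LOQ need at least 3 blank replicates")
    if not certified > 0:
        raise ValueError("certified value must be positive")
    sd = float(blanks.std(ddof=1))
    return {
        "recovery_percent": 100.0 * measured / certified,
        "lod": 3.0 * sd,
        "loq": 10.0 * sd,
    }


__all__ = [
    "SPECIES_COLUMNS",
    "SUM_COLUMN",
    "NON_STOICHIOMETRIC",
    "SE_ATOMS",
    "IMPLIED_MOLAR_MASS",
    "reference_cohort",
    "make_table",
    "round_half_away",
    "AggregateStats",
    "aggregate",
    "percent_composition",
    "se_to_protein",
    "validation_stats",
]
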