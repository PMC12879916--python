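#!/usr/bin/env python
"""Simulate the 13-injection serum cohort and write the raw chromatograms.

Each injection carries the cohort's known per-species Se loads (0.1 mL of
serum on column) through the forward instrument model: five isotope
channels, constant ⁷⁴Se-enriched post-column spike, noise-free by default.
Raw multi-isotope CSVs are bulky, so they land in scratch/ for inspection;
the downstream analyses regenerate them deterministically from the seed.
"""

from pathlib import Path

from selenospec.chrom_io import write_chromatogram
from selenospec.synthetic_data import make_reference_cohort

OUT = Path(__file__).resolve().parent.parent / "scratch" / "chromatograms"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = make_reference_cohort(noise_model="none", seed=SEED)
    for chrom, truth in cohort:
        stem = chrom.sample_id.replace(" ", "_")
        write_chromatogram(chrom, OUT / f"{stem}.csv")
        truth.save(OUT / f"{stem}.truth.yaml")
    total = sum(sum(t.se_mass_ng.values()) for _, t in cohort)
    print(f"wrote {len(cohort)} chromatograms to {OUT}")
    print(f"total Se on column across the cohort: {total:.2f} ng")


if __name__ == "__main__":
    main()
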