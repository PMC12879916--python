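# Methods

## The measurement being modelled

A serum sample (0.1 mL, taken as 0.1000 g at unit density) is injected onto
a column-switching SEC/affinity separation and the effluent is merged, just
before the ICP-MS nebulizer, with a constant flow of ⁷⁴Se-enriched spike.
The instrument cycles through five Se isotopes (74, 76, 77, 78, 80) at 0.3 s
dwell each over a 50-min run. Five fractions elute in a fixed order:
glutathione peroxidase (~3 min) and selenometabolites (~5 min) unretained,
then SELENOP (~20 min), a SELENOW-containing fraction (~25 min) and
selenoalbumin (~31 min) released by the gradient and valve program.

Because the spike flow is constant and its isotopic composition is known,
any natural-composition Se eluting at time *t* is quantified from the
measured ⁷⁸Se/⁷⁴Se ratio alone — no species-specific standard, no
sensitivity calibration, no drift or matrix correction. This is the
species-unspecific online isotope-dilution analysis (IDA) principle.

## The IDA equation and its identities

Writing MF for mass flow (ng Se/min), Aw for atomic weight, a_{x,j} for the
atom fraction of isotope j in composition x ∈ {nat, sp}:

    MF_s(t) = MF_sp · (Aw_nat/Aw_sp) · (a_sp,74/a_nat,78)
              · (R_m(t) − R_sp) / (1 − R_m(t)·R_nat)

with R_m = I₇₈/I₇₄, R_sp = a_sp,78/a_sp,74, R_nat = a_nat,74/a_nat,78 and
MF_sp = spike concentration × spike flow. The equation follows from the
molar balance of the post-column mixing point; the test suite checks it
against an independently coded molar-balance evaluation to 1e-10 relative
over random parameter draws, plus its structural identities:

- MF_s = 0 exactly at R_m = R_sp (no analyte);
- a pole at R_m = 1/R_nat (spike fully diluted): points whose denominator
  is within 1e-9 of zero are masked and counted, never silently zeroed or
  interpolated, so quantification stays auditable;
- monotone increasing in R_m on the physical branch R_sp < R_m < 1/R_nat;
- invariant under rescaling both intensity channels by a common factor
  (detector sensitivity cancels in the ratio).

Isotope abundances and masses are the IUPAC/CIAAW representative values
(natural ⁷⁴Se 0.0089, ⁷⁶Se 0.0937, ⁷⁷Se 0.0763, ⁷⁸Se 0.2377, ⁸⁰Se 0.4961,
⁸²Se 0.0873; atomic weight 78.971). The default spike is 99.9 % ⁷⁴Se with
the remainder on ⁷⁸Se; its atomic weight is recomputed from the abundances
and cross-checked at load.

Ratio smoothing (centered moving average of both channels before dividing)
is available but defaults to off (`smoothing_points=1`); integrated window
masses are insensitive to it at the 0.2 % level on noise-free runs. A
linear mass-bias model across the Δm = 4 gap can be applied in the
simulator and removed in quantification; the default is zero bias.

## Forward model (synthetic data)

Expected counts per second on channel j:

    I_j(t) = S·(1 + b·(m_j − m₇₈)) · [ MF_nat(t)·a_nat,j/Aw_nat
                                       + MF_sp·a_sp,j/Aw_sp ] + baseline

where MF_nat(t) is a sum of unit-area species peaks scaled by the injected
ng of Se. Defaults, chosen once as a realistic operating point where the
measurement itself fixes no value:

| parameter | default | rationale |
|---|---|---|
| peak shape | Gaussian | no peak model is implied by the measurement; EMG (`emg_tau_min`) available as an option |
| σ (GPx, SMT) | 0.25 min | narrow unretained peaks; >4σ clearance from window edges |
| σ (SELENOP, SELENOW fraction, SeAlb) | 0.5 min | broader retained-protein peaks, ≥4σ inside their windows |
| spike | 100 ng/mL × 0.1 mL/min = 10 ng Se/min | keeps the ⁷⁴Se spike baseline within 10× of the tallest ⁷⁸Se peak |
| sensitivity S | 1e6 cps per (ng/min) | ~4×10³ counts per dwell at the SELENOP ⁷⁸Se apex, i.e. percent-level shot noise per point |
| baseline counts | 0 | the reaction cell removes the spectral background; a constant offset is available for robustness studies |
| time grid | one shared grid, 1.5 s spacing | 5 isotopes × 0.3 s dwell; the sub-cycle channel stagger is negligible against minute-wide peaks |

Poisson noise draws counts per dwell period (`expected_cps × 0.3 s`) from a
seeded generator; two runs with the same spec are bitwise identical.

What the simulator does **not** emulate: argon/hydride spectral
interferences (removed instrumentally in the measurement being modelled),
retention-time drift, peak tailing from column overload, detector dead
time, baseline wander, or carry-over between injections. Passing tests
therefore demonstrate the correctness of the quantification chain given a
well-behaved instrument, not robustness to pathological chromatography.

## Integration and reporting

Baseline is the median mass flow over a blank window (default 40–48 min,
after the last peak and before re-equilibration; ≥5 valid points required).
Windows are fixed-time (GPx 2–4, SMT 4–8, SELENOP 15–23, SELENOW+others
23–28, SeAlb 28–35 min): the named peaks elute at stated times, and fixed
windows make the analysis deterministic. Integration is trapezoidal on the
dense uniform grid (higher-order schemes change results by <0.01 %).
Negative areas are clipped to zero only at reporting, with the raw value
and a flag retained; windows with >20 % masked points are flagged
unreliable. Concentrations are ng Se/mL = ng / 0.1000 g under the
density-1 g/mL serum convention.

Per-sample concentrations are reported at 0.01 ng/mL, and the cohort
statistics chain from the reported table — the convention printed tables
follow, and the reason a column whose mean is an exact decimal tie (the
GPx column averages exactly 3.55) rounds reproducibly. Statistic rows use
the sample SD (n−1; the n denominator fails to reproduce the cohort's
printed SD values), SEM = SD/√n, and half-away-from-zero rounding to one
decimal (banker's rounding disagrees with the printed 3.55 → 3.6). Before
the final quantisation, values are pre-rounded at 9 decimals so that
binary float noise a few ulp below a decimal tie cannot flip the printed
cell. Percent composition divides full-precision column means and rounds
once to integers; on the reference cohort GPx recomputes to ~3.4 % where
the accompanying report text says 2 % — the discrepancy is reported as
such, not resolved.

Protein concentrations follow from Se stoichiometry:
mg/L = (ng Se/mL) · M / (n_Se · 78.971) / 1000, with n_Se = 13 for SELENOP
and 1 per GPx subunit. The molar masses bundled as defaults (49 943.8 and
26 981.8 g/mol) are *back-derived* from the reported averages and mg/L
values — synthetic regression fixtures with provenance noted in the code,
not literature constants — so the mg/L round trip is a consistency check,
not an independent validation. Conversion is refused for selenoalbumin
(nonspecific Se incorporation) and the SELENOW-containing fraction
(unresolved co-eluting species). Method-validation formulas are the
conventional recovery = 100·measured/certified and LOD/LOQ = 3σ/10σ of
≥3 blanks.

## Peptide confirmation

Digestion applies the plain Keil trypsin rule — cleave after K or R except
before P — enumerating all peptides with up to the configured missed
cleavages, with 1-based positions retained (the rare W·KP/M·RP exception
clauses of the extended rule are deliberately omitted). Peptide masses sum
a bundled residue table (standard monoisotopic and average values;
selenocysteine U = 150.95364 Da mono) plus water, with carbamidomethyl-C
(+57.02146 Da) as the fixed modification and selenocysteine→dehydroalanine
(−81.93218 Da, the Se-loss degradation DTT-containing digests promote) as
the bundled variable modification; other modifications can be supplied as
mass deltas.

Matching is greedy one-to-one: all (peptide variant, observed mass) pairs
within the ppm tolerance (default 20 ppm, monoisotopic) are assigned in
order of ascending absolute error, ties broken by fewer missed cleavages
then earlier start position, each observed mass and peptide used at most
once — a deterministic, auditable rule. The score is residue-level
sequence coverage, |union of matched intervals| / length, which is monotone
in the observed-mass set; confirmation tiers are <60 % not confirmed,
60 % to the confirmation threshold partially confirmed, and ≥85 %
(configurable) confirmed. On an 85-residue protein with matched peptides
spanning 75 residues this reports 88.24 % — the regime in which a
selenoprotein-W identification is called confirmed. b/y fragment ladders
(proton-adjusted for charge) are provided for spectrum annotation;
spectrum deconvolution, decoy-based FDR and Se-isotope-pattern detection
in ESI spectra are out of scope.

Vendor coverage metrics are not publicly specified; residue-level coverage
is this package's defined interpretation of "sequence match", and the
85/75 fixture is synthetic (constructed, not a database sequence), labelled
as such wherever it appears.

## Problem sizes and determinism

The cohort reproduction runs 13 noise-free injections (2001 time points ×
5 channels each) and completes in seconds; the noise study uses 50 Poisson
seeds of an average-composition injection, enough to pin the mean recovery
bias well below the 2 % band counting statistics predict at these count
rates. All seeds are explicit arguments; nothing derives from the clock.

## Known limitations

- Fixed-time windows mis-assign mass if retention drifts; no alignment is
  attempted.
- The simulator's clean baseline makes baseline estimation trivially easy;
  the median estimator is robust but untested against sloping backgrounds.
- Greedy matching is not globally optimal when several peptides fall within
  tolerance of several observed masses; with deconvoluted neutral-mass
  lists at 20 ppm this is rarely binding.
- Coverage-based confirmation carries no statistical error model (no decoy
  FDR); tiers are operating conventions, not probabilities.
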