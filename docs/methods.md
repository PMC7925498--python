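# Methods

## Mass model

A sulfolipid is modelled as the sulfoquinovosyl-glycerol core C9H18O10S
(sulfoquinovose C6H12O8S + glycerol C3H8O3 − H2O for the glycosidic bond)
plus one acyl chain per class position, minus one water per ester bond. An
acyl chain C:D contributes its free-acid composition C(n)H(2n−2d)O2.
Two mass scales are kept strictly separate:

* *monoisotopic* — sums of most-abundant-isotope masses (NIST values via
  pyteomics); [M−H]⁻ is the neutral monoisotopic mass minus the mass of a
  hydrogen atom. The electron mass (~0.55 mDa) is ignored — far below the
  0.5 m/z matching tolerance of a unit-resolution triple quadrupole.
* *nominal* — sums of integer mass numbers (C=12, H=1, N=14, O=16, S=32)
  minus 1 for deprotonation. Nominal masses are computed from mass numbers,
  never by rounding monoisotopic values: at m/z ≳ 500 the accumulated
  hydrogen mass defect exceeds 0.5 (SQDG 16:0/18:2 has monoisotopic [M−H]⁻
  817.51 but nominal 817), so rounding would mislabel species.

Species display names follow the MRM-panel convention (class + nominal
[M−H]⁻, e.g. "SQDG 815"); the vendor convention naming the commercial
standard by its neutral nominal mass ("SQDG 816" = SQDG 16:0/18:3) is kept
as an alias because both circulate.

Isobaric enumeration searches unordered chain combinations from a
configurable fatty-acid pool. The default pool (14:0, 15:0, 16:0, 16:1,
17:0, 18:0, 18:1, 18:2, 18:3, 18:4, 20:4, 20:5, 22:6) covers the chains
commonly esterified in cyanobacterial and plant glycolipids; no authoritative
pool exists for the assay, so it is a constructor argument everywhere.
Unordered pairs are deliberate: a Q1 precursor mass cannot distinguish sn
positions, and regiochemistry is handled separately.

## Fragmentation

Negative-mode CID of sulfolipids yields class-diagnostic headgroup ions at
nominal m/z 81, 125, 153, 165, 225 and 255, plus per-chain neutral losses of
the free fatty acid and of its ketene (acid − H2O). Elemental assignments
are attached where established (81 = HSO3⁻, 153 = C3H5O5S⁻, 165 = C4H5O5S⁻,
225 = C6H9O7S⁻, i.e. dehydrated deprotonated sulfoquinovose); the
compositions used for m/z 125 (C2H5O4S⁻) and 255 (palmitate carboxylate) are
plausible but not established, are flagged `assignment_uncertain`, and are
matched on nominal values only. Mass balance — precursor = fragment +
neutral loss, to 0.001 on the monoisotopic scale — is enforced by
construction and property-tested over the whole default pool.

For the 16:0/18:3 standard the acid-loss fragments are nominal m/z 559
(16:0 loss) and 537 (18:3 loss): 815 − 278 = 537 requires the
octadecatrienoyl loss arithmetically, whatever chain label one attaches to
the fragment informally.

sn-position ranking implements the empirical rule that the acid-loss fragment
of the sn1 chain is the more intense; ties, missing intensities and identical
chain pairs return an explicit "ambiguous" verdict rather than a guess.
Precursor annotation ranks pool candidates within a 0.5 m/z tolerance
(configurable) by the count of observed products explained, ties broken by
summed absolute mass error. No fragment-intensity model exists for these
lipids, so intensities carry no weight in the ranking.

## Transition panel

A panel analyte owns exactly three transitions (one quantifier, two
qualifiers) with instrument parameters (dwell, declustering and entrance
potentials, collision energy, cell exit potential) stored as signed values
as tuned. The bundled reference panel has 27 analytes (cerebroside internal
standard, one SQMG, 25 SQDGs; 81 transitions). Product ions carry tuning
offsets (the sulfonate ion appears between 79.9 and 81.1; 224.x is the
dehydrated-sulfoquinovose ion), so all matching uses a 0.5 m/z tolerance
box on both Q1 and Q3; the 224-vs-225 variation is treated as one ion.
Two panel analytes (867, 871) have no retention time and are screening-only:
peak assignment skips them with a flag. The ISD's printed molar mass
(794 g/mol) and precursor (792.0) are both stored as printed; the CSV schema
carries the molar mass in a trailing optional column.

Generated transitions for a new species use the sulfonate diagnostic (81) as
quantifier and two qualifiers from the {225, 165, 153, 95} family — the
dominant pattern across the reference panel — with the precursor set to the
monoisotopic [M−H]⁻ rounded to one decimal and potentials at configurable
defaults (no autotune emulation).

## Peak processing

Time is minutes end-to-end; mzML times (seconds) are converted on read.
The mzML support is a narrow chromatogram-list reader/writer (32/64-bit
float, plain or zlib-compressed arrays, SRM channel ids
`"SRM SIC Q1=<precursor> Q3=<product>"`) — the subset SRM acquisitions
actually produce — built directly on lxml.

Detection: rolling-minimum baseline (2 min window) is subtracted; the signal
is smoothed with a 5-point moving average (width configurable, 1 disables);
local maxima above `min_snr` (default 3, the conventional detection floor)
times the noise are kept. Noise is the scaled median absolute deviation of
the smoothing residual — on an exactly noise-free trace it is zero and the
SNR is reported as infinity rather than discarding the peak. Peak boundaries
walk from the apex to the nearest valley or to 1% of apex height, whichever
comes first; a Gaussian truncated at 1% of its apex retains 99.75% of its
area, so integrated areas agree with the closed form A·σ·√(2π) to well
within 1%. `integrate` itself is a plain trapezoidal integral with
interpolated endpoints (exact for piecewise-linear signals); baseline
subtraction there is opt-in (`baseline=None`, a constant, or `"rolling"`),
because an unconditional rolling-minimum subtraction would, e.g., null a
constant signal.

Assignment: a peak belongs to its channel's analyte iff |apex − panel Rt| ≤
0.5 min (default); multiple peaks in the window resolve to the largest area
with a note, everything else is reported unassigned rather than dropped.

## Calibration and quantification

Response is the analyte/ISD area ratio — the standard reading of constant
internal-standard addition (the ISD, a cerebroside structurally similar to
SQDGs but absent from plant matrices, is spiked at 5 µg/mL everywhere).
The curve is ordinary least squares of response on nominal concentration
(statsmodels), with optional 1/x weighting for heteroscedastic data;
unweighted is the default. Residual SD uses n−2 degrees of freedom.
Degenerate designs (one concentration for all levels, or a perfectly flat
response) raise `SingularFitError`: a zero-slope curve is unusable since
every downstream quantity divides by the slope.

LOD/LOQ use the ICH calibration-curve formulas 3.3·s/slope and 10·s/slope.
The national-standard family of "calibration method" limits has several
variants; the ICH residual-SD form is implemented and named in the report so
the choice is auditable.

Back-calculation inverts the line; responses below the intercept floor at
zero with an `<LOD` flag. Content per dry weight = concentration × extract
volume × dilution factor / sample mass (µg/g, reported as mg/g); composition
shares are percentages of the summed content over analytes ≥ LOQ and sum to
100 by construction. Validation statistics use the sample SD (n−1): per QC
level, intra-day CV is the mean of within-day CVs of back-calculated
concentrations, inter-day CV pools all days (reported only with ≥ 2 days),
accuracy is mean back-calculated / nominal × 100, and the pass flag applies
the FDA CV < 15% rule (threshold configurable).

## Synthetic data

The generator emulates the acquisition the toolkit processes: per panel
transition, one Gaussian peak (σ = 0.15 min) at the panel retention time on
a 52-minute grid sampled every 0.01 min (the LC program: 2 min hold, 4 min
ramp, 34 min at the final eluent, then re-equilibration). Quantifier area =
response factor × concentration; qualifier areas are fixed fractions (0.4,
0.2) of the quantifier — MRM qualifier ratios are tuned constants with no
published model, so these are arbitrary and configurable. Area noise is
multiplicative lognormal with unit mean (CV-parameterized, matching typical
LC-MS heteroscedasticity); baseline noise is additive Gaussian clipped at
zero counts; retention-time jitter is Gaussian per analyte. Default response
factors are anchored so the default calibration design (10 equidistant
levels, 1–10 µg/mL, ISD constant at 5 µg/mL) fits a slope of 0.330 — the
reference method's mean calibration slope — which the noiseless series
reproduces exactly (R² = 1).

Calibration and QC simulators use the plain multiplicative form
response = rf·c·(1 + ε), ε ~ Normal(0, CV), with an optional per-day
multiplicative effect to separate inter- from intra-day variability. Ground
truth is always returned next to the data, and every artifact round-trips
through the corresponding reader.

What the simulator does *not* emulate — gradient chemistry, ion suppression,
co-elution of isobars, carryover, isotope patterns, non-Gaussian peak shapes
(tailing), and matrix effects. Passing tests therefore demonstrate the
correctness of the processing chain on well-behaved inputs, not robustness to
real-matrix pathologies; recovery and matrix-effect figures require spiked
real samples by nature.

## Problem sizes and numerical choices

Test and acceptance runs simulate the full 27-analyte panel at 0.01-min
sampling (~5 200 points × 75 channels), fit 10-point calibrations, and use
6 replicate injections for precision checks and 200 seeded repetitions for
the CV-calibration property — sizes chosen to mirror the assay design while
keeping the suite fast. The mean sample CV of n = 5–6 normal replicates at
σ = 5% carries the c4 small-sample bias (≈ 0.94–0.95), which is why the
200-repetition mean is asserted in [4%, 6%] rather than at 5% exactly.
All random draws flow through `numpy.random.default_rng(seed)`; identical
seeds give identical outputs everywhere, including file round-trips.

## Known limitations

* Quantification of species without authentic standards is surrogate
  calibration against the single SQDG standard; reported concentrations for
  those species are relative to its response factor.
* Annotation is nominal-mass-gated and cannot separate isobaric acyl pairs
  without loss-fragment evidence; with only diagnostic ions observed, ties
  are returned as ties.
* Peak detection assumes baseline-resolved peaks; co-eluting isomer
  deconvolution and cross-batch retention alignment are out of scope.
* The published LOQ of the underlying assay (1.44 µg/mL) derives from
  unpublished instrument data and is not reproducible from printed numbers;
  the toolkit reports whatever the ICH formulas yield for the data at hand.
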