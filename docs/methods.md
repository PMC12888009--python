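# Methods

## Composition model

A venom is represented at the toxin-family level. Relative abundance in
g/100 g venom comes from RP-HPLC peak areas (the 215 nm signal integrates
peptide-bond absorbance, so area share approximates weight share); peaks
the caller leaves unassigned stay in the denominator and are reported as
their own bucket, so abundances always total 100 %. The molar scale is
millimoles of toxin per 100 g of whole venom:
`molar% = 1000 · mass% / M` with `M` the family's representative molecular
mass in daltons. This per-100-g-venom convention reproduces every
published molar cell across the seven species to ±0.001, which is the
package's regression oracle for the conversion.

`molecule_fraction` restricts its denominator to families with a
registered molecular mass (the ten tabulated classes). Trace components
without a tabulated mass cannot enter a molar sum; this is also the only
convention under which the published SVMPi molecule fraction (89.8 %) is
recovered.

Printed-value comparisons round half away from zero at the table's
precision; all internal computation is full precision.

### Compositional patterns

Venoms are classified by their K49/D49 phospholipase balance:
pattern II when K49 is negligible (< 0.05 mmoles %), pattern I when
K49/D49 ≥ 1.5, pattern III for 0.67 ≤ K49/D49 < 1.5; below 0.67 the venom
is nearer the D49-dominant pattern and falls to II. The thresholds are
configuration, not code. The published grouping describes pattern I as
"highest K49, lowest PIII"; one venom (*B. pauloensis*, K49/D49 ≈ 1.24
but strongly depressed PIII) sits on the I/III boundary, and an optional
`low_piii_rescue` threshold promotes such borderline cases to I when PIII
falls below it. By the ratio thresholds alone it classifies as III; we
keep the explicit thresholds and expose the rescue rather than hard-coding
the published grouping.

### Band allocation

When a chromatographic fraction contains several SDS-PAGE bands, its
chromatogram percentage is split by densitometry shares; within a band,
co-migrating proteins are split by the relative summed intensities of each
protein's three most abundant peptide ions. The allocation is exactly
conservative (outputs sum to the fraction's percentage). A single-protein
band needs no intensities; a multi-protein band with zero total intensity
is an error rather than an arbitrary split.

## Antivenomics (3GA)

Retained fraction %Ri = 100·Ri/(Ri+NRi); captured mass =
(%Ri/100)·(share/100)·load. Nonspecific retention measured on mock or
naive-IgG columns is subtracted from %Ri with a floor at zero; because the
source protocol does not state the correction arithmetic, a no-correction
mode is exposed and both are reported by the chain when asked.

Saturation is extrapolated by an ordinary least-squares degree-2
polynomial of captured mass against venom load. The vertex is trusted only
if the parabola is concave and the vertex lies within twice the largest
observed load: beyond that the parabola is unsupported extrapolation, and
an upward-opening fit means no saturation is evident; in both cases the
largest observed captured mass is reported and the toxin flagged
unsaturated. The fit is to captured mass (the quantity summed into
MaxBind) rather than to %R; fitting %R and multiplying through is the
plausible alternative and gives the same noiseless vertex for a toxin
observed at fixed share.

MaxBind = Σ per-toxin maxima (μg) / antivenom on the column (mg), i.e.
mg venom per g antivenom. Unit conversions use the antivenom's F(ab')₂
content: 46.45 g/L and 0.4645 g per 10 mL vial (the per-vial figure and
the published mg/mL column are mutually consistent only at this
concentration, which is therefore the adopted constant).

## Probit dose–response

Quantal assays are fitted by maximum-likelihood binomial regression with a
probit link on log₁₀(dose) (statsmodels GLM/IRLS). The median dose is
10^(−intercept/slope); its 95 % CI comes from the delta method applied to
g(β) = −β₀/β₁ on the log scale, then exponentiated — the standard Finney
construction. No natural-response (Abbott) correction is applied: control
animals are untreated. Tables with complete separation (a pure 0→n step
and fewer than two partial-response groups) cannot support an ML fit; the
median is then reported as the geometric mean of the bracketing doses with
`converged=False` and the bracketing doses as the interval. A
grid-search likelihood oracle in the tests confirms the ML optimum on
small tables to 1e−6.

Potency: P = ED50·(n−1)/n for an n×LD50 challenge (n = 5 here), applied
elementwise to the CI bounds. P/MaxBind·100 may legitimately exceed 100 %:
if neutralizing a lethal subset of toxins abrogates whole-venom lethality,
potency reflects that subset while MaxBind counts binding to everything.
The point estimate of the ED50 is used throughout; CI weighting of the
potency chain would require the unpublished joint distribution.

## MHD and unit transforms

Minimum hemorrhagic dose: hemorrhagic area is conventionally linear in
log dose, so area is regressed on log₁₀(dose) and the line inverted at
1 cm²; with exactly two points this reduces to two-point log-linear
interpolation. A flat response is an error, and a 1 cm² crossing outside
the observed area range warns that the estimate is an extrapolation.
Enzymatic activities are plain unit transforms: azocoll units are ΔA540
per 0.003 per minute per mg venom; PLA₂ activity converts ΔA425 to nmol
chromophore via 25.8 nmol per 0.01 absorbance. Thrombin-like activity has
no published unit transform (raw endpoint absorbance) and is deliberately
not computed.

## Statistics layer

Pearson r with R² and the two-sided t-test p-value; OLS with adjusted R²
and the overall-F p-value, with an optional species factor encoded as
reference-level dummies (reference = alphabetically first level,
deterministic) and an optional interaction. Rank-deficient designs raise
an error naming the collinear columns. The published correlation
coefficients depend on per-specimen supplementary data not in the tables,
so these operations are validated on synthetic data with known structure
instead. Sample SD uses the n−1 denominator and is undefined at n = 1.

## Synthetic-data generator

All generators are pure functions of `(GeneratorConfig, seed)` —
byte-identical on rerun — and return their ground truth.

* **Compositions**: multiplicative lognormal noise (mean-one, default CV
  0.15) around the published species templates, renormalized to the
  template total; the K49-PLA₂ and PIII-SVMP deviations are drawn from a
  bivariate normal with correlation −0.7, emulating the clade's inverse
  K49/PIII trend. The CV is chosen so that synthetic between-specimen
  scatter is of the same order as the published functional-assay SDs.
* **Chromatograms**: one Gaussian peak per family at evenly spaced
  retention times in the canonical elution order (SVMPi first,
  PIII-SVMP last), peak area equal to the family's mass %. Exact minutes
  are nowhere asserted. No tailing or co-elution — integration windows
  of ±4σ close the loop to better than 1 % absolute by construction,
  which real chromatograms would not.
* **Immunocapture**: per toxin, captured = Bmax·t/(Kd + t) of the
  presented toxin mass t = load·share/100, capped at t, with lognormal
  noise (default CV 3 %); Ri/NRi areas are back-computed so the analysis
  identities hold exactly at zero noise. Defaults: Bmax proportional to
  proteome share (8 μg per share point, total ≈ 650 μg on a 7 mg column,
  the observed MaxBind scale) and a common apparent Kd of 25 μg, which
  places saturation within the 100–3600 μg dose design as observed.
* **Lethality**: deaths ~ Binomial(n, Φ(slope·(log₁₀d − log₁₀median))),
  default median 70 μg (≈ 3.3 μg/g in an 18–22 g mouse) and slope 4 on
  the 23–230 μg design.
* **Hemorrhage**: area = β·log₁₀(dose) + α + Gaussian noise, with α set
  from the configured true MHD (default 3 μg, inside the 1.25–15 μg
  design).

Passing recovery tests on these generators shows the estimators are
correct under the assumed noise models and designs; it does not certify
performance on real chromatograms (overlapping peaks, baseline drift) or
real assay heterogeneity.

## Problem sizes and numerical choices

Simulation-based checks use 100 seeded replicates for probit and MHD
recovery and 200 for the 3GA loop — enough for the pass-rate bounds
(≥ 90 %) to be stable while keeping the whole suite under a minute.
Quadratic fits use `numpy.polyfit`; probit uses IRLS with tolerance
1e−10; the 3GA quadratic-vertex tolerance (±15 % against a dense-grid
oracle of the same procedure) reflects the method's intrinsic bias when a
parabola approximates a Langmuir curve, not fitting error. Degenerate
inputs (zero total area, both areas zero, flat dose–response, single dose
group, n = 1 SD) raise `ValueError` rather than returning sentinels.

## Known limitations

* Family-level only; no isoform resolution, no MS/MS identification.
* The quadratic saturation model is the source convention; it can
  overshoot the true asymptote by ~10 % on deeply saturated series and
  undershoot badly when saturation is not reached (such toxins are
  flagged).
* Published MaxBind, LD50/ED50 point estimates and correlation
  coefficients depend on raw data not in the tables; the pipeline
  reproduces their derivation chains and validates the estimators by
  simulation instead.
* The dichotomy thresholds are a formalization of a qualitative
  published description; one borderline venom depends on the optional
  low-PIII rule (above).
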