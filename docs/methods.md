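# Methods

This note documents the models, conventions and design choices behind
`optonose`, what the synthetic-data generator does and does not emulate, and
the problem sizes the validation suite runs at.

## Response model and scoring

A dye spot's response to an exposure is the Euclidean (L2) distance in
(R, G, B) space between the exposed spot's aggregated reading and the paired
unexposed control strip. Distances are computed on raw aggregated channel
counts with no normalisation or white balancing: the metric is
scale-equivariant (multiplying all channels by s > 0 multiplies every
distance by s), so any global sensor gain cancels out of rankings,
correlations and classifications built on it. Replicate aggregation is the
channel-wise arithmetic mean of the 10 raw sensor reads per spot; the
replicate standard deviation is retained alongside the mean for error bars.
Channels are stored as floats on a 0–255 scale (the usual 8-bit RGB driver
convention); the full-scale value is configurable, and saturated or
non-finite channel values are rejected at parse time rather than imputed.

Controls are separate unexposed strips paired by batch, carried in the
readings table via an `is_control` flag, not time-zero readings of the same
strip. Reading-table parsing groups raw rows by
(panel, gas, concentration, replicate, day, condition) and errors loudly on
missing control rows, out-of-panel spot indices or malformed numerics.

## Screening and panel selection

Selectivity is scored by average subtraction: a dye's mean response to one
gas minus its mean response across all screened gases. By construction each
dye's deviations sum to zero, so a large positive deviation identifies a gas
the dye is disproportionately sensitive to. Redundancy between dyes is
measured by the Pearson correlation of their response profiles across all
shared exposures; a dye with zero variance is reported as having undefined
correlations rather than propagating NaN.

Panel selection is deterministic: (1) drop every dye whose largest deviation
is for water vapour — the operational definition of "water-sensitive", since
humidity is ubiquitous and uninformative; (2) take the three top-ranked dyes
by target-analyte deviation; (3) for each other non-water gas, take the
top-ranked unselected dye; (4) during the per-gas picks, skip (and record)
any candidate correlating above 0.95 with an already-selected dye; (5) stop
at eight spots, warning on a partial panel rather than padding. Ranking ties
break lexicographically by dye identifier so results are reproducible.

Two deliberate choices here were genuinely open. First, the correlation
filter is *not* applied inside the target trio: three dyes tuned to the same
analyte co-respond by nature (their profiles typically correlate at
0.94–0.99), and the procedure intentionally stacks three of them for target
sensitivity; filtering there would collapse the trio to a single dye.
Second, deviations — not raw sensitivities — drive both the target and the
per-gas picks, because a dye with the largest *difference from its own
average* maximises signal while minimising interference from other gases.
Because published phrasing of "x% higher than the average" is ambiguous
between (d−mean)/mean and d/mean, the audit helper reports both conventions.

## Calibration

Headspace concentration from injecting V₁ µL of a liquid volatile (purity p,
density d g/mL, molecular weight M g/mol) into a sealed V₂-litre container is

    c [ppm] = 22.4 · p · d · V₁ / (M · V₂),

implemented exactly in this conventional printed form, with 22.4 L/mol the
molar volume at STP. Strict dimensional analysis of µL/(g/mol·L) on a
volume-ppm scale would carry an additional 10³ factor; a
`physical_units=True` flag applies it for users who want the dimensionally
consistent variant, while the default keeps the standard convention. The
injection-volume solver is the exact algebraic inverse.

The dose-response form is a rectangular hyperbola (Langmuir isotherm),
r(c) = baseline + r_max·c/(K+c), chosen because paper-dye responses saturate
at low ppm while no mechanistic functional form is established; it is the
simplest strictly increasing saturating curve with an analytic inverse. It
is fitted by bounded least squares (scipy `curve_fit`, trust-region
reflective) with data-driven initial values; non-convergence raises with
diagnostics, and non-monotonic replicate means beyond the pooled replicate
sd are recorded as warnings.

The linear range is detected as the widest window of consecutive distinct
concentrations, anchored at the lowest one, whose ordinary linear fit
reaches R² ≥ 0.98 (threshold configurable; minimum three distinct
concentrations; if even the minimal window misses the threshold it is used
with a warning). The limit of detection follows the ICH-style convention
LOD = 3.3·σ/slope with σ the residual sd of the linear-window fit — note σ
includes lack-of-fit curvature as well as noise, which is the honest
operational detection limit of the linearised readout. Inversion of the
Langmuir curve is analytic, c = K·(r−b)/(r_max−(r−b)); estimates above the
linear range are flagged "saturated" (qualitative only), responses at or
above the plateau are flagged "out-of-range" with no extrapolated number,
and responses below baseline map to 0 ppm.

## Fingerprint identification

PCA centres (optionally standardises to unit variance) the dye columns and
eigen-decomposes the covariance (via scikit-learn's full-SVD solver). Signs
are fixed so each loading's largest-magnitude entry is positive, making
outputs identical across linear-algebra backends. Standardisation defaults
to ON for condition analysis because dyes differ widely in response
magnitude, and OFF reproduces a raw-covariance PCA; the number of retained
components is a parameter rather than a fixed 2 or 3. A zero-variance dye
column under standardisation is an error naming the dye.

KNN classification is written in-package because its tie-breaks are part of
the contract: the majority label among the k nearest training fingerprints
(Euclidean), vote ties resolved by the single nearest neighbour's label,
distance ties by training order (stable sort). k defaults to 3.

Condition separability evaluates, per day, leave-one-out KNN accuracy over
that day's fingerprints plus the mean silhouette of condition groups in the
first-two-PC plane; a day is "separable" when LOO accuracy ≥ 0.9 (the
threshold is ours — published day-level separation claims are typically
visual — and configurable). Days with a single condition are skipped with a
note.

## Synthetic ground truth

The generator plants, per (dye, gas): a maximal response magnitude
(affinity), a half-saturation concentration, and a fixed unit direction in
RGB space; exposure to a mixture moves the spot colour from its per-dye
control baseline (near the pale-paper (200, 200, 180), jittered) by the
vector sum of Langmuir magnitudes along those directions. Directions have
non-positive components — dye spots darken/bleach from pale paper — which
both mimics real chromogenic behaviour and keeps default responses inside
the 0–255 sensor range; any clipping increments a counter, and defaults
produce none.

Each dye prefers one gas, assigned round-robin, with affinity
`selectivity_contrast × 40` counts (contrast default 4, must exceed 1) and
half-saturation near 5 ppm; dyes sharing a preferred gas have affinities
shrunk geometrically (×1.3⁻¹ per extra dye) so "the best dye for gas g" is
strictly defined in the truth. Off-target affinities are 0.3–0.9 × 40
counts with half-saturations of 2–8 ppm, capped at 0.7× the preferred
affinity so the preferred gas dominates by construction. Water vapour is an
ordinary gas column, so humidity cross-talk and water-preferring dyes fall
out of the same machinery.

Noise has two planted parts: per-channel Gaussian *strip* noise
(`noise_sd`, default 1 count, applied independently to test and control
strips — strip-to-strip manufacturing variability dominates), and small
per-read instrument noise (`read_noise_sd`, default 0.3 counts) on each of
the 10 raw reads. The test−control channel difference therefore has sd
√2·noise_sd, and the noisy distance follows a scaled noncentral-χ(3)
distribution — the closed form the Monte-Carlo tests check against.

The default 5-day stress time course plants, per condition (control, high
salinity, nutrient starvation), per-day emissions of the target aldehyde
plus two auxiliary volatiles. The aldehyde declines over days in all
conditions, runs higher under salinity than control on days 1–3 and under
starvation than control on days 1–2, with salinity above starvation
throughout; day-1 differences (3.00/3.02/3.05 ppm) are deliberately far
below measurement noise. From day 2 each stress additionally shifts its own
auxiliary volatile (ethanol for starvation, acetone for salinity, 0.5 → 2.0
ppm), reflecting that stressed plants alter a *blend* of emissions: this is
what keeps the multi-dye fingerprints separable on days 4–5 even after the
aldehyde trajectories converge, while day 1 remains inseparable.

What the generator does **not** emulate: mechanistic dye chemistry (pH
indicator equilibria, porphyrin coordination, cyclodextrin inclusion,
quantum-dot quenching) — adjuvant effects appear only as planted affinity
patterns; drift, temperature effects and ambient-light variability;
non-Gaussian or correlated noise; and real biological variability between
plants beyond the replicate noise model. Passing tests therefore demonstrate
the correctness and statistical behaviour of the *analysis*, not the
performance of any physical sensor.

## Validation scales and numerical choices

The test suite validates: exact oracle agreement of the distance formula on
10⁵ random pairs and metric axioms on 10⁴ triples; headspace-formula
identities over 10⁴ random gas specifications; screening recovery of the
planted panel over 100 seeds (19 dyes × 7 gases × triplicates, contrast 3);
Langmuir recovery (plateau 100, half-saturation 10 ppm, σ = 1, six
concentrations 0.5–25 ppm in triplicate, 100 seeds, median within 20%);
LOD self-consistency and noise-halving on a near-linear truth (100 seeds);
PCA fractions against an explicit covariance-eigendecomposition oracle; and
stress separability (days ≥ 2 and not day 1) over 100 seeds with
label-shuffled nulls. These sizes keep the full suite under a minute on a
single core while leaving the statistical margins wide.

Numerical conventions: replicate summary is the mean; Pearson correlations
are clipped into [−1, 1] against rounding; PCA uses the full SVD solver;
ranking ties break lexicographically; all simulation entry points take an
integer seed and produce byte-identical outputs for equal seeds.

## Known limitations

- The Langmuir form is an assumption; strongly sigmoidal or biphasic dye
  responses would need a different model (the linear-range/LOD machinery
  would carry over).
- LOD inherits lack-of-fit from the linearised window; with strongly curved
  truths it is conservative relative to a noise-only σ.
- The correlation filter compares only against already-selected dyes, so
  selection can depend on gas ordering in principle; gas order is fixed by
  first appearance for determinism.
- Fingerprints are capped at eight dyes, matching the physical eight-section
  sensor paper.
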