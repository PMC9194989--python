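# Methods

`tldose` implements the measurement-side analysis of infant CT
dosimetry: converting thermoluminescent-dosimeter (TLD) readings taken
inside a 1-year-old anthropomorphic phantom into organ absorbed doses,
skeletal-tissue doses and ICRP 103 effective doses, normalised to
CTDI_vol, and comparing the result against organ-dose tables produced by
Monte Carlo dosimetry software.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## TLD processing

A batch of LiF:Mg,Cu,P chips is characterised by repeated uniform
irradiations.  Per run, a chip's sensitivity factor (SF) is its charge
divided by the batch-mean charge; the chip's SF is the mean over runs.
Chips are rejected once, at characterisation, if any per-run SF falls
outside ±10 % of unity or the replicate SFs are not reproducible within
±10 % of their own mean.  Annealing/readout settings are campaign
metadata; no thermal or fading model is applied (glow-curve
deconvolution and supralinearity corrections are out of scope).

The calibration factor CF (Gy/nC) is the nominal calibration dose
(default 0.5 Gy, delivered on a beam-quality-matched orthovoltage unit)
divided by the mean SF-corrected charge of the calibration chips.  The
per-chip dose is

    D_n = (SF_n · r_n − b) · CF

with `r_n` the raw charge and `b` the background charge.  The background
is subtracted from the sensitivity-corrected *charge*, before the
charge→dose conversion: `b` is a charge-domain quantity, and subtracting
it after multiplying by CF would mix units.  (The alternative reading is
selectable via `background_in_dose=True` for sensitivity studies.)  `b`
is the mean of the five unexposed chips' SF-corrected charges — the
minimum-variance aggregate in the absence of a stated rule.  Negative
net signals are clamped to zero and flagged rather than reported as
negative doses.

Each scan is acquired twice; chips whose two doses differ by more than
20 % of their pair mean are flagged for a third measurement, and the run
farthest from the median of the three is dropped.

## Beam model and tissue conversion

The CT beam is modelled analytically: Kramers-form bremsstrahlung
N(E) ∝ (kVp − E)/E on 1-keV bins from 10 keV to the tube potential,
filtered by exponential attenuation through the listed (material, mm)
pairs, normalised to unit fluence.  Characteristic anode lines are
omitted — they are second order for mass-energy-absorption ratios.
Measured or externally simulated spectra can be supplied as
(keV, fluence) CSVs and used everywhere the analytic model would be.

Beam quality is summarised by the aluminium half-value layer (HVL),
solved by bracketed bisection to 1e-4 mm on the air-kerma-weighted
transmission (weights fluence·E·(μen/ρ)_air), and by the effective
energy: the monoenergetic energy whose μ_Al equals ln 2 / HVL, found by
log-log inverse interpolation of the Al attenuation table.  The beam /
calibration matching check passes when effective energies agree within
±5 keV (inclusive).  HVL-matched effective energy is the adopted
definition — standard in diagnostic physics; fluence-weighted mean
energy is also exposed (`mean_energy`) for comparison.

Water dose converts to tissue dose through the spectrum-weighted ratio

    f_T = Σ w(E)·[μen/ρ]_T(E) / Σ w(E)·[μen/ρ]_W(E),   w(E) = Φ(E)·E

i.e. a ratio of spectrum-averaged coefficients with energy-fluence
weighting (absorbed dose is proportional to energy fluence times
μen/ρ).  The unattenuated beam spectrum is used deliberately: no
adjustment is made for phantom scatter or depth hardening.  The factor
is invariant to fluence normalisation; at ≤1 keV bins the discrete sum
agrees with trapezoid integration to well under 0.5 %.

Coefficient tables are log-log interpolated: μen/ρ spans three decades
over 10–150 keV and is near power-law, so log-log is exact at grid
points and faithful between them.  Out-of-grid queries raise; nothing
extrapolates.

## Organ aggregation

An organ's dose is the mean of the tissue-converted doses of all its
chip measurements, both scan sessions pooled; the uncertainty is one
*sample* standard deviation (ddof = 1) of that pooled set — the
conservative convention where none is prescribed.  Special rules:

- **Colon** — five segments (ascending 3, transverse 3, descending 2,
  sigmoid 2, rectum 1 chips) combined by segment mass fractions
  (fixture sums to 1; SD propagated as √Σ f² σ²).
- **Muscle** — unweighted mean over all torso and leg chips, excluding
  surface (skin), lens and the spine chips (which report their own
  rows).
- **Skin** — the six dedicated surface chips only.
- **Single-chip organs** (heart, kidney, spleen, pancreas, uterus,
  prostate) report the spread of their two repeat measurements; with
  identical runs an SD of 0 is reported honestly.
- **Pancreas** has no stated chip position in the physical layout; the
  default map assigns it one mid-abdomen chip.  This is a package
  choice, not a documented feature of the campaign.

Organs without a dedicated μen/ρ table map to soft tissue via a
configurable alias.

## Skeletal dosimetry

Red-bone-marrow (RBM) and shallow-marrow ("bone surface") doses follow

    D = Σ_i  D_W,i · f_i · (1 + S_i) · M_i / M_total

over the five instrumented skeletal sites (legs, pelvis, rib, spine,
skull).  D_W,i is the site's mean chip water dose (the same raw
readings feed both compartments), f_i the water-to-marrow conversion,
S_i the site's dose enhancement factor (DEF — extra dose from
photoelectrons released in adjacent trabecular bone), and M_i/M_total
the site's share of the skeleton's marrow mass.  The shallow-marrow
conversion mixes red- and yellow-marrow coefficients by site
cellularity before the spectrum weighting.  DEFs are scalar per-site
factors for a fixed beam quality, matching how published site factors
are applied; an energy-resolved DEF table would trigger spectral
averaging but none ships by default.  Site mass fractions must close to
1; partial-skeleton computation requires an explicit renormalisation
flag.

The bundled skeletal fixture uses age-1 style masses (150 g total RBM),
full cellularity, and *adult* shallow-marrow DEFs: comprehensive
pediatric shallow DEFs are not available in the literature, so the
fixture values must not be read as pediatric ground truth.

## Effective dose

E = Σ_T w_T·D_T with the ICRP 103 weights (0.12 × {RBM, colon, lung,
stomach, breast, remainder}, 0.08 gonads, 0.04 × {bladder, esophagus,
liver, thyroid}, 0.01 × {bone surface, brain, salivary glands, skin}).
The gonad dose is the testes (male) or ovaries (female).  The remainder
block takes the single 0.12 weight applied to the unweighted mean of
the *measured* remainder organs: heart, kidney, muscle, pancreas, small
bowel, spleen, plus prostate (male) or uterus (female).  This is the
measured-organ intersection of the ICRP 103 remainder list; the
membership is configurable.  Breast enters at full weight for both
sexes — the physical phantom is hermaphroditic.  Lens and spine carry
zero weight and never enter E.

The standard error is first-order uncorrelated propagation of the
weighted sum, SE = √(Σ w_T² σ_T²), with the remainder SD propagated
through its mean as √(Σ σ²)/k.  Organ SDs (1 SD of pooled
measurements) stand in as the per-organ uncertainties.  Effective doses
are also reported per mGy CTDI_vol (32-cm reference phantom).

## Software comparison

Dosimetry packages report sex-specific organ doses; non-reproductive
organs whose male/female values agree within 5 % are averaged into a
hermaphroditic dose comparable to the sexless phantom.  Larger splits
are still averaged but flagged; prostate, testes, ovaries and uterus
pass through per sex.  Agreement per cell is the signed percentage
variation (D_soft − D_ref)/D_ref × 100; summaries average |variation|
over organ × protocol cells (signed means would let over- and
underestimates cancel; a signed mode exists behind a flag), with an
optional organ exclusion set for known outliers such as bone surface.
Organ vocabularies are mapped through an alias CSV; an unmatched name
is a hard error, and organs a package does not report stay null, never
zero.

## Synthetic data generator

The generator emulates the measurement campaign from a declared ground
truth and inverts the processing chain exactly:

- **Chip batch** — 115 chips, three sensitivity runs, base response
  4 nC (200 mGy at a nominal 0.05 Gy/nC).  Inlier chip factors are
  normal (σ = 0.02) clipped to ±5 %; the 8 declared outliers sit at
  ≥ ±15 %, so characterisation must reject exactly the declared set.
  Per-run readout noise is 0.5 % lognormal.
- **Scan readings** — two repeat sessions; per-chip charge
  r = (D_true/CF_true·η + b·η′)/SF with unit-mean lognormal noise
  (default CV 5 %), additive background charge 0.005 nC, CF_true
  0.05 Gy/nC, five background chips and five calibration chips (0.5 Gy
  nominal, exposed at each session and read out in one sitting, hence
  no accrued background).  Calibration and placement chips are drawn at
  random from the active batch.
- **Ground truth** — per-organ water-equivalent doses default to the
  measured CTDI_vol-normalised organ doses times the protocol's
  CTDI_vol, so end-to-end runs land on campaign-scale numbers (~20 mGy
  per organ at protocol 1).  Skeletal-site water doses are proxied by
  adjacent organs (spine row for spine, brain for skull, muscle for
  legs/pelvis/rib).
- **Software tables** — reference dose × declared multiplicative bias,
  so the comparison harness must recover (bias − 1)·100 exactly.

What it does *not* emulate: phantom geometry and dose gradients within
an organ (all chips of an organ share one true dose), energy dependence
of the TLD material, scatter tails outside the scan range, fading, and
scanner-specific bowtie spectra.  Passing recovery tests therefore
demonstrate correctness of the *processing chain*, not fidelity of any
physical transport model.

## Numerical choices and limitations

- All noise is seeded (`numpy.random.default_rng`); identical seeds
  give bit-identical campaigns on any platform.
- HVL bisection tolerance 1e-4 mm; weight/mass-fraction closure
  tolerances 1e-9 (weights, colon) and 1e-6 (skeletal masses).
- Test and demonstration problem sizes mirror the campaign itself (115
  chips, 94 placed, two sessions); a full end-to-end run takes well
  under a second.
- Coefficient fixtures (μen/ρ, attenuation, marrow masses, DEFs, colon
  fractions) are representative values in the style of the standard
  compilations (ICRU 46, NIST, ICRP 70/89/110) shipped as editable CSVs
  with provenance columns; swap in your own tables for
  metrology-grade work.
- The effective-dose reconstruction from the bundled measured organ
  table is sensitive to the remainder membership; the default
  (measured-organ intersection) reproduces the published normalised
  effective doses to about 1 %.
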