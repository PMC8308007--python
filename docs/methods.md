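# Methods

## The screening model

The package implements deterministic point-estimate dietary risk screening
for trace elements in powdered foods, in the form used by regulatory
exposure assessments (US EPA-style reference doses and slope factors).

For one sample, one element and one exposure scenario:

```
EDI = C × (m_serving / 1000 × k) / BW      µg·kgBW⁻¹·day⁻¹
HQ  = EDI / RfD                            dimensionless
HI  = Σ HQ over the additive list          dimensionless
CR  = EDI ⊘ CSF                            dimensionless risk
```

with `C` the element concentration in the powder (µg·kg⁻¹), `m_serving`
the manufacturer serving mass (g; the single g→kg conversion point is in
`compute_edi`), `k` the daily serving count, `BW` body weight (default
70 kg), `RfD` the oral reference dose (µg·kg⁻¹·day⁻¹) and `CSF` the
cancer slope-factor constant ((µg·kg⁻¹·day⁻¹)⁻¹).

Assumptions inherited from this model class: chronic intake at a constant
rate, additivity of hazard quotients across co-occurring elements (no
interaction terms), linear no-threshold carcinogenesis, and a single
deterministic consumer (no body-weight or intake distribution). These are
screening-level simplifications, not dose–response modelling.

### The slope-factor convention

The conventional definition of cancer risk is `CR = EDI × CSF`. The
tabulated risk values this package reproduces, however, are only obtained
by *dividing* the intake by the slope-factor constant; multiplication does
not reproduce any of them, division reproduces all spot-checked cells at
both serving counts. Both modes are therefore implemented
(`CRConvention.TABLE_MATCH`, the default, divides; `LITERAL` multiplies;
they differ by a factor CSF², which a property test pins down), and every
report names the mode in force. The package takes no position on intent
beyond defaulting to the convention that matches the reference tables.

### Element lists

HI membership is a fixed 15-element list carried as data in the
toxicological reference table (`in_hi_list`), not "everything with an
RfD": the reference table also carries the Cr(VI) constants (RfD 3.0,
CSF 500) on a row that sits on neither risk list, because only total Cr is
measured and the Cr(VI) constants do not apply to it. Pt, Au, Bi, Mg and
Ti have no reference dose and are excluded from HQ/HI by data, not code.
The carcinogen list is Be, Cd, Pb.

## Censoring semantics

A concentration cell is exactly one of *quantified*, *below-limit* (with
its reporting limit, the `<X` of the source table) or *above-range* (the
measurement exceeded the top calibration standard; no number exists for it
without re-analysis at higher dilution).

- Below-limit values enter the intake arithmetic by policy: `zero`
  (default), `half_limit` (L/2) or `at_limit` (L). Zero is the default
  because it reproduces the reference hazard-index tabulation to <0.1% on
  the golden row; the other two are retained for sensitivity analysis and
  are guaranteed (and property-tested) to order HI monotonically:
  HI(zero) ≤ HI(half) ≤ HI(limit). Substituting zero biases the screen low
  for heavily censored elements — this is visible, not hidden: exposure
  rows record the policy used.
- Above-range values are *excluded* from all sums and counted per sample
  (`n_excluded` in the risk table), so the resulting under-estimate of HI
  is visible in the report. An `error` policy is available for pipelines
  that must not tolerate unquantifiable cells.

## Dilution back-calculation

`C_powder = C_solution × DF × V / W`, with the returned digest volume
recorded in mL and converted to litres inside the function so that
µg·L⁻¹ × L / kg yields µg·kg⁻¹. DF defaults to 5 (the 1:5 pre-analysis
dilution); the analysis path refuses to back-calculate without an explicit
returned volume — the nominal 10 mL default lives only in the synthetic
generator, where no measured volume exists. The forward transform is the
exact algebraic inverse; a 1000-case property test holds the round trip to
1e-12 relative.

## QC rules

Percent recovery is `100 × measured / expected`; acceptance bands are
inclusive at both endpoints (the conventional reading of "100 ± 25%"),
75–125% for matrix-spiked controls and 80–120% for certified reference
material. Replicate RSD is carried and reported but never gates a verdict.
Resolution-transmission gates (MR/LR in 10–12%, HR/LR in 1–2% for ¹¹⁵In)
are hard inclusive bounds with an optional symmetric tolerance (default
0); low-resolution sensitivity requires ≥ 100,000 cps. Footnoted fallback
measurements (carryover reruns, diluent readback standards) are carried as
annotations on the control object, not as separate verdict logic.

## Packaged study fixtures

The package embeds a 36-sample protein-powder panel (27 whey, 2 pea,
2 soy, 2 mixed-plant, 2 whey/soy/egg blends, 1 casein; 20 reported
elements — Mg exceeded the calibration range in every sample and is
absent), its serving and digestion masses, the toxicological constants,
and a 96-row batch QC recovery table. These are byte-stable transcriptions
of a published study's printed tables and serve as the golden dataset for
the acceptance tests.

Two cells of the reference hazard-index tabulation (samples P12 and P31)
are not reproducible from the study's own printed inputs under any
censoring policy (recomputed values are ~13% and ~6% low respectively);
the acceptance suite documents this as a known discrepancy of the source
tabulation rather than adjusting any fixture value.

## Synthetic panel generator

The generator emulates the measurement chain end to end: true powder
concentration → forward dilution transform → multiplicative Gaussian read
noise → back-calculation → censoring.

- **True concentrations** are log-uniform over each element's observed
  span in the packaged panel (those spans cover 2–4 orders of magnitude;
  uniform sampling would make censoring events either vanishingly rare or
  dominant).
- **Noise** is multiplicative Gaussian truncated at zero, at per-element
  RSD levels defaulting to the packaged QC batch medians (0.1–13%) — the
  simplest model consistent with percent-RSD reporting. A calibration test
  checks that 1000 replicates at 5% nominal RSD show 5% ± 0.5% empirical
  RSD.
- **Censoring**: back-calculated values below the element's
  powder-equivalent quantification limit become below-limit records;
  solution readings above the top calibration standard (50 µg·L⁻¹ default)
  become above-range records.
- **Sample metadata**: weighed mass uniform on 0.41–0.52 g, serving mass
  drawn from the serving sizes occurring in the packaged study, returned
  volume fixed at a nominal 10 mL (per-sample volumes are unpublished;
  the choice is flagged in generated metadata).
- **Determinism**: a single global seed keys one independent
  counter-derived stream per (sample, element) via numpy `SeedSequence`
  spawn keys over the fixed panel order, so identical seeds give
  bit-identical output and enlarging the element set never perturbs draws
  already made for other elements.

What the generator does **not** emulate: spectral interferences, plasma or
calibration drift, internal-standard correction, or digestion recovery
losses. Synthetic panels therefore validate the pipeline's arithmetic,
censoring logic and report plumbing — passing tests on synthetic data say
nothing about instrument-level failure modes in real panels.

## Numerical choices

- Internal computation is never rounded; report formatting rounds HI to
  3 decimals and cancer risk to 2-significant-figure scientific notation.
- Classification thresholds follow the reference tabulation's legends:
  HI is *elevated* strictly above 1; cancer risk is *low* up to and
  including the threshold (default 10⁻⁴, configurable — exceedance counts
  take the threshold as a parameter because different narratives use 10⁻⁴
  and 10⁻³ cuts).
- Exceedance counts are strict (`>`).
- Element identity is the bare chemical symbol; isotope-labelled input
  columns (`208Pb`, `²⁰⁸Pb`, `^63^Cu`) are normalised at ingestion only.
- `RiskAssessment.fit()` is deterministic — "fit" evaluates the exposure
  model over the data (the statsmodels-style Model → Results shape is kept
  for its ergonomics), it does not estimate parameters.

## Problem sizes

The packaged panel is 36 samples × 20 elements; the full acceptance run
(including the 1000-replicate noise calibration and 1000-case round-trip
property suite) completes in a few seconds.

## Known limitations

- No probabilistic or age-stratified exposure; single point-estimate
  consumer.
- No LOD/LOQ estimation, calibration regression or drift correction; the
  quantification limits are taken as given.
- Censoring substitution (zero / L/2 / L) is the classical crude approach;
  no maximum-likelihood or Kaplan–Meier treatment of left-censored data.
- The table-matching slope-factor convention is an empirical choice to
  reproduce the reference tabulation; users wanting the conventional
  product form must select `literal` explicitly.
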