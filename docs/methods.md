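# Methods

## Reporter model

The reporter transcript expresses firefly luciferase (FFL) from every copy
and an FFL–Nanoluciferase (Nluc) fusion only from copies edited at the
recoded stop codon. With editing fraction `e`, fusion stability `s`,
per-molecule brightness ratio `β` and amplitude `A` (arbitrary counts):

```
FFL  = A · [(1 − e) + s·e]
Nluc = A · e · s · β · η
```

Unedited transcripts contribute free FFL; edited transcripts contribute
the fusion, which carries both activities but at the reduced steady-state
level `s` because the fusion protein is rapidly turned over. `η` is an
Nluc-enzyme inhibition factor (1 except for Nluc-enzyme inhibitors). The
measured ratio is therefore

```
Nluc/FFL = β·e·s / (1 − e + s·e),
```

which reduces to the naive brightness-only arithmetic `β·e`
(`naive_ratio`) when `s = 1` and FFL depletion is ignored. The naive model
predicts a ratio of 1.5 at 1% editing and 150 at full editing for
`β = 150`; observed ratios sit far below that, which the model attributes
entirely to `s ≪ 1`.

Compound action enters through a Hill occupancy
`f = max_effect · doseʰ / (doseʰ + IC50ʰ)` shared by all mechanism
classes — one potency/shape parameterisation keeps the generator minimal
and matches concentration-dependent inhibitor behaviour:

- *editing inhibitor*: `e = e₀(1 − f)`
- *editing activator*: `e = e₀ + (1 − e₀)f` (modelled symmetrically to
  inhibitors; activator mechanisms are not otherwise specified)
- *Nluc-enzyme inhibitor*: `η = 1 − f` (ratio drops, FFL untouched — the
  designed false-positive class, separable only by a counter-screen)
- *cytotoxic*: both channels × `(1 − f)` (ratio invariant, FFL drops —
  caught by the toxicity filter, not the ratio)

`editing_dose_curve(dose) = e_max(1 − e^{−k·dose})` maps an ADAR-expression
surrogate (e.g. transfected plasmid amount) to editing. Its saturating form
makes editing rise log-like in expression while the ratio stays
near-linear, so the ratio is convex when plotted against editing percent —
the qualitative chain the reporter exhibits.

### Defaults

| parameter | default | meaning |
|---|---|---|
| β | 150 | per-molecule Nluc:FFL brightness ratio |
| s | 0.01 | fusion steady-state level vs free FFL; a free simulator parameter chosen so defaults reproduce the qualitative gap between measured and naive ratios, not an estimate |
| e₀ | 0.39 | baseline editing of the high-editing HeLa reporter clone |
| amplitude | 10⁶ | arbitrary counts |

A consequence of the FFL term worth knowing: a *strong* editing activator
depresses FFL (most transcripts become the unstable fusion), so at
saturating potency activators are removed by the 40% FFL filter rather
than flagged; only moderate activators (final `e ≲ 0.64` with the
defaults) appear in the activator list. This is a property of the model,
documented rather than patched, since the assay's real counterpart —
unspecific reporter perturbation — is filtered the same way.

## Synthetic screens

`simulate_screen` lays a compound library into 384-well plates (columns
1–22 compounds at 10 μM, column 23 vehicle, column 24 the positive control:
an Nluc-enzyme inhibitor with IC50 0.08 μM, the potency of the
best-characterised control inhibitor, quenching Nluc by 10/10.08 ≈ 99.2%).
Observed counts are expected signals × independent mean-1 lognormal noise
per channel. Lognormal (not additive Gaussian) noise keeps counts positive
and CV-stable. Defaults:

- noise CV 0.08 per channel. For a well with expected ratio `r₀` the
  observed control-ratio moments are closed-form
  (`mean = r₀(1+cv_f²)`, `sd = mean·√((1+cv_n²)(1+cv_f²)−1)`), giving an
  expected plate Z′ of ≈ 0.66 at the defaults — the quality band of a good
  campaign; tests verify simulated plates match this closed form.
- library 33 000 compounds (94 plates), mechanism mix 97.65% inactive,
  0.6% editing inhibitor, 0.25% activator, 0.5% Nluc-enzyme inhibitor,
  1% cytotoxic, IC50s log-uniform on 0.01–10 μM (per-action ranges
  configurable). The mix is illustrative — the true mechanism composition
  behind a primary hit list is unknowable without counter-screens — and
  yields a sub-percent primary hit rate at the default thresholds.
- no plate gradients by default (an optional linear row/column term exists
  for robustness testing); FFL read decay 0.5/h (one-hour half-life) and
  stable Nluc, applied only when a read delay is given.

`simulate_trace` emits per-call A/C/G/T peak heights: at the edited site
G ∝ editing% and A ∝ 100 − editing%; elsewhere the called base carries the
full peak. The default peak baseline is 0 so zero-noise round-trip through
`editing_pct` is exact; a nonzero baseline is available and is the main
divergence risk against background-correcting chromatogram viewers.

What the simulator does **not** emulate: cell-growth or transfection
variability, interferon kinetics, compound fluorescence/quenching
artefacts other than the Nluc-enzyme class, plate-edge effects (unless the
gradient is enabled), or correlated channel noise. Passing tests therefore
demonstrate the pipeline's statistical behaviour under the stated noise
model, not performance on any particular real campaign.

## Screening statistics

- Control summaries use per-plate sample means and SDs (ddof = 1), the
  moments the Z′ formula is written in; a robust (median/MAD) option was
  considered and left out of the default path.
- Normalisation is per plate, never global; percent inhibition is
  invariant under a common rescaling of a plate's ratios, so
  cytotoxicity-free global effects cancel.
- Threshold conventions: hit at inhibition **≥ 70** (inclusive), toxic at
  FFL inhibition **> 40** (strict), following the usual wording of
  screening protocols ("threshold set to" vs "higher than"); both
  configurable. The activator threshold (−50%) is a package choice with no
  external reference point.
- A well with FFL ≤ 0 is excluded with a recorded reason (dead well), not
  scored as 0. A plate failing the Z′ gate (default 0.4) is excluded
  whole, logged. A compound appearing on two plates is an error — the
  primary screen format has one well per compound.
- No multiple-testing correction anywhere: hit calling uses fixed
  normalised thresholds, not p-values, by design.

### Dose–response

`fit_4pl` fits `bottom + (top − bottom)/(1 + exp(h·(ln IC50 − ln d)))` by
least squares (scipy `curve_fit`), IC50 on the log scale, initialised at
the geometric mid-dose with h = 1. Non-convergence — optimizer failure, a
flat response (range < 10⁻⁹), or an IC50 more than two decades outside the
tested dose span — is reported via `converged=False`, never an exception.
The constrained variant fixes bottom/top at 0/100 for sparse 3-point
confirmation data.

`retest` confirms a hit when all doses were measurable, inhibition is
monotone non-decreasing with dose up to a 10-point dip allowance
(measurement-noise tolerance), and the top dose reaches the hit threshold.
Toxicity is not re-filtered at retest (already applied upstream).

## Sanger quantification

`editing % = 100·G/(A+G)` from peak heights at the base call; C and T are
ignored and the statistic is scale-invariant. The site is located as
anchor start + signed offset, where the anchor (≥ 10 nt, typically the
RT-PCR primer) must match exactly once on either strand; for a
minus-strand match the offset is walked in the anchor's orientation and
flipped back to trace coordinates. `offtarget_scan` reports editing at
every reference adenosine within a ± window (truncated at trace ends),
suppressing calls below `min_pct` (default 5%) from the list but counting
them in the summary. Coordinates are 0-based internally, 1-based in
reports. Peak *height* is used, not area, and no baseline subtraction is
applied by default.

## Group comparisons

`fold_change` is mean(treated)/mean(control) with a two-sided two-sample
Student's t-test (equal variances; Welch behind a flag). With n < 2 in
either group the fold is reported without a p-value. Stars: ** p < 0.01,
*** p < 0.001. Replicates are compared as given; when normalising to an
untreated reference, normalise per replicate before averaging.

## Problem sizes in the test suite

Monte-Carlo checks use sizes chosen for tight-but-cheap statistics: 100
simulated plates for the Z′ closed-form comparison (tolerance 0.02,
several times the standard error of the mean), 30 plates per point on the
CV grid, 10 seeds × 704 compounds for planted-inhibitor recall, 20 seeds
for IC50 recovery at 5% noise, 200 traces for peak-height recovery error,
and one full-scale 94-plate screen end-to-end. The hypothesis profile is
derandomised so runs are reproducible.
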