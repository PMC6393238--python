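# editscreen

Analytics for high-throughput screens built on a dual-luciferase A-to-I RNA
editing reporter, plus a mechanistic simulator that generates complete
synthetic screens for testing and power analysis.

## The assay

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA; inosine
is read as guanosine. The reporter places firefly luciferase (FFL) upstream
of a GluA2 R/G-site hairpin whose editing site has been recoded to an amber
stop codon (UAG): editing converts it to a tryptophan codon (UGG), allowing
read-through into an in-frame Nanoluciferase (Nluc). Every transcript makes
FFL; only edited transcripts make Nluc, so the per-well **Nluc/FFL ratio**
is an internally normalised editing statistic.

A 384-well screening plate carries library compounds in columns 1–22,
vehicle (0.1% DMSO) negative controls in column 23 and a 10 μM Nluc-enzyme
inhibitor as the 100%-inhibition positive control in column 24. The
pipeline implements:

- **Plate QC** by the screening-window Z′-factor,
  `Z′ = 1 − 3(σp + σn) / |μp − μn|`, computed per plate on control ratios;
  plates below a configurable minimum (default 0.4) are excluded.
- **Per-plate normalisation** of each compound well's ratio to percent
  inhibition: the negative-control mean maps to 0%, the positive-control
  mean to 100%.
- **Cytotoxicity filtering**: compounds whose FFL signal drops more than
  40% below the negative-control FFL mean are removed before hit calling.
- **Hit calling** at ≥ 70% ratio inhibition; ratio *activators* are flagged
  at ≤ −50% (i.e. ≥ 50% activation).
- **Confirmation**: retest at 2.5 / 5 / 10 μM with a monotone-dose check,
  and four-parameter logistic (4PL) IC50 fitting.
- **Sanger quantification** of editing from chromatogram peak heights,
  `editing % = 100 · G / (A + G)` at the anchored site, with off-target
  scanning of flanking adenosines. AB1 traces (via Biopython) or plain
  peak-height CSVs are accepted.
- **Fold-change comparisons** (two-sided Student's t-test) for knockdown /
  interferon-induction experiments.

The simulator (`editscreen.synth_screen`) generates screens from a
mechanistic reporter model — brightness ratio β, fusion-protein stability
s, baseline editing e₀ — with compounds drawn from five latent mechanism
classes (inactive, editing inhibitor, editing activator, Nluc-enzyme
inhibitor, cytotoxic) acting through Hill occupancy, under multiplicative
lognormal well noise. Ground-truth labels are emitted alongside, so recall,
false-positive modes and QC behaviour are all measurable.

## Worked example

Simulate a 10-plate screen (3 520 compounds, 8% well noise) and analyse it:

```bash
editscreen simulate --n-compounds 3520 --cv 0.08 --seed 1 --out demo
editscreen analyze --measurements demo/measurements.csv \
                   --platemap demo/platemap.csv --out demo_results
```

which prints

```
10 plates (0 failed QC), 3520 compounds, 33 hits (0.9%), 2 activators, 40 toxic-filtered
```

i.e. every plate passed the Z′ gate, 33 compounds reached 70% ratio
inhibition after 40 FFL-toxic compounds were filtered out — a 0.9% primary
hit rate — and 2 compounds increased the ratio by ≥ 50%. `demo_results/`
contains `plate_qc.csv`, `results.csv` (per-compound normalised values and
flags), `hits.csv`, and `summary.json`; `demo/ground_truth.csv` holds the
planted mechanisms for comparison.

The dilution arithmetic for the acoustic-dispense protocol is also exposed:

```python
>>> from editscreen.plate_model import SCREEN_DISPENSE_PLAN, final_concentration
>>> final_concentration(SCREEN_DISPENSE_PLAN)
(9.97008973080758, 0.0997008973080758)
```

60 nl of 10 mM stock into 20 μl, of which 10 μl goes onto cells in 20 μl:
10 μM compound and 0.1% DMSO to the precision quoted on screening
protocols.

Sanger quantification from a peak-height CSV:

```bash
editscreen sanger --trace trace.csv --anchor CATTTGATCACCAGATAAACC --offset 25
```

## File formats

- Measurements CSV: `plate_id,well,channel,value`, channel ∈ {FFL, Nluc},
  one row per well per channel.
- Plate map CSV: `plate_id,well,role,compound_id,dose_uM`, role ∈
  {compound, neg_control, pos_control, empty}.
- Trace CSV: `position,base,A,C,G,T` per base call (`sample` column
  optional).

Wells are `A1`–`P24` (row letter + 1-based column, no zero padding).

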