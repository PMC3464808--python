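# Methods

This note documents the models behind each `tsplasmid` module, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Buried-residue prediction (`tsplasmid.burial`)

Two per-residue tracks are computed over a protein sequence:

* **Windowed average hydrophobicity** — the mean scale value over a
  centred window of `window_avg` residues (default 7, odd). Short windows
  respond to compact buried stretches; the 7-residue default is a common
  choice for core-packing detection.
* **Hydrophobic moment** μH — per window of `window_moment` residues
  (default 11, roughly three helical turns), the magnitude of the vector
  sum of hydrophobicities at successive angles of `delta` degrees per
  residue, divided by the window size. `delta = 100°` (default) matches
  the α-helix period of 3.6 residues/turn; 160° probes β-strands. μH is
  invariant under a global rotation of all angles, so only the angular
  *increment* matters.

Terminal windows are truncated to the residues that exist rather than
padded — padding would invent sequence. The hydrophobicity scale defaults
to the Eisenberg consensus scale (the standard scale in hydrophobic-moment
analysis) and is replaceable via a two-column TSV.

**Probability calibration.** Raw track values are mapped to P(buried)
through a logistic `p = expit((x − s0)/k)`. The mapping is a documented
stand-in: the original burial-prediction program's calibration is
unpublished. Defaults were fixed once, at design time, by boundary cases:

* average track `(s0, k) = (0.24, 0.20)`: a poly-Ile window (x = 1.38)
  maps to p ≈ 0.997 ≥ 0.99 and a poly-Asp window (x = −0.90) to
  p ≈ 0.003 ≤ 0.01;
* moment track `(s0, k) = (0.35, 0.08)`: an ideal amphipathic helical
  face (hydrophobic residue every ~3.6 positions) maps well above the
  0.80 region threshold while small-|H| polar backgrounds stay below it.

**Region calling.** Residues with `p_avg > 0.90` or `p_moment > 0.80`
(the two defaults mirror the original site-selection thresholds) are
merged into maximal runs of consecutive candidates (gap tolerance 0); each
region reports one suggested site — the position of the highest triggering
probability, ties resolved toward the average-hydrophobicity track and
then the lower position. All coordinates are 1-based inclusive.

## Library design and screen calls (`tsplasmid.library`)

Each mutant CDS differs from the wild type in exactly one codon, which is
replaced by the **most-frequent codon** for the new amino acid in the
supplied codon-usage table (relative synonymous frequencies; exact ties
break alphabetically for determinism). Substitution panels per site:

* `asp_probe` — Asp only (small, rigid, charged: the canonical
  poorly-tolerated probe of a buried site);
* `kstw` — Lys, Ser, Ala, Trp (a charged, a polar, a small and a large
  hydrophobic residue), minus the wild type;
* `random_all` — n residues drawn without replacement from the 19
  non-wild standard residues with a seeded generator (3–4 per site is the
  realistic library density).

The bundled codon-usage table is a toy AT-rich table in the Kazusa TSV
dialect, adequate for deterministic codon choice in tests and demos; a
measured genomic table can be supplied instead. The bundled CDS
(`datasets.synthetic_repb_like_cds`) is likewise a labelled synthetic
stand-in that carries the correct wild-type residue at each of the ten
mutagenised sites, so the printed 34-member library layout can be rebuilt
codon-exactly without shipping the real gene.

**Phenotype rule.** Over the call alphabet {+, +/−, −} at 48 °C and
58 °C: (+, +) → active; (+, −) and (+, +/−) → Ts; (−, −) → inactive; a
+/− call at 48 °C → ambiguous (never Ts — the permissive-temperature
evidence is itself equivocal); growth at 58 °C only is anomalous and also
ambiguous. The rule is total over the 3×3 grid. Applied to the bundled
screen table it yields 6 Ts, 4 active, 23 inactive, 1 ambiguous. (The
printed table's own prose count of fully inactivating substitutions is 22;
strict row counting gives 23 — the table is transcribed as printed and the
discrepancy left alone. One row, `770-I51C`, names Cys but lists Gln; it
is kept as printed and flagged in `datasets.SCREEN_TABLE_NOTES`.)

## Growth kinetics (`tsplasmid.growth`)

OD600 readings are blank-corrected, rescaled to a 1 cm pathlength by a
user-supplied multiplicative factor (instrument-specific, hence an input),
clamped at a floor (default 1e-4; clamping rather than dropping preserves
window alignment) and transformed with the **natural log** (the
growth-rate convention, so slopes are in h⁻¹). A window of
`window_points` readings (default 20 ≡ 1 h at 3-min sampling) slides one
reading at a time; each window gets an OLS slope, and μMax is the maximal
slope, ties to the earliest window. The reported `stderr` is the OLS
slope standard error within the selected window. An optional `min_mean_od`
guard (off by default) excludes low-signal windows where relative reading
noise explodes.

**Estimator calibration caveat.** Because μMax is a *maximum over many
overlapping windows*, measurement noise inflates it: with reading noise of
CV σ the selected window's slope is biased upward by roughly the spread of
window-slope noise (≈ 2 σ_slope over ~100 windows), while the in-window
stderr estimates only σ_slope. At σ = 1% on a logistic curve the nominal
±2·stderr interval still covers the true rate in ≳95% of simulated
replicates (the property the test suite asserts); at σ = 2% coverage
drops to ~79% on logistic curves (and further on unbounded exponentials).
This is intrinsic to maximum-window estimators, not a defect of the
implementation; noiseless curves are recovered exactly. Users needing
calibrated uncertainty at higher noise should average replicate wells
before fitting.

## qPCR copy number (`tsplasmid.qpcr`)

Primer efficiency comes from the OLS slope of Cq on log10 template amount
over a serial dilution: `E = 10^(−1/slope) − 1` (slope −3.3219 ⇔ 100%).
Copy number uses the efficiency-corrected ratio against a single-copy
calibrator construct,

    PCN = (1+E_t)^(Cq_t,cal − Cq_t,sam) / (1+E_r)^(Cq_r,cal − Cq_r,sam),

which reduces exactly to 2^−ΔΔCq at E = 1. Replicate Cqs are aggregated
by arithmetic mean with sample sd; replicates deviating > 0.5 cycles from
the median are flagged. Efficiencies are stored as fractions and displayed
as percent. The limit of detection uses the 100%-efficiency convention
`2^−(Cq_NTC − Cq_ref)` — the convention under which the published Cq pair
(19.12, 31.09) reproduces the published 2.5 × 10⁻⁴ — with an
efficiency-corrected base available via the `eff_target` argument. Raw
fluorescence processing and Cq calling are out of scope; inputs are
instrument-exported Cq tables.

## Plasmid stability (`tsplasmid.stability`)

PSR is the ratio of log10 CFU gains with versus without selection. It is
invariant under a common rescaling of all four counts, so plating dilution
factors cancel if applied consistently (dilution correction belongs in the
reader, not the formula). Classification uses a tolerance band
`zero_band` (default 0.05) around the exact anchors: ≥ 1 − band stable,
within ±band of 0 non-replicating, below −band lost, otherwise unstable —
exact 0/1 boundaries are unusable on noisy counts. Replicate experiments
are summarised by per-replicate PSRs with their mean and sd; no
within-replicate error propagation is attempted.

## Synthetic data (`tsplasmid.simulate`)

All generators are pure functions of their arguments including the seed.
Noise models: multiplicative lognormal (mean 1) for OD readings and plate
counts, additive Gaussian for Cq. Defaults emulate the assay conditions
the analyses were built for: 3-min sampling, od0 = 0.01, 6 h duration;
9-level ten-fold dilutions; triplicate Cq panels; 7 generations per curing
passage; 20-point fitting windows.

* `gen_growth_curve` — logistic with optional lag and carrying capacity
  (capacity `None` = pure exponential). It does not emulate diauxie,
  evaporation drift, or condensation artifacts.
* `gen_dilution_series` — Cq steps of `log(fold)/log(1+eff)` per
  dilution; no plateau or stochastic single-molecule effects at the low
  end.
* `gen_qpcr_panel` — a calibrator at 1:1 and a sample whose target Cq is
  advanced by `log(PCN)/log(1+E)`; inter-run drift is not modelled.
* `gen_cfu_experiment` — deterministic expected counts `2^g` and
  `2^g (1−q)^g` under multiplicative plating noise; plasmid loss is not
  simulated cell-by-cell, so the generator cannot produce demographic
  stochasticity at small population sizes.
* `gen_test_protein` — polar background restricted to small-|H| residues
  (S, T, N, Q, G): charged residues' large scale magnitudes would let
  chance charge periodicity mimic an amphipathic face and fire the moment
  track on negative controls. Buried blocks are solidly hydrophobic, or
  periodically hydrophobic (`period` ≈ 3.6) when `amphipathic=True`.

Because the generators share the analyses' own parametric forms, passing
round-trip tests demonstrates internal consistency and estimator
correctness — not robustness to real-data pathologies (baseline drift,
outlier wells, contaminated plates), which the analyses only partially
guard against (Cq outlier flags, the OD floor, the low-OD window guard).

## Problem sizes

Tests and the acceptance script run on desk-scale inputs chosen as
typical single-assay sizes: 121-point growth curves (6 h at 3-min
sampling), 9-level dilution series, triplicate Cq panels, four-count CFU
experiments, proteins of 150–340 residues, and 200-replicate Monte-Carlo
checks for stochastic properties.

## Known limitations

* The burial calibration is a stand-in; absolute P(buried) values are
  meaningful only relative to the documented thresholds, and no claim is
  made that they reproduce any particular published score track.
* Site selection within a region takes the single probability peak;
  structural context (catalytic motifs, DNA-binding regions) must be
  screened manually.
* μMax uncertainty is within-window only (see the calibration caveat).
* The PSR model treats generations as synchronous doublings; per-cell
  loss rates inferred from PSR are effective, not mechanistic.
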