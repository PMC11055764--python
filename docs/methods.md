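# Methods

## The readthrough estimator

A dual-reporter construct expresses an RFP–SCC–GFP fusion: every
translated mRNA yields one RFP; a GFP is appended only when the
ribosome reads through the stop codon in the SCC cassette. Under this
linear model the expected GFP/RFP intensity ratio of a transfected
cell is proportional to the readthrough fraction, and dividing by the
same ratio of a 100 % control construct (no stop between RFP and GFP)
cancels the channel gains and the expression distribution:

    TR% = 100 · [(Ḡ_sample − Ḡ_bg)/R̄_sample] / [(Ḡ_ctrl − Ḡ_bg)/R̄_ctrl]

Choices embedded in the estimator, and why:

- **Ratio of well-level means**, not mean of per-event ratios.
  Per-event ratios blow up on low-RFP events; the ratio of means is
  the method-of-moments estimator of the proportionality constant and
  is stable at 10,000 events/well. (A per-event mode is deliberately
  not offered; the well mean is the unit of analysis throughout.)
- **Background subtraction at the well level.** The GFP-channel signal
  of an RFP-only construct (bleed-through + autofluorescence) is
  averaged over the plate's background wells and subtracted from every
  well's mean GFP. Subtraction happens after averaging because the
  correction is an offset on the channel mean, not a per-cell quantity
  we can observe.
- **Per-plate normalization.** Control and background wells are
  measured in triplicate on every plate, so gain drift between plates
  cancels. Background could alternatively be pooled across plates;
  per-plate was chosen since the background wells already exist on
  each plate and plate-to-plate gain differences then cancel for the
  background term too.
- **Clamping.** Corrected GFP below zero is clamped to 0: readthrough
  cannot be negative, and at basal levels the subtraction can
  otherwise produce small negative ratios that bias group means.
- **Aggregation** treats all 9 wells (3 replicates × 3 experiment
  plates) as exchangeable units, reported as mean ± sample sd (n − 1).
  A nested per-experiment mean is easy to compute from the per-well
  table but is not the default.

## Gating

Rectangular scatter gate, inclusive bounds (FSC 23,000–75,000; SSC
12,500–67,500 a.u.), then the fluorescence rule RFP > 700 **or**
GFP > 100 with strict inequalities, applied after the scatter gate.
"From X to Y" is read as inclusive and "higher than" as strict; both
conventions are config-switchable (`GateConfig`) because instrument
exports differ in how they bin boundary values. Wells with fewer than
500 included events are flagged `low_n` and excluded from replicate
aggregation — a guard against ratio instability in poorly transfected
wells; the threshold is a free parameter of `GateConfig`.

## Group comparison

One-way fixed-effects ANOVA from between/within sums of squares, then
each group versus a named reference by a two-sided t-test using the
pooled within-group mean square (df = N − k), with Bonferroni
multiplication by the number of comparisons, clamped at 1.
Significance tiers are assigned at p < 0.033 (*), < 0.002 (**) and
< 0.001 (***). Degenerate case: when the within-group mean square is
zero, F is defined as 0 (all groups identical) or ∞ (identical within,
different between), with p = 1 or 0 accordingly.

## Agreement statistics

Lin's CCC uses population (1/n) moments, following the coefficient's
original definition; Bland–Altman limits use the sample sd (n − 1) of
the differences, following common practice. Differences are oriented
as high-content assay minus reference assay. No CCC confidence
intervals are computed.

## Densitometry

Blot readthrough is I_FL/(I_FL + I_trunc) per lane. The relative
protein level of a PTC construct divides its signal by the wildtype
lane **on the same blot** (cross-blot ratios are refused — exposures
are not comparable). "Signal" defaults to total (FL + truncated)
MeCP2, switchable to FL-only (`use_total=False`); the choice is
genuinely open and both are useful. Loading-control normalization is
available but off by default so the default output matches the plain
band-ratio definition.

## Localization scoring

The nucleus along a drawn line is the largest contiguous run of
positions with DAPI ≥ 50 % of its maximum — the simplest reproducible
operationalization of a DAPI overlay. Enrichment = mean Flag inside /
mean Flag outside, with an ε = 1e−6 floor on the denominator. Calls:
nuclear ≥ 2, cytoplasmic ≤ 0.5, mixed between; cutoffs are exposed on
`LocalizationScorer`. Expected classes per variant follow from the NLS
annotation (aa 173–193 and 251–270): a PTC at residue r removes an NLS
iff r ≤ its end; variants lacking NLS1 are cytoplasmic untreated and
mixed after induction (partial restoration), variants retaining NLS1
are nuclear. Because the underlying imaging readout is qualitative,
this module is verified by property tests and synthetic-profile
recovery only.

## The synthetic-data generator

`SimConfig` emulates the assay so each stage can be checked by
parameter recovery without any external data:

- 10,000 events/well; a fraction f = 0.4 of cells transfected.
- Per-cell expression E ~ LogNormal(µ = 7.6, σ = 1.0) (median ≈ 2,000
  a.u.); channel gains c_R = c_G = 5, so a 100 % control cell reads
  GFP/RFP ≈ 1.
- RFP = c_R·E·ε, GFP = tr·c_G·E·ε′ + bleed, with multiplicative
  log-normal measurement noise (σ = 0.05, mean fixed at 1) and a
  GFP-channel bleed of 0.3 % of the RFP signal; additive log-normal
  autofluorescence (medians 80/10 a.u.) on both channels.
- Scatter ~ Normal, means inside the gate (45k/30k transfected,
  42k/28k untransfected, sd 8k), clipped at 0.
- GFP output is **linear in TR** — the mechanistic reading of a fusion
  reporter (one GFP per readthrough event per transcript); no
  translational bursting.
- Layout: every plate carries triplicate 100 %-control, background and
  untransfected wells; each sample group appears as 3 wells on each of
  3 experiment plates. Treatment acts only through the truth table.
- Reproducibility: one root seed; each well uses a child generator
  keyed `[seed, plate_index, well_index]`, so any well can be redrawn
  in isolation.
- `zero_noise()` switches off expression spread, measurement noise,
  bleed and autofluorescence, making the estimator identities exact
  (controls → exactly 100 %; tr = 0 → exactly 0).

Transfection efficiency and the noise magnitudes are free parameters —
the assay reports none of them — set once to values typical of
transient HeLa transfection and bench cytometers. The untransfected
population is placed so ≥ 99 % of its events fall below both inclusion
thresholds.

Blot lanes split a common amount A into A·r and A·(1 − r) bands with
independent multiplicative log-normal noise (σ = 0.1 default, median
1). Line profiles plant a Gaussian DAPI bump in the central third and
inside/outside Flag ratios of 8 (nuclear), ≈ 0.15 (cytoplasmic) and
1.5 (mixed) plus additive noise.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: mRNA stability and nonsense-mediated
decay, PTC-position effects along the transcript, geneticin
pharmacology and dose–response, spectral compensation, doublets,
plate-edge effects, and day-to-day instrument drift beyond what
per-plate normalization cancels. Recovery on synthetic plates
demonstrates the *estimator's* correctness, not the biology.

## Problem sizes

The acceptance script simulates each flow condition at the assay's
full scale (9 sample wells × 10,000 events plus per-plate controls,
≈ 360,000 events per condition; seconds per condition) and each blot
condition with 4 replicate lanes. Module tests use a down-scaled
generator (2,000 events/well) where full scale adds nothing to the
property under test.

## Known limitations

- The packaged variant table records flanking SCC sequences only where
  explicitly documented; most flanks are left empty and flagged
  `unverified`, so insert design requires a user-supplied CDS for
  those variants. One stop class (p.R294X) is flagged
  `inferred-by-count` — it is implied only by the 2/6/6 partition.
- The FCS adapter covers the common list-mode single-width
  float/integer layouts only; CSV is the canonical format.
- Fixed rectangular gates only; no data-driven gating.
- No mixed-effects modeling of plate/experiment structure; the 9 wells
  are treated as exchangeable.
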