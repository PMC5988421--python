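# Methods

This note records the models, defaults and numerical choices behind
`rmskit`, and what the synthetic-data generators do and do not emulate.

## Junction-spanning read detection

A fusion transcript is confirmed by realigning reads against a short
*junction window*: the last `flank` bases of the upstream gene fragment
joined to the first `flank` bases of the downstream fragment, with the
breakpoint at index `flank` (0-based, half-open coordinates
throughout). A read is retained iff

1. it aligns full-length, gapless, within the window with at most
   `max_mismatches` mismatches (default 0 — exact match), and
2. its overlap with each side of the breakpoint is at least
   `min_overlap` bases (default 6 bp).

Design choices:

- **Gapless, full-length, exact alignment only.** The reference is a
  short known sequence and the filter rejects any mismatch, so
  indel-tolerant alignment would change the contract without adding
  sensitivity. Exactness is applied to the whole read (the stricter of
  the two possible readings of a "no mismatch" rule).
- Both strands are scanned by default; forward orientation is preferred
  when both match; among multiple qualifying offsets (possible only
  with pathological repeats) the smallest wins. These tie-breaks make
  output deterministic.
- `'N'` never matches, in either read or window: conservative under an
  exact-match rule.
- Reads overhanging the window ends are non-hits. Callers should set
  `flank ≥ read_length − min_overlap` so every true spanning read is
  fully contained; the simulator's default `flank = 80` satisfies this
  for 75 bp reads at the 6 bp rule.
- Paired-end mates are scanned independently and counted as individual
  physical reads (mate ids keep their `/1`, `/2` suffixes).

The implementation is verified against an exhaustive brute-force scan
over every offset and both strands on randomized read/window pairs.

## Discovery screen

The screen takes a log2-intensity matrix over three conditions —
control, wild-type factor, fusion factor (`gfp` / `pax3` /
`pax3_foxo1`) — with technical triplicates, and composes:

1. **Quantile normalization** (matrix-level): every column's sorted
   values are replaced by cross-sample rank means; ties receive the
   average of the rank means they span (the limma convention). This is
   a deliberate stand-in for probe-level RMA: the package ingests
   expression matrices, not raw array files, so background correction
   and probe summarization are out of scope and normalization happens
   at the matrix level. On tie-free (continuous) data one pass is a
   fixed point; with ties, tie-averaging makes a second pass a
   near-identity rather than an exact one.
2. **Per-gene Welch t-tests** of each treated condition against the
   control, t = (x̄_treated − x̄_control)/√(s₁²/n₁ + s₂²/n₂) with
   Welch–Satterthwaite df and a two-sided p. Genes constant in both
   groups are flagged degenerate (p = 1 at equal means). Technical
   triplicates are treated as independent samples, mirroring the
   triplicate design; this is anti-conservative with respect to
   biological replication and is flagged as such.
3. **Up-calls**: unadjusted p < 0.05 and log2FC > 0 by default. No
   multiple-testing correction is applied by default (the screen is a
   ranking device, not an inference procedure); a Benjamini–Hochberg
   option exists (`bh=True`).
4. **Signature intersection**: shared = up(wild-type) ∩ up(fusion);
   fusion-unique = up(fusion) \ up(wild-type).
5. **Ortholog filter**: fusion-unique genes without a human ortholog
   are dropped; one-to-many mappings are rejected rather than resolved.
6. **Ranking** by descending linear fold change (2^log2FC), ties broken
   by ascending p then lexicographic gene id.
7. **PCA** on the gene-centered matrix (all genes, not only significant
   ones), samples as observations; scores and variance fractions come
   from an SVD and are checked against an independent
   eigendecomposition in the tests.

### Statistical calibration

The Welch test's finite-sample size depends on the group size. Measured
on simulated Gaussian nulls, the empirical two-sided size at α = 0.05
is ≈ 0.048 at n = 10 per group but only ≈ 0.035 at n = 3: the
Satterthwaite df approximation makes the test *conservative* at very
small n. The calibration test therefore checks nominal size at n = 10,
where calibration reflects the implementation rather than small-sample
theory, and separately asserts conservatism (size ≤ α) at triplicates.
Consequence for the screen: at triplicates the per-null-gene
false-up-call rate is ≈ 1.7% rather than 2.5%, but with ~20 planted
genes the chance that at least two of them are *also* falsely called in
the wild-type arm (and so leave the fusion-unique set) is still ≈ 5%
per study; together with the fold-change compression described below,
planted-set recovery of ≥ 19/20 holds in roughly 92–95% of seeded
studies, not always.

### Normalization compresses planted effects

When planted genes dominate the upper ranks of the fusion columns only,
quantile normalization averages their elevated values with unshifted
ranks from control columns, shrinking the estimated fold change. This
is a real property of rank-based normalization under asymmetric
differential expression, not an artifact of the implementation; it is
visible in the tests as occasional planted genes falling just below the
significance threshold.

## ΔΔCt relative quantification

Per sample, ΔCt = mean Ct(target) − mean Ct(reference);
ΔΔCt = ΔCt(sample) − ΔCt(calibrator); fold = 2^(−ΔΔCt). The calibrator
fold is exactly 1 by construction. Replicate spread is the standard
deviation of per-target-replicate ΔΔCt values (each replicate paired
with the sample's reference mean), reported on the linear scale as the
asymmetric range 2^(−(ΔΔCt ± sd)); with a single replicate the spread
is reported absent rather than zero. The statistic is invariant to a
constant Ct offset applied to a sample's target and reference together
(e.g. input-amount differences).

## Pixel and fusion statistics

- Positivity is strict (`intensity > threshold`). With
  `threshold="auto"`, Otsu's method on the image histogram supplies the
  value and it is reported alongside the count; on a two-level image
  Otsu can land exactly on the background level, which strict
  inequality handles correctly. How thresholds are chosen in a given
  experiment is ultimately an acquisition-side decision; the
  auto/manual scheme is a documented stand-in.
- Timepoint-persistence counts apply one shared threshold to both
  images (acquisition settings are assumed identical); group
  comparisons across embryos are left to an ordinary two-tailed t-test.
- Nuclei are assigned to the myosin-positive cell label under their
  centroid pixel — the simplest rule consistent with "nuclei within a
  cell"; a majority-overlap rule could be swapped in behind the same
  interface. Myogenic index = assigned nuclei / total nuclei; fusion
  capacity counts only cells with `per-cell count ≥ fusion_min_nuclei`
  (default 4, encoding the strict "> 3 nuclei" multi-nucleation rule as
  an inclusive bound). Both indices are invariant under label
  permutation and image translation, and fusion capacity ≤ myogenic
  index always.

## Survival statistics

- Kaplan–Meier product-limit estimation and the two-group log-rank test
  are delegated to lifelines; Fisher's exact test to scipy. The tests
  cross-check them against hand product-limit computation, a hand O/E/V
  log-rank example (χ² ≈ 2.882), and exact rational-arithmetic
  hypergeometric enumeration.
- Tied event/censoring times follow the standard convention: events are
  processed before censorings.
- Tumor incidence = 1 − KM with tumor detection as the event; animals
  censored tumor-free before `min_age` (default 30 days) are excluded
  from the denominator; tumor-free animals are censored at their last
  observation, including non-tumor deaths after `min_age`
  (censoring-at-death — a modeling choice, flagged because competing
  risks are not modeled).
- The two-sided Fisher p uses the probability-mass rule (all
  margin-fixed tables at most as probable as the observed one), the
  convention of the common graphing packages.

## Synthetic-data generators

All generators are pure functions of their parameters and a seed
(bit-identical reruns) and return truth tables sufficient to score any
downstream stage.

- **Reads.** Fragments of length `2·read_len + 50` with one mate per
  end, the far mate reverse-complemented, and fragment orientation
  randomized so spanning reads occur on both strands. A fixed
  `round(n_pairs · spanning_fraction)` of pairs place their
  junction-proximal mate uniformly over start offsets crossing the
  breakpoint; other pairs are drawn from the two wild-type transcripts
  in equal proportion. Qualities are constant Phred 40 ('I') because
  the downstream filter uses sequence identity only. Substitution
  errors are i.i.d. per base. Not modeled: quality decay, indels, PCR
  duplicates, coverage biases.
- **Expression study.** Values = per-gene Gaussian baseline
  (mean 7, sd 1 on the log2 scale) + planted effect + i.i.d. Gaussian
  noise. Defaults encode the emulated design at desk scale: 1000 genes,
  30 shared / 20 fusion-unique / 15 wild-type-unique planted genes at
  log2FC = 2, noise sd 0.25, technical triplicates, ortholog fraction
  0.7. The Gaussian-on-log2 noise model is a stand-in — the original
  array-level noise model is unknowable from a processed matrix — so
  passing tests certify the pipeline's algebra and calibration, not
  robustness to real microarray artifacts (probe effects, batch
  structure, correlated noise).
- **Ct tables.** Reference gene fixed at Ct 20, target at
  `25 − log2(fold)`, i.i.d. Gaussian replicate noise in cycles; the
  requested fold is recovered exactly at zero noise and in expectation
  (up to the small lognormal mean bias, ≈ 0.2% at sd 0.1) otherwise.
- **Masks.** Cells are rectangles on a grid, nuclei radius-3 disks on
  an internal sub-grid with ±1 px seeded jitter, free nuclei on
  background rows; infeasible geometry raises. Geometry is schematic by
  design — only containment enters the statistics.
- **Survival.** Geometric per-day event times (memoryless daily
  hazard), censored at `censor_day`, matching a daily-observation
  design (24/48/72 hpf → days 1, 2, 3). No competing risks, no
  time-varying hazard.

## Problem sizes used in the automated checks

The acceptance-style tests run at desk scale, chosen so each check has
the power it needs: 10,000 random read/window pairs for oracle
equivalence, 10,000 simulated read pairs for recall/precision, 100
seeded studies for discovery recovery, 10,000 null genes for test
calibration, and 1000 equal-hazard simulations for log-rank type-I
error. `scripts/acceptance.py` recomputes the two filter-boundary
constants (6 bp retention boundary; 3-nucleus fusion-capacity
exclusion boundary) from scratch at any seed.

## Known limitations

- Technical replicates are treated as independent; no biological
  variance component.
- Quantile normalization assumes comparable global distributions; it
  distorts when differential expression is strong and asymmetric (see
  above).
- No multiple-testing correction by default; the candidate list is a
  ranking, not a set of validated discoveries.
- The Welch test is conservative at triplicates.
- Centroid-based nucleus assignment can misassign nuclei whose
  centroid falls outside a concave cell; the synthetic shapes are
  convex, so this does not arise in the shipped fixtures.
- Survival utilities cover two-group comparisons only (no trend tests,
  Cox models or competing-risks estimators).
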