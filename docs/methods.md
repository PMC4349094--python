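# Methods

## Scope and model structure

`emcsim` is a forward/inverse model of the enzyme-mismatch-cleavage (EMC)
mutation screen read out on a lab-on-a-chip dsDNA electropherogram.  The
forward chain is: mix → re-anneal → heteroduplex digestion → exonuclease
degradation → trace synthesis.  The inverse chain is: size calibration →
peak calling → classification → cleaved-fraction quantification.  Every
stage is a pure function of explicit inputs plus a seed, so each stage can
be tested against closed forms or independent oracles.

## Re-annealing

Denatured strands re-pair at random with no kinetic bias, giving duplex
fractions (1−p)² : p² : 2p(1−p) for mutant molar fraction p.  The
heteroduplex fraction is symmetric in p ↔ 1−p and maximal (50%) at p = 0.5.
The two heteroduplex orientations (WT-sense/mutant-antisense and the
converse) form in equal amounts and are digested separately because their
cleavage products differ in apparent size around a bulge.

Two distinct "pooling" quantities are exposed and kept apart deliberately:
the heteroduplex fraction of total DNA, 2p(1−p), which *falls* as one
heterozygote is diluted into a pool, and the fraction of mutant strands
captured in heteroduplexes, 1−p, which *rises*.  Pool arithmetic itself is
`n_het / (n_individuals × ploidy)` (one heterozygote among eight diploids:
6.25%).

## Cleavage and partial digestion

Lesions are classed as SNV or bulge (1, 2–19, ≥20 nt); an enzyme profile
maps each class to a cleavage probability, treated as an independent
Bernoulli trial per site and per molecule.  All 2^k cut subsets are
enumerated exactly (capped at k = 16); the all-cut state equals the whole
digest, and the enumeration is cross-checked in the tests against an
independent 10⁵-draw Monte-Carlo oracle.

Cut placement: a cut at WT coordinate i severs the strand 3′ of base i, so
the 5′ fragment has length i.  On a bulge the cut sits 3′ of the bulge *on
the bulge-carrying strand*; since the 3′ direction reverses between the two
duplex orientations, a k-nt deletion heteroduplex produces flanking
products differing by exactly k bp between orientations (the doublet).  A
counter-nick on the opposite strand at the duplex junction promotes every
nick to a double-strand break; nick-only intermediates are not modelled
because the chip reads double-stranded fragments.  For SNVs both
orientations cut after the lesion position in sense coordinates; the 1-bp
antisense offset a single-strand-specific nuclease might produce is below
the sizing resolution and is not modelled.

The apparent size of a duplex product is its longer strand (a 3′ overhang
adds to apparent size).  Homoduplexes are never cleaved in this model, so
`hetero_cleaved_fraction ≤ 1` by construction.

## Enzyme calibrations (packaged presets)

Per-lesion probabilities are calibration fixtures stored in JSON with
provenance notes, not constants:

| parameter | T7E1 | Surveyor | basis |
|---|---|---|---|
| p_cut (bulge ≥ 20 nt) | 0.74 | 0.60 | 50:50 plateau: 74% / 60% of heteroduplexes cleaved (an alternative T7E1 reading of ~80% is noted in the preset) |
| p_cut (SNV) | 0.05 | 0.50 | resolvase prefers indels; single-strand nuclease prefers substitutions |
| p_cut (bulge 1 nt / 2–19 nt) | 0.60 / 0.70 | 0.35 / 0.50 | interpolated between the SNV and ≥20-nt anchors, preserving each enzyme's class preference |
| exo nibbling (nt per 5′ end) | 0 | 3 | Surveyor's intrinsic 5′ exonuclease |
| mass to sub-25-bp background | 0 | 15% | Surveyor's DNA loss and small-fragment accumulation |
| baseline / jitter (FU) | 2.0 / 0.3 | 6.0 / 1.0 | flat low baseline vs elevated irregular baseline |

The noise values and the fluorescence scale (4.8 FU·bp per unit of molar
fraction × bp, giving ~50 FU main peaks at a 250-ng load) were fixed once
so that the packaged exon-3 fixture reproduces the documented qualitative
contrasts and the 5%/10% detection limits; they are configuration, and
changing them changes the detection limits as expected (tested:
the limit is non-decreasing in baseline jitter).

## Trace synthesis

Fragments render as Gaussians on a fixed log-spaced 10–2000-bp axis
(2000 points) with area = scale × molar abundance × apparent size
(intercalating-dye response is mass-proportional).  Peak width is
σ(size) = 1 bp + 0.02 × size, the chip's nominal ~2% sizing spread; this
is what merges a 20-bp difference near 490–570 bp into one peak while
resolving it below ~300 bp.  Markers at 15 and 1500 bp get fixed canonical
areas and are excluded from quantification.  Exonuclease degradation
shortens each fragment by the expected 2 × nibbling rate (per-molecule
Poisson draws average out over the molecular population; an rng-driven
mode exists), routes the removed mass plus the preset mass fraction to a
degradation pool, and conserves total mass; the pool renders as an
exponential spectrum (decay 8 nt) below ~25 bp.  Baseline offset and white
jitter are added last; traces are deterministic per seed.

## Trace analysis

* **Calibration:** two-point log-linear mapping anchored on the outermost
  prominent peaks, which map exactly to 15 and 1500 bp.  Missing markers
  reject the trace.
* **Baseline:** rolling 10th percentile of the lightly smoothed signal
  (Savitzky–Golay, window 7), window 201 grid points, subtracted before
  calling.  A 50-point window was tried first and rejected: on the log
  axis it is comparable to a peak's own width, so it climbs the peak
  flanks and eats 5–20% of true peak area.
* **Detection threshold:** max(2 FU, 3.3 robust noise sd), the
  conventional 3.3σ limit-of-detection rule with σ estimated by the MAD
  of the baseline-subtracted trace.  On the quiet T7E1 baseline the 2-FU
  floor governs; on Surveyor's noisy baseline the 3.3σ term does.
* **Merging:** called maxima closer than max(5 bp, 1.5 σ(size)) are one
  unresolved peak.  The merge threshold is deliberately below the 2σ
  resolution limit because two overlapping Gaussians at that limit
  already pull their observed maxima inward; 2σ over-merges genuinely
  resolvable 20-bp doublets near 370 bp.
* **Integration:** trapezoidal area of the baseline-subtracted signal
  between flanking minima, capped at ±4 σ(size) around the apex so that
  flat noise between distant peaks is not booked as peak area.  Area, not
  height, is the quantification currency.
* **Classification:** greedy nearest-match of called peaks to expected
  fragment sizes within 5% (each expected size labels at most one peak);
  unmatched sub-25-bp peaks are degradation background.  The 5% tolerance
  collapses the 1-bp doublet of a 1-nt deletion while keeping 20-bp
  doublets distinct below ~300 bp.  Expected sizes are shifted by the
  expected nibbling when the enzyme has exonuclease activity.
* **Statistic:** cleaved mass fraction = Σ cleaved area / Σ non-marker,
  non-background area; dividing by 2p(1−p) gives the per-heteroduplex
  efficiency.  The statistic is invariant to uniform rescaling of the
  fluorescence axis.

## Titration and detection limits

For each mutant fraction the full pipeline runs with replicate noise
realizations (seeds spawned from one master seed).  The detection
criterion — both expected cleavage peak classes called in ≥90% of
replicates — stands in for the visual call made on real traces and is
configurable.  Default study sizes: the 5–95% grid, 25 replicates; the
packaged acceptance run uses the {5, 10, 20, 30, 40, 50}% sub-grid, which
brackets both enzymes' limits.  On the packaged exon-3 fixture the limits
are 5% (T7E1) and 10% (Surveyor) and are stable across master seeds.

The noiseless curve follows eff × 2p(1−p) × L/(L − k p²): the small
correction (≤2%) arises because the mutant homoduplex is k = 20 bp lighter
than the WT one, so the mass denominator is not perfectly symmetric in p.
Symmetry tests assert the measured asymmetry equals this predicted
offset rather than pretending the mass scale is exactly symmetric.  At a
50:50 mix the correction makes the measured plateau 37.3% (T7E1) and
30.3% (Surveyor) rather than exactly eff/2.

## Synthetic fixtures

Surrogate amplicons are random sequences with exact base counts matching
the documented lengths and GC contents (488 bp/35.0%, 572 bp/37.6%,
500 bp/37.4%); the lesion-class cleavage model is sequence-agnostic, so
sequence identity affects no downstream statistic.  WT bases at the
complex-allele substitution positions are forced (by count-preserving
swaps) to the documented reference alleles so the documented transitions
are representable.  The designed 20-bp deletions are placed at the
midpoint of the window in which the two cleavage products differ by
150–200 bp (start 189 on the 572-bp amplicon, giving 188/384 and 208/364
products).  Fixture generation is deterministic per seed and the packaged
seed regenerates byte-identical files.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: PCR artefacts (template recombination,
allele drop-out, polymerase errors), sequence-context-dependent cleavage
preferences, cooperative or time-course kinetics, chip-to-chip sizing
bias, and Surveyor's reported asymmetric failure at very high mutant
fractions (the model is symmetric apart from the mass correction above).

## Degenerate inputs and numerical choices

Empty variant specs, empty fragment sets and pure-noise traces are valid
(identity, marker-only trace, empty peak table); zero total peak area,
missing markers, out-of-range or overlapping edits, duplicate cut
positions and >16 sites are rejected with specific errors.  Fragments
outside 10–2000 bp are clipped from rendering with a warning.  Trapezoidal
integration on the log grid is accurate to ~10⁻³ relative for isolated
peaks, well inside the 0.01 round-trip tolerance; determinism is exact
(bit-identical traces per seed).
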