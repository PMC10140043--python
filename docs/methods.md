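# Methods

This note records the models implemented in `aptaswitch`, their
assumptions, the calibration defaults, and the choices made where the
design was genuinely open. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Translation-initiation free-energy model

The binding free energy of the 30S subunit to an mRNA is
`ΔG_total = ΔG_final − ΔG_initial`, with

```
ΔG_final = ΔG_mRNA:rRNA + ΔG_start + ΔG_spacing + ΔG_standby + ΔG_refold
```

* **Folding engine.** All secondary-structure energetics come from
  ViennaRNA (v2.7) minimum-free-energy folding with the Turner 2004
  nearest-neighbour parameter set and dangling-end contributions
  disabled. The folding temperature is 37 °C (310.15 K), the standard
  biophysical convention; the TX-TL assays this package analyzes run at
  29 °C, and no temperature rescaling of the energy parameters is
  attempted — the apparent β (below) absorbs the compression of the
  dynamic range observed in cell-free data. Hard constraints use the
  dot-bracket constraint alphabet (`.` free, `x` unpaired, `()` enforced
  pair); enforced pairs are validated to be Watson–Crick or GU before
  folding because the engine silently tolerates non-canonical enforced
  pairs.
* **SD search.** The anti-SD is the 3′-terminal nine nucleotides of the
  E. coli 16S rRNA (`ACCUCCUUA`), configurable. Candidate placements are
  enumerated by sliding a 9-nt window so that the spacing between the 3′
  end of the SD-paired span and the start codon runs from 0 to 15 nt; the
  best intermolecular duplex in each window is found with ViennaRNA's
  `duplexfold`. The same realized SD span can surface from several
  windows with different duplex alignments; all are scored and the
  placement minimizing ΔG_final wins (ties: smaller spacing, then 5′-most
  span). When no window pairs at all, a flagged sentinel breakdown with
  all ribosome terms zero is returned instead of an exception so the
  designer can still score dead candidates.
* **Footprint.** The ribosome footprint reaches from the 5′ end of the SD
  span to 13 nt past the first start-codon nucleotide. ΔG_refold is the
  MFE of the mRNA with the footprint forced unpaired (aptamer constraints
  honoured outside it).
* **Spacing penalty.** Piecewise-quadratic in the deviation from the
  5-nt optimum: `0.10·d²` kcal/mol when stretched, `0.30·d²` when
  compressed. The functional form is the package's calibration choice
  (compression is the costlier distortion); both coefficients live in the
  config.
* **Standby penalty.** Simplified model, isolated in one function for
  later replacement: the penalty is the free-energy cost of additionally
  forcing the 15-nt window immediately 5′ of the SD span unpaired, given
  the state's footprint-open fold (clamped at ≥ 0). Constraint pairs
  touching the window are released in the opened fold, so a
  protein-locked helix parked on the standby site shows up as a docking
  penalty. The published surface-area standby model is out of scope.
* **Start codons.** `AUG −1.194`, `GUG −0.0748`, `UUG −0.0435` kcal/mol —
  calibration defaults, configurable.
* **Rate law.** `TIR = k_tir · exp(−β·ΔG_total)`. β = 0.45 /(kcal/mol)
  is the in vivo apparent Boltzmann factor; `txtl_calibration()` uses
  β = 0.23, the compressed cell-free value. k_tir is anchored so that a
  reference 5′ UTR with ΔG_total = −7.52 kcal/mol maps to 36,400 au.

## Four-state riboswitch model

Only the four predominant states are modeled: {protein-free,
protein-bound} × {mRNA free, ribosome-bound}. In the bound states the
aptamer's protein-bound structure is applied as a hard constraint to both
the initial and final folds; dots in the declared structure are
*unconstrained* positions free to refold with flanking mRNA.

* **Steric rule.** An SD placement whose footprint overlaps any position
  the constraint forces *paired* is infeasible in the bound state — the
  ribosome cannot displace a protein-locked helix. If no placement
  survives, the sentinel breakdown is used. This one rule produces
  protein-dependent steric repression without any additional term.
* **ΔG_ligand** = RT·ln(K_d) with a 1 M reference state.
* **Refolding penalty** `ΔG_refold = ΔG_initial(locked) −
  ΔG_initial(free) ≥ 0`, the energy needed to reach the bound mRNA
  conformation.
* **Occupancy.** Single-site equilibrium binding, protein in excess:
  `f = P/(P + K_d)`. This is the simplest law consistent with a
  "specified protein concentration"; ligand depletion and multivalent
  binding are not modeled.
* **Ensemble rate.** Rates, not energies, average over an mRNA ensemble:
  `TIR(P) = f·TIR_bound + (1−f)·TIR_unbound` (implemented in a
  cancellation-free form so identical states give exactly 1.0).
* **Ratios.** R_conc uses f at K_d; R_actual at
  `K_d,eff = K_d·exp(ΔG_refold/RT)`, a Boltzmann reweighting of the
  affinity by the stability of the bound conformation (the exact
  published form of this correction is not restated anywhere; this is
  the package's documented choice). All ratios are reported ≥ 1 with an
  `as_designed` flag carrying the direction, which makes the hierarchy
  `1 ≤ R_actual ≤ R_conc ≤ R_max` an exact theorem of the implementation
  (f is monotone in affinity and the oriented ratio monotone in f).

## Genetic designer

NSGA-II-style: fast non-dominated sorting, crowding distance, binary
tournament, per-region one-point crossover, per-base mutation (0.05),
and bounded insertion/deletion operators so the designed length itself
evolves within the configured range (default 44–55 nt combined pre+post;
a 44–55-nt space spans 10^26–10^33 sequences). Objectives: the
mode-oriented fold-change at saturation, plus TIR in the
translation-permissive state (maximized) and the repressed state
(minimized). Fitness is evaluated at P → ∞ (R_max); R_actual is reported
for post-hoc ranking — the worked example in the README shows why both
matter. Determinism: a single `random.Random(seed)` drives everything,
all sorts carry explicit lexicographic tie-breaks, and elitist selection
makes the best fold-change non-decreasing across generations (tested).
Forbidden motifs (default: `AUG` in designed 5′-UTR regions) are repaired
by resampling offending bases; the aptamer itself is never touched by any
operator. A brute-force enumerator (refusing spaces above 10^5) serves as
the oracle for tiny design spaces; its combined-length lower bound is
relaxed below the usual 44-nt design window exactly so such oracle spaces
can be expressed, with a feasibility check that the designed region plus
any fixed scaffold can still host an SD.

## Subconstraint scanning

All L(L+1)/2 contiguous aptamer subregions [i, j] are refolded in
isolation by MFE; the refold (unpaired flanks left as dots) becomes the
bound-state constraint, the flanking aptamer nucleotides migrate into the
pre-/post-aptamer regions, and the assembled mRNA is byte-identical — an
invariant the tests enforce. R_actual is recomputed per cell at the
assay's maximum-induction concentration. Constraint selection maximizes
the squared Pearson correlation between ln(predicted R_actual) and
ln(measured ratio) across riboswitches sharing the aptamer, with ties
(including zero-variance grids) broken to the smallest region then the
5′-most start, and reports the fraction of riboswitches within 2-fold.
Selection is per-aptamer; joint optimization across aptamers is not
attempted.

## Assay analysis

Endpoint = mean of the last 15 samples; background = mean of the first
15; the slow fluorophore-independent drift is removed by subtracting the
same endpoint-minus-background quantity from a no-DNA reaction. The
window width is a flag; the two windows must not overlap. Regulation
ratios are mode-oriented (+ligand/−ligand for ON, inverse for OFF) and
divided by the no-aptamer control's ratio *expressed in the same
orientation* — a control that rises 2.37-fold under a repression assay
has control ratio 1/2.37, so the correction multiplies, reproducing the
standard correction arithmetic. Dose–response uses a signed-amplitude
Hill fit (baseline at P = 0, initial half-max at the median tested dose,
n bounded to [0.1, 10]); flat data is flagged degenerate, non-convergence
flagged, never silent. The apparent β is the OLS slope of ln(endpoint) on
−ΔG_total, with Pearson R², the two-sided slope p-value and a t-based
95% CI. Pairwise comparisons use Welch's two-tailed t-test (α = 0.05).

## Synthetic data

The generator emulates what the real workflow measures, not the
measurement hardware: logistic reporter-accumulation traces
(baseline + drift + plateau/(1+e^{−r(t−t₀)}) + Gaussian noise; defaults:
10-min sampling, 60 points, onset 295 min, rise 1/min), toy aptamers
(hairpin / bulged / double-hairpin G:C stems whose declared bound
structure is verified to equal their MFE), and whole studies: N random
riboswitch constructs around one aptamer (N = 34 by default, matching
the scale of the regression analyses; 20 for constraint-recovery
studies), model-true endpoints computed under a chosen true calibration
(β = 0.23) and true subconstraint, traces and lognormal-noisy measured
ratios derived from those endpoints. Because measured quantities are
closed-form functions of the generating parameters, every downstream
estimate has an exact target. What this does *not* emulate: mRFP1
maturation kinetics, resource competition between constructs, pipetting
covariance, or real aptamer–protein structural ensembles — passing
recovery tests shows the estimators are self-consistent, not that the
biophysics of a real aptamer is captured.

Constraint-recovery studies use the double-hairpin aptamer: its
subregions refold into genuinely different structures, so grid cells are
distinguishable. With 20 constructs, the generating full-length
subconstraint is recovered exactly for lognormal measurement noise up to
σ = 0.1 (the documented threshold; beyond it neighbouring cells with
nearly collinear prediction vectors start to win).

## Numerical choices and limitations

* Folding results are memoized on (sequence, constraint, temperature);
  all published-value arithmetic is exact floating point.
* Problem sizes in tests and the acceptance script (toy aptamers of
  12–25 nt, constructs of 55–75 nt, 1,000-construct property sweeps,
  200-replicate regression studies) were chosen as the smallest sizes at
  which every property under test is non-trivially exercised.
* Known limitations: no cotranscriptional/kinetic folding (equilibrium
  thermodynamics only); no codon-usage or mRNA-stability effects; the
  standby model is the simplification described above; steric repression
  by the protein body itself (as opposed to a locked helix) is outside
  the free-energy model, so structure-invariant steric designs are
  predicted R_max = 1 by construction.
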