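# Methods

## Scope and model of the inference chain

The package mirrors a four-stage computational argument for calling a
protein a GAP: (1) a structure-prediction screen nominates binding
partners by interface confidence; (2) geometric triage of the predicted
complex asks whether the candidate supplies an arginine finger to the
GTPase's γ-phosphate; (3) conservation analysis asks whether that
surface is under selection; (4) kinetics quantifies catalysis.  All
stages run on synthetic inputs with planted ground truth, so every
quantitative claim of the pipeline is testable without external data.

## Screen ranking

Per-model score files carry an ipTM in [0, 1], optionally a pTM and a
PAE matrix (entries clipped to [0, 31.75] Å, the ceiling of the common
emitter dialect, with a warning).  The pair statistic is the arithmetic
mean of the ipTM over the model replicates (expected 3; deviations are
kept and logged — silently dropping data is worse than flagging it).
The mean is computed with exact rational arithmetic
(`statistics.mean`), so a pair whose replicates all equal the threshold
compares *equal* to it rather than a rounding error away; the
plausibility boundary is inclusive (mean ipTM ≥ 0.6).  Rank ties are
broken lexicographically by (bait, prey) to keep output deterministic.
Because PAE plots are usually judged by eye, the quantitative surrogate
reported here is the mean over both off-diagonal (inter-chain) blocks,
which makes it symmetric in chain order.

## Structure triage

**Correspondence.** Residue pairs come from a BLOSUM62 global alignment
(gap open −10, extend −0.5) of the chains' one-letter sequences; only
aligned non-gap positions with Cα on both sides enter the fit, and
fewer than three pairs is an error.

**Superposition.** The rigid transform is the closed-form SVD (Kabsch)
solution with the reflection branch excluded (det(R) = +1, verified to
1e-8); collinear point sets are rejected as rank-deficient.  RMSD is
computed on the matched Cα after transformation.  Tests cross-check the
solution against an independent library implementation and against
1,000 random rigid transforms (optimality), and verify recovery of
known transforms to machine precision.

**Ligand transplantation and finger calls.** GTP atoms are mapped by
the fitted transform; the γ-phosphate set is {PG, O1G, O2G, O3G} and
the guanidinium set {NE, NH1, NH2, CZ}.  "Close proximity" is
quantified as a minimum pairwise distance ≤ 4.5 Å — the typical
arginine-finger contact range — exposed as a parameter.  Arginines with
no guanidinium atoms are skipped with a warning rather than failing the
run.  Calls are sorted by distance; the distance is invariant under
rigid motions of the input because the reference is re-superposed.

**Surfaces.** Interface membership uses a 4.0 Å heavy-atom cutoff
(visual judgements in the source analyses imply no number; 4.0 Å is a
standard contact criterion).  Surface identity is the Jaccard index,
classified distinct (< 0.1) / overlapping / shared (> 0.5); both
thresholds are parameters.  β-strand ranges are *annotations supplied
by the user* (TSV), not computed — loop membership is strict
inequality between the upstream strand's end and the downstream
strand's start.

## Conservation

The per-column score is 1 − H/ln 20 with H the Shannon entropy of the
gap-excluded 20-state frequency vector.  This is not a phylogenetic
(rate4site/Bayesian) score: it ignores tree structure and sequence
redundancy, and absolute values are not comparable across alignments
with different taxon sampling.  The pipeline's conclusions rest only on
*relative* conservation of a patch versus its surface background, which
the permutation test quantifies: the null redraws patch-sized subsets
without replacement from the pooled residue scores, preserving the
score distribution, and the p-value carries the add-one correction so
it is never zero.  Columns with > 50 % gaps are masked; columns where
the reference is gapped are dropped from the numbering.

## Kinetics

The model is a bare single exponential (pseudo-first-order); no drift
or baseline term is fitted by default, because the underlying assay
analyses state single-exponential fits and nothing more.  Initial
values: F₀ = first sample, F∞ = mean of the last 10 % of samples,
k = ln 2 / (time of first midpoint crossing); k is bounded to
(1e-6, 10) s⁻¹.  A trace whose span is below five tail standard
deviations is rejected as degenerate; rising traces are fit with
negative span and flagged.  The second-order rate is exactly
k_obs/[GAP]; results also carry the display unit ×10⁴ M⁻¹s⁻¹.

The packaged calibration table holds five conditions — Avl9 on soluble
ΔN-Arf1 (1.5×10⁴ M⁻¹s⁻¹ at 1 μM GAP), Avl9 on membrane-bound myr-Arf1
without (69×10⁴, 1 nM) and with prenyl-Rab8 (480×10⁴, 1 nM), DENND6A on
ΔN-ARL8B (0.18×10⁴, 1 μM), all published values, and an Age2 benchmark
(0.15×10⁴, 1 μM) derived from the published statement that Avl9 is
tenfold faster than Age2.  Trace duration defaults to 7/k_obs (≈ 10
half-lives) so the plateau is well constrained.

Endpoint assays use an ordinary least-squares standard curve
(absorbance vs μM phosphate) and activity = (P_enzyme − P_mock)/time
with a 5-minute default reaction time; negative activities are reported
and flagged, not suppressed.  GEF detectability defaults to a 2-fold
increase of the fitted exchange rate over the intrinsic (buffer-only)
rate — the source observation is qualitative non-detection, so the
threshold is a parameter.

## Colocalization

Manders coefficients are intensity-weighted with per-channel
thresholds: M1 sums channel-1 intensity over pixels where channel 2 is
above threshold, normalised by the channel-1 sum over its own
above-threshold pixels (sub-threshold channel-1 pixels are excluded
from numerator and denominator); M2 is symmetric.  Default thresholds
are Otsu's criterion on a 256-bin histogram; when several cut points
tie — the usual case for punctate images, whose histograms have an
empty gap between background and spots — the tying bin centres are
averaged so the threshold lands mid-gap instead of at the gap's lower
edge (library implementations that return the first maximising bin are
equivalent for classification but report a gap-edge number).  Analysis
is single-plane 2-D.  Group statistics are Welch's unequal-variance
t-test (Satterthwaite df) and one-way ANOVA with Tukey HSD.

## Synthetic data: what it emulates, and what it does not

* **Score files** reproduce the screen's JSON dialect with per-pair
  target mean ipTM; replicate values are jittered then re-centred so the
  realised mean equals the target (shrinking the spread at the [0, 1]
  boundaries).  The deterministic screen fixture used in examples and
  acceptance checks sets jitter to zero so that boundary pairs sit
  exactly on the threshold.
* **Toy complexes** are Cα-only chains plus the atoms the geometry
  needs: a 40-residue helical GTPase with a six-atom GTP, and a
  150-residue bait chain whose single arginine's NH1 is placed exactly
  the requested distance (default 3.0 Å, residue 116) from the
  γ-phosphorus after superposition; every other bait residue is ≥ 10 Å
  from every GTP atom, which the generator verifies before emitting.
  PDB serialisation rounds to the 3-decimal coordinate grid, so
  superposing the two copies yields an RMSD of order 1e-3 Å rather than
  0; the planted-distance contract (± 0.01 Å) absorbs this.  These are
  geometric fixtures, not protein-like structures: no secondary
  structure, packing or stereochemistry.
* **Alignments** mutate non-conserved positions i.i.d. at a per-site
  rate with no gaps and no phylogeny, so conservation signals are
  sharper than in real alignments.
* **Traces** are exact single exponentials plus white noise — no
  photobleaching drift, mixing dead time or instrument baselines.
* **Images** are isotropic Gaussian spots of equal amplitude with
  centre-sharing controlling true overlap, ≥ 6σ centre separation for
  non-shared spots, and optional white noise — no camera noise model,
  uneven illumination or out-of-focus light.

Consequently, passing tests demonstrate the *correctness of the
computations* (fits recover planted parameters, detectors find planted
geometry, statistics match closed forms) — not robustness to the
artefacts of real predictions, alignments or micrographs.

## Numerical choices and problem sizes

Generators are seed-deterministic (NumPy `default_rng`).  The test and
acceptance workloads are sized for interactive runs: 101-pair screens,
40-point superpositions, 50×60 alignments with ≤ 10⁴ permutations,
512-sample traces, 256×256 images, 60-fit recovery sweeps, 500-run
p-value calibrations — each stage completes in seconds.  Fold ratios
are reported both raw and rounded to integers, since published fold
statements round unrounded fits.

## Known limitations

No mmCIF input; hydrogens are ignored in interface detection; no
multi-exponential or drift-corrected kinetic models; no Costes/Pearson
colocalization; conservation is alignment-only (no structure weighting
or tree inference).  The pipeline consumes structure-prediction
*outputs*; it does not run a predictor, build MSAs by homology search,
or assign secondary structure.
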