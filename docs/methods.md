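# Methods

This note documents the models and procedures implemented in
`achescreen`, the parameters that matter, the numerical choices made
where the design was genuinely open, what the synthetic generators do and
do not emulate, and the known limitations.

## Scope and stand-ins

The package owns the bespoke mathematics of an AChE virtual-screening
cascade. The surrounding engines are deliberately out of scope and enter
only through plain-text interchange contracts:

* docking (induced-fit and ensemble) is consumed as a
  `mol_id,conformation_id,xp_gscore` CSV;
* molecular dynamics is consumed as `frame,time_ns,value` RMSD/RMSF
  traces;
* pharmacophore hypothesis generation and 3D matching are consumed as a
  molecules × models phase-score TSV with a stable/unstable origin row;
* decoy libraries are produced by a property-matched sampler from a
  user-supplied pool rather than an external decoy service;
* pocket-descriptor frame extraction is replaced by a declared simplified
  extractor (k-means medoids in stable zones, z-score outliers in
  unstable zones).

Each stand-in is labelled as such in its docstring. The synthetic-data
module fabricates all of these inputs with known ground truth so that
recovery can be tested quantitatively.

## Family clustering

Similarity is Tanimoto over Morgan (circular) fingerprints, radius 2,
2048 bits — the standard open radial-fingerprint configuration; both
parameters are exposed. A pair of empty fingerprints is defined as
similarity 1 (indistinguishable molecules), one empty against non-empty
as 0. Clustering is agglomerative average linkage on distance
1 − similarity (scipy); ties in merge order follow scipy's deterministic
ordering.

The Kelley–Gardner–Sutcliffe penalty selects the cluster count: per level
k, the average spread is the mean over clusters with ≥ 2 members of the
mean within-cluster pairwise distance; spreads are linearly rescaled
across levels onto [1, n−1] and penalty(k) = rescaled spread + k, argmin
on the smallest k at ties. Levels where every cluster is a singleton have
undefined spread and are reported as missing. When all spreads are equal
the rescaled value is defined as 1 everywhere, so the penalty degenerates
to 1 + k. Note a structural property of this criterion: if the k-range
floor coincides with the true cluster count there is no under-clustered
level left to pay a large spread, and rescaling then amplifies
within-cluster noise; the penalty discriminates reliably only when the
true count lies strictly inside the range. The cluster count is
therefore exposed as a user parameter rather than always taken from the
argmin.

Cluster IC50 statistics use the sample standard deviation (n−1);
singletons report SD 0 with a flag. The four retention criteria (mean
< 10,000 nM; SD < 14,900 nM; size > 58; CV < 1.7) are all strict
inequalities, with the ≥ 3-of-4 rule and thresholds configurable. The
centroid representative minimizes mean distance to the other members,
ties to the lexicographically smallest identifier.

## Conformation sampling from trajectories

The seven-point extractor applies selectors in a fixed order — nearest to
the mean, nearest to mean − 2·sd, nearest to mean + 2·sd, lowest,
second-lowest, highest, second-highest (sample sd) — each taking its
best-matching frame among those not yet taken, ties to the earliest
frame. This collision rule guarantees exactly 7 distinct frames for any
trace of length ≥ 7 (property-tested over random traces); the ordering
and tie rule are this package's choice, since only the selector set and
the count of 7 are externally fixed.

Paired RMSD is the root-mean-square deviation over label-aligned atoms,
optionally after Kabsch superposition (SVD with reflection correction).
Diversity selection is greedy maximin: seed with the globally most
distant pair, then repeatedly add the conformation maximizing its minimum
distance to the chosen set, ties to the smallest index. Greedy maximin is
not guaranteed to reach the enumerated optimum (nor to be stable under
single swaps); it is the conventional reading of "selected for highest
conformational diversity" and is what the tests pin down, via an
independent reimplementation.

## Stability segmentation

Pipeline per trace: EMA with α = 2/(period+1) seeded at the first
observation (period default 5,000 frames, i.e. one tenth of a
50,000-frame trajectory; scaled-down test profiles keep the 1:10 ratio,
e.g. 500 on 5,000 frames) → min–max normalization → absolute forward
difference (the last point copies its predecessor so lengths match) →
min–max normalization of the derivative. A frame is flagged unstable when
the normalized derivative exceeds the threshold (default 0.6): a large
derivative of the moving average is precisely "the moving average in
transit", so the dual condition collapses to one test on the smoothed
signal's derivative. A raw-derivative mode is provided
(`normalize_derivative=False`) because whether the 0.6 threshold applies
to a normalized or raw derivative is not externally fixed; raw per-frame
derivatives of a [0,1] signal are ~10⁻⁴ and essentially never exceed 0.6.

Flags are OR-combined across a trace bundle sharing one time grid.
Flagged runs separated by less than a gap-merge window (1% of trace
length) are merged, and merged runs shorter than a minimum duration
(also 1%) are discarded — isolated single-frame flags are noise, whereas
genuine transition zones are contiguous multi-nanosecond intervals. The
complement of the unstable intervals is stable; zero-range normalization
(constant traces) yields no flags and one full-span stable zone.

On the synthetic generator (piecewise-stationary Gaussian segments,
levels 1.5 Å apart, noise σ = 0.15 Å, 50-frame linear ramps, 5,000 frames
over 500 ns), the planted transitions are recovered in 100/100 seeded
replicates with the detected interval within 2% of span of each planted
change point. Detected intervals start at the ramp and extend ~1–3% of
span beyond it — the EMA's decay tail — so interval *midpoints* are
biased late; localization is therefore measured as distance from the
change point to the interval.

## YN1 and YN2

YN1 normalizes ligand efficiency (LE = −score/MW) and log10 IC50 within
exactly the molecule set passed in — i.e. the molecules recovered by
ensemble docking for one cluster — and sums the normalized LE with the
inverted normalized log IC50. Degenerate all-equal LE or IC50 makes that
term 0 with a flag rather than an error. YN1 ∈ [0, 2], monotone
increasing in docking-score magnitude and decreasing in IC50.

YN2 averages three [0,1] terms: stable-match fraction, unstable-match
fraction, and the phase score normalized to the [ph_min, ph_max] range
observed among known actives at validation time. Below ph_min the score
is exactly 0 regardless of match counts — molecules that fit no model
well are excluded outright. Phase scores above ph_max (possible on novel
screening libraries, where the active range was fitted elsewhere) clamp
to normalized 1 with a flag; a degenerate ph_max = ph_min range defines
the phase term as 1 for qualifying molecules, flagged. The activity
threshold maximizes recall + specificity; candidates are the observed YN2
values, which is exact because the objective is piecewise constant
between them (a dense-grid check is exercised in tests). Classification
at a threshold uses ≥. ROC-AUC uses rank averaging for ties
(cross-checked against the Mann–Whitney pair statistic).

In paired simulations on the synthetic phase-score generator, YN2-mode
validation raises specificity substantially over the plain
OR-combination operating point at equal recall, which is the metric's
purpose: the OR rule alone accepts any molecule matching a single model.

## ML screening

Test split is floor(n × 0.2) uniformly at random under the seed. Decoys
are drawn per active from the pool, matched on MW ± 25 g/mol,
logP ± 1, H-bond donors/acceptors ± 1, rotatable bonds ± 2 (bins
configurable) and required to stay below Tanimoto 0.4 to every active;
shortfalls are reported rather than silently padded. Descriptor pruning
removes constant columns (flagged), min–max scales, groups columns with
|Pearson r| ≥ 0.9 by transitive closure, and keeps each group's
highest-variance member (column order on ties). Min–max scaling, not
standardization, precedes the variance comparison — standardization would
force all variances to 1 and make the rule vacuous. Balancing runs
k-means (k = number of training actives) on the scaled retained
descriptors and keeps the decoy nearest each centroid (smallest id on
ties).

The four algorithms are trained in a standardize-then-classify pipeline
with stratified 5-fold CV maximizing ROC-AUC over small fixed grids
(logistic C ∈ {0.01, 0.1, 1, 10}; SVM C ∈ {0.1, 1, 10} ×
γ ∈ {scale, 0.1}, wrapped in sigmoid calibration for probability output;
tree depth ∈ {3, 5, ∞} × min leaf ∈ {1, 5}; forest of 100 trees,
depth ∈ {3, ∞} × features ∈ {√d, d}). The grids are deliberately small so
a family trains in seconds; they are not a claim about optimal search
spaces. Model selection sums four [0,1] terms — test specificity,
true-negative fraction on the decoys excluded during balancing, family
recall, non-family rejection — with equal weights (the weighting was an
open choice) and breaks ties random forest > SVM > logistic regression >
decision tree.

## Assay analysis

Initial velocity is the least-squares slope over the best early window:
among prefixes of ≥ 3 points ending within the first 5 minutes, the
longest one maximizing R² (constant prefixes count as R² = 1 with slope
0). The window rule is this package's choice; only "early linear
portion" is externally fixed. Note that on a 45 s sampling grid an
exponential-approach curve with rate 0.01 s⁻¹ decays too fast for any
3-point window to approximate the tangent slope within 5%; the guarantee
that the early-window slope is close to the true initial rate holds for
curves whose early phase is near-linear at the grid resolution (rates
≲ 10⁻³ s⁻¹ on this grid), and the tests exercise exactly that regime.

%Inhibition = (1 − V0_sample/V0_control) × 100; the factor is
configurable for audit but only ×100 produces a percent scale. IC50
defaults to log-linear interpolation between the pair of concentrations
bracketing 50% (exactly-50% points short-circuit); the 4PL fit
(bounded least squares, fallback to interpolation with a flag on
non-convergence) is the robust alternative and reports an SD across
replicates when present. Interpolation is scale-equivariant in
concentration. Unit conversion is conc[µg/mL]/MW × 10⁶ nM with optional
nearest-100 rounding.

On synthetic plates (1:1 dilutions from 450 down, 3 replicates, 2%
multiplicative velocity noise, Hill slope 1) the 4PL estimate recovers
the true IC50 with ~1% median error over 200 seeds.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their config (seed included).
Families are built from nine fixed open scaffolds (quinoline, carbazole,
benzamide, …) decorated with enumerated substituents, so within-family
Tanimoto exceeds between-family and average linkage at the true k
recovers the families (adjusted Rand ≥ 0.9 in tests); IC50s are
log-normal around per-family geometric means (defaults 200 / 2,000 /
20,000 nM, geometric SD 3). Docking scores are Gaussian per pose around
−7 kcal/mol with a −2 kcal/mol mean shift for actives (SD 1) and a 10%
unrecovered fraction. Phase-score matrices use Bernoulli matches
(actives 0.8 stable / 0.7 unstable; decoys 0.15 / 0.1) with
label-dependent Gaussian scores.

None of this mimics real chemical property distributions, real docking
score landscapes, or real pharmacophore match statistics. Passing the
recovery tests demonstrates that the algorithms are implemented correctly
and behave as designed under controlled signal/noise — not that the
cascade would achieve comparable enrichment on a real screening library.

## Problem sizes

Default test and demo sizes are chosen so the whole suite runs in about a
minute on one CPU: libraries of ~75 molecules in 3 families, 5,000-frame
traces (EMA period 500), 100-seed recovery replicates for segmentation
and decoy balancing, and 200-seed plates for IC50 recovery. All sizes
scale up through the config objects.

## Known limitations

* No 3D structure handling: no conformer generation, protonation-state
  enumeration, or tautomers; SMILES are used as given.
* No trajectory-format parsing (DCD/XTC) in the core; traces enter as
  CSV.
* The ligand-based pharmacophore stage of the cascade filters on an
  externally supplied match table; hypothesis perception is not
  implemented.
* The cascade terminates at the YN2-ranked per-family list; downstream
  re-docking and free-energy re-ranking are export hooks, not
  implemented.
* Greedy maximin diversity selection is a heuristic; it can fall short of
  the enumerated optimal subset.
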