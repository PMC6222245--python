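# Methods

## Problem and model

Stereo-electroencephalography (SEEG) implants 10–18 intracerebral electrodes
to localise the epileptogenic zone of a drug-resistant focal epilepsy.
Planning the electrode trajectories is patient-specific but not arbitrary: a
centre's surgeons reuse recognisable exploration schemes.  `seegplan` models
that practice from retrospective plans in four stages.

**1. Trajectory descriptors.**  Each trajectory (entry point EP, target
point TP, both RAS mm) is sampled along its arc at a regular step (default
1 mm, plus the exact end-point) against a labelled atlas volume, with
nearest-voxel lookup — labels are categorical, so no interpolation.  The raw
label sequence is reduced to a descriptor `d = [entry zone; target zone]`
through a zone configuration:

- `merge_map` folds raw labels into composite zones.  The default rules for
  Desikan–Killiany-style tables merge hippocampus with para-hippocampus
  (exploring one implies the other along the same needle), fold the putamen
  into the insular zone (electrodes crossing the insula and ending in the
  putamen belong to the insular exploration), and join lingual, cuneus,
  precuneus and pericalcarine into a single occipital zone (occipital
  explorations are sparse and spatially, not label-wise, distinctive).
- `ignore_labels` (white matter, unknown/0) are transparent during
  traversal.
- `exclusion_zones` (ventricles, brain stem, cerebellum) classify a
  trajectory as an outlier when its *deepest non-ignored* label is one of
  them: the exclusion is terminal, not mid-traversal, because crossing CSF
  near a ventricle wall is unremarkable while *ending* in such a structure
  indicates a mis-segmented or atypical trajectory.

The clinical target of an electrode need not be its geometric end-point; it
can be any zone it crosses, and deciding which one normally takes clinical
knowledge.  We encode that knowledge in the configurable target-zone set and
take the **deepest traversed member** of that set, which is deterministic
and reproducible.  The entry zone is the **first cortical zone traversed**
(atlases do not label scalp or skull, so the skin point cannot be used).
Trajectories with no admissible entry or target zone are outliers and never
enter pattern mining.

**2. Exploratory patterns and mean trajectories.**  Plans are mapped to a
common average brain space through per-patient affine registrations
(plain-text 4×4, row-major; the subject→average direction).  Descriptors
are computed there against a single average-space atlas, which keeps the
model self-contained; per-subject parcellations would work identically
through the same interface.  Non-outlier trajectories sharing a descriptor
form an exploratory pattern.  Each pattern is compressed by k-means on the
joint 6-D (entry ⊕ target) vectors — joint, because clustering entries and
targets separately could pair an entry sub-cluster with the wrong target
sub-cluster.  The initial k is `U`, the maximum number of same-descriptor
electrodes any single plan uses (a plan that places three insular electrodes
is covering three sub-regions, so three means are warranted).  A cluster is
significant only if it contains **at least 5%** of the pattern's
trajectories (`≥` on the real-valued product, no rounding); otherwise k is
decremented and k-means rerun, down to a documented floor of k = 1.  Each
final cluster becomes a mean trajectory: centroid EP/TP plus scalar
dispersions σ_ep, σ_tp defined as the RMS *radial* (Euclidean) distance of
member points from the centroid — scalar, because the validation criterion
uses σ as a radius.

k-means uses k-means++ initialisation with 10 restarts and a caller-supplied
seed; the iterative pruning is therefore deterministic and reproducible, and
equals an exhaustive downward k-sweep under the same seeding (property
tested).  Mean-trajectory indices u are assigned by descending member count,
ties broken by entry-point lexicographic order, so persisted bundles are
byte-reproducible.

**3. Planning strategies.**  Every plan becomes a boolean vector over the
ordered mean-trajectory list (bit y set iff the plan contributed a
trajectory to mean trajectory y; membership is taken from the clustering
assignment, never re-matched geometrically).  Plans are clustered
agglomeratively on pairwise Jaccard distance (1 − |∧|/|∨|; two empty
vectors are at distance 0 by convention).  The default linkage is **average
(UPGMA)**: the common pairing with Jaccard dissimilarity, avoiding
single-linkage chaining on nested plans.  Flat groups are read off at a cut
threshold — an empirical, centre-specific choice, so it is an explicit
parameter (default 0.7) and the CLI can export a QA dendrogram for visual
selection.  Each group yields a strategy: bit y is kept iff **at least two
member plans** support it, filtering patient-specific electrodes out of the
reusable scheme.  Singleton groups necessarily produce all-False strategies;
they are kept (flagged) to preserve the group partition.

**4. Initialisation and the 2σ criterion.**  For a new subject with
registration affine A (subject→average), the selected strategy's mean
trajectories are mapped through A⁻¹, giving an initialised plan (IP).
Validation against a manual plan (MP) pairs IP and MP trajectories
one-to-one by minimum-cost linear assignment on d_ep + d_tp, restricted to
descriptor-compatible pairs when the manual descriptors are computable
(pairing optimality is verified against brute-force permutation on small
instances).  A pair is **correctly mapped** when d_ep ≤ 2σ_ep AND
d_tp ≤ 2σ_tp, both inclusive.  A singleton mean trajectory has σ = 0 and
can only pass on an exact hit; such pairs are flagged as degenerate.
`fraction_mapped` is the passing fraction over *paired* (i.e. initialised)
trajectories.

**Risk indices.**  Two read-only safety scores support before/after
comparisons: the insertion angle arccos(|direction · surface normal|)
(0° = perpendicular entry, ideal; the normal is supplied explicitly rather
than computed from a scalp mesh), and the minimum distance from a binary
vessel mask, computed from its Euclidean distance transform sampled along
the trajectory and split at a configurable depth (default 10 mm) into a
proximal and a distal tract.  Distances are voxel-centre based, accurate to
about one voxel diagonal.  Trajectory optimisation is out of scope.

## Synthetic cohorts

Clinical planning data cannot be shared, so the generator plants a known
model and draws cohorts from it: vertical mean trajectories, one per
40 mm-wide column of a block atlas (entry slab on top, deep target block,
white-matter filler between), disjoint strategies over them, and per-plan
draws with isotropic Gaussian EP/TP noise (default σ = 2 mm per axis, so
RMS radial deviation σ√3), per-trajectory dropout (default 10%), optional
per-pattern multiplicity with 10 mm lateral offsets (to exercise U > 1),
and invertible random per-subject affines (±5° rotation, ±5% scale, ±5 mm
translation) so the average-space normalisation is genuinely exercised
rather than bypassed.  Default cohort size is 40 plans over 4 strategies of
3 mean trajectories — small enough for seconds-scale runs while leaving
every stage non-trivial.  Ground truth is written to a sidecar `truth/`
directory the pipeline never reads.

What the generator does **not** emulate: real cortical geometry and
curvature, per-subject anatomical variability beyond an affine, label noise
at zone boundaries, correlated electrode placements within a plan, and the
unbalanced pattern frequencies of a real centre.  Passing recovery tests
therefore demonstrates correctness of the mining machinery under its own
assumptions, not clinical validity on hospital data.

## Numerical choices and degenerate inputs

- One convention everywhere: RAS mm world coordinates, 0-based voxel
  indices, explicit `subject`/`average` space tags validated at module
  boundaries.
- Points outside the atlas grid read label 0 (ignored); affines must have
  |det| > 1e-12 and the homogeneous last row.
- k exceeding the pattern size is clamped with a warning; empty patterns
  and empty label sequences are contract errors.
- The significance comparison is `n_members ≥ min_frac · pattern_size`
  exactly (inclusive, unrounded); the 2σ comparison is likewise inclusive.
- Plans whose trajectories are all outliers get all-False vectors (logged),
  not dropped, so the plan partition is preserved.
- A generated plan always keeps at least one trajectory even under heavy
  dropout, so plans are never empty.

## Known limitations

- Exact strategy-partition recovery at a fixed cut threshold is not
  guaranteed under per-trajectory dropout: a plan reduced to a single mean
  trajectory can sit farther than the threshold from its own group's
  average.  Threshold selection remains an empirical step, as in practice.
- With n members per mean trajectory, centroid estimates carry a radial
  standard error of σ√3/√n; tests on small cohorts must expect occasional
  ~2-standard-error excursions.
- The atlas-driven descriptor inherits the atlas's granularity; zones
  thinner than the sampling step can be missed (descriptors are tested to
  be step-invariant only down to half the thinnest crossed zone).
- Vessel distances are voxel-centre approximations; sub-voxel accuracy
  would need an anti-aliased distance field.
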