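# Methods

## Model

The segmentation is a binary discriminative random field on the voxel grid.
Nodes are voxels; edges connect 6-neighbors. The posterior over labelings
`x ∈ {−1,+1}^N` given observations `y = (intensities n, coordinates p)` is

    log Pr(x|y) = Σ_i A(x_i, y) + Σ_i Σ_{j∈N_i} I(x_i, x_j, y) − log Z.

The double sum over sites and neighborhoods counts each unordered edge twice
(once per direction); the minimize-form energy folds this as a factor of two
on the per-edge tables. The partition function Z is never computed: MAP
inference only needs potential differences.

**Association.** A logistic model on h = [1, f_g, f_u, f_l]:
A(x_i,y) = log σ(x_i wᵀh_i), evaluated as −softplus(−x z) so it is
overflow-safe at |z| in the hundreds. The three features are the squared
intensity z-score under a Gaussian nodule-intensity model, the indicator of
falling outside the training intensity range (strict inequalities at both
ends), and the squared physical distance from the estimated nodule center
normalized by the estimated radius (f_l = |p−l|²/r² in mm, implemented as a
componentwise division by σ_loc = r/spacing in voxel units). No kernel
expansion is applied to the features; h is the identity mapping of f plus a
bias element.

**Interaction.** An Ising term attenuated by the neighbors' intensity
difference: I = β x_i x_j v δ, δ = max(1 − |n_i−n_j|/1000, 0). The 1000 HU
scale is a config value (`delta_scale`); it is appropriate for a
Hounsfield-like intensity scale where parenchyma-to-nodule steps are ~850 HU.
β is a fixed 0/1 switch (default 1); v is the learned scalar. β·v ≥ 0 makes
every pairwise table submodular, which is what guarantees that min-cut finds
the exact global MAP; inference refuses non-submodular energies rather than
truncating them, and learning enforces v ≥ 0.

**Features see the smoothed volume.** At inference the volume is smoothed
with a 3D Gaussian of 1 voxel standard deviation before geometry estimation
and feature computation. (The geometry chain's own step-1 filter is 2D
in-slice, also 1 voxel sd; the two are distinct operations and both are
applied.) "One voxel radius" in the source material is read as sd = 1 voxel.

## Geometry estimation

Global constants (μ_int, σ_int, t_min, t_max) are the pooled mean, sample
standard deviation (ddof = 1), minimum and maximum of mask-positive voxel
intensities across the training set. A training set whose positive voxels are
all identical is rejected rather than silently producing σ = 0.

Per nodule, from the seed point:

1. in-slice 2D Gaussian denoising (sd 1 voxel), then strict double
   thresholding t_min < n < t_max → initial segmentation;
2. a physically isotropic box grown around the seed in steps of the finest
   spacing until ≥ 75% of box voxels are negative (first crossing);
   r_init = half the box edge;
3. lung subvolume: morphological close then open of the *inverted* initial
   segmentation with a 6 mm-radius ball, refill of the nodule area with an
   r_init/2 ball at the seed, and a final 6 mm close. Structuring elements
   are physical-radius balls rasterized by voxel-center inclusion (ellipsoids
   in voxel units on anisotropic grids). Morphology uses edge-replicated
   padding so regions touching the volume boundary are not eroded by the
   implicit zero border;
4. restriction of the initial segmentation to the lung mask, then to the
   6-connected component containing the seed;
5. center refinement: on the seed's slice, the 8-connected local maximum of
   the in-slice 2D Euclidean distance transform nearest the seed (ties: the
   larger distance, then the lexicographically smaller index);
6. final radius r: a sphere grown from the refined center in steps of the
   finest spacing, stopping when a shell adds no positive voxels or the
   in-sphere positive fraction drops below 0.5; the radius before the stop is
   returned;
7. σ_loc = r / spacing componentwise.

**Boundary-censored box growth.** Near a pleural wall whose intensity falls
inside (t_min, t_max), the 75%-negative criterion of step 2 is unreachable in
principle: a near-planar positive wall keeps roughly half of any seed-centered
box positive, so the box either hits the volume bounds or only satisfies the
criterion once it has swallowed most of the volume. Both outcomes are
boundary-censored, not informative. The criterion therefore only counts if it
is met while the box is still fully inside the volume; otherwise r_init is
read off the in-slice 2D distance transform at the peak nearest the seed
(which measures the nodule radius toward the aerated-lung side even when the
nodule abuts the wall) and rescaled by ((4π/3)/0.25)^{1/3}/2 ≈ 1.28 so that
it matches the box-growth definition on isolated spheres. An all-positive
seed slice falls back to the half extent. Without this, every juxtapleural
case inherits a fill ball (step 3) far larger than the nodule, the lung mask
annexes part of the wall, and the location feature is mis-scaled; with it,
juxtapleural accuracy is limited only by the model's genuine reliance on the
location feature to separate wall from nodule.

Steps 5–6 operate on the component-filtered mask (the alternative reading —
the unfiltered initial segmentation — would let distant structures distort
the center and radius). All per-nodule processing runs on a cube of physical
half-width max(2.5 · r_init, 12 mm) around the seed and is mapped back to
full-volume coordinates; features decay within ~2 radii of the center, so a
larger margin only adds background voxels (and graph size) without changing
the labeling. Voxels outside the cube are labeled −1.

## Inference

The negated log-potential is reduced to the standard s-t min-cut
construction: per-voxel terminal excesses plus one directed arc per edge with
capacity B+C−A−D ≥ 0 (table [[A,B],[C,D]], submodularity). Source side =
label +1. Capacities are floats; they are scaled to integers by a factor
chosen so that both the largest capacity and an upper bound on the max-flow
value (the cheaper of the two all-terminal cuts) fit in int32, then solved
with scipy's C++ max-flow. On small instances the scaling leaves ~1e−9
relative rounding; on full volumes the label of a voxel whose posterior sits
within ~1e−6 of exactly 0.5 could in principle differ from the float
decision, which is far below the noise level of everything measured here.
The labeling is recovered by BFS reachability on the residual graph
(deterministic: fixed node order, fixed edge insertion order; exact ties at
zero residual label a voxel −1), and the reported energy is always recomputed
in float64 from the original tables. `solve_map_exhaustive` enumerates all
labelings of ≤ 20 voxels (lexicographically smallest on ties) and serves as
the independent oracle in the tests.

## Learning

θ = [w0..w3, v] is learned by maximizing the training F-score of full
graph-cut inference. tp/fp/fn are pooled across training cases by default
(per-case averaging is a config switch); an empty prediction has precision 0
by definition. Geometry and features do not depend on θ and are cached once
per case. v < 0 scores 0 (with no exception) so the search can leave the
non-submodular region.

The annealer is a re-implementation, not a port: Gaussian proposals with
per-component sd `step_scale · T`, acceptance of worse moves with probability
exp(−ΔF · accept_scale / T), exponential cooling T ← 0.97 T from T0 = 1 over
500 iterations, and reannealing every 50 iterations (T resets to T0 and the
state returns to the best-so-far point). Defaults: step_scale 1, accept_scale
50. The objective is piecewise constant (it depends on θ only through a
discrete labeling), so unbounded high-temperature random walks can drift into
saturated plateaus and never return; the periodic best-restart is what makes
a 500-evaluation budget reliable (observed: without it, runs can terminate on
the all-positive plateau). The best-ever θ is returned, so the result never
scores below the starting point θ = 0.

Two further consequences of the plateau structure:

- **One-sided default bounds.** f_g, f_u and f_l are costs, so the
  association probability of the nodule label must be non-increasing in each;
  the default bounds are w1, w2, w3 ≤ 0 (bias free, v ≥ 0 for
  submodularity), honored by rejection-resampling of proposals. On an easy
  training set the objective is flat in the sign of the location weight
  (intensity alone separates nodule from aerated lung), and an unconstrained
  fit can return a *positive* location weight that rewards distance from the
  center — harmless in training, catastrophic on juxtapleural test cases.
  The sign constraint encodes the model's cost semantics; it is also the
  reproducible form of the hand-tightened one-sided bounds that the original
  training procedure applied around its first optimum.
- **Minimum-norm tie-break.** Exact ties in the objective are resolved toward
  the smaller ‖θ‖, both for move acceptance and for the returned best.  The
  optimal set is a plateau; without a tie-break the returned point within it
  is an arbitrary function of the random path, and large-‖θ‖ plateau points
  (e.g. a large bias compensated by shallow feature weights) generalize
  measurably worse to nodule configurations absent from the training set.
  The minimum-norm point is the canonical representative of an
  underdetermined fit.

## Synthetic phantoms

The generator emulates small chest-window crops around a solid nodule:

- lung parenchyma at −850 HU, nodule at 0 HU, wall/vessel at +50 HU,
  i.i.d. Gaussian noise sd 40 HU — solid nodules are near water density,
  aerated lung near air, and chest-wall soft tissue slightly above water;
- anisotropic spacing 0.7×0.7×1.25 mm (typical reconstructed chest CT);
- nodule: a sphere, optionally perturbed radially by a bounded deterministic
  combination of degree ≤ 3 direction harmonics (`lumpiness` = maximum
  relative perturbation);
- optional juxtavascular cylinder through the nodule center and juxtapleural
  wall slab (6 mm) at the low-x face with the nodule parked against it;
- partial-volume blur: Gaussian psf, default sd 0.8 voxels, applied before
  noise;
- ground truth is the voxel-center rasterization of the nodule solid
  *before* blur and noise, so analytic sphere volumes can be checked against
  voxel counts and the mask is independent of noise level and noise seed.

Training sets mirror an isolated-nodule training regime (radius 4–7 mm, no
juxta variants); evaluation sets span 3–10 mm and include juxtavascular and
juxtapleural cases. Everything is reproducible from an integer seed.

What the phantoms do *not* emulate: anatomically curved pleura, ground-glass
or cavitating nodules, scanner reconstruction kernels and streak artifacts,
respiratory motion, and the inter-reader variability of manual ground truth.
Passing the phantom suite therefore demonstrates the correctness of the
estimator, the potentials, the solver and the training loop under controlled
conditions — not clinical-grade accuracy on real CT.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 4 training phantoms,
500 annealing iterations and 20 held-out phantoms — sizes chosen to mirror a
small-training-set regime while keeping a full from-scratch run in minutes on
one CPU. Tolerances: association normalization holds to 1e−12; energy/
log-potential complementarity to 1e−8 relative; the graph-cut/exhaustive
comparison to 1e−9 absolute. Geometry on noiseless spheres recovers the
radius within 2 finest-spacing steps and the center within one voxel across
3–10 mm. Degenerate inputs raise typed errors naming the failing stage
(seed on a negative voxel, seed excluded by the lung mask, empty seed slice,
empty ground truth, σ = 0 intensity models, non-submodular parameters).

## Known limitations

- Juxtapleural nodules are separated from the wall only by the location
  feature f_l, because wall soft tissue falls inside the training intensity
  window; expect boundary leakage into the wall of order the estimated-radius
  error (held-out Dice ~0.7–0.8 on wall cases versus ~0.95–0.99 on isolated
  ones).
- The threshold feature f_u uses the pooled min/max of training intensities —
  extreme order statistics that widen with partial-volume blur and noise, so
  f_u carries little information when training masks include rim voxels.
- Training optimizes the pooled F-score; with very heterogeneous nodule
  sizes, large nodules dominate the objective.
- One seed per nodule is assumed correct and inside the nodule; there is no
  recovery from a mis-clicked seed.
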