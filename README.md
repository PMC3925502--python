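# drfseg

Semi-automatic 3D segmentation of solid lung nodules in CT volumes from a
single seed point, using a **discriminative random field** (DRF) solved
exactly by graph cuts.

Radiologists tracking pulmonary nodules across longitudinal CT studies need
voxelwise nodule volumes, but manual contouring is slow. Given one clicked
seed point per nodule, this package estimates the nodule's location and size
by morphological filtering, builds a binary random field over the voxel grid,
and computes the exact maximum a posteriori (MAP) labeling — nodule versus
background — by min-cut/max-flow. Model parameters are learned from a handful
of labeled training nodules by simulated annealing on the voxelwise F-score
of full inference results. A synthetic CT-phantom generator provides
training, test and regression data with exact ground truth, so everything in
the repository runs with no external data.

## Model

For voxels \(s_i\) with observed (pre-smoothed) intensity \(n_i\), voxel
coordinates \(p_i\) and labels \(x_i \in \{-1, +1\}\), the posterior over
labelings factorizes over the 6-neighborhood graph:

```
log Pr(x | y) = Σ_i A(x_i, y) + Σ_i Σ_{j ∈ N_i} I(x_i, x_j, y) − log Z
```

with a logistic **association potential** on per-voxel features

```
A(x_i, y) = log σ(x_i · wᵀ h_i),      h_i = [1, f_g, f_u, f_l]

f_g = (n_i − μ_int)² / σ_int²                 (Gaussian intensity cost)
f_u = 0 if t_min < n_i < t_max else 1         (threshold model cost)
f_l = ‖(p_i − l) / σ_loc‖²                    (distance from estimated center,
                                               normalized by estimated radius)
```

and an intensity-attenuated Ising **interaction potential**

```
I(x_i, x_j, y) = β · x_i x_j · v · max(1 − |n_i − n_j| / 1000, 0).
```

The constants (μ_int, σ_int, t_min, t_max) are the pooled mean, standard
deviation, minimum and maximum of nodule voxel intensities in the training
masks. The nodule center `l` and radius `r` (σ_loc = r/voxel size) are
estimated per nodule from the seed point by a seven-step morphological
procedure (in-slice denoising and double thresholding, bounding-box radius
estimate, lung-subvolume extraction by close/open with a 6 mm ball,
seed-component filtering, 2D-distance-transform center refinement, and
sphere-growth radius estimation). For β·v ≥ 0 the negated log-potential is a
submodular pairwise energy, so the global MAP is found exactly by s-t
min-cut. The weights θ = (w, v) are learned by simulated annealing on the
training-set F-score (equivalently Dice) of full graph-cut inference.

## Worked example

```python
import drfseg as d

# four labeled training nodules (here: synthetic phantoms with ground truth)
training = d.make_training_set(4, rng_seed=7)

model = d.NoduleDRF(training)                       # fits intensity constants
res = model.fit(d.AnnealConfig(iterations=500, rng_seed=1))
print(res.summary())

# segment a new volume from its seed point and score it
vol, truth, seed = d.make_phantom(d.PhantomSpec.for_radius(6.0, rng_seed=99))
pred = res.segment(vol, seed)
m = d.compute_metrics(pred, truth, vol.spacing)
print(f"dice={m.fscore:.3f} precision={m.precision:.3f} recall={m.recall:.3f}")
```

Output from the run above:

```
Discriminative random field nodule segmentation
================================================
training cases:        4
annealing iterations:  500
best training F-score: 0.9880

Association weights w (bias, f_g, f_u, f_l):
   5.3668  -0.6821  -4.0814  -1.3392
Interaction weight v:  0.0941  (beta = 1)

Intensity model:
  mu_int = -118.44 HU   sigma_int = 141.21 HU
  t_min  = -552.84 HU   t_max     = 124.78 HU

dice=0.989 precision=0.990 recall=0.989
```

The learned weights read as expected: a positive bias inside the nodule and
penalties on the intensity z-score, the out-of-threshold indicator and the
normalized distance from the estimated center; the small positive `v`
smooths labels across similar-intensity neighbors.

The same pipeline is scriptable from the shell:

```bash
drfseg phantom --out data --radius 6 --seed 3        # volume + mask + seed
drfseg train data --out params.json --iterations 500
drfseg segment data/phantom_vol.nii.gz --params params.json --out data
drfseg evaluate data
```

Volumes and masks are NIfTI (`.nii`, `.nii.gz`) or MetaImage (`.mha`,
`.mhd`); seeds are one integer voxel triple in plain text or JSON.

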