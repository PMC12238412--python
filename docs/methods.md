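# Methods

This note documents the models, conventions and design choices behind
`fedsim`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic federations

Each site is generated from a `SitePhantomSpec`: a case count, a
per-channel affine intensity shift (scale and offset, the site's
"scanner"), an additive Gaussian noise level, a lesion radius range (in
voxels) and an enhancing-tumor fraction range. A case is a 4-channel
image (channel order T1, T1-Gd, T2, FLAIR) plus a label map with values
0 / 1 (necrotic core, NCR) / 2 (edema, ED) / 4 (enhancing tumor, ET).

Lesions are nested ellipsoids: the whole tumor is a random ellipsoid
(per-axis radii jittered ±25% around a sampled radius), the tumor core a
concentric ellipsoid at 50–80% of the radius (the shell between them is
edema), and the enhancing tumor is the centre-most fraction of core
voxels. Selecting ET as the innermost *fraction* of core voxels (rather
than a third concentric ellipsoid) makes the realized ET/TC voxel ratio
track the sampled fraction to within discretization error and guarantees
a single connected central ET blob, which gives the hole-filling
post-processing realistic inputs.

Tissue classes have distinct per-channel mean intensities; in particular
the contrast channel (T1-Gd) is elevated only inside ET, mirroring the
clinical signature that defines enhancement. The site's affine shift is
applied *after* the noise draw, so two sites differing only in offset
produce voxel-wise identical images up to exactly that offset under the
same seed — which makes the site-shift invariant exactly testable.

Defaults: 32×32 2-D grids (3-D grids such as 24³ work but are slower),
lesion radii 5–10 voxels, ET fraction 0.2–0.5, noise σ = 0.05. The
default geometry is deliberately small so that whole federated
experiments finish in minutes on one CPU; it emulates the *statistical*
structure of multi-site data (skewed sizes, site shifts, nested labels),
not MRI physics, registration or skull-stripping. Passing tests on these
phantoms demonstrates correctness of the benchmark machinery, not
segmentation performance on real MRI.

Site sizes can be fixed, Poisson (the canonical skewed-site-count model)
or log-normal; zero draws are redrawn so no client is ever empty. The
validation split is `n_val = max(1, round(0.2·n))` (half-up), drawn once
per client. The artificial partitioning splits each of the largest sites
into equal parts after a stable sort by whole-tumor size (ties broken by
case index), preserving the case multiset.

## Local model and training

The trainable model is a two-level residual encoder–decoder in numpy:
3³-kernel convolutions, ReLU, one residual block at full resolution, a
2× mean-pool to a 2w-channel bottleneck, nearest-neighbor upsampling, an
additive encoder–decoder skip, and a 1×1 classification head over the
four tissue classes. Default width w = 8 (≈ 4,500 parameters in 2-D).
Analytic gradients are verified against central finite differences in
the test suite.

The local loss is cross-entropy plus soft Dice (1:1), the dominant
combination for tumor segmentation; soft Dice is computed per foreground
class over batch-global sums with ε = 1e-7. The optimizer is plain SGD
(momentum available but off by default). Batch order is seeded per
(client, round), so local training is bitwise reproducible and identical
across aggregation algorithms. Parameters are exchanged as a flat
float64 vector plus a (name, shape) layout, so any convex combination
folds back losslessly.

## Simulated time

Per client and round, T_k = T_down + T_up + T_val·N_val + T_train·N_train,
each component drawn once per round from N(μ_x,k, σ_x,k); per-sample
components scale with the client's split sizes. The round time is
max_k T_k over the selected clients. Negative normal draws are floored
at 10⁻³ of the mean (normals are unbounded below, times are not); the
floor is part of the documented conventions. Communication times are
per-round constants independent of model size — in the simulated regime
training dominates and transmission is negligible.

The default profile is *size-proportional* (μ: down 60 s, up 60 s, val
3 s/sample, train 30 s/sample, σ = 10% of μ, per-client speed factors
uniform in [0.8, 1.2] drawn once per experiment), which makes large
clients the slowest — the regime in which selective client sampling
matters. Real per-site timing measurements are not public; these
magnitudes are configurable analogues, not calibrated fits.

## Evaluation metrics

* **DSC** = 2|Y∩Ŷ|/(|Y|+|Ŷ|) per region (WT ⊇ TC ⊇ ET). Conventions:
  both masks empty → 1.0; exactly one empty → 0.0.
* **HD95**: boundary voxels are mask voxels with ≥1 face-adjacent
  non-mask neighbor (array edges count as boundary); directed distances
  are exact Euclidean distances (via distance transform, honoring voxel
  spacing); the score is the max of the two 95th percentiles with the
  linear-interpolation percentile definition. If exactly one mask is
  empty the distance is undefined and a sentinel is reported (default
  373.13, the image-diagonal penalty convention of the BraTS community;
  configurable and recorded with results). Sentinel values participate
  in rankings as worst-in-group.
* **Convergence score**: the validation-DSC-over-simulated-time curve is
  projected to its running maximum (a later DSC drop is not penalized
  because the best-validation model is kept), treated as a *step*
  function — the DSC is only observed at round boundaries, so no
  between-round interpolation is justified — held to the budget, 0
  before the first point, and integrated; the area is divided by the
  budget for comparability across budgets, giving a score in [0, 1].
  Curve point i is (cumulative time after round i, pooled validation DSC
  of the round-i global model), with the initial model at t = 0.

## The federated round loop

select → distribute → each selected client validates the received model,
then trains locally → weighting terms → combination → aggregation →
optional server-optimizer step → timing draw → clock advance. Runs stop
when the cumulative simulated time exceeds the budget (default 168 h);
the budget-exceeding round is recorded but earns no credit: its model is
excluded from final-model selection and from the convergence curve, so a
long final round cannot benefit a policy.

The per-round global validation DSC is pooled across **all** clients
(weighted by validation-split size), not only the selected ones — it
emulates a fixed 20% validation split of the full training data, and it
keeps the curve comparable across selection policies.

The master seed fans out into independent named streams (data,
initialization, batches, timing, selection). Timing draws are consumed
for every roster client each round, in fixed order, whether or not the
client was selected; this guarantees the fairness contract that changing
the aggregation algorithm (or the selection policy) cannot perturb the
timing sequence. FedAvg's N_k is the client's training-split size.

Degenerate inputs: a selection policy that would pick zero clients falls
back to full participation (flagged in the trace); all-zero weighting
terms fall back to uniform (flagged); zero denominators and zero
parameter distances are clamped at ε = 1e-8 (flagged). Flags are written
to the run log. In multi-term multiplicative combinations, terms are
normalized individually and the product renormalized only at the end;
for strictly positive terms the order is immaterial, and the final-only
renormalization defines the degenerate-zero behavior (an all-zero unit
is an error naming the offending clients).

The HT-TUAS-style parameter-change rescale multiplies each client weight
by ‖w_t^k − w_{t−1}^k‖₁ raised to a signed strength. The published
summary does not fix the sign; the default preset uses strength −1
(down-weighting large movers, a stability rationale), and a positive
strength up-weights them. The reference for a client's previous
parameters is its last local model, or the previous global model if it
was not selected before.

## Ranking

Both schemes are rank-then-aggregate with minimum-rank tie handling.
Task-1-style: per case, algorithms are ranked on 3 regions × 2 metrics
(DSC descending, HD95 ascending) and the convergence-score rank
(computed once — it is constant per algorithm — and replicated) is
appended with weight 3, giving N·3·3 ranks per algorithm. The reported
ranking score is the *mean* of the collected ranks, which orders
identically to the total sum but matches familiar leaderboard scales.
Task-2-style: within each institution, per-case ranks are averaged per
region-metric combination and re-ranked to give per-institution ranks;
the final score is the mean of the K·3·2 per-institution ranks, so every
institution weighs equally regardless of its case count. An institution
where some algorithm has no evaluable cases is excluded globally by
default (and reported); a "pairwise-available" mode instead drops it
only from the affected algorithm's average.

The QC screen sorts cases by the DSC between a strong reference model's
prediction and the provided annotation and flags the lowest-scoring
⌈q·n⌉ cases (default q = 0.2, inclusive ceiling) as candidate annotation
errors; with a known corruption set it reports the captured fraction.

## Post-processing conventions

* `fill_tc`: one hole-filling pass per orientation (axial → coronal →
  sagittal for 3-D volumes; a 2-D map is one axial slice), where holes
  are non-TC regions not 4-connected to the slice border; enclosed
  voxels (background or edema) become NCR; NCR/ET voxels are never
  changed. Whether the orientation cycle should repeat to convergence is
  not fixed by the published descriptions; a single cycle is the
  default, with `until_convergence=True` available.
* Volume thresholds are strict `<` everywhere (`min_voxels` equal to the
  component size keeps it).
* Component connectivity defaults to faces (scipy connectivity 1);
  configurable.

## Problem sizes and limitations

The test suite and the acceptance script use 32×32 phantoms, federations
of 2–6 sites with 6–40 cases each, runs of up to ~26 rounds, and a
5-simulated-hour budget for the skewed-federation comparison — sizes
chosen so the full pipeline exercises every component in about a minute
on one CPU. Known limitations: no MRI physics or preprocessing
emulation; the miniature model is an analogue of a full-resolution
residual U-Net, not a replica; synthetic site-size and timing laws are
stand-ins for unpublished real-world distributions; no straggler/failure
simulation (clients never drop out uninvited); no privacy mechanisms
(secure aggregation, differential privacy); and the multiple-gradient-
descent style aggregator is out of scope because its solver-level
details are not published.
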