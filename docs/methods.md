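# Methods

`cardiomesh` models a population of beating biventricular hearts represented
as fixed-topology triangulated surface-mesh sequences, learns a conditional
generative model over them, and scores how far an individual heart deviates
from the synthetic "normal" hearts matching its clinical profile.

## Data model

A sequence is `T` frames of one cardiac cycle. Every frame shares one
topology: a vertex set partitioned into three labelled anatomical parts —
LV cavity, myocardium (Myo) and RV cavity — each a closed, consistently
oriented triangle 2-manifold. Coordinates are millimetres. Cavity volumes
come from the divergence theorem (signed tetrahedra against the origin),
converted to millilitres. The myocardium is stored as a genuine shell:
an outward epicardial surface plus an inward-oriented endocardial copy, so
its enclosed volume *is* the wall volume and LV mass is simply
`wall volume x 1.05 g/ml` (the standard CMR tissue-density convention; the
density is a package decision, not a learned quantity).

End-diastole (ED) is the frame of maximum LV cavity volume, end-systole (ES)
the minimum, ties broken to the earliest frame. Ejection fraction is
`(EDV - ESV) / EDV x 100`.

Sequences serialize as one binary little-endian PLY per frame (double
precision, so round trips are lossless) plus a JSON manifest holding the
subject id, conditions, vertex labels and per-part face sets. The reader
validates closure, orientation and topological identity across frames.

## Synthetic population

Real cardiac mesh cohorts are access-controlled, so the package ships a
seeded generator whose ground truth is known exactly:

* **Conditions.** Sex ~ Bernoulli(0.5); age ~ U(45, 80) years; height and
  weight are sex-specific normals (F: 162±7 cm, 70±12 kg; M: 176±7 cm,
  84±13 kg), clipped to physiological ranges.
* **Phenotype model.** With BSA from the Mosteller formula,
  `LVEDV = 90 + 30·BSA + 20·sex − 0.3·(age−60)` ml plus optional Gaussian
  noise (SD 8 ml by default); `LVEF = 60 − 2·(age−60)/10` %, clipped to
  [35, 75]; RV volumes are 1.1× their LV analogues; LV wall volume is
  `85 + 30·sex` ml. Coefficients were chosen once to give realistic adult
  ranges (LVEDV ≈ 100–180 ml, LVEF ≈ 50–70 %) and plausible condition
  effects; they are not fitted to any dataset.
* **Geometry.** Icosphere-based template: LV cavity and epicardium are
  prolate (1:1:1.5) ellipsoids, the RV a flattened lateral ellipsoid.
  Scales are solved against the *discrete* mesh volume of the icosphere, so
  a noise-free subject's measured phenotypes equal the specified ones up to
  floating-point error, not just up to discretization.
* **Motion.** Frame 0 is ED. Radial scaling about the long axis follows a
  raised-cosine systolic phase `s(t)` with `s(0)=0` and `s=1` at
  `es_fraction·T` (default 0.35), so LV volume traces
  `EDV − (EDV−ESV)·s(t)`; wall volume is held constant over the cycle.
* **Shape noise.** A per-subject smooth random displacement field (six
  Gaussian bumps, SD 0.5 mm) applied identically to every frame, preserving
  closure and topology.
* **Disease.** Three stylized perturbations of the ground-truth record:
  dilatation (EDV ×(1+0.4·severity)), hypertrophy (wall volume
  ×(1+0.6·severity)) and reduced contraction (stroke volume
  ×(1−0.5·severity)).

What the generator does **not** emulate: real anatomy (no valves, septum or
trabeculation), regional wall-motion abnormality, imaging noise or
segmentation error, inter-site variation. A green test therefore
establishes that the pipeline recovers the stated population structure, not
that it would reach any particular accuracy on clinical data.

## Model

A conditional VAE over sequences, with clinical conditions
c = (age, sex, weight, height):

* **Condition encoder** — MLP (5 → 64 → 32) on z-scored continuous
  conditions (training-set statistics stored in the checkpoint) and one-hot
  sex, giving z_c ∈ R³².
* **Mesh encoder** — three graph-convolution layers
  (D^{-1/2}(A+I)D^{-1/2} propagation on the template edge graph; widths
  3 → 64 → 64 → 64) over per-vertex displacements from the template
  (divided by 50 mm), mean-pooled over vertices, then one FC layer to a
  64-d frame latent. Template-relative input matters: the constant
  population shape carries no information, and with raw coordinates the
  informative deviations sit orders of magnitude below the mean signal,
  leaving the encoder (and the normative deviation score) effectively
  blind. Mean pooling makes the encoder exactly invariant to consistent
  vertex permutation.
* **Temporal encoder** — the T frame latents plus two learnable
  distribution-parameter tokens; sinusoidal temporal encodings are added to
  the frame tokens (pure self-attention is permutation-equivariant, so
  without them the posterior could not see frame order). Every token is
  concatenated with z_c (width 96). Two pre-norm blocks (4 heads, FF 1024,
  dropout 0.1, residuals after each block, final LayerNorm). Learned
  96 → 64 heads read off μ, log σ and the per-frame outputs.
* **Latent.** z_a = μ + ε·σ with ε ~ N(0, I); σ is stored as a log-scale.
  Evaluation-time reconstruction uses ε = 0 (posterior mean).
* **Temporal decoder** — sinusoidal positional encodings of the frame
  indices (embedded 64 → 96) query, via two pre-norm cross-attention
  blocks, the single memory token [z_a; z_c]; an output head returns T
  frame latents.
* **Mesh decoder** — five FC layers (64 → 96 → 256 → 512 → 1024 → 3V). The
  final bias is initialised to the template coordinates, which is exactly
  equivalent to predicting displacements from the template and is what
  makes CPU-scale training with a fixed learning rate of 1e-4 feasible.
  At the reference scale (V = 22,043, T = 50) the configuration counts
  ≈ 69.5 M parameters.

The whole network runs on a small numpy reverse-mode autodiff engine inside
the package (no deep-learning framework is a dependency); its gradients are
validated against central finite differences in the test suite.

## Training

Loss per sequence (batch size one):

    L = L_R + β·KL(N(μ, σ²) ‖ N(0, I)) + λ_s·L_S,   β = 0.01, λ_s = 1

where L_R is the mean over frames of the symmetric Chamfer distance between
predicted and target vertex sets (sum of the two directed mean
nearest-neighbour distances, in mm) and L_S is the mean over frames of the
Laplacian smoothness (mean over vertices of the norm of the mean
neighbour-offset vector). Optimisation is Adam at a fixed 1e-4 — no
schedule, no weight decay, no clipping by default (clipping is available as
a recovery flag). Parameter init is He normal for ReLU-fed layers (fan-in
uniform attenuates both signal and gradients per layer at these widths),
fan-in uniform for the remaining linear maps; distribution tokens
N(0, 0.02²). Everything is seeded: init, data order, ε draws, dropout.

Desk defaults (T = 20, 162 vertices per surface, 50 epochs) train in
minutes on one CPU; the reference scale (T = 50, 22k vertices, 300 epochs)
is reachable by configuration but needs GPU-class compute.

## Evaluation and normative scoring

* **Reconstruction** — Hausdorff distance and average symmetric surface
  distance between corresponding per-part vertex sets (the meshes share
  topology, so no surface resampling is introduced), per structure and
  averaged, at ED, at ES and over all frames, averaged over subjects.
* **Generation** — per-phenotype histogram KL divergence (Freedman–Diaconis
  bins on the pooled sample, additive smoothing 1e-8, direction
  KL(real‖synthetic)) and 1-D empirical Wasserstein distance between real
  and generated phenotype samples, optionally within decade-of-age or sex
  strata (strata under 20 samples are skipped with a warning).
* **Latent vector** — mean of the transformer-encoder frame-token outputs
  (before reparameterization), 64-d, computed in evaluation mode for
  determinism.
* **Latent delta** — Δz = ‖z_real − mean of 100 z_synth‖₂, where the
  synthetic references are generated from the subject's own conditions with
  z_a ~ N(0, I) and re-encoded by the same encoders. Δz is a personalized
  normative deviation score: large values mean the heart's shape/motion is
  atypical for its demographic profile.
* **Downstream harnesses** — disease classification AUC (AdaBoost, LDA,
  linear SVM; features standardized per split; AUC averaged over five
  seeded random train/test splits) and an association scan of Δz against
  binary outcomes using a single-covariate logistic score test with
  Bonferroni correction sized to the outcomes actually tested.

## Numerical choices and limitations

* Distances use exact KD-tree nearest neighbours; the Chamfer gradient
  treats the current nearest-neighbour assignment as fixed (the standard
  subgradient).
* Norms inside losses add 1e-12 under the square root to keep gradients
  finite at coincident points.
* Model dtype is configurable (float64 default; float32 recommended for
  CPU training — the test suite trains its shared model in float32).
* The Σ produced by the distribution token is interpreted as a scale
  (standard deviation), stored as log σ; the KL uses the matching
  closed form.
* Degenerate inputs fail loudly: empty point sets, open or inconsistently
  oriented part surfaces, isolated vertices, topology drift across frames
  and non-finite losses all raise.
* Known limitations: vertex-to-vertex (not point-to-surface) distances;
  stylized anatomy; single-component RV ellipsoid; no long-axis motion or
  valve modelling; no multi-GPU or large-scale training path.
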