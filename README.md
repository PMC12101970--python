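# cardiomesh

Conditional spatio-temporal generative modelling of beating-heart surface
meshes, with personalized normative deviation scoring.

## The problem

Cardiac imaging pipelines can turn a cine scan into a sequence of
triangulated surface meshes — T frames of one cardiac cycle, with labelled
left-ventricular cavity, myocardium and right-ventricular cavity — that
capture both the shape and the motion of an individual heart. What counts
as a *normal* heart, however, depends strongly on who the heart belongs to:
age, sex, weight and height all shift chamber volumes, mass and ejection
fraction. `cardiomesh` is for researchers who want to model that
conditional distribution and ask, for a given individual, *how far is this
heart from the normal hearts of people like this?*

The package provides:

* a mesh data model with validated closed-surface parts, binary PLY
  serialization, surface metrics (Chamfer, Hausdorff, average symmetric
  surface distance), Laplacian smoothness and clinical phenotype
  extraction (LVEDV, LVESV, LVEF, LVM, RVEDV, RVESV, RVEF);
* a seeded synthetic population generator (condition-dependent beating
  biventricular meshes with known ground truth and optional disease
  perturbations) so the whole pipeline runs without access-controlled data;
* the generative model: a conditional VAE whose mesh encoder is a graph
  convolutional network, whose temporal encoder/decoder are transformers
  with two learnable distribution-parameter tokens, and whose decoder maps
  per-frame latents back to vertex coordinates;
* training (Chamfer + β-KL + Laplacian smoothing loss, Adam, fully seeded)
  on a numpy autodiff core — no deep-learning framework required;
* evaluation and analytics: reconstruction error tables, real-vs-generated
  phenotype distribution similarity (KL / Wasserstein), the latent
  deviation score Δz, and classification/association harnesses.

## The model in brief

Each frame is encoded by a 3-layer GCN to a 64-d latent; the T frame
latents (plus sinusoidal temporal encodings) and two learnable tokens
μ_token, Σ_token — each concatenated with a 32-d condition embedding z_c —
pass through a pre-norm transformer encoder. The two token outputs
parameterize a diagonal Gaussian, z_a = μ + εσ. A transformer decoder
queried by positional encodings of the frame indices, with [z_a; z_c] as
memory, emits per-frame latents that a 5-layer FC decoder turns back into
V×3 vertex coordinates. Training minimises

    L = L_Chamfer + β·KL(N(μ, σ²) ‖ N(0, I)) + λ_s·L_smooth

with β = 0.01, λ_s = 1, Adam at a fixed 1e-4, batch = one sequence.

The personalized normative score of a heart with latent vector z_real
(mean of the encoder's frame outputs) is

    Δz = ‖ z_real − (1/100) Σᵢ z_synth,i ‖₂

over 100 synthetic hearts generated from the subject's own conditions.

## Worked example

```python
from cardiomesh import (
    Condition, PopulationSpec, ModelConfig, TrainConfig,
    make_dataset, train, generate, compute_phenotypes, latent_delta,
)
from cardiomesh.population import DiseaseSpec, generate_sequence
from cardiomesh.training import load_split

spec = PopulationSpec(n_subjects=24, T=10, vertices_per_part=42, seed=1)
manifest = make_dataset(spec, "scratch/demo", seed=1)
state, report = train(manifest, ModelConfig(T=10, dtype="float32"),
                      TrainConfig(epochs=10, seed=1))
print(report.epoch_summary()["L_total"].iloc[[0, -1]].round(3).to_dict())

c = Condition(age=60, sex=0, weight=70, height=162)
sample = generate(c, n_samples=5, seed=2, state=state)[0]
print(compute_phenotypes(sample))

healthy = generate_sequence(c, spec, seed=3)
sick = generate_sequence(c, spec, seed=3, disease=DiseaseSpec("low_ef", 0.8))
print(latent_delta(state, healthy, n=50, seed=4).delta_z,
      latent_delta(state, sick, n=50, seed=4).delta_z)
```

prints (numbers from this exact script):

```
{0: 12.733, 9: 9.162}
PhenotypeRecord(LVEDV=139.70029687905202, LVESV=77.72510100778648,
                LVEF=44.3629664759565, LVM=80.67557570850268,
                RVEDV=152.375953066138, RVESV=66.58552704700007,
                RVEF=56.301814225175704, ed_frame=0, es_frame=4)
0.005088336178473268 0.009133390009017382
```

The epoch-mean total loss falls from 12.7 to 9.2 mm-scale as the model
learns the population; the generated heart's volumes land in the realistic
adult range implied by the conditions; and the reduced-contraction heart
sits about 1.8 times farther from its personalized normative cloud than
the healthy one — Δz is doing its job as a deviation score. (A 10-epoch,
24-subject demo model is far from converged; the test suite trains
50 epochs on 60 subjects and separates disease from health at AUC ≥ 0.7.)

There is also a CLI mirroring the library one-to-one:

```bash
cardiomesh --config cfg.yaml --out data/ simulate
cardiomesh --config cfg.yaml --out run/ train --data data/
cardiomesh --out gen/ generate --checkpoint run/checkpoint_final.npz \
    --age 60 --sex f --weight 70 --height 162 --n 20
cardiomesh --out eval/ evaluate --checkpoint run/checkpoint_final.npz --data data/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline from scratch — simulates a population, trains the
model, evaluates held-out reconstruction and computes a latent delta — and
writes the acceptance report JSON to `--out`.

## Layout

```
src/cardiomesh/
  meshes.py       mesh data model, PLY I/O, metrics, volumes, phenotypes
  population.py   synthetic beating-heart population generator
  autodiff.py     numpy reverse-mode autodiff + Adam
  model.py        condition/mesh/temporal encoders, decoders, checkpoints
  training.py     losses, optimisation loop, loss reports
  evaluation.py   eval tables, KL/WD, latent delta, classifiers, scans
  cli.py          command-line interface
docs/methods.md   full model and generator description
```
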