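# vqnorm

Normative modeling of 3-D gray-matter density maps through discrete
tokenization and autoregressive likelihoods of typicality.

## The problem

Psychiatric symptoms in youth are dimensional and heterogeneous: two
children with the same score may deviate from typical neurodevelopment in
different brain regions. Normative modeling sidesteps group averaging by
learning a reference distribution from *typical* subjects only and
scoring each individual's deviation from it. `vqnorm` implements a
generative variant of this idea for structural MRI-derived gray-matter
maps and provides everything needed to exercise it end-to-end on
synthetic phantom cohorts — no imaging data download required.

## The model

A volume `x` is compressed by a vector-quantized autoencoder: the encoder
produces a latent grid `z_e(x)`, each latent vector is snapped to its
nearest codebook entry `e_k`, giving a grid of discrete codes `q(z|x)`
(24x28x24 at full resolution, i.e. a "sentence" of 16,128 tokens; the
phantom default is 8x8x8 = 512). The sentence is serialized in a recorded
raster order and modeled by a causal transformer trained with next-token
cross-entropy on typical subjects (the lower quartile of the total
symptom score). At test time the transformer emits, per position `t`,

    P(token_t | tokens_<t)   — the likelihood of typicality

of the brain segment that token encodes. Likelihoods are upscaled back to
voxel space (nearest-neighbor block replication), averaged within the
regions of an atlas parcellation and over the whole brain, and screened
for associations: Pearson `r` against dimensional symptom scales and age,
AUC with a 1,000-permutation p-value against binary diagnoses, all
Bonferroni-corrected within the evaluation family (alpha = 0.05).

Models are implemented in NumPy with hand-written gradients (Adam,
layernorm, causal attention) and are deliberately small; a full phantom
study trains in about a minute on one CPU. See `docs/methods.md` for
assumptions, parameter defaults, and known limitations.

## Worked example

Parameter recovery on a phantom cohort: 240 subjects on a 32^3 grid with
10 regions, a gray-matter density reduction of 0.012 units per point of
the total symptom score injected into the two highest-baseline regions,
models trained on the typical lower-quartile subset, associations
evaluated on the held-out test split (n = 72):

```python
from vqnorm.experiments import parameter_recovery_spec, run_recovery

spec = parameter_recovery_spec(seed=1)
print("affected regions:", spec.effects[0].rois, "gamma:", spec.effects[0].gamma)
run = run_recovery(spec, seed=1)
for r in run.results:
    if r.significant:
        print(f"{r.roi_name:12s} x {r.target_name:6s}  r={r.effect:+.3f}  "
              f"p_corrected={r.p_corrected:.2e}")
```

prints

```
affected regions: (6, 9) gamma: -0.012
ROI_006      x total   r=-0.683  p_corrected=2.12e-09
ROI_009      x total   r=-0.682  p_corrected=2.43e-09
whole_brain  x total   r=-0.649  p_corrected=3.81e-08
```

Exactly the two injected regions (and the whole brain, which contains
them) correlate with the coupled scale — negatively, because lower
typicality accompanies higher symptom load — while all 41 uncoupled
(region, scale) pairs stay non-significant after Bonferroni correction.

The same pipeline is available stage-by-stage from the shell:

```bash
vqnorm run-all --seed 1 --outdir runs/demo          # or: vqnorm simulate /
vqnorm associate --seed 1 --outdir runs/demo        # train-tokenizer / train-ar / score
```

Each stage writes its artifacts (NIfTI volumes, model checkpoints, CSV
score and association tables) plus a JSON manifest with the config echo
and seed under the run directory.

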