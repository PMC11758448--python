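# sect2mdi

Synthetic dual-energy material decomposition from single-energy CT, at desk
scale: phantom simulation, a windowed-transformer GAN with two task-specific
decoders, image-quality metrics, and the diagnostic-accuracy statistics of a
binary reader study.

## The problem

After endovascular thrombectomy for ischemic stroke, a bright region on
follow-up non-contrast CT can be either extravasated blood (intracranial
hemorrhage, ICH) or harmless retained contrast (contrast staining, CS). The
two are indistinguishable at a single tube voltage; dual-energy CT separates
them into a virtual non-contrast image (VNC — blood persists) and an iodine
overlay map (IOM — iodine only), but dual-energy hardware is scarce. The
approach implemented here trains an image-to-image network to synthesize the
two material maps (sVNC, sIOM) from the single-energy image alone, so the
standard dual-energy reading rule — *hyperdensity persisting on VNC is
blood* — can be applied without a dual-energy scanner.

The package provides every stage needed to exercise and verify the method
without clinical data:

* `sect2mdi.phantom` — paired-case simulator built on the linearized
  three-material forward model `SECT = blur(VNC + k·IOM) + noise`, with
  blood and iodine lesions that are intensity-matched on SECT (so only
  morphology separates them), plus stratified train/validation splitting;
* `sect2mdi.model` / `sect2mdi.nn` — the generator (pyramidal windowed-
  transformer encoder, bottleneck, two independent decoders) and the two
  convolutional discriminators, on a small numpy autodiff engine;
* `sect2mdi.training` — L1 + non-saturating adversarial losses, GradNorm
  task balancing, Adam with a reduce-on-plateau schedule;
* `sect2mdi.quality` — PSNR / SSIM with fixed data range;
* `sect2mdi.readereval` — Clopper–Pearson intervals, single-operating-point
  ROC AUC, the paired DeLong test, Cohen's kappa, and exhaustive
  reconstruction of 2×2 tables from rounded published metrics;
* `sect2mdi.cli` — a `sect2mdi` command wrapping simulate / train / infer /
  quality / evaluate into reproducible runs.

## Worked example

```python
import numpy as np
from sect2mdi import (PhantomConfig, ModelConfig, TrainConfig,
                      MaterialDecompositionGAN, simulate_cohort, psnr)

cases = simulate_cohort(PhantomConfig(), n=40, seed=1)
model = MaterialDecompositionGAN(
    cases, ModelConfig(), TrainConfig(iterations=200, seed=7))
res = model.fit()
print(res.summary())

val = simulate_cohort(PhantomConfig(), n=8, seed=2)
report = res.evaluate(val)
print(report.to_text())
```

prints (numbers from this exact run; your hardware timing will differ, the
values will not):

```
Material-decomposition GAN fit
==============================================
generator parameters:          914706
discriminator parameters:      174577  (x2)
iterations:                       200
final L1 (VNC):                 5.938
final L1 (IOM):                 3.029
final task weights:        (1.000, 1.000)
final learning rate:       1.00e-03
          sVNC                    sIOM
          PSNR (dB)   SSIM (%)    PSNR (dB)   SSIM (%)
this run  28.54 ± 0.61  68.05 ± 1.31  27.43 ± 2.60  83.19 ± 6.17
```

The `final task weights` are the GradNorm-balanced loss weights (still at
their (1, 1) warmup values after this short run; longer fits upweight the
iodine task, whose raw L1 is smaller). The evaluation table reports
per-cohort mean ± sd image fidelity of the generated maps against the
known ground truth. A longer fit — the acceptance study uses 200 training
cases and 800 iterations — pushes sVNC fidelity roughly 6 dB above the
copy-input baseline PSNR(SECT, VNC); docs/methods.md discusses which parts
of the dual-energy reading the desk-scale model does and does not achieve.

The automated dual-energy reading of generated maps is one call:

```python
readings = res.read_cases(val)        # case_id, call, score, gold
```

## Command line

```
sect2mdi simulate --config config.yaml --n 50 --out runs/a --seed 1
sect2mdi run --config config.yaml --stages simulate,train,infer,quality,evaluate
sect2mdi verify-reader-metrics
```

Each run directory receives the exact config used, a manifest, NIfTI
volumes, the per-iteration training log (losses, GradNorm weights, learning
rate), checkpoints, generated maps, and the quality / reading reports.
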