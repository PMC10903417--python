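# virtustain

Virtual fluorescence staining of bright-field microscopy, with downstream
quantification.

Chemical fluorescence staining of cell structures is invasive, phototoxic,
expensive and hard to reproduce. For cells whose structures leave a trace
in transmitted light — such as stem-cell-derived adipocytes, whose
high-refractive-index lipid droplets are clearly visible in bright-field —
a conditional generative adversarial network (cGAN) can replace the dyes:
it translates a multi-slice bright-field z-stack into virtually stained
fluorescence channels for lipid droplets, cytoplasm and nuclei, and those
images feed the same segmentation and feature-extraction pipeline a
chemically stained image would.

`virtustain` implements that workflow end to end for researchers in
quantitative cell biology and image-based profiling:

* **phantom** — a synthetic adipocyte generator producing paired
  bright-field stacks and fluorescence targets with exact ground truth,
  reproducing the contrast hierarchy the method exploits (droplets
  clearly visible, cytoplasm faint, nuclei invisible in bright-field);
* **models / training** — the U-Net-shaped generator G, the conditional
  patch discriminator D, and a per-channel MSE U-Net baseline, trained with
  ℓ_gen = BCE(D(x, G(x)), real) + λ·‖G(x) − y‖₁ and
  ℓ_disc = BCE(D(x, y), real) + BCE(D(x, G(x)), fake),
  plus tiled prediction for fields larger than one forward pass;
* **metrics** — nMAE_px = mean|pred − target| / mean(target), SSIM and
  PSNR per channel over a validation set;
* **profiling** — nuclei-first adaptive-threshold segmentation with shape
  declumping, cytoplasm as secondary objects propagated from the nuclei,
  two-pass global-threshold droplet segmentation with intensity
  declumping, and five features per structure class (count, mean area,
  integrated intensity, mean intensity, std of per-object mean
  intensities);
* **stats** — per-image nMAE_cp, Pearson ρ with Fisher-z 95% CI, and
  two-tailed unpaired Student t tests with significance stars.

The networks run on a compact numpy CNN stack (im2col + GEMM convolutions
with hand-written, numerically verified backward passes) sized for
single-CPU desk-scale experiments.

## Worked example

Train the cGAN on the built-in 64-px phantom and quantify the result:

```python
import numpy as np
from virtustain.io import desk_phantom_params
from virtustain.phantom import sample_scene, render_fluorescence, render_brightfield
from virtustain.models import (GeneratorConfig, DiscriminatorConfig,
                               build_generator, build_discriminator)
from virtustain.training import TrainConfig, train_cgan
from virtustain.metrics import ssim

def pairs(n, seed0):
    out = []
    for i in range(n):
        p = desk_phantom_params(seed=seed0 + i)
        s = sample_scene(p)
        fl, _ = render_fluorescence(s, p)
        bf = render_brightfield(s, p)
        out.append((bf.astype(np.float32) / 65535, fl.astype(np.float32) / 65535))
    return out

train, val = pairs(200, 1000), pairs(15, 9000)
gen = build_generator(GeneratorConfig(depth=3, base_width=12), seed=0)
disc = build_discriminator(DiscriminatorConfig(in_channels=10, depth=3,
                                               base_width=12), seed=1)
cfg = TrainConfig(epochs=200, batch_size=8, crop_size=32, val_freq=10, seed=0)
gen, hist = train_cgan(train, val, gen, disc, cfg)
print("val nMAE_px first:", np.round(hist.val_nmae[0], 2))
print("val nMAE_px last: ", np.round(hist.val_nmae[-1], 3))
print("droplet SSIM:", round(float(np.mean(
    [ssim(gen.forward(x[None])[0][0], y[0]) for x, y in val])), 3))
```

On one CPU this takes a few minutes and prints

```
val nMAE_px first: [ 7.9   6.69 23.49]
val nMAE_px last:  [0.284 0.364 0.748]
droplet SSIM: 0.803
```

i.e. the validation pixel error collapses for all three channels —
including the nuclei, which have *zero* contrast in the bright-field
input and are inferred entirely from surrounding context — and the
droplet channel reaches a structural similarity of 0.80 against the
target stain.

The same pipeline is available from the shell:

```sh
virtustain simulate --n-fields 20 --seed 0 --out data/
virtustain run --seed 0 --out results/      # simulate→train→predict→evaluate→profile→report
virtustain profile --image data/sample_0000_fl.tif --out-prefix prof
```

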