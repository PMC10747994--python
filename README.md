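# abfp — attention-balanced feature pyramid for low-contrast lesion detection

Detecting small intestinal stromal tumours (and low-contrast lesions in
general) in CT slices is hard for anchor-based detectors: lesions vary in
shape and size, their edges are blurred, and their grey values sit close to
the surrounding tissue. Standard feature-fusion necks (FPN and relatives)
propagate information mainly between *adjacent* pyramid levels, so deep
semantic and shallow detail features end up unevenly mixed. This package
implements the **attention-balanced feature pyramid (ABFP)** neck, which
fuses *all* levels symmetrically and re-distributes the result, for people
building or studying multi-scale detection pipelines on medical images.

## The method

Given pyramid levels {C₂…C₅} (or any uniform-channel pyramid), the balanced
feature pyramid first rescales every level to the intermediate resolution
(max pooling downwards, nearest-neighbour interpolation upwards) and
averages them into a single *balanced semantic map*:

    C̄ = (1/N) Σᵣ Cᵣ                    (no learned parameters)

The balanced map F_b = C̄ is then refined by two attention gates acting **in
parallel**, and the gated copies are summed:

    M_c(F) = σ( W₁·relu(W₀·avgpool(F)) + W₁·relu(W₀·maxpool(F)) )   ∈ (0,1)^C
    M_s(F) = σ( f⁷ˣ⁷([avgpool_c(F); maxpool_c(F)]) )                 ∈ (0,1)^{H×W}
    F_ab   = (M_c(F_b) ⊗ F_b) ⊕ (M_s(F_b) ⊗ F_b)

(σ sigmoid, ⊗ elementwise product, ⊕ elementwise sum; the shared MLP uses a
reduction ratio r, the spatial gate a 7×7 convolution over the channel-wise
average and max planes). Finally the refined map is rescaled back to every
level's resolution and **added to the original level** — each level receives
the same cross-scale information, and all shapes are preserved, so the block
stacks on any neck (FPN, PAFPN, BiFPN) that emits a uniform-channel pyramid.

The package ships, around that core:

- `abfp.pyramid` — the pyramid data model and rescale / integrate / strengthen;
- `abfp.attention` — channel and spatial gates and the parallel refinement;
- `abfp.neck` — a baseline top-down FPN and the composed FPN + ABFP neck
  (with a 3×3-convolution refinement as the attention-off ablation arm);
- `abfp.evaluation` — single-class COCO-style AP/AP50/AP75/AR;
- `abfp.synthetic` — deterministic generators for feature pyramids and
  low-contrast elliptical-lesion scenes with ground-truth boxes;
- `abfp.detector` — a micro anchor-based single-stage detector (tiny conv
  backbone, focal loss, smooth-L1, SGD with warmup) that proves the neck
  end-to-end on CPU;
- `abfp.autodiff` — the small reverse-mode autodiff engine the detector
  trains with.

All training-facing math runs on a numpy-based tape; no GPU framework is
required.

## Worked example

`examples/` contains one narrative script per capability. Training the
micro detector on synthetic lesion scenes (`examples/train_micro_detector.py`):

```
32 training / 8 validation images, 80 lesions
detector parameters: 156,884
epoch 1/4  loss 1.5975  lr 0.00567
epoch 2/4  loss 0.8839  lr 0.00833
epoch 3/4  loss 0.6955  lr 0.01000
epoch 4/4  loss 0.6816  lr 0.00100

held-out AP 0.006  AP50 0.027  AP75 0.000  AR 0.200
```

The loss falls as the detector starts to localise lesions; this short demo
(40 images, 4 epochs) only begins to learn, while the desk-scale study run
by the acceptance script (200 images, 12 epochs) reaches AP50 ≈ 0.5 on its
held-out split against 0.0 for the untrained detector. The evaluator
example (`examples/evaluate_detections.py`) shows how AP decays as the IoU
threshold tightens (AP50 0.752 vs AP75 0.257 on its hand-built scenario):
loose localisations stop counting as matches.

A thin CLI wraps the same functions for shell use:

```sh
abfp gen-data --out data/ --seed 1 --n-images 200
abfp train --data data/ --attention on --out det.npz
abfp eval --checkpoint det.npz --data data/ --out results.json
abfp selftest
```

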