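# m3bnet

Multi-modal, multi-branch retinal vessel segmentation for ultra-widefield
(UWF) fundus photographs.

UWF photography images ~200° of the retina non-invasively, but its vessels
sit at low contrast on a large, unevenly illuminated field — the regime
where segmentation networks fragment thin vessels.  Fluorescein angiography
(FFA) shows the same vasculature at high contrast but is invasive.  This
package implements a framework that gets the best of both: a CycleGAN-style
branch learns UWF→FFA style transfer, and its latent features **Z2** are
selectively fused into the segmentation branch's latent **Z1** wherever the
two agree in feature space.

The segmentation branch encodes each training patch together with co-centred
2× and 3× context windows (side ratio 1:2:3, all resized to one input size)
through three stride-8 extractors, merges the scales by cross-attention

&nbsp;&nbsp;&nbsp;&nbsp;Z1 = Fs + αm·IN(Att(Fm→Fs)) + αl·IN(Att(Fl→Fs)),

gates the transfer features blockwise with the Euclidean distance
d = √Σ(xᵢ−yᵢ)² at similarity threshold 0.5 (SFM), decodes with
attention-guided ×2 upsampling blocks (AUM, two attention stages per level),
and refines with a compact U-shaped head.  Metrics are the field's usual
Dice = 2TP/(2TP+FP+FN), Sen = TP/(TP+FN) and BACC = (TPR+TNR)/2.

Because the clinical UWF/FFA datasets are private, the package ships a
**phantom generator**: branching vascular trees rendered as aligned
low-contrast UWF-like and high-contrast FFA-like image pairs with exact
binary masks, so the entire four-stage pipeline — transfer pre-training,
context-encoder pre-training, frozen-backbone end-to-end training,
stitched-image evaluation — runs on one CPU core in minutes.  The networks
run on a small numpy autodiff engine included in the package (`m3bnet.nn`);
no GPU framework is required.

## Worked example

```bash
python examples/04_train_tiny.py
```

trains all four stages on 70 phantom pairs (tiny preset) and evaluates 10
held-out images:

```
stage-4 loss: first epoch 1.552 -> last epoch 1.070
dice   52.16 ±  3.76 %
sen    95.69 ±  1.38 %
tpr    95.69 ±  1.38 %
tnr    74.52 ±  3.35 %
bacc   85.11 ±  2.15 %
```

Dice is the overlap between the thresholded stitched probability map and
the exact phantom mask inside the circular field of view; sensitivity near
0.96 with ~0.75 specificity means the tiny model finds essentially every
vessel pixel at the cost of some background over-call — the expected profile
after a short desk-scale run on 70 images (the 200-pair end-to-end runs
reach 0.72–0.82 mean Dice depending on the seed).  `examples/01–03` demonstrate the phantom
statistics, CLAHE preprocessing and patch geometry, and the selective fusion
gate; `05` produces a Grad-CAM of the final decoder level.

A thin CLI wraps the same functions:

```bash
m3bnet generate-data --out-dir data --n-pairs 120 --seed 0
m3bnet train --manifest data/manifest.csv --work-dir runs/tiny --tag tiny
m3bnet predict --checkpoint runs/tiny/stage4.npz --image data/0000_uwf.png --out pred.png
```

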