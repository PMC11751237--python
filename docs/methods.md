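# Methods

## The problem

Ultra-widefield (UWF) fundus photographs cover ~200° of the retina in one
shot, but vessels appear at low contrast on an unevenly illuminated
background, and the frames are large (thousands of pixels per side), so
segmentation networks work on patches and lose context.  Fluorescein
angiography (FFA) shows the same vasculature at much higher contrast but is
invasive.  The framework implemented here improves UWF vessel segmentation
by (i) learning a UWF→FFA style transfer and injecting its latent features
into the segmentation encoder where they agree with the segmentation
features, (ii) encoding each patch together with co-centred 2× and 3×
context windows, and (iii) decoding with attention-guided upsampling.

## Model

**Style-transfer branch.**  Two resnet-style generators (UWF→FFA, FFA→UWF)
and two patch discriminators in the CycleGAN lineage, trained with a
least-squares adversarial loss and cycle-consistency L1.  Because the
training pairs here are pixel-aligned, a paired L1 between the generated and
true angiogram is added (weight λ_pair = 10, alongside λ_cyc = 10 and an
optional identity term λ_id = 5; the desk-scale preset sets λ_id = 0 to drop
two generator passes per step).  The UWF→FFA encoder output after the
residual blocks — stride 4 relative to the patch — is the latent Z2.

**Multi-scale segmentation encoder.**  Three convolutional extractors
(stem + three stages, output stride 8, shared channel count), one per patch
scale.  Windows of side s, 2s, 3s share one centre, are reflect-padded where
they overrun the image, and resized to a common input size.  The middle and
large extractors are pre-trained and frozen; the small extractor trains
end to end.

**LPFM.**  Cross-scale scaled-dot-product attention with the context maps as
queries and the small-patch map as keys/values:

    Gm = Att(Fm → Fs),   Gl = Att(Fl → Fs)
    Z1 = Fs + αm · IN(Gm) + αl · IN(Gl)

αm, αl are learnable scalars initialized at 0.5; IN is non-affine instance
normalization ("regularized" read as instance norm; zero-variance channels
normalize to exactly 0).  A flag swaps the query/value role assignment for
the alternative reading of the attention direction.

**SFM.**  Z1 and (projected) Z2 are reduced to channel means, jointly
min-max normalized to [0, 1], and compared per block of a 4×4 grid with the
Euclidean distance d = sqrt(Σ(xᵢ−yᵢ)²).  Similarity is 1 − d/√n (√n being
the largest attainable distance for n pixels in [0, 1]), and blocks with
similarity ≥ 0.5 take the elementwise mean (Z1+Z2)/2; all other blocks pass
Z1 unchanged.  The "partial sampling" comparison is deterministic blockwise
by default; a seeded random-pixel-subset variant and an off switch are
provided.  Z2 (stride 4) is average-pooled to stride 8 and channel-projected
by a 1×1 convolution trained in stage 4.

**AUM decoder.**  Each level upsamples ×2 (bilinear) and evaluates

    A1      = Att(C2C1(M), C2C1(M), C3(M))
    Output* = C2C1(M) + A1
    A2      = Att(C5(Output*), C5(Output*), C4C1(M))
    Output  = C5(Output*) + A2

with C1–C3 7×7 convolutions (stage E1) and C4, C5 3×3 (stage E2; the E2
kernel size is unstated upstream and chosen smaller, matching "the key
difference being the scale of convolution operations").  Att pools
query/key/value maps to at most `max_tokens` spatial tokens (32² default)
before the token-level softmax attention and resizes the attended map back,
bounding the N² cost.  Three levels take the stride-8 latent to patch
resolution.  Between levels (never inside the equations) an instance norm +
ReLU restores activation scale — without it the chained additive attention
levels grow activations ~40× at initialization and optimization stalls.

**Refiner.**  A compact 2-level U-shaped head turns decoder features into
1-channel logits; probabilities are their sigmoid.  The refiner input
concatenates the raw small patch to the decoder features: the stride-8
latent alone cannot localize 1–2 px vessels at desk scale, and the extra
full-resolution intensity channel gives the refinement stage direct evidence
while leaving every upstream module and contract unchanged.

## Training

Four stages: (1) transfer branch on paired small patches; (2)/(3) middle and
large extractors against vessel masks through a disposable 1×1-conv +
upsample head (supervised pretext — masks exist in both datasets, so this is
the least-assumption objective; an autoencoding pretext would also fit);
(4) everything else (small extractor, LPFM scalars, Z2 projection, decoder,
inter-level norms, refiner) with stages 1–3 frozen.  Freezing is verified by
hashing every frozen parameter before and after the stage.

Optimizer: Adam, lr 4e-4, weight decay 5e-4 (applied to every stage; the
published setting names only the segmentation network), batch 5 (or 2 for
the PRIME-FP20-style configuration), 200 epochs at full scale.  One
optimizer per stage, reinitialized at stage boundaries; optimizer state is
checkpointed so a resumed run is step-identical to a straight-through run.
One root seed fans out to per-stage, per-epoch streams
(`SeedSequence([seed, stage, epoch])`), making runs bit-reproducible.

Segmentation loss: class-balanced binary cross-entropy plus (1 − soft Dice),
equally weighted.  The BCE weights normalize foreground and background to
equal total weight (mean weight 1, so a class-balanced mask reduces to plain
BCE); without the balancing, thin vessels (<10% of pixels) drive short
training schedules into the all-background optimum.

Training centres are sampled foreground-biased (a centre lands on a vessel
pixel with probability 0.5 by default) against the same imbalance; a flag
disables the bias.

## Phantom data

The generator emulates only the statistics that matter to the pipeline:
recursive binary branching trees (angular jitter ±30°, per-generation width
decay 0.8 and length decay 0.75, terminal vessels 1–2 px) rooted on the rim
of a circular field of view; butt-capped anti-aliasing-free rasterization
gives the exact shared mask; UWF-like rendering is bright background (0.55)
plus a 2–4-mode low-frequency cosine illumination field (amplitude 0.15)
minus a small vessel offset (0.15) plus Gaussian noise (σ 0.03); FFA-like
rendering is a dark background (0.12) plus a large vessel offset (0.55).
Defaults give ~9% vessel coverage.  The phantom does not model lesions,
eyelash artifacts, registration error between modalities, or realistic
texture — passing tests show the pipeline's mechanics and learning dynamics,
not clinical performance.

## Presets and desk scale

The `full` preset mirrors the published geometry (1024² training frames,
256/512/768 windows resized to 256², 128-channel stride-8 features,
200 epochs).  The `tiny` preset keeps every mechanism but shrinks shapes so
the entire four-stage pipeline trains on one CPU core in minutes: 128²
phantoms, 64² patches, 16-channel encoders, 8-channel transfer base,
attention pooled to ≤16² tokens, stage epochs (3, 2, 2, 10), identity loss
off.  Channel counts below the published ratio are a CPU-throughput choice;
all tests and the acceptance run use this preset.

## Numerical choices

- Probabilities are clipped to [1e-6, 1−1e-6] inside the BCE.
- Soft Dice uses +1 smoothing in numerator and denominator, so an empty
  mask with an empty prediction scores a loss of 0.
- Metric conventions at degenerate counts: Sen = 1 when TP+FN = 0, Dice = 1
  when 2TP+FP+FN = 0, TNR = 1 when FP+TN = 0; such images are flagged.
- Inference tiles with 50% overlap and uniform overlap averaging; stitching
  crops of any map reproduces the map exactly.
- CLAHE parameters: clip limit 2.0 (OpenCV scale, mapped to skimage's
  normalized limit), 8×8 tile grid; global histogram equalization available
  behind a flag.  Constant images pass through unchanged.
- Masks are resized nearest-neighbour, intensities bilinear; rotations are
  restricted to multiples of 90° so labels stay binary.

## Known limitations

- The numpy engine is single-threaded except for BLAS matmuls; the full
  preset is defined but impractically slow on CPU — it exists as the
  faithful configuration, not a tested path.
- Stride-2 downsampling makes the full network only approximately
  flip-equivariant (the sampling grid is asymmetric); the property is exact
  for the stride-1 decoder stack and is tested there.
- The SFM's benefit on phantoms is small and seed-dependent: the phantom's
  FFA is a deterministic re-rendering of the same mask, so the transfer
  latent carries less complementary information than a real angiogram
  would.  The pipeline asserts the direction (fusion does not hurt on
  average), not a magnitude.
- "Threshold and range of 0.5" upstream is read as a single threshold; no
  second margin hyperparameter is implemented.
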