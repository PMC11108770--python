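# Methods

## Overview

`echovlm` is a desk-scale re-creation of a contrastive vision-language
pipeline for echocardiography. Two encoders — a convolutional image tower
and a causal (decoder-only) transformer text tower — project video frames
and templated report text into a shared unit-norm embedding space. The
symmetric InfoNCE (CLIP) objective aligns matched frame-report pairs against
in-batch negatives. A frozen trained model is then adapted to downstream
tasks purely through prompts: binary detection by similarity to
positive-case prompts, regression by sweeping a candidate-value grid, and
clinical analytics by pairwise cosine similarity between embeddings.

Everything runs on one CPU in minutes; no GPU, pretrained weights or
external data are required. The price of desk scale is that absolute
performance numbers are properties of the synthetic cohort and the small
towers, not clinical results.

## Synthetic paired data

The generator is the package's study system, not a test fixture. Each
patient carries a 12-channel standard-normal latent vector mapped
deterministically and monotonically to clinical attributes:

| attribute | mapping | range / levels |
|---|---|---|
| LVEF | `clip(round(60 + 15 z), 15, 80)` | percent |
| PAP | `clip(round(25 + 12 z), 10, 90)` | mm Hg |
| chamber dilation (LV, LA, RV, RA) | thresholds 0.15 / 0.8 / 1.4 on z | normal, mild, moderate, severe (~56/23/13/8%) |
| LV wall (hypertrophy) | same thresholds | same |
| devices (pacemaker, TAVR, MitraClip, Impella) | z > 1.04 each | ~15% prevalence each |
| pericardial effusion | thresholds 0.9/1.5/2.0/2.5 | none, small, moderate, large, tamponade |

Per study the patient latent is perturbed: `z_study =
((1-d) z_patient + d eps) / sqrt((1-d)^2 + d^2)` with drift `d` (default
0.15), so `d = 0` duplicates the patient state and `d = 1` makes studies
independent while preserving unit marginal variance.

Videos are 224 x 224 8-bit RGB frame stacks. A 90-degree fan with apex at
top-center masks the scan sector (pixels outside are exactly 0). Four
ellipses model the chambers (dark blood pools, bright walls) in an
apical-four-chamber layout; chamber axes scale 1.0/1.15/1.3/1.5 with
dilation grade and LV wall thickness grows 4-12 px with hypertrophy grade.
The LV blood-pool area oscillates sinusoidally over an 8-frame cycle with
relative amplitude LVEF/100 and a random phase per video, so the full
ejection-fraction signal lives in cycle dynamics and a single frame
constrains it only partially — mirroring the intrinsic limitation of
single-frame encoders on real echo. In addition, ejection fraction remodels
the ventricle's shape statically and area-preservingly: the LV axis ratio
interpolates from 1.0 (spherical) at LVEF 15 to 1.5 (elongated) at LVEF 80.
Sphericity is the single-frame correlate of systolic function that real
echocardiograms carry (dilated, spherical ventricles indicate reduced
function), and without such a static correlate no single-frame encoder can
recover LVEF from this generator at all: we measured a linear single-frame
ceiling of corr 0.07 with ground truth, and contrastive training with a
constant report target per video actively learns phase invariance, erasing
instantaneous-size information. Because the remodeling preserves area it is
not confounded with the dilation grades, which scale both axes. Devices render as fixed bright primitives (lead line, ring, clip,
cannula); effusion as a dark pericardial rim. Additive Gaussian noise
(s.d. 5/255) is applied inside the fan.

Reports are generated fill-in-the-blank from the template grammar: one
sentence per attribute (8-12 core sentences), 0-7 boilerplate sentences,
seeded shuffle of sentence order. Every attribute is recoverable from the
text by regular expressions (verified at 100% on 1,000 draws), and numeric
values round-trip exactly.

What the generator does **not** emulate: speckle statistics, probe motion,
view variation, Doppler, report style variation beyond the grammar, label
noise between image and text. Tests passing here show the machinery is
correct and that the training signal is learnable; they say nothing about
clinical accuracy on real echocardiograms.

The standard cohort used throughout is 132 patients x 2 studies (1-2 videos
of 8-12 frames each), split by patient 100/32 into exactly 200 training and
64 validation studies. The event (trajectory) cohort is 50 patients with 3-4
studies inside one year and a procedure date planted between two studies;
with `event_redraw` the post-procedure latent state is re-drawn (a planted
change-point), without it the event is a pure null.

## Template tokenizer

Templated reports are tokenized by matching whole sentences against slotted
regular expressions, longest template first, case-insensitively. A matched
sentence emits one template token plus one token per slot: a severity token
(mild/moderate/severe/small/large) or the NUMBER token. Numeric values are
carried out-of-band in the token sequence rather than spelled in digits;
unmatched sentences emit a single UNK token. The vocabulary is grammar
driven (template count + 3 specials + severities); no fixed size is imposed.
Tokenize-detokenize is an exact round trip for UNK-free sequences.

Numeric magnitudes enter the text tower as multi-frequency Fourier features
(sin/cos at 5 frequencies spanning the 0-200 range) through a learned
projection added at NUMBER-token positions. An earlier design (value/100
times a single learned direction) was numerically invisible after layer
normalization — prompt embeddings for LVEF 0 and 100 differed by under 1% —
so it could never carry value information into the contrastive objective;
the Fourier features separate values at initialization.

## Encoders

Desk-scale defaults: `small_convnet` image tower (4x4 average-pool stem
224 -> 56, then four conv blocks 3x3 with stride 2/2/2/1 to 32/64/96/96
channels, global average pool, layer norm, linear projection) and a 4-layer,
128-wide, 4-head causal transformer text tower with learned positions,
pooled at the final real token; joint dimension D = 128, base context
length 77 tokens. A heavier `convnext_like` tower (patchify stem + residual
stages) is available behind the same contract. Embeddings are always divided
by their Euclidean norm.

Initialization detail that matters: visually similar frames produce pooled
features with cosine ~0.995 at initialization, which stalls the contrastive
loss at ln N for its whole (short) schedule. The final projections are
therefore initialized with 4x the usual He/Glorot scale, which spreads the
unit-norm embeddings enough for the loss to engage immediately.

The checkpoint is a single npz archive with config, weights, the full
vocabulary JSON and its SHA-256 hash; loading against a mismatched
vocabulary is refused.

## Training

Symmetric InfoNCE with a learnable log-scale temperature initialized at
ln(1/0.07) and capped at scale 100. AdamW (betas 0.9/0.98, decoupled decay
0.2 on matrix parameters). Learning rate ramps linearly over 20 steps to
1e-3 and cosine-decays to zero. One uniformly random frame per video per
epoch (reproducible from seed, epoch and video id) pairs with the study's
tokenized report; with probability 0.3 the text side uses a random
contiguous snippet of 1-4 whole sentences instead of the full report,
mirroring how short-context report encoders are trained.

Every optimizer step additionally carries a second, value-aligned InfoNCE
term: the same image batch is contrasted against each study's single
number-bearing sentence (by default the ejection-fraction sentence), and
this loss is added to the whole-report loss with weight 8. The term exists
because of feature suppression: the other attributes already identify the
matching report, so the plain report loss actively suppresses the weak
static ejection-fraction correlate (a linear probe on embeddings from plain
training reaches corr 0.02-0.22 with truth, against 0.87 when training on
ejection-fraction sentences alone). Scheduling variants fail in instructive
ways — value-dominant batches starve retrieval; report-dominant phases erase
previously learned value features; value-dominant late phases cannot imprint
them at cosine-decayed learning rates. Summing both losses on every step is
the only variant we found that holds both signals simultaneously, and it is
the desk-scale surrogate for the production-scale regime where huge batches
contain near-duplicate attribute profiles that force numeric tie-breaking.
The high weight reflects that the numeric correlate is the weakest visual
signal in the generator. The value term is restricted to number templates
with a pixel correlate (configurable); including a visually silent quantity
(pulmonary pressure here) turns the term into label noise and measurably
degrades retrieval.

Desk defaults are batch 32 for 30 epochs (~270 steps on the standard
cohort, ~3 minutes on one CPU including per-epoch validation). Batch 1,024 and multi-thousand-step warmups
of production-scale training remain expressible in the config. Patient
overlap between train and validation splits aborts training. After each
epoch, validation MCMRR (mean cross-modal retrieval rank; chance (N+1)/2) is
computed over one random video per validation study, one fixed random frame
per video; the checkpoint with the lowest validation MCMRR is returned.
Validation retrieval uses study representatives rather than all videos so
the pairing stays bijective.

## Zero-shot adapters

Binary: mean over the first 20 frames (stride 2) of the mean cosine
similarity to the positive-case prompts. Regression: candidates (for LVEF,
integers 0..100) are substituted into a base prompt; per frame the top
floor(0.2 K) candidates by similarity survive (ties to the lower value),
each survivor's similarity is averaged over the frames where it survived
(a zero-filled variant is available behind a flag), the top floor(0.2 K) by
that average are kept, and the prediction is the median of their values —
for an even count the upper-middle element, which both returns a real
candidate and makes a symmetric similarity peak at 60 yield exactly 60.
For K = 101 the retained set has exactly 20 members. Study-level predictions
average the per-video outputs.

The sampled-prompts strategy replaces synthetic short prompts with full
validation reports (up to 10 per observed LVEF value; up to 200 positive
reports for binary tasks), keeping the text encoder in-distribution for
long-context models trained on whole reports.

## Retrieval, analytics, saliency

Retrieval ranks are 1-based with midrank ties; MCMRR is the average of the
two directional mean ranks; top-k hit rates pool both directions. Patient
re-identification treats pair cosine similarity as a continuous score for
"same patient" and computes the Mann-Whitney AUC with midranks (cross-checked
against an exhaustive concordance count and scikit-learn in tests). Pair
sampling is stratified (default 5,000 per class, with replacement never
used; scarcer classes contribute every distinct pair). Study-level
similarity is the mean over all cross pairs of video embeddings.
Trajectories use a closed +/-200-day window around the procedure date,
baseline at the earliest in-window study; the pre/post AUC pools points
across patients and scores by negated similarity so that values above 0.5
mean detectable change.

Saliency is integrated gradients with the image-prompt cosine similarity as
the objective, midpoint Riemann path from a black baseline (matching the
dark out-of-sector background; a blurred baseline is available), channels
summed. The completeness gap |sum(attr) - (f(x) - f(baseline))| is stored on
every map. A CAM-style feature-weighting variant is an explicit extension
point but not implemented.

## Numerical choices and degenerate inputs

- All similarity math in float64; towers in float32.
- Ties: retrieval midrank; regression candidate ties to the lower value.
- Empty token sequences are rejected by the text encoder (no padding-only
  inputs); empty videos are rejected by frame sampling.
- The contrastive loss of a single pair is 0; batches of fewer than 2 items
  are skipped.
- Random-frame sampling hashes the video id with CRC-32 so that frame
  choices are stable across processes.
- Problem sizes throughout (cohort of 264 studies, 30 epochs, D = 128) were
  chosen so a full train-evaluate cycle takes about three minutes on one CPU,
  which is what makes multi-seed controls practical.

## Known limitations

- The image tower is single-frame; the cycle-dynamics component of ejection
  fraction is invisible to it, and the static sphericity correlate is the
  weakest visual signal in the generator. Zero-shot LVEF recovery is the
  hardest property in the package and depends on the value-aligned loss
  term; without it the contrastive objective suppresses the correlate
  entirely.
- PAP has no pixel correlate by design; it bounds achievable retrieval
  sharpness between studies identical in every visual attribute.
- The tokenizer's sentence splitter assumes period-terminated sentences, as
  produced by the grammar.
- No calibration: zero-shot binary scores are similarities, not
  probabilities.
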