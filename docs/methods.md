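# Methods

`cnvconfirm` performs *in silico* confirmation of candidate rare copy-number
variants (CNVs) called from exome read-depth data.  Candidate calls from
exome CNV callers are notoriously noisy; the package re-creates, in a
trainable form, the manual-inspection step analysts perform on read-depth
plots: it renders each candidate as an image of the carrier's normalized
depth against a panel of reference samples and classifies the image into
{rare deletion, rare duplication, artifact} with a convolutional network.

## Depth normalization

The unit of measurement is the capture target.  Targets ≥ 1000 bp are first
split into n = ceil(L/1000) near-equal windows (remainder base pairs go to
the leftmost windows), which keeps windows in the 500–1000 bp range and lets
a CNV covering part of a long probe move a whole window.  For each sample,
raw mean depth RD_t is normalized as

    O_t = (RD_t · M / M_x) / M̄

with M_x the median depth of all targets in the same GC bin as target t
(bin width 0.01 by default), M the overall median and M̄ the overall mean.
This removes the two sample-global biases — GC content and total sequencing
depth — and leaves local, panel-shared biases in place deliberately: they
cancel visually against the reference panel.  Two numerical choices are not
pinned down by the formula itself and are made here explicitly: the GC bin
width (0.01, configurable), and GC bins whose median depth is zero, where
the ratio is undefined; such bins fall back to the global median (ratio 1)
with a warning.  A sample with all-zero depth is rejected rather than
normalized.

## Reference panels

For each case sample the k = 100 samples with the highest Pearson
correlation of normalized depth (over autosomal, nonzero-variance targets)
form its reference panel; ties break by sample id for determinism.
Spearman correlation is available as an option.  Family members are
excluded from a case's panel via the pedigree: a rare inherited CNV present
in a parent chosen as reference would erase exactly the contrast the image
is meant to show.

## Image encoding

Target midpoints x_t are compressed with x'_t = x_0 + Σ ln(1 + (x_t −
x_{t−1})) so exon-sized gaps and intron-sized gaps both stay on canvas, and
depth is drawn as y' = ln(1 + y), mapping the diploid baseline to ln 2 with
symmetric offsets for losses and gains.  Each target is a dot, adjacent
dots are connected by straight lines; references are drawn first in gray
(#808080), the case last in blue (#0000FF).  The y-range is fixed at
[0, ln 6] for every image so a given copy-number contrast always has the
same pixel extent; larger values are clipped.  The window spans the CNV's
targets plus a flank of max(num_targets, 10) targets per side (clipped at
chromosome bounds) — enough context for the panel contrast without drowning
small CNVs.

Rendering uses a small deterministic rasterizer at the final 224×224
resolution instead of a plotting library: no anti-aliasing, fonts, axes or
randomized raster features, so identical inputs give byte-identical pixels
and the two colors appear exactly.  Line width (2 px) and dot size (3 px)
are fixed in the style configuration and recorded in each image's metadata.

## Training labels from trios

Large-scale experimental validation of training CNVs is impractical, so
labels come from Mendelian inheritance in offspring–parents trios.
Candidate calls are first filtered to the regime the classifier targets:
cohort frequency ≤ 1%, ≥ 2 capture targets, autosomal, and ≤ 75% of the
call length inside segmental duplications.  Overlapping same-sample,
same-type calls from different callers are merged: candidate breakpoints
are the union of the members' breakpoints and the chosen interval maximizes
the depth-contrast score |mean(O inside) − 1| − |mean(O flank) − 1| on the
carrier's normalized depth, with a flank of up to 5 targets per side.  This
contrast rule is a deliberate, documented simplification of external
breakpoint-resolution tooling and is isolated in one operation so it can be
swapped.

A filtered, merged child call is then labeled:

* **rare deletion / rare duplication** when a same-type parental call covers
  ≥ 50% of the child call (the same overlap fraction used for WGS support,
  one consistent semantic);
* **artifact** when it has *zero* parental overlap, the Phred-scaled
  no-CNV score NQ is ≥ 60 in *both* parents over the region (ruling out
  parental false negatives), and exactly one caller reported it —
  multi-caller Mendelian errors are likely real (often de novo) and are
  excluded;
* everything else (ambiguous partial overlap, low parental NQ, multi-caller
  child-only calls) is left unlabeled and excluded from training.

The NQ threshold of 60 matches the conventional stringency used for exome
CNV genotype-quality filtering and is configurable.  True de novo CNVs are
rare, and single-caller de novo events are the one contamination path into
the artifact class; the labeling purity measured on synthetic cohorts
(≥ 95%) quantifies that residual.

Labeled CNVs are split 60/20/20 into train/validation/test.  The split is
keyed on stable CNV identifiers and a seeded permutation, so membership is
reproducible and independent of input order; all images of one CNV land in
one split.

## Classifier

The classifier maps a 224×224×3 image to three softmax probabilities in the
fixed order (RARE_DEL, RARE_DUP, ARTIFACT); prediction takes the maximum
probability, with ties resolved by class order.  Two backbones are
implemented on a bundled NumPy backend (standard/depthwise convolutions,
ReLU, global average pooling, dense head, Adam):

* `generic_cnn`: six 3×3 convolutions (16, 32, 64, 64, 128, 128 channels,
  stride 2 except the last), global average pooling, 3-unit head;
* `mobilenet_v1`: the MobileNet-v1 stem + 13 depthwise-separable blocks,
  with a width multiplier α (default 0.25) so it trains in reasonable time
  on a CPU.

A ResNet-50 backbone is not provided on this backend.  No pretrained
weights are bundled and none are downloaded, so `pretrained=True` is
rejected; networks initialize from a seeded He scheme, which keeps the full
suite network-free and bit-reproducible.

Training follows the transfer protocol: phase 1 trains the head only with
every base weight frozen (Adam, 1e-3 — the phase-1 rate is a free choice);
phase 2 fine-tunes the whole network at 1e-5 with a fresh optimizer.  Both
phases run batches of 32 for up to 20 epochs with early stopping after 3
epochs without loss improvement (validation loss when a validation set is
given).  The final model is the epoch checkpoint with the highest selection
accuracy.  Selection uses the validation split by default; selecting on the
test split — the literal protocol of choosing the model with the highest
test accuracy — is available via `select_on="test"` but leaks information
and is not the default.  Since a randomly initialized base has nothing
worth freezing, `train_from_scratch` offers the matching single-phase
end-to-end protocol at the phase-1 rate; this is the route used for
`generic_cnn`.  Class imbalance is left as-is by default; balanced
downsampling can be reproduced by subsetting before training.

## Evaluation

WGS covers the genome evenly, so high-confidence WGS CNVs of the same
individuals (the union of two complementary WGS callers, deduplicated by
merging same-type overlaps per sample) serve as proxy ground truth.  An
exome call is *supported* when ≥ 50% of its length (inclusive) is covered
by same-type standard intervals of its sample.  Coverage accumulates over
the merged union of standard intervals by default so fragmented WGS calls
are not penalized; a strict single-interval reading is available.
Precision per caller is supported/all.  The recall denominator is the
deduplicated union across *all* callers of supported exome calls — the
method confirms calls and cannot create new ones, so recall is measured
against what exome calling recovered at all.  Three-class metrics
(per-class and macro precision/recall/F1, one-vs-rest AUC from the stored
probabilities, 3×3 confusion matrix) use scikit-learn; AUC for a class
absent from the truth is reported as undefined.

## Synthetic cohorts

The simulator generates what the method assumes of real exome data, with
defaults chosen as a realistic mid-size exome regime:

* targets of 120–300 bp with 0.5–30 kb gaps across 22 autosomes, GC drawn
  from a Beta(2.5, 2.5) rescaled to [0.2, 0.8];
* per-target depth ~ negative binomial with mean 100 × gc_bias(GC) ×
  target efficiency × sample scale and dispersion giving CV ≈ 0.2 at mean
  100; the GC bias is a smooth unimodal bump (0.8 + 0.4·exp(−(GC −
  0.45)²/2·0.15²)), target efficiency and sample scale are lognormal
  (σ = 0.15 and 0.10);
* trio families; each child draws Poisson(2) rare CNVs of 2–40 targets,
  heterozygous by default (0.5×/1.5×), inherited from exactly one parent
  with probability 0.95 (true de novo CNVs are rare), the parent's call
  missed with probability 0.05 (parental false negatives exercise the NQ
  refinement);
* artifacts: Poisson(1) per sample, depth wobble of 0.7–0.8× or 1.2–1.3×
  over 2–5 targets, emitted as a single-caller call with no truth entry;
* decoy calls that each violate one candidate filter (common, single-
  target, chrX, segdup-embedded) exercise the filtering rules;
* cohort frequencies are drawn (rare calls « 1%) rather than counted in the
  small cohort: the simulated families stand in for the rare-variant regime
  of a much larger population;
* a WGS-style standard set contains exactly the simulated truth, and the
  caller emulator reports each truth CNV through 1–3 callers with ±1-target
  breakpoint jitter.

What the simulator does **not** model: batch effects and capture-kit
structure (so depth correlations between simulated samples are honest but
low), read-level artifacts, homozygous events (available via config),
mosaicism, and common CNV polymorphism beyond the decoy calls.  Passing
tests on these cohorts demonstrate that the pipeline's logic and training
machinery behave as designed under the method's own statistical
assumptions; they do not certify performance on any real capture platform.

## Problem sizes and verification

The bundled end-to-end verification (tests and the acceptance script) uses
desk-scale problems chosen to exercise every stage: a 50-family cohort for
labeling purity, and a 100-family cohort yielding 150 images per class
(reference panels of up to 100 samples) for classifier training with
`generic_cnn` under the standard protocol.  On such cohorts the trained
classifier reaches test accuracy above 0.9 with all per-class recalls above
0.8, and replacing the classifier with an oracle that keeps exactly the
WGS-supported calls drives precision to 1.0 at unchanged recall — the
limiting case of the precision-vs-recall trade the confirmation step is
designed to make.

## Known limitations

* The NumPy backend is CPU-bound and desk-scale; it is not intended for
  cohort-scale training runs.
* Without bundled pretrained weights the transfer protocol starts from
  random features, so its phase-1/phase-2 split is a protocol contract
  rather than a knowledge-transfer benefit.
* The breakpoint-merging contrast score is a simplification; calls whose
  true breakpoints fall inside capture gaps cannot be recovered better than
  target resolution.
* Sex chromosomes are excluded throughout (copy-number baseline differs by
  sex).
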