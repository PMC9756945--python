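# cnvconfirm

**In silico confirmation of rare copy-number variant (CNV) calls from exome
read-depth data.**

Exome CNV callers (XHMM, CANOES, CLAMMS, CODEX, ...) disagree wildly and
produce many false positives, so analysts routinely end a CNV analysis by
eyeballing read-depth plots — which does not scale.  `cnvconfirm` turns that
manual inspection into a classifier: it renders each candidate CNV as the
same kind of depth image an analyst would look at and classifies it into
**rare deletion**, **rare duplication** or **artifact**.

The pipeline, stage by stage:

1. **Normalize** per-target read depth (Mosdepth/CLAMMS-style input).
   Targets ≥ 1 kb are split into 500–1000 bp windows, then each sample is
   rescaled by the median approach

       O_t = (RD_t · M / M_x) / M̄

   (M_x = median depth of targets in the same GC bin, M/M̄ = overall
   median/mean), so a diploid target sits at ~1, a heterozygous deletion at
   ~0.5, a duplication at ~1.5.
2. **Select references**: the k = 100 samples with the highest Pearson
   correlation of normalized depth form the case's contrast panel (family
   members excluded).
3. **Encode**: over the CNV's targets plus flanking context, draw the
   transformed depth profile — x'_t = x_0 + Σ ln(1 + Δx), y' = ln(1 + y) —
   as dots and connecting lines, references in gray (#808080) first, case
   in blue (#0000FF) on top, in a deterministic 224×224 RGB raster.
4. **Label** training data from trios by Mendelian inheritance: calls seen
   in child *and* parent are true rare CNVs; child-only calls with
   confidently CNV-free parents (NQ ≥ 60 in both) and a single caller are
   artifacts; candidates are pre-filtered to rare (≤ 1%), ≥ 2-target,
   autosomal calls mostly outside segmental duplications.
5. **Train / predict**: a convolutional network (six-layer CNN or a
   MobileNet-style depthwise-separable net on the bundled NumPy backend)
   maps images to three softmax probabilities; training uses Adam, batches
   of 32, ≤ 20 epochs, patience-3 early stopping, and the two-phase
   transfer protocol (frozen-base head training, then whole-network
   fine-tuning at 1e-5).
6. **Evaluate** against WGS of the same individuals: an exome call is
   supported when ≥ 50% of its length is covered by same-type WGS
   intervals; precision is per caller, recall is measured against the
   deduplicated union of supported calls across all callers.

A `fixtures` module simulates complete cohorts (negative-binomial depth
with GC bias, trio inheritance, artifact wobbles, multi-caller call sets
with jitter, a WGS-style truth set), so every stage runs and is tested
without access to any real dataset.

## Worked example

```bash
python examples/03_trio_labeling.py
```

prints, for a simulated 50-family cohort:

```
raw candidate calls from 3 callers: 590
after rare/multi-target/autosome/segdup filters: 549
after multi-caller merging: 357
labeled training calls: {'ARTIFACT': 54, 'RARE_DEL': 46, 'RARE_DUP': 38}
unlabeled child calls (ambiguous/possible de novo) are excluded from training
split 60/20/20 -> 84/27/27
```

590 caller records collapse to 357 distinct candidates after the candidate
filters and depth-contrast breakpoint merging; inheritance labels 84 of the
children's calls as true rare CNVs and 54 refined Mendelian errors as
artifacts, and the rest (partial parental overlap, low parental NQ,
multi-caller child-only calls — possible de novo events) stay out of the
training set.  The other examples cover normalization
(`01_normalize_depth.py`), image encoding (`02_encode_cnv_image.py`),
training and scoring the classifier (`04_train_and_evaluate.py`) and the
WGS benchmark (`05_wgs_benchmark.py`).

The same stages are available as a CLI:

```bash
cnvconfirm simulate --families 50 --seed 0 --out cohort/
cnvconfirm normalize --targets cohort/targets.bed --depth-dir cohort/depth --out norm.tsv
cnvconfirm label --calls-dir cohort --matrix norm.tsv --ped cohort/cohort.ped \
    --segdup cohort/segdup.bed --out labeled.tsv
cnvconfirm encode --matrix norm.tsv --calls labeled.tsv --ped cohort/cohort.ped --out-dir images/
cnvconfirm train --images images/ --labels labeled.tsv --arch generic_cnn --seed 7 --out model/
cnvconfirm predict --model model/ --images images/ --out predictions.tsv
cnvconfirm evaluate --calls calls.tsv --confirmed kept.tsv --standard wgs.tsv --out report/
```

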