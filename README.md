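# mvseg — multi-view CNN segmentation of head-and-neck tumors on multi-sequence MRI

Head-and-neck squamous cell carcinomas are delineated manually on MRI for
radiotherapy planning and response assessment — slow, operator-dependent work.
`mvseg` implements an automatic pipeline for segmenting the primary tumor from
three MRI sequences (T1-weighted, STIR, and optionally contrast-enhanced T1):

1. **Standard space** — a study template built by voxel-wise non-zero
   averaging of registered T1 volumes, keeping voxels present in ≥ 30% of
   contributors (the *occupancy mask*); each case enters this 1-mm isotropic
   frame through a two-step affine → rigid registration, with cross-sequence
   transforms concatenated.
2. **Multi-view CNN** — around each voxel, six 32×32×3 patches are cut
   (axial/coronal/sagittal × two pyramid scales; channels T1, T1gad, STIR,
   variance-normalized to ±4 SD and zero-padded at borders).  Six parallel
   branches (3×3 conv + batch norm + ReLU, 2×2 max pool, 25% dropout, dense)
   feed two fused dense layers and a 2-way softmax.
3. **Training** — class rebalancing by sampling 50% of tumor and 1% of
   healthy in-mask voxels; Adam, batch 512, soft-dice loss over the batch

       L = 1 − (2 Σ pᵢgᵢ + ε) / (Σ pᵢ + Σ gᵢ + ε)

   with learning rate 10⁻³ lowered by 20% every fifth epoch; five-fold
   cross-validation stratified on tumor volume × location.
4. **Evaluation** — Dice similarity coefficient (DSC) per case, intraclass
   correlation ICC(2,1) (single-measure, absolute agreement) between manual
   and automatic volumes per fold, subgroup analyses over T/N stage, location
   and four volume groups (≤3, 3–7, 7–15, >15 cm³) with Wilcoxon rank-sum
   tests.

Clinical images cannot ship with the package, so a **phantom generator**
produces multi-sequence cases with exactly known ground truth (tumor volume,
sequence contrast, inter-sequence misalignment, missing contrast channels);
every stage is tested against that ground truth.  See `docs/methods.md` for
the model details and design choices.

## Worked example

`examples/03_train_and_segment.py` trains on six phantoms and segments two
held-out ones:

```
$ python examples/03_train_and_segment.py
training on 6 phantoms, holding out ['case-3-006', 'case-3-007']
epoch mean soft-dice loss: [0.308, 0.114, 0.062]
case-3-006: DSC 0.575   predicted  21.6 cm^3 vs reference  18.9 cm^3
case-3-007: DSC 0.580   predicted  23.5 cm^3 vs reference  17.0 cm^3
A falling loss and held-out DSC well above chance show the network recovered
the tumor contrast pattern rather than memorizing voxels.
```

The loss falls as the network learns the tumor's STIR hyperintensity and
contrast enhancement; held-out DSC near 0.6 with predicted volumes tracking
(and slightly overestimating) the reference means the learned rule
generalizes across phantoms rather than memorizing training voxels.  The
larger 12-phantom, 5-epoch study run by `scripts/acceptance.py` reaches a
held-out DSC around 0.8.  The other examples cover phantom generation (`01`),
template construction and rigid-motion recovery (`02`), and cohort scoring
with subgroup statistics (`04`).

## Command line

The same stages are available as a CLI for shell use:

```bash
mvseg simulate --n 12 --out data/ --seed 7
mvseg build-template --t1-list t1s.txt --threshold 0.30 --out template.nii.gz
mvseg preprocess --case data/cases/case-7-000 --template template.nii.gz --out prep/case-7-000
mvseg train --cases data/manifest.csv --data prep/ --mask template_mask.nii.gz --out runs/
mvseg segment --checkpoint runs/fold0.ckpt --case prep/case-7-000 \
              --mask template_mask.nii.gz --out pred.nii.gz
mvseg evaluate --pred-dir preds/ --ref-dir prep/ --manifest data/manifest.csv \
               --folds runs/folds.csv --out report.json
```

All subcommands honor `--seed`; a full chain rerun with identical flags
reproduces its masks, manifests and fold assignments bitwise.

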