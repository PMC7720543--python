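# bcadepth

Voxel-wise segmentation of bladder cancer from adherent bladder-wall
tissue on 3D T2-weighted MRI, and quantitative measurement of the tumor's
**invasion depth** — the key index for choosing between bladder-preserving
and radical surgery. The package is aimed at medical-image-analysis
researchers who have wall surface segmentations (or want to prototype on
synthetic data) and need the full chain from voxel features to a depth
estimate in millimetres.

## Method

Inside a *candidate region* (a mixed tumor+wall zone flagged by
wall-shape abnormality), every voxel is described by **1159 features**:
3 location features plus, for each of 17 images (the original volume and
16 stationary-wavelet subbands), 20 intensity features (the voxel, its 6
face neighbours, the 3×3 in-plane patch means at those 7 sites, and 6
centre-minus-neighbour differences) and the 48 responses of the
Leung–Malik texture filter bank.

A linear SVM with recursive feature elimination (SVM-RFE: iteratively
drop the feature with the smallest |w|; subset size chosen by fivefold
CV accuracy) yields a calibrated probability map p(tumor). Thresholding
at p = 0.5 with largest-component and hole-filling postprocessing gives
the **hard boundary**; voxels with 0.1 ≤ p ≤ 0.9 form the **soft
boundary**, the mixed-tissue interface. Segmentations are scored with the
Dice coefficient, DSC(S_G, S_A) = 2|S_G ∩ S_A| / (|S_G| + |S_A|).

Wall thickness is measured with the Laplace-equation streamline method:
solve ∇²φ = 0 between the inner surface (φ = 0) and outer surface
(φ = 1), and integrate streamlines of ∇φ from each inner-surface voxel —
the arc length is the local bladder-wall thickness (BWT). After excising
the segmented tumor from the wall, the invasion depth is

    T_ID = T_mean − T_min

with T_mean the mean BWT away from the candidate region and T_min the
minimum residual BWT under the tumor. All three are reported in mm on a
1 mm isotropic grid.

Because the underlying patient dataset is not publicly available, the
package includes a first-class phantom generator — an ellipsoidal bladder
with a known wall thickness and a tumor excavating the wall to a known
depth, with per-tissue intensity/texture statistics — used by the test
suite and the evaluation harness. See `docs/methods.md` for the model
details and what phantom results do and do not show.

## Worked example

Run the default end-to-end batch — train the classifier on 4 phantoms,
validate on 10 phantoms with invasion depths 0.5–2 mm:

```
$ bcadepth run-all --seed 1 --out results/
mean DSC 0.917 +/- 0.027; mean |dT_ID| 0.717 mm
report -> results
```

`results/report.csv` holds one row per case, e.g.

```
case,true_depth_mm,dsc,t_id_manual_mm,t_id_pipeline_mm,abs_diff_mm,n_soft_voxels
0,0.5,0.953,0.633,1.748,1.115,103
1,1.0,0.877,1.661,2.140,0.478,184
2,1.5,0.914,1.679,2.403,0.724,132
...
```

Reading a row: `dsc` compares the pipeline's hard-boundary segmentation
with the ground-truth tumor mask (0.88–0.95 here — tight overlap);
`t_id_manual_mm` is the invasion depth computed from the ground-truth
mask, `t_id_pipeline_mm` from the pipeline's own segmentation, and
`abs_diff_mm` isolates how much segmentation error moves the depth
estimate — mostly below 1 mm, the single-voxel error bound of the 1 mm
grid.

Single stages are available as library calls and subcommands
(`phantom make`, `features extract`, `train`, `segment`, `thickness`,
`depth`), e.g.:

```
$ bcadepth depth --inner ph/inner.nii.gz --outer ph/outer.nii.gz \
    --wall ph/wall.nii.gz --cancer ph/tumor.nii.gz \
    --candidate ph/candidate.nii.gz --out report.json
T_mean=2.725  T_min=1.146  T_ID=1.579 mm -> report.json
```

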