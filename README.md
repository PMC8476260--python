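# multiatlas

Multi-atlas segmentation of small 3-D structures — built for the
skull-base foramen ovale, a few-mm canal used as the puncture target in
trigeminal interventions, where manual CT delineation is tedious and
single-atlas transfer is too brittle.

The toolkit implements the classical three-step pipeline end to end:

1. **Atlas selection** — rank an atlas library against the image to
   segment by normalized cross-correlation,
   `NCC = Σ(F−F̄)(A−Ā) / √(Σ(F−F̄)² Σ(A−Ā)²)`, and keep the top *k*
   (default 10).
2. **Registration** — align each selected atlas with a coarse-to-fine
   affine stage followed by a cubic B-spline free-form deformation
   (displacements of a control grid, tensor-product cubic basis
   `B₀..B₃`), both maximizing normalized mutual information
   `(H₁+H₂)/H₁₂` sampled at 2000 random voxels per iteration, then
   propagate the atlas label through the recovered transform.
3. **Label fusion** — combine the propagated labels by majority vote
   (MV), STAPLE (EM jointly estimating a consensus and each atlas's
   sensitivity/specificity), or SIMPLE (iterative discarding of
   under-performing atlases).

Predictions are scored by Dice overlap `2|A∩B|/(|A|+|B|)`, the 95%
Hausdorff distance, and the average symmetric surface distance, all
surface distances in physical mm. Because the clinical CT cohorts behind
this kind of work are private, the package ships a synthetic phantom
generator — a noisy ellipsoidal bone shell pierced by two foramen-like
canals, deformed per subject by random smooth warps — that provides
arbitrarily many test cases with exact ground truth. See
`docs/methods.md` for models, parameters and limitations.

## Worked example

Fuse ten simulated raters (sensitivity 0.90, specificity 0.95) of a known
mask and recover their performance parameters
(`python examples/04_label_fusion.py`):

```
single raters: accuracy 0.9424 .. 0.9464
majority vote: accuracy 0.9999
       STAPLE: accuracy 1.0000
       SIMPLE: accuracy 0.9999

STAPLE estimated mean sensitivity 0.900 (simulated 0.90), specificity 0.950 (simulated 0.95), 4 EM iterations
```

Every fusion method beats every individual rater, and STAPLE's EM
recovers the simulated sensitivity/specificity to three decimals.

Segment a synthetic test case end to end
(`python examples/05_end_to_end_segmentation.py`):

```
selection (atlas_id, NCC):
  atlas002  0.9303
  atlas000  0.9169
  atlas001  0.8859
  atlas003  0.8808

fused label: 493 voxels
dice 0.815   hd95 0.500 mm   asd 0.197 mm
```

Dice 0.815 against the hidden truth with sub-voxel surface distances
(HD95 0.5 mm = one voxel at the phantom's 0.5 mm spacing). The other
examples cover cohort generation, NCC ranking, and registration recovery
of a known deformation.

## Command line

A thin CLI wraps the library for shell use:

```bash
multiatlas phantom --n-atlases 20 --n-tests 10 --seed 42 --out cohort/
multiatlas segment cohort/tests/test000_gray.nii.gz cohort/atlas \
    --side left --fusion staple --k 10 --out seg.nii.gz --report run.json
multiatlas evaluate seg.nii.gz cohort/tests/test000_label_left.nii.gz
multiatlas benchmark cohort/ --out results/
```

Registration presets: `desk` (default; 64³ phantom scale, minutes per
cohort) and `paper` (the full clinical parameterization — 4×1000 affine
and 5×3000 B-spline iterations at a 5 mm grid). YAML overrides via
`--config`.

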