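# lcseg

Geometry-based locus coeruleus (LC) region estimation on T1-weighted brain
MRI.

## The problem

The LC is a thin (~14.5 mm long, 2–2.5 mm wide) noradrenergic nucleus in
the rostral pons, implicated early in several neurodegenerative diseases.
On standard T1-weighted images it produces **no usable contrast**, so its
neighbourhood can only be estimated geometrically from dimensional
landmarks — about 3 mm lateral of the midline, 1 mm rostral of the
fourth-ventricle floor, and 16–20 mm above the pontomedullary junction —
yielding a deliberately *inflated* presumptive region (~19.7 mm³ per side)
that contains the LC.  `lcseg` is for researchers who want to localize
that region automatically in conventional MRI databases and carry regional
statistics downstream.

The package provides:

* **`geometry`** — the landmark protocol as an analytic mask construction,
  plus erosion, mask volumes, and the Dice cap `2/(1+α)`: a region `α`
  times larger than a contained label can never exceed that Dice against
  it (α = 2.7 → 0.54).
* **`phase`** — the spectral-whitening "phase image"
  `Re(IDFT(F/(|F|+ε‖F‖)))` and std-normalization, the domain-shift-robust
  input representations.
* **`elv`** — Expected-Label-Value localization: atlas labels fused over a
  grid of translations, each weighted by a softmax of windowed normalized
  cross-correlation (FFT-exact), no deformable registration.
* **`unet`** — a patch-based 3D U-Net (two down-sampling stages, Dice-family
  objective, Adam, lr 0.002 dropped 95% every 5 epochs, overlap-averaged
  sliding-window inference), written in pure NumPy with exact gradients
  and seed-reproducible training; five input variants (image / nmz /
  phase / image+phase / nmz+phase).
* **`atlas`** — fuzzy probabilistic atlas construction and an asymmetric
  diffeomorphic-demons baseline with label propagation.
* **`evaluation`** — Dice, sensitivity, binarize + largest component,
  soft-mask combination, LOOCV harness, cohort summary statistics.
* **`stats`** — regional means under propagated masks and the
  Bonferroni-corrected correlation scan (`p_B = p·N_imaging·N_external`)
  with partial-correlation ICV adjustment.
* **`phantom`** — a seeded synthetic brainstem generator (midline,
  fourth ventricle, pontomedullary junction, spindle-shaped bilateral LC
  truth ≈ 7 mm³/side, enlarged masks ≈ 19.7 mm³/side, a site knob for
  3T-vs-7T-like contrast shift) so everything is testable at desk scale.

Localizers are sklearn-style estimators (`fit`/`predict`,
`get_params`/`set_params`), and a `lcseg` CLI wires the stages into
reproducible, provenance-tracked runs.

## Worked example

```python
from lcseg import (PhantomSpec, make_phantom, make_cohort, geometric_lc_mask,
                   mask_volume, dice_cap, dice, ELVLocalizer, binarize_lcc)

case = make_phantom(PhantomSpec(seed=1))
print(round(mask_volume(case.lc_left), 1))    # 6.9   (truth LC, mm^3)
print(round(mask_volume(case.mask_left), 1))  # 19.9  (presumptive region)

geo = geometric_lc_mask(case.landmarks, "left", case.image)
print(round(dice(geo, case.mask_left), 2))    # 0.67

alpha = mask_volume(case.mask_left) / mask_volume(case.lc_left)
print(round(dice_cap(alpha), 2))              # 0.51  (attainable-Dice cap)

cohort = make_cohort(6, base_seed=7)
elv = ELVLocalizer(side="left").fit(cohort[1:])
pred = binarize_lcc(elv.predict(cohort[0].image))
print(round(dice(pred, cohort[0].mask_left), 2))  # 0.68
```

The truth label sits on the external-label volume scale (~7 mm³), the
presumptive region on the manual-mask scale (~19.7 mm³); their ratio caps
the attainable Dice near 0.5 — which is why held-out localization scores
around 0.6 against the presumptive region are good performance here.

Command-line equivalent:

```bash
lcseg make-phantom --n 6 --seed 7 --out cohort/
lcseg geom --landmarks cohort/phantom-A-0007-000/landmarks.json \
           --side left --ref cohort/phantom-A-0007-000/image.nii.gz \
           --out geo_left.nii.gz
lcseg elv --test cohort/phantom-A-0007-000/image.nii.gz \
          --atlas-dir cohort/ --side left --out elv_left.nii.gz
```

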