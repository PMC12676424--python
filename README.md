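# layerlens

Anatomically grounded explainability for volumetric ultrasound classifiers.

Deep models that classify 3D ultrasound — for example, detecting myofascial
pain (MP) from paraspinal B-mode and shear-wave elastography (SWE) volumes —
are accurate but opaque: voxel-level saliency maps are noisy and hard to
read anatomically.  `layerlens` explains such models at the level clinicians
reason at: the stack of tissue layers (dermis, superficial fat, superficial
fascial membrane, deep fat, deep fascial membrane, muscle).  It is written
for imaging-ML researchers who have a volumetric classifier and co-registered
layer segmentations and want quantitative, validated statements about *which
tissue* drives the prediction.

## The method

For classifier `C`, scan `I`, and layer mask `M_i`, the occlusion delta

    Δ_i = logit(C(I)) − logit(C(I ⊙ (1 − M_i)))

measures how much zeroing layer *i* moves the prediction.  Across a dataset,

    PDSS_i = (1/N) Σ max(Δ_i, 0)        (pushes toward MP)
    NDSS_i = −(1/N) Σ min(Δ_i, 0)       (pushes toward control)
    SS_i   = (1/N) Σ |Δ_i| = PDSS_i + NDSS_i

with volume-adjusted variants dividing each scan's delta by its layer voxel
count ‖M_i‖.  Pairwise structure comes from the occlusion interaction score
`OIS_ij = (SS_ij − SS_i − SS_j) / max(SS_i + SS_j, ε)` (positive = synergy,
negative = redundancy) and the Pearson correlation of per-scan saliencies.

The package also provides:

* **CARN training** — a curriculum-adaptive re-weighting scheme: EMA
  per-sample difficulty `L ← βL + (1−β)l`, easy-first exposure growing as
  `f_e = f_min + (1−f_min)·e/(E−1)`, and a learned voxel-weight map applied
  to the input (`ŷ = C(G(I) ⊙ I)`), trained jointly; plus hierarchical
  prediction averaging (scan → site → side → visit → patient);
* **faithfulness metrics** — insertion/deletion curves with trapezoidal
  `AUC_ins`, `AUC_del`, `AUC_Δ` and `IROF = max i_k / (min d_k + ε)` for
  any layer ranking;
* **validation** — a model-randomization sanity check and per-layer
  univariate logistic association `logit P(MP=1) = β0 + β1·S_i` with a
  pre-specified directional significance criterion;
* **synthetic phantoms** — layered speckled B-mode + smooth stiffness
  volumes with the full scan hierarchy and planted additive, synergistic,
  or redundant layer signals, so every claim above is testable end to end.

## Worked example

Train on phantoms whose class signal lives in layer 5 (the deep fascial
membrane, DFM), then score every layer on held-out scans:

```bash
python examples/03_layer_saliency.py
```

```
     layer_name     ss  ss_ci_lo  ss_ci_hi   pdss    ndss  va_ss_e6
         dermis 0.0119    0.0115    0.0122 0.0000  0.0119    5.2552
superficial_fat 0.0083    0.0081    0.0084 0.0000  0.0083    3.5570
            SFM 0.0268    0.0262    0.0275 0.0000  0.0268   11.6174
       deep_fat 0.0071    0.0070    0.0073 0.0000  0.0071    3.0869
            DFM 0.0798    0.0779    0.0817 0.0798 -0.0000   34.9365
         muscle 0.0055    0.0053    0.0057 0.0000  0.0055    2.7690

saliency ranking (most important first): ['DFM', 'SFM', 'dermis',
'superficial_fat', 'deep_fat', 'muscle']
```

The planted layer tops the ranking by a wide margin, its 95% CI well clear
of every other layer, and its delta is purely positive (PDSS ≈ SS,
NDSS ≈ 0): occluding the DFM always pushes the prediction toward control,
i.e. its presence is what signals disease.  The volume-adjusted column
(×10⁻⁶, per voxel) shows the same conclusion survives normalizing away
layer size.  The other examples cover phantom generation, curriculum
training with hierarchical aggregation, faithfulness curves against random
and volume-based rankings, and the sanity/association validation.

There is also a CLI for shell use — `layerlens simulate | train | predict |
explain | faithfulness | sanity | associate | run` — each a thin wrapper
over the library; `layerlens run --config cfg.yaml` executes the whole
pipeline and writes seed- and config-hash-stamped CSVs.

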