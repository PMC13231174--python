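# ncetseg

Automated sub-segmentation of peritumoral edema in glioblastoma MRI into a
putative **non-contrast-enhancing tumor (nCET)** subregion and vasogenic
edema, and evaluation of the derived **T2/FLAIR Heterogeneity Index (TFHI)**
as a survival biomarker.

## The problem

Glioblastoma infiltrates well beyond its contrast-enhancing core. On
conventional MRI, part of the peritumoral "edema" seen as FLAIR
hyperintensity is thought to harbor non-enhancing tumor: tissue with
*relatively lower FLAIR* signal but persistently *high T2* signal, in
contrast to vasogenic edema, which is hyperintense on both sequences.
`ncetseg` delineates that subregion automatically from co-registered,
skull-stripped T2 and FLAIR volumes plus a BraTS-style anatomical label map
(necrosis = 1, edema = 2, contrast-enhancing tumor = 4), and quantifies it as

```
TFHI = V_nCET / V_edema  ∈ [0, 1]
```

the fraction of the total edema volume occupied by putative nCET. The
package is aimed at neuro-imaging researchers studying peritumoral
heterogeneity, surgical planning beyond the enhancing core, and
imaging-biomarker survival analysis.

## Method

1. **NLSVFMM edema split.** Within the edema mask, per-voxel (T2, FLAIR)
   features (z-scored in-mask) are modeled as a two-component bivariate
   Gaussian mixture with *spatially varying* mixing proportions π_ik,
   regularized by *non-local* patch-similarity weights
   w_ij = exp(−‖P_i − P_j‖²/h²) over FLAIR patches. EM alternates
   r_ik ∝ π_ik N(x_i; μ_k, Σ_k) with weighted MLE of (μ_k, Σ_k) and the
   mixing update π_ik ← (r_ik + β Σ_j w_ij r_jk)/(1 + β Σ_j w_ij); a
   penalized log-likelihood is tracked and kept non-decreasing. The class
   with the lower mean FLAIR is labeled nCET.
2. **Boundary cleanup.** Inside a 4-mm band measured inward from the outer
   edema boundary, isolated 26-connected nCET islands of fewer than 100
   voxels are reassigned to vasogenic edema — only when the island lies more
   than 10 mm from the contrast-enhancing tumor (partial-volume artifact
   control that never touches small lesions).
3. **Per-case validation.** Mann-Whitney U between the two subregions'
   FLAIR intensities (significant at P < .01) and the practical-relevance
   statistic %ΔI = |Ī_nCET − Ī_vasog| / (max I_brain − min I_brain) · 100,
   required to exceed 5%.
4. **Survival analysis.** Harrell-c-index-optimal dichotomization of TFHI,
   Kaplan-Meier curves with median OS difference, univariate Cox hazard
   ratio with 95% CI and Wald p, and incremental multivariable Cox tiers
   (clinical → +perfusion → +volumetric, each ± TFHI) with MGMT coded
   methylated = 0 / unmethylated = 1, missing imputed by prevalence, and
   continuous covariates scaled to [0, 1].

## Worked example

`python examples/segment_phantom_case.py` builds a synthetic case with a
known nCET compartment (25% of the edema) and runs the full pipeline:

```
configured nCET fraction : 0.250
estimated TFHI           : 0.267
Dice vs ground truth     : 0.922
FLAIR %dI                : 16.3
Mann-Whitney p (FLAIR)   : 0.00e+00
statistically / practically significant: True / True
```

The estimated TFHI lands within 0.02 of the configured fraction, the mask
overlaps the ground truth at Dice 0.92, and both per-case validation
criteria pass. `examples/survival_stratification.py` and
`examples/incremental_cox.py` demonstrate the survival stage on simulated
cohorts with known hazard structure.

## Command line

```bash
ncetseg phantom   --out demo --seed 1            # synthetic case + cohort.csv
ncetseg run-case  --t2 demo/t2.nii.gz --flair demo/flair.nii.gz \
                  --anatomy demo/anatomy.nii.gz --out demo/result
ncetseg run-cohort --cohort demo/cohort.csv --out demo/survival
ncetseg stratify  --cohort demo/cohort.csv --plot km.png
ncetseg coxfit    --cohort demo/cohort.csv --tier full --with-tfhi
```

`run-case` writes a label map (0 background, 1 necrosis, 2 vasogenic edema,
3 nCET, 4 CET) and a JSON case report (fit diagnostics, removal report,
validation, biomarkers); runs are bit-reproducible for a fixed seed. A YAML
config (blocks `nlsvfmm`, `cleanup`, `validation`, `survival`, `phantom`)
overrides any default.

## Limitations

Inputs must be preprocessed upstream (co-registration, resampling, brain
extraction, bias correction) and anatomical labels are consumed, not
produced. The identified subregion is an imaging construct — low-FLAIR
voxels inside the edema — not cellular-level proof of infiltration. See
`docs/methods.md` for the model details, parameter defaults and what the
synthetic studies do and do not demonstrate.
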