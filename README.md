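# popdcquant

Quantification pipeline for studies of POPDC (Popeye domain containing)
protein membrane trafficking in muscle. POPDC1/BVES and POPDC2 are
transmembrane cAMP-effector proteins of cardiac and skeletal muscle whose
disease variants mislocalize away from the sarcolemma; assessing that
mislocalization quantitatively requires the same handful of measurements
over and over:

* **Muscle-fiber compartment quantification** — segment fiber
  cross-sections from a membrane-marker immunostain (α-sarcoglycan, SGCA),
  split each fiber into a sarcolemmal ring and a cytoplasmic interior, and
  measure per fiber the SGCA-normalized sarcolemmal target level
  `ring_mean(target) / ring_mean(SGCA)`, the sarcolemma:cytoplasm
  enrichment, and the cross-sectional area.
* **Single-cell localization ratios** — in transfected cells with a DiD
  membrane dye and a nuclear stain, the plasma-membrane : cytoplasm mean
  intensity ratio of each co-expressed reporter.
* **BiFC interaction quantification** — transfection-gated,
  nucleus-excluded `median(Venus) / median(mRFP)` per image, group means
  normalized to the wild-type pair (≡ 1), compared by one-way ANOVA +
  Dunnett.
* **Type-1 quantitative BRET stoichiometry** — titrations at constant total
  expression and varying donor:acceptor ratio; after background subtraction
  and expression normalization, corrected BRET vs acceptor fraction
  *f* = acceptor/(donor+acceptor) is fit to ideal curves

  * monomer (bystander only): `BRET = s · f/(1−f)` (linear in the
    acceptor:donor ratio, non-saturating),
  * n-mer (n ≥ 2): `BRET = Bmax · [1 − (1−f)^(n−1)]` (probability a donor's
    complex contains ≥ 1 acceptor under random assembly),

  with the complex order classified by lowest AICc. The constant-total
  design is itself checked by an F-test of total expression vs ratio.
* **Statistics layer** — control-median normalization (control ≡ 1),
  distribution-free median 95% CIs, Mann–Whitney, Kruskal–Wallis + Dunn
  (Holm-adjusted), ANOVA + Dunnett.

Because studies of patient biopsies rarely deposit raw images, the package
ships first-class **synthetic-data generators** (`popdcquant.synth`) that
emulate biopsy cross-sections (area-weighted polygonal fiber mosaics with a
bright sarcolemmal ring), transfected-cell fields, BiFC fields and BRET
titrations — each with exact ground-truth masks and noise-free intensities,
so every stage of the pipeline is testable end to end.

## Worked example

A patient-vs-control biopsy comparison on synthetic sections in which the
patient's sarcolemmal target intensity is reduced to 75% of control:

```python
from popdcquant import synth, pipelines

patient = [synth.generate_biopsy(
    synth.BiopsySpec(n_fibers=150, group_effect=0.75, seed=101))[0]]
control = [synth.generate_biopsy(
    synth.BiopsySpec(n_fibers=150, seed=202))[0]]

report = pipelines.run_biopsy_study(patient, control)
pat, ctl = report["groups"]["patient"], report["groups"]["control"]
print(f"patient: {pat['median_normalized']:.3f}, "
      f"95% CI {pat['ci_low']:.3f}, {pat['ci_high']:.3f}; n = {pat['n']}")
print(f"control: {ctl['median_normalized']:.3f}, "
      f"95% CI {ctl['ci_low']:.3f}, {ctl['ci_high']:.3f}; n = {ctl['n']}")
print(f"Mann-Whitney U = {report['mann_whitney']['statistic']:.0f}, "
      f"p = {report['mann_whitney']['p_value']:.3g}")
```

prints

```
patient: 0.766, 95% CI 0.752, 0.783; n = 150
control: 1.000, 95% CI 0.978, 1.024; n = 150
Mann-Whitney U = 465, p = 9.85e-47
```

i.e. the per-fiber SGCA-normalized sarcolemmal level, expressed relative to
the control median (set to 1), recovers the simulated 25% reduction: the
patient median is 0.766 with a ring-ROI dilution bias of a few percent (see
`docs/methods.md`), and the group difference is overwhelmingly significant
at 150 fibers per arm. The control group's own normalized median is exactly
1 by construction.

The same analyses are available from the shell:

```bash
popdc synth --kind biopsy --seed 1 --out imgs/          # image + ground truth
popdc fiberquant --images imgs/ --out fibers.csv        # per-fiber table
popdc qbret --plate plate.csv --out fit/                # titration fit
popdc study-biopsy --patient pt/ --control ct/ --out report/
```

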