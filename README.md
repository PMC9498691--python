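# asymtraj

Temporal ordering of Alzheimer's-disease biomarkers from contralateral
neuroanatomical asymmetry.

As Alzheimer's disease progresses, biomarkers are thought to leave their
normal range sigmoidally, each in its own epoch: CSF amyloid-β first, tau
next, brain structure and memory later, clinical function last.  `asymtraj`
implements an analysis pipeline that places *morphological asymmetry*
measures on that timeline.  From labeled 3D brain volumes (83-region
anatomical label maps with 40 contralateral region pairs) it computes, per
pair, five features — mean volume `mV`, normalized volume difference
`dV/mV`, mean surface area `mSA`, normalized difference `dSA/mSA`, and the
post-registration Jaccard overlap `J` of the right region with the
reflected, rigidly registered left region.  It then aligns heterogeneous
longitudinal cohorts to each subject's MCI→AD conversion (adjusted time 0),
imputes an anchor for never-converting subjects by covariate-matched
hot-deck nearest neighbors (validated with replicate imputations and
bootstrapped two-sample Kolmogorov–Smirnov tests), and characterizes every
biomarker with a single-knot segmented regression

    y = a + β₁·t + (β₂ − β₁)·(t − ψ)₊ + ε,

whose breakpoint ψ (months relative to conversion) marks the biomarker's
inflection.  Sorting conclusive fits by ψ yields the temporal ordering.

Real clinical-cohort data (e.g. ADNI) require credentialed access, so the
package ships a first-class synthetic-data module: paired 3D regions with
known size/shape asymmetry and rigid offsets, and cohorts of converters and
static subjects whose biomarkers follow staggered sigmoid time courses with
known inflection times.  Every synthetic output comes with its answer key.

Intended users: neuroimaging/biostatistics researchers studying biomarker
staging, and anyone needing a tested reference implementation of
event-anchored alignment with hot-deck time imputation or Muggeo-style
breakpoint estimation.

## Worked example

The packaged demo config simulates a 60-subject cohort (30% converters),
computes asymmetry features for a synthetic region pair, aligns and imputes
the time axis, validates the imputation with 25 replicate imputations, and
fits the segmented models:

```bash
asymtraj run --config src/asymtraj/data/demo_config.yaml --out demo/
```

```
INFO asymtraj.pipeline: stage synthesize complete
INFO asymtraj.pipeline: stage align complete
INFO asymtraj.pipeline: stage validate complete
INFO asymtraj.pipeline: stage fit complete
completed 4 stages; manifest in demo/manifest.json
```

`demo/ordering.csv` holds the recovered biomarker ordering (knots in months
relative to conversion; planted knots were −65, −50, −35, −15, +10):

```
 variable    knot  knot_se  slope_pre  slope_post         trend
 csf_ptau -44.447    3.688      0.013       0.186 destabilizing
  csf_tau -33.932    1.383      0.214       1.507 destabilizing
 adni_mem -21.884    1.466     -0.009      -0.033 destabilizing
csf_abeta -20.366    4.161     -0.727      -0.263   stabilizing
     mmse  -3.939    1.359     -0.051      -0.222 destabilizing
```

Reading this: total tau begins destabilizing ~34 months before conversion,
the memory composite ~22 months before, MMSE around conversion — the
planted stagger of the destabilizing markers, shifted toward zero because
the fits here run on *imputed* times, whose anchor noise attenuates knots
(most visibly for the early amyloid marker; see `docs/methods.md`).  On
ground-truth times the planted ordering of the amyloid/tau/memory/MMSE
panel is recovered in 200 of 200 simulated cohorts (that check is part of
the test suite).  `demo/ks.csv` summarizes the imputation validation —
p-values min 0.875, mean 0.994, 0 of 25 replicates rejected at α = 0.05 —
i.e. the replicate time axes are statistically indistinguishable from the
original, and `demo/features.csv` holds the per-pair asymmetry row
(here a near-symmetric synthetic pair, J = 0.96, dV/mV = 0.008).

Individual stages are also available as subcommands (`synth`, `features`,
`align`, `validate`, `fit`, `report`), all reading and writing plain CSV;
`report` renders per-variable mean curves with the fitted spline and knot.

## Library surface

```python
from asymtraj import synth, features, align, segfit

pv = synth.make_paired_volume(synth.ShapeSpec(size_ratio=1.2, seed=0))
row = features.compute_pair_features(pv.volume, {"pair_id": 1, "name": "demo",
                                                 "right_label": 1, "left_label": 2})

sim = synth.simulate_cohort(n_subjects=150, seed=0)
adjusted, meta = align.build_adjusted_times(sim.visits)
fit = segfit.fit_biomarker(times, values, variable="mmse")
```

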