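# isletmorph

Semi-automated morphometry of pancreatic islets from multichannel
immunofluorescence section images.

Quantitative islet histology asks how an intervention — a gene knockout, a
cell-ablation model, a diet — changes the size, shape and cellular
composition of the islets of Langerhans. The raw material is a series of
stained pancreas sections (typically four 8 µm head-to-tail sections per
mouse) imaged in three channels: insulin immunoreactivity marking β cells,
a second marker (glucagon, somatostatin, cleaved caspase-3, Ki67 or BrdU),
and DAPI marking nuclei. `isletmorph` turns those images into per-islet
measurements, per-mouse summaries and group-level statistics, and ships a
synthetic-section generator with exact ground truth so the whole pipeline
can be validated without any slide.

The package is aimed at labs doing islet phenotyping who want the
measurement rules to be explicit, configurable and testable rather than
buried in ad-hoc image-analysis macros.

## What is measured

An **islet** is operationally a connected hormone-positive region that
contains at least one insulin⁺, DAPI-stained cell and has cross-sectional
area strictly greater than 50 µm². Candidate regions that fail this
definition are excluded and tagged with the reason: hormone signal without
nuclei, regions with only non-β hormones, sub-threshold specks,
out-of-focus (blurred) regions, and ambiguous near-contiguous
micro-clusters of a few insulin⁺ cells that cannot be called one islet or
several.

Per retained islet:

- cross-sectional area *a* (pixel count × pixel size²) and perimeter *p*
- Feret's diameter — the longest caliper distance across the islet
- circularity 4π*a*/*p*² (1 for a circle, lower when elongated)
- β-, α- (and optionally δ-) cell cross-sectional areas from the hormone
  masks
- β-cell count from watershed-separated nuclei, and
  β-cell size = β area / β count
- marker⁺ β-cell counts for apoptosis/proliferation markers

Per mouse (pooling the four sections):

- relative islet (β-cell) area = 100 × total islet (β) area / total
  sectioned pancreas area
- β-cell mass = (total β area / total pancreas area) × pancreas-plus-spleen
  weight
- islet density = islet count / pancreas area (mm⁻²)
- islet size-class distributions (percent of islets per area bin)

The statistics module implements the matching cohort conventions: Student's
t test, two-way and repeated-measures two-way ANOVA with Bonferroni or
Tukey post hoc tests, Pearson correlation with simple linear regression,
automatic log transform for groups with unequal variance, iterative Grubbs
outlier removal, and the significance bands p < 0.05 (significant) and
0.05 ≤ p < 0.1 (trend).

## Worked example

Generate a small synthetic cohort with a planted 1.5× effect on mean islet
area, run the full pipeline, and test the group difference:

```python
from isletmorph import (
    AnalysisConfig, CohortDesign, GroupEffect, analyze_cohort,
    generate_cohort, two_group_test,
)

design = CohortDesign(
    groups=[("control", 3), ("lowghrelin", 3)],
    sections_per_mouse=2,
    islets_per_section=15.0,
    group_effects={"lowghrelin": GroupEffect(area_multiplier=1.5)},
    rng_seed=7,
)
manifest = generate_cohort(design, "demo_cohort")

config = AnalysisConfig(threshold_method="fixed")
islets, mice = analyze_cohort(manifest, config)
print(mice[["mouse_id", "group", "n_islets", "mean_islet_area_um2",
            "mean_beta_count", "relative_islet_area_pct"]].round(1))

a = mice.loc[mice.group == "control", "mean_islet_area_um2"]
b = mice.loc[mice.group == "lowghrelin", "mean_islet_area_um2"]
res = two_group_test(a, b)
print(f"mean islet area: {b.mean() / a.mean():.2f}x higher "
      f"(t = {res.statistic:.2f}, p = {res.p:.4f}, {res.category})")
```

Output:

```
     mouse_id      group  n_islets  mean_islet_area_um2  mean_beta_count  relative_islet_area_pct
   control_01    control        33               1635.6             15.7                      1.1
   control_02    control        30               2057.7             20.2                      1.2
   control_03    control        34               2246.1             22.1                      1.5
lowghrelin_01 lowghrelin        30               2697.8             26.9                      1.6
lowghrelin_02 lowghrelin        36               2884.9             29.2                      2.0
lowghrelin_03 lowghrelin        29               2997.7             31.0                      1.7
mean islet area: 1.44x higher (t = -4.39, p = 0.0118, significant)
```

Each row is one mouse: its retained islet count over the sections, mean
islet area (µm²), mean β cells per islet and the percent of sectioned
pancreas occupied by islet tissue. The estimated 1.44× group ratio recovers
the planted 1.5× multiplier to within small-cohort sampling error, and the
t test on per-mouse means calls the difference significant.

The same steps are available from the shell: `isletmorph simulate`,
`segment`, `measure`, `summarize`, `stats` and `validate` (see
`isletmorph --help`).

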