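# ccflow

Quantification of choriocapillaris flow deficits from averaged en face
OCT angiography, with the cohort statistics of a pachychoroid
case–control design and a ground-truthed synthetic data generator.

## The problem

The choriocapillaris — the capillary monolayer feeding the outer retina
— appears on en face OCTA as a fine meshwork interrupted by *flow
voids*: regions without detectable flow signal. In pachychoroid
spectrum disease (here pachychoroid pigment epitheliopathy, PPE,
against healthy controls), the questions are (i) whether the flow-void
load differs between groups and (ii) whether the deficit co-localizes
with *pachyvessels*, the pathologically dilated outer choroidal veins
visible as dark lumens on structural en face OCT.

A single 3 × 3 mm OCTA frame is too speckled to segment the meshwork,
so nine repeated acquisitions are rigidly registered — using the
high-contrast superficial capillary plexus (SCP) slab of each cube as
the registration target, with the same transform then applied to the
choriocapillaris slab — and averaged. The averaged image is binarized
with the **Phansalkar local adaptive threshold** (radius 15 px): for
window mean *m* and standard deviation *s*,

    T = m · (1 + p·e^(−q·m) + k·(s/r − 1)),   p=2, q=10, k=0.25, r=0.5,

a rule designed for low-contrast images whose objects of interest are
darker than their surroundings. Inverting the binary image yields the
flow-void mask, from which three metrics are computed per eye: void
count, total void area (mm²) and mean void size (µm²). Binarizing and
inverting the choroidal en face scan the same way yields the
pachyvessel mask, and the co-localization statistic is the percentage
of flow-void area lying over pachyvessels.

Group inference uses unpaired t-tests (from raw values or from
published n/mean ± sd summaries), chi-square for the sex ratio, Pearson
correlation, and partial correlation for age/sex-adjusted p-values.

Because the study's device images were never deposited, the package
ships a first-class synthetic generator — lobular meshwork scenes with
known void masks, gamma-speckled jittered acquisitions, choroid scans
with vessel ribbons, and cohort tables drawn from the published group
distributions — so every stage is testable against stored ground truth.

## Worked example

`python examples/01_average_and_quantify_one_eye.py` simulates one eye
(300 × 300 px at 10 µm/px, true void fraction 13 %, nine frames at
default speckle and fixation jitter) and runs the full chain:

```
true void area:      1.171 mm^2 (fraction 0.130)
measured void area:  1.212 mm^2 (1304 voids, mean 930 um^2)
frames averaged:     9 of 9
registration quality: 0.82-1.00 (normalized correlation)
```

The measured total area lands within a few percent of the simulated
truth; the count and mean size describe the merged components the
threshold actually sees. The other examples cover pachyvessel
co-localization (`02`), the cohort report tables (`03`) and the
end-to-end study driver (`04`). The same operations are scriptable from
a shell:

```sh
ccflow simulate stack --seed 1 --out eye1/
ccflow run-all --seed 7 --out study/
ccflow stats --cohort study/cohort.csv --out study/report
```

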