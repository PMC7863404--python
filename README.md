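# cochleaquant

Quantification pipeline for mouse inner-ear gene-therapy experiments:
3D hair-cell morphometry from confocal whole-mounts, cochleograms on a
place–frequency map, ABR/DPOAE feature extraction, and auditory-behavior
scoring — with a synthetic-data generator that renders every raw input
with known ground truth, so the whole pipeline is testable without any
animal data.

## Who it is for

Auditory neuroscience labs that quantify cochlear rescue experiments:
counting surviving inner (IHC) and outer (OHC) hair cells along the
cochlea, measuring nuclear mispositioning in LINC-complex mutants
(e.g. nesprin-4 knockouts, where OHC nuclei shift apically), scoring
viral transduction from reporter fluorescence, and reading out hearing
recovery from auditory brainstem responses (ABR), distortion-product
otoacoustic emissions (DPOAE), and cued fear conditioning.

## What it computes

* **Nuclear-position morphometry** — for each hair cell, a circular arc
  is fitted through three 3D landmarks (apical surface *A*, nucleus
  centroid *N*, basal end *B*; the circumcircle in their common plane)
  and the nucleus position is the arc length from *A* to *N*, in µm,
  optionally normalized by the total *A*→*B* arc length.
* **Cochleograms** — nuclei are segmented from DAPI (Otsu threshold +
  distance-transform watershed), typed IHC/OHC by lateral offset from a
  pillar-cell polyline, and counted in 100 µm bins of arc length from
  the apex. A frequency *f* (kHz) is mapped to its cochlear place with
  the mouse place–frequency map *d*% from base = 156.5 − 82.5·log₁₀(*f*),
  distance-from-apex = (1 − *d*/100)·*L* with *L* = 5.13 mm.
* **Transduction** — a cell is GFP-positive when its mean nuclear GFP
  exceeds the control mean by 2 control SDs (per cell type);
  intensities are reported as (I − µ_c)/µ_c. FLAG/DAPI line profiles
  are centered at the nuclear periphery (maximal DAPI along a radial
  line) and normalized per channel.
* **Audiology** — ABR threshold = lowest intensity whose response
  window peak-to-peak exceeds k·SD of the pre-stimulus baseline (k = 4)
  at that and every higher intensity; P1 latency and P1−N1 amplitude
  from the first post-onset peak/trough. DPOAE 2f1−f2 amplitude vs the
  flanking noise floor, with a +6 dB detection criterion and the same
  monotone threshold rule.
* **Behavior** — activity = fraction of pixels changed per frame;
  freezing = sub-threshold activity runs ≥ 1 s; fear-conditioning
  summaries over the 90–150 s (pre-tone) and 150–210 s (tone) bins of
  day 2; open-field rotations/distance/center time over 5–15 min.
* **Statistics** — Pearson correlation with two-tailed p, Holm–Šidák
  step-down adjustment, balanced two-way ANOVA, paired before/after
  t-tests.

## Worked example

```python
import numpy as np
from cochleaquant.cochleomap import frequency_to_place
from cochleaquant.synthgen import study_params, gen_cochlea_stack, \
    ABRSimParams, gen_abr_series
from cochleaquant.imaging import segment_nuclei, classify_cells, RowGeometry
from cochleaquant.morphometry import fit_arc, nucleus_position
from cochleaquant.audiology import abr_threshold

print(f"12 kHz place: {frequency_to_place(12.0):.3f} mm from apex")

for geno in ("WT", "KO"):
    params = study_params(geno, seed=0, n_cells_per_row=12,
                          survival_base=1.0, survival_slope=0.0)
    stack, truth, polyline = gen_cochlea_stack(params)
    dets = classify_cells(segment_nuclei(stack), stack,
                          RowGeometry(polyline=polyline))
    d = [nucleus_position(fit_arc(c.apical_um, c.centroid_um, c.basal_um))
         ["distance_from_apical"] for c in dets if c.type == "OHC"]
    print(f"{geno}: mean OHC nucleus distance {np.mean(d):.2f} um "
          f"({len(d)} cells)")

series, truth = gen_abr_series(ABRSimParams(frequencies=(12.0,),
                                            true_threshold_db=45.0, seed=0))
res = abr_threshold(series[12.0])
print(f"ABR threshold at 12 kHz: {res.threshold_db:.0f} dB SPL "
      f"(true {truth[12.0]['threshold_db']:.0f})")
```

prints

```
12 kHz place: 1.669 mm from apex
WT: mean OHC nucleus distance 9.89 um (36 cells)
KO: mean OHC nucleus distance 6.90 um (36 cells)
ABR threshold at 12 kHz: 45 dB SPL (true 45)
```

The 12 kHz place (1.669 mm from the apex) is where regional OHC
survival is scored; the WT−KO difference (~3 µm) recovers the apical
nuclear shift programmed into the knockout simulation; and the ABR
threshold estimate lands on the programmed true threshold.

## Command line

```bash
cochleaquant simulate --kind stack --genotype KO --seed 1 --out data/
cochleaquant place --freq 12
cochleaquant abr --in abr.csv --out features.csv --onset-ms 8
cochleaquant dpoae --in dpoae.csv --out dp.csv
cochleaquant fear --in behavior.csv
cochleaquant run config.yaml --out results/
```

`run` executes configured stages (simulate → segment → morphometry →
cochleogram → transduction → stats) from one YAML file and writes a
manifest with parameter echoes and output hashes; reruns with the same
seed are byte-identical.

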