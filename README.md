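# mitoquant

Quantification of mitochondrial dynamics from light- and electron-microscopy
data: network morphology, foci-mediated tethering kinetics, ER–mitochondria
contact-site geometry, and the photoactivatable-GFP fusion assay. The package
is aimed at cell biologists who quantify mitochondrial fusion phenotypes
(e.g. in mitofusin or MTCH2 perturbation experiments) and want the usual
by-hand/FIJI measurements as explicit, scripted, reproducible rules.

Because such studies rarely ship raw microscopy, `mitoquant` includes a
first-class synthetic-data module that renders ground-truthed scenes for all
four modalities, so every stage of the analysis can be verified end to end
without any image downloads.

## What it computes

**Aspect ratio and network class.** Images are background-subtracted (white
top-hat), thresholded (Otsu by default), and labeled. Each mitochondrion gets
the aspect ratio of its second-central-moment ellipse,
AR = √(λ₁/λ₂) ≥ 1, where λ are the eigenvalues of the pixel covariance
matrix (unit-square pixel convention, so an L×w rectangle gives exactly
L/w). Cells are classified Elongated (>90 % of objects with AR ≥ 2),
Fragmented (>90 % round), Hyperfused (one reticular component holding ≥ 75 %
of mitochondrial area), Collapsed (≥ 75 % of area clumped near the network
centroid), or Intermediate, with rules evaluated in that priority order
(Collapsed and Hyperfused first).

**Tethering events.** In two-channel time-lapse stacks (3 s frame interval),
bright foci are detected per frame, linked into tracks by greedy
nearest-neighbour assignment with gap closing, and scored by a state machine
over the mitochondria-channel label maps: an event opens when a focus sits
within the adjacency radius of two distinct mitochondria and closes at
separation or fusion (the partners merging into one component for at least
two confirmation frames). Only events lasting strictly more than 15 s are
reported — shorter touches are "kiss and run" — with mean duration, SEM,
fruitful (fused) counts, and a Welch t-test between conditions.

**ER–mitochondria contacts.** From traced geometry in physical nm
(mitochondrial outlines as polygons, ER tubules as polylines), ER runs within
60 nm of the nearest mitochondrial surface become contact sites, each with an
arc length, a GAP (mean sampled distance), and a GAP bin ([0,15), [15,30),
[30,60] nm). Per-cell summaries report contacts per mitochondrion, mean
contact length, mean perimeter, and the percentage of perimeter covered by
the union of projected contact arcs.

**PA-GFP fusion assay.** The GFP-positive area inside the mitochondrial mask
is measured at 0, 5 and 10 min after photoactivation and normalized to the
initially photoactivated area; curves are averaged across cells with SEM.

## Worked example

```sh
python examples/tethering_events.py
```

simulates a fusion-competent ("WT-like", 23 events, 20 + Exp(20) s dwell) and
a fusion-impaired ("KO-like", 18 events, 40 + Exp(40) s dwell) live-imaging
experiment and measures both end to end:

```
condition  n_events  n_censored  mean_duration_s  sem_duration_s  n_fruitful  n_unfruitful  duration_ratio  ttest_p
  WT-like        23           0        33.913043        3.407683          13            10        2.231197 0.000008
  KO-like        18           0        75.666667        6.688689           9             9        2.231197 0.000008
```

The KO-like condition spends about twice as long tethered (ratio ≈ 2.2 in
this single simulated experiment), the difference is highly significant, and
roughly half of the events are fruitful (end in fusion). The other example
scripts (`classify_morphology.py`, `er_contacts.py`, `pagfp_spread.py`) walk
through the remaining capabilities the same way; each prints its numbers with
a sentence on what they mean.

A `mitoquant` command-line interface binds the stages into a file-based
pipeline (`simulate`, `segment`, `classify`, `tether`, `contacts`, `fusion`,
`report`), writing CSV tables stamped with the config hash plus a run
manifest, so identical config + seed reproduces byte-identical outputs.

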