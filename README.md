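# dcquant

Quantification of **dorsal closure** in *Drosophila* embryos from segmented
time-lapse movies, for developmental biologists comparing closure dynamics
across genotypes (e.g. formin mutants against wild-type controls).

During dorsal closure the extraembryonic amnioserosa (AS) contracts in
pulses while the flanking epidermal sheets converge and "zip" together
from the two canthi of the eye-shaped dorsal hole. `dcquant` measures, from
integer label-image stacks and hole contours:

* **AS cell pulsation** — in a 15-min window opening when the dorsal gap is
  50 µm wide, the normalized relative apical area of the six most central
  cells, n(t) = A(t)/Ā − 1, with pulse count and pulse amplitude (height,
  peak minus preceding trough) from prominence-filtered peak detection;
* **AS cell shape** — the convexity shape index
  N(t_x) = AS_area(t_x) / Ch_area(t_x), the ratio of the cell polygon's
  area to its convex hull's (1 = convex, < 1 = wavy), plus apical area and
  perimeter at the 50-µm gap;
* **closure kinetics** — hole width W(t) and length L(t), leading-edge
  convergence speed (rate of width decrease, 3-frame smoothed), zipping
  speed v(t_x) = (length(t_x) − length(t_x+1))/Δt, closure duration from
  timepoint zero (end of germ-band retraction), and the length-to-width
  ratio when the gap is 30 µm wide;
* **filopodia** — number and length per engrailed stripe (six per embryo)
  from polyline annotations, while the leading edges are 30–50 µm apart;
* **group statistics** — D'Agostino–Pearson normality, Kruskal–Wallis with
  Dunn's many-to-one post hoc, one-way ANOVA with Dunnett's comparisons,
  Pearson chi-square on phenotype-category tables, and significance stars
  (ns > 0.05 ≥ * ≥ ** ≥ *** ≥ ****).

Because suitable public recordings are scarce, the package ships a
**synthetic-embryo generator**: genotype presets (WT, dia, frl, DAAM,
form3) whose piecewise-linear speed profiles and pulsation parameters
encode published kinetic values, rendered as hole contours and rasterized
pulsing cell sheets with exact ground truth, so every analyzer can be
validated by parameter recovery.

## Worked example

```sh
$ dcquant quantify --preset WT --seed 1 --out wt_run
WT: duration 176 min, max v_conv 1.09 µm/min, mean zip(0-84) 1.12 µm/min
```

The run renders a wild-type embryo (4-min closure frames, 30-s AS frames),
re-measures it end to end, and writes tidy tables under `wt_run/`.
`kinetics.csv` holds the per-embryo summary:

```
genotype,seed,duration_min,max_v_conv,initial_v_conv,initial_v_zip,mean_zip_0_84,lw_ratio_at_30
WT,1,176.0,1.0920...,0.5785...,0.7190...,1.1212...,5.5130...
```

i.e. the hole closes 176 min after timepoint zero (the 4-min frame grid
quantizes the preset's 174 min), the leading edges converge at up to
1.09 µm/min starting from 0.58 µm/min, zipping starts at 0.72 µm/min and
averages 1.12 µm/min over the first 84 min. `as_cells.csv` gives one row
per central AS cell:

```
track_id,area_um2,perimeter_um,shape_index,amplitude,pulse_count,genotype,seed
11,166.02,57.01,0.871,0.1959,3,WT,1
20,151.02,52.77,0.896,0.1975,4,WT,1
...
```

— apical areas of 130–170 µm², wavy shapes (N ≈ 0.87), and 3–4 pulses of
relative amplitude ≈ 0.196 per window, recovering the generator's
peak-to-trough truth of 2a = 0.20 to within 2%. Other subcommands:
`dcquant simulate` (write a synthetic embryo to disk), `dcquant stats`
(group comparisons on a tidy CSV), and `dcquant benchmark`
(generated-vs-recovered parameter table across presets).

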