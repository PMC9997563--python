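# flywell

Analysis pipeline for 96-well fly feeding-behavior assays: video-based
silhouette tracking, food-interaction and locomotion measures,
feeding-bout denoising, group statistics, and dye-based food-intake
quantification. It is written for labs running *Drosophila* feeding and
survival experiments in well-plate formats, where each well houses one
fly filmed from above on a near-infrared backlight and fed through a
liquid food port at the bottom of the well.

## What it computes

**Tracking.** Each frame is binarized per well against a per-pixel
temporal-median background (a pixel is a fly pixel when it is more than
δ intensity levels darker than background, δ = 25 by default);
connected-component analysis labels the foreground, and the largest
component of at least `min_area` = 8 px is retained as the fly
silhouette, with its area and centroid.

**Measures.** Two per-frame measures follow the silhouette: a binary
*food-interaction flag*, set to 1 only when every silhouette pixel lies
inside the annotated food circle, and the Euclidean *inter-frame
distance* between consecutive centroids (pixels). Both are aggregated
over nonoverlapping 2-min intervals into a food fraction and a
cumulative distance.

**Feeding bouts.** Starved flies feed in bursts of ≈7 sips × 0.13 s =
0.91 s, which at 30 fps is 30 × 0.91 = 27.3 frames. The raw flag stream
is therefore denoised in two passes: interior gaps shorter than 10
frames are closed, then flagged runs shorter than 27 frames are removed.
The surviving runs are the feeding bouts.

**Statistics.** Cohorts (grouped by sex, pretreatment, diet) are
compared with two-sided unpaired Mann–Whitney U tests in 10-min windows
(15–25, 25–35, 35–45, 45–55 min), one value per fly per window, with
Benjamini–Hochberg adjustment across the windows of a comparison.
Trend curves use lowess with a smoothing span of 0.25.

**Consumption.** Dye signals (absorbance at 630 nm from excreta, or
in-body fluorescence) are converted to food amounts through a linear
standard curve `signal = slope·amount + intercept`; amounts are reported
per fly and per hour, with dead/damaged wells excluded via the plate
map.

**Synthetic sessions.** A generator renders ground-truthed sessions —
one dark elliptical fly per well following a two-state roam/at-food
Markov chain, optional sip-burst texture and sub-fly speck noise — so
every stage is testable without real video.

## Worked example

```
flywell simulate --seed 42 --out demo --wells 4 --duration-s 60 --speck-rate 0.2
flywell pipeline --video demo/frames --layout demo/layout.json \
    --platemap demo/platemap.csv --out demo_out
```

`demo_out/intervals.csv` then begins

```
well,interval,start_s,n_frames,food_fraction,distance_px,partial
A1,0,0.0,1800,0.555,5348.2995888578735,True
A2,0,0.0,1800,0.5872222222222222,5664.197107269816,True
```

— fly A1 spent 55.5% of the first (partial, 60 s) interval fully inside
its food circle and traveled 5348 px — and `demo_out/bouts.csv` lists
the denoised feeding bouts in seconds:

```
well,bout_index,start_s,duration_s
A1,0,7.033333333333333,5.6
A1,1,17.733333333333334,12.233333333333333
```

The denoising constants themselves are derived, not hard-coded:

```python
>>> from flywell.bouts import burst_frame_threshold, BoutParams
>>> burst_frame_threshold(7, 0.13, 30)   # frames per feeding burst
27.3
>>> BoutParams().min_on_frames           # floored minimum feeding run
27
```

## Layout of a session

A session directory holds a `frames/` image sequence (PNG, lexicographic
order), `layout.json` (versioned schema: frame geometry, fps, 96
four-corner well polygons, 96 food circles), and `platemap.csv`
(`well,sex,pretreatment,diet_kcal,flies_per_well,alive`). See
`docs/methods.md` for the model details, parameter defaults, and known
limitations.
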