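# mldcyto

Automated cell identification, tracking and lineage analysis from
**nanoparticle moving-light-display (MLD) microscopy**.

Cells that endocytose fluorescent nanocrystals (quantum dots) concentrate
them into 10–50 intracellular vesicles, which appear in a fluorescence
movie as clusters of bright, point-like light sources arranged around the
nucleus. Just as a handful of markers on a moving person suffices to
perceive the whole figure, these sparse light points suffice to identify
each cell, follow its motion, and recognise mitosis — without segmenting
cell outlines at all. `mldcyto` implements that idea as a pipeline:

1. **imaging** — multi-focal-plane stacks are fused block-wise by the
   absolute-gradient criterion; the composite is thresholded at
   θ = µ + σ (image mean plus standard deviation) and a row/column
   cross-referencing peak finder reduces it to a *binary element map*:
   one (x, y) point per nanoparticle-loaded vesicle.
2. **clustering** — each frame's elements are partitioned into cells by
   seeded k-means (objective: within-cluster sum of squares
   Σᵢ Σ_{b∈Cᵢ} ‖b − µᵢ‖²), seeded from the previous frame's centroids.
   Elements farther than 30 µm from every seed spawn new seeds; seeds
   with no element within 12.5 µm are removed; clusters whose mean
   pairwise element separation exceeds 15 µm are re-clustered with an
   extra seed, accepted only if the mean silhouette score
   s = (b − a)/max(a, b) improves.
3. **tracking** — centroids of successive frames are linked greedily in
   ascending distance order within a 10 µm radius (one parent per
   centroid, at most two children per parent; a two-child parent is a
   division candidate; unmatched newcomers are new progenitors).
4. **mitosis** — each track carries its *mitotic curve*, the mean
   separation of its elements over time. Mitotic rounding condenses the
   vesicle cloud (separation falls below 0.6× its stable baseline);
   after cytokinesis the daughter clusters drive it back above the
   baseline, at which point the cluster is split into two daughters and
   a division event is recorded.
5. **lineage** — division events assemble binary lineage trees with
   per-cell motility vectors (net displacement / elapsed time, µm/h)
   and population statistics, including the two-point doubling time
   T = Δt / log₂(N₁/N₀).
6. **robustness** — an operational-range sweep re-runs detection and
   clustering across noise-filter thresholds, mapping element counts,
   centroid counts and centroid displacement.
7. **synthetic** — a ground-truthed simulator renders movies of
   proliferating, QD-labelled cells (perinuclear vesicle rings, mitotic
   condensation, binomial vesicle partitioning, focal-plane spread,
   Gaussian background noise) so every stage is testable at desk scale.

## Worked example

Simulate a two-cell movie (5-minute frames, ~8 h inter-mitotic time) and
run the full pipeline in memory:

```python
from mldcyto import PipelineConfig, SimConfig, run_pipeline, simulate_movie, to_newick

cfg = SimConfig(field_um=(120, 120), pixel_size_um=0.5, n_planes=3,
                n_frames=110, initial_cells=2, rng_seed=5, snr=2.5,
                vesicles_per_cell=(20, 40), imt_hours_mean=8.0,
                imt_hours_sd=0.2, min_initial_spacing_um=45,
                border_margin_um=30, initial_age_uniform=False)
frames, truth = simulate_movie(cfg)
result = run_pipeline(PipelineConfig(pixel_size_um=0.5), frames)

print("cells at t=0:       ", len(result.states[0].centroids))
print("cells at t=9.1 h:   ", len(result.states[-1].centroids))
print("divisions confirmed:", len(result.divisions))
for ev in result.divisions:
    print(f"  track {ev.parent_track_id} -> {ev.daughter_track_ids}, "
          f"rounding minimum at frame {ev.frame_of_minimum} "
          f"({ev.minimum_um:.1f} um), confirmed frame {ev.frame_confirmed} "
          f"(baseline {ev.baseline_um:.1f} um)")
print("true division frames:", [d["frame"] for d in truth.divisions])
print(to_newick(result.lineage))
```

prints

```
cells at t=0:        2
cells at t=9.1 h:    4
divisions confirmed: 2
  track 0 -> (6, 7), rounding minimum at frame 96 (0.0 um), confirmed frame 97 (baseline 4.6 um)
  track 1 -> (8, 9), rounding minimum at frame 102 (0.0 um), confirmed frame 103 (baseline 4.5 um)
true division frames: [96, 102]
(c8:1,c9:1)c1:8;
(c10:0.5,c11:0.5)c2:8.5;
c3:0;
c4:0;
c5:0;
c6:0;
c7:0;
```

Both programmed divisions are recovered at the correct frame: each
cell's mean element separation holds a ~4.5 µm baseline, collapses to a
single merged peak as the cell rounds up (minimum 0.0 µm), and crosses
back above the baseline one frame after cytokinesis, where the cluster
is split into two daughter tracks. The Newick forest (branch lengths in
hours) shows the two family trees; the zero-length roots `c3`–`c7` are
transient noise progenitors — sporadic above-threshold pixels that spawn
a seed for one frame and are retired by the proximity rules, exactly the
"rogue element" bookkeeping the seeding rules exist for.

## Command line

```sh
mldcyto simulate --out movie/ --seed 1 --frames 48 --cells 10
mldcyto run movie/ --out results/ --pixel-size-um 0.25
mldcyto detect movie/ --out elements.csv        # imaging stage only
mldcyto track elements.csv --out staged/        # clustering + linking
mldcyto sweep movie/ --out sweep.csv --plot sweep.png
mldcyto lineage results/                        # print the lineage summary
```

All intermediate artifacts are plain CSV/JSON/Newick; `run` writes a
manifest echoing the configuration so runs are reproducible byte for
byte.

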