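# shoalkit

Quantitative analysis of zebrafish social vision: how juvenile fish
recognize conspecifics from *biological motion* — the discrete, ~1.25 Hz
swim-bout kinematics of another fish — and how that percept drives
shoaling.  The package implements, as a reusable and tested pipeline, the
four analyses such a study runs, each exercisable end-to-end on synthetic
data generated in-package:

1. **Stimulus kinematics** (`shoalkit.stimuli`) — parametric virtual
   conspecifics: dots advancing in discrete jumps at bout frequency *f*
   or continuously at the display rate, on circular / trefoil /
   naturalistic paths; Gaussian-speed-profile bouts with controlled peak
   acceleration; looming discs; and all linear↔angular conversions
   (a 4 mm dot at 18 mm subtends 12.7°; a 5 mm/s jump at 1.5 Hz executed
   in one 60 Hz frame implies 12 m/s²).
2. **Shoaling metrics** (`shoalkit.behavior`) — attraction via a
   time-shift null: with IADr the real mean inter-animal distance per
   5-min chunk and IADs its mean over 10 cyclic time shifts of the
   neighbour trajectory,

   ```
   attraction = (IADs − IADr) / IADs
   ```

   plus egocentric (heading-up) neighbour-density maps, a radial-scan
   repulsion score for the short-range density void, velocity-peak bout
   detection, and the looming escape fraction (post/pre displacement
   ratio > 2).
3. **Neural tuning** (`shoalkit.tuning`) — ΔF/F epoching of calcium
   traces against 5 s pre-stimulus baselines, per-stimulus mean
   responses, percentile responsiveness filtering, and the bout
   preference index

   ```
   BPI = (mean ΔF/F(bout) − mean ΔF/F(continuous))
         / (mean ΔF/F(bout) + mean ΔF/F(continuous))
   ```

   with bout-like = 0.75–3 Hz, continuous = 6–60 Hz; neurons with
   BPI > 0.5 (a threefold bout response) are bout preference neurons
   (BPNs).  Tuning peaks are located with a degree-2 interpolating
   spline (log₂ axis for frequency).
4. **Anatomy & activity mapping** (`shoalkit.anatomy`, `shoalkit.cfos`)
   — per-hemisphere Gaussian KDE of cell coordinates normalized to cell
   counts with iso-density contours; and c-fos/elavl3 two-channel
   normalization, per-cluster bulk signal, Cohen's *d* effect matrices
   vs the no-stimulus condition with Bonferroni-corrected (α/3)
   two-tailed t-tests, and average-linkage hierarchical clustering of
   effect profiles.

`shoalkit.synthetic` generates every input class with known ground
truth — coupled/uncoupled swimming dyads, frequency-tuned calcium
populations (τ = 7 s kernel, 5 volumes/s downsampled to 1/s), clustered
3-D cell coordinates, and two-channel volumes with depth attenuation and
planted effect sizes — so every pipeline stage closes its testing loop.

## Worked example

```python
from shoalkit.synthetic import gen_dyad, gen_traces, FollowerParams, NeuronSimParams
from shoalkit.behavior import attraction, neighbor_density_map, repulsion_score
from shoalkit.tuning import make_schedule, epoch_dff, mean_responses, classify_bpns

partner, focal = gen_dyad("follower", FollowerParams(seed=0), duration_s=1200.0)
att = attraction(focal, partner)
rep = repulsion_score(neighbor_density_map(focal, partner))
print(f"attraction = {att.attraction:.3f}  "
      f"(IADr {att.iadr_mm.mean():.1f} mm, IADs {att.iads_mm.mean():.1f} mm)")
print(f"repulsion score = {rep.score:.2f}, density peak at r = {rep.r_peak_mm:.1f} mm")

schedule = make_schedule(seed=0)
traces, truth = gen_traces(NeuronSimParams(n_neurons=200, seed=0), schedule)
table = mean_responses(epoch_dff(traces, schedule))
res = classify_bpns(table, freq_map=dict(zip(schedule["label"], schedule["freq_hz"])))
print(f"BPNs: {res['is_bpn'].sum()}/{len(res)} classified "
      f"({(truth['cls'] == 'selective').sum()} planted selective)")
```

prints

```
attraction = 0.730  (IADr 10.9 mm, IADs 40.5 mm)
repulsion score = 1.53, density peak at r = 9.5 mm
BPNs: 30/200 classified (30 planted selective)
```

The follower stays ~11 mm from its partner while the time-shift null
sits at ~40 mm, giving strong attraction; its exclusion radius carves a
central void in the neighbour map (density peak away from the centre,
positive repulsion score); and all 30 planted frequency-tuned neurons —
and no untuned ones — are recovered as BPNs.

The same analyses are reachable from the shell:

```sh
shoalkit simulate dyad --out sim --seed 0
shoalkit behavior --focal sim/focal.csv --neighbor sim/partner.csv --out results
shoalkit selftest
```

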