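# toadhop

Forelimb landing-preparation kinematics for hopping anurans.

Cane toads land forelimbs-first, absorbing the hop's impact energy with
their arms.  A landing is stable when the ground reaction force (GRF)
passes close to the centre of mass; since at impact the GRF is
approximately parallel to the body's velocity, a toad can minimize
toppling torques by aligning its forelimb angle **α** (wrist–mid-humerus
segment vs horizontal) with the impact angle **γ_TD** (the velocity-vector
angle of the snout at touchdown).  `toadhop` implements the full analysis
chain for testing this idea with marker-based kinematics:

* quintic-spline smoothing and analytic differentiation of 3-D marker
  trajectories (wrist, mid-humerus, snout) sampled at 500 frames/s;
* hop event detection: initiation T₀ (first snout speed > 5 cm/s, with an
  upward-velocity inclusion filter), lift-off (sustained free-fall
  acceleration), and touchdown (wrist reaching the landing surface);
* the alignment statistic: δ = γ − α per frame, a pooled band around mean
  δ_TD, the alignment time T_a (first sustained band entry), onsets
  O_T0 / O_LO, duration D_a, excursion, and continual-alignment flags;
* a planar rigid-body landing model: net torque about the COM as a
  function of arm angle, impact angle and geometry, with a
  torque-minimizing arm-angle solver;
* statistics: per-animal OLS of α_TD on γ_TD, random-intercept linear
  mixed models fitted by maximum likelihood with full-vs-null
  likelihood-ratio tests, and means-of-individual-means summaries;
* a synthetic-hop generator reproducing the study design (6 animals ×
  three platform heights — flat 0 cm, low 5 cm, high 9 cm — with 6–12
  hops each) plus exact ground truth, used to validate the whole chain.

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

Simulate a cohort, analyze it, and fit the headline statistics:

```python
import toadhop as th

cfg = th.HopSimConfig(hops_per_treatment=(8, 8))
recordings, truth = th.simulate_cohort(cfg, seed=1)
metrics, series, info = th.analyze_recordings(recordings)

included = metrics[metrics.included]
print("included hops:", len(included), "of", len(metrics))
print("mean delta_TD: %.2f deg"
      % included.groupby("animal_id").delta_td.mean().mean())
print(included.groupby("treatment").d_a.mean().round(3))
print("continually aligned: %.3f"
      % th.continual_alignment_fraction(metrics))
```

which prints

```
included hops: 143 of 144
mean delta_TD: -5.59 deg
treatment
flat    0.256
high    0.302
low     0.297
Name: d_a, dtype: float64
continually aligned: 0.986
```

The cohort mean of individual-mean δ_TD (−5.6°) recovers the generator's
population target (−4.1°) to within the between-animal sampling noise of
six random intercepts; the mean alignment duration D_a grows from flat
(256 ms) through low (297 ms) to high (302 ms) platforms, because toads
align before lift-off and longer falls simply extend the tracked aerial
phase; and 98.6% of hops stay inside the alignment band from T_a through
touchdown.  `th.stats_report(metrics)` formats the per-animal
regressions, the α_TD mixed models, and the onset/duration
likelihood-ratio tests into a text report.

The same pipeline runs from the shell:

```sh
toadhop simulate --seed 1 --outdir sim        # trajectory + ground-truth CSVs
toadhop analyze sim/trajectories.csv --outdir analysis
toadhop stats analysis/metrics.csv
toadhop torque-map --out torque_map.csv       # alpha x gamma torque sweep
toadhop full --seed 1 --outdir run            # simulate + analyze + stats
```

Trajectory CSVs are long-format with columns
`hop_id, animal_id, treatment, time_s, marker, x_m, y_m, z_m`; recorded
data in that schema can be analyzed directly with `toadhop analyze`.

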