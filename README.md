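# nursetag

Nursing kinematics of humpback whale (*Megaptera novaeangliae*) mother–calf
pairs from suction-cup bio-logging tags, for movement ecologists working
with combined video + motion-sensor deployments (CATS-style tags) on
feeding grounds.

Nursing is brief, subsurface, and rare — of the order of 0.3% of daytime
video on feeding grounds — so detecting a kinematic signature requires
comparing visually verified nursing events against carefully matched
baseline behaviour. `nursetag` implements that full analysis chain:

1. **I/O** (`io_core`) — plain-text tag records (tri-axial specific force
   in m/s², depth, speed) and typed event logs (nursing, probable nursing,
   proximity, foraging, poor-video intervals), plus packaged reference
   tables from four calf and two mother deployments.
2. **Synthetic deployments** (`synthetic`) — a seeded generator producing
   dive cycles, heave-axis fluke stroking, gravity-consistent pitch, and
   nursing events with configurable effect sizes; every downstream stage
   is testable against its ground truth.
3. **Kinematics** (`kinematics`) — decimation to 10 Hz, whale-frame
   rotation from a calm calibration window, static/dynamic separation by
   centred running mean, overall dynamic body acceleration
   (ODBA = |dₓ| + |d_y| + |d_z|), pitch/roll, and fluke-stroke detection
   by band-pass + Schmitt-trigger zero crossings.
4. **Dive phases** (`dive_phases`) — breath-to-breath dives split into
   descending (surface → first attainment of maximum depth), optional
   horizontal, and ascending (the earliest suffix that descends toward the
   surface without ever rising more than 10 m above its running minimum
   depth).
5. **Sampling** (`sampling`) — the randomized, phase-matched design:
   every nursing event at its true duration, plus per phase nursed in,
   15 (calves) or 9 (mothers) disjoint 30 s non-nursing windows drawn by
   uniform random start + forward scan, avoiding nursing, probable-nursing
   and poor-video time, with an exact feasibility check.
6. **Metrics & statistics** (`metrics_stats`) — per-segment depth/speed/
   ODBA/fluke-stroke-rate (FSR, strokes·s⁻¹) and circular angle means; a
   linear mixed model `response ~ nursing × phase` with a random intercept
   per individual and a Wald F-test for the nursing effect
   (F(1, n − rank X − (g−1))); nursing/proximity/foraging time budgets by
   exact interval arithmetic.

## Worked example

```python
import nursetag as nt

spec = nt.DiveSpec(surface_s=45, descent_rate=0.5, max_depth=60,
                   bottom_s=180, ascent_rate=0.5)
cfg = nt.SimConfig(seed=3, fs_hi=40.0, dive_plan=(spec,) * 6,
                   nursing_events=((100.0, 27.0),))
record, truth = nt.simulate_deployment(cfg, "demo-01", role="calf")

proc = nt.process_record(record)                      # 10 Hz, ODBA, strokes
table = nt.build_phase_table(proc.depth, proc.fs)     # dive phases
segs = nt.build_segment_table({"demo-01": proc}, {"demo-01": table},
                              truth.events, nt.SamplingConfig(seed=1))
metrics = nt.metrics_table(segs, {"demo-01": proc})
nursing = metrics[metrics.is_nursing]
baseline = metrics[~metrics.is_nursing]
print(f"nursing  ODBA {nursing.mean_odba.mean():.3f} m/s^2, "
      f"FSR {nursing.fsr.mean():.3f} strokes/s")
print(f"baseline ODBA {baseline.mean_odba.mean():.3f} m/s^2, "
      f"FSR {baseline.fsr.mean():.3f} strokes/s")
```

prints

```
nursing  ODBA 0.243 m/s^2, FSR 0.407 strokes/s
baseline ODBA 0.205 m/s^2, FSR 0.247 strokes/s
```

i.e. during the simulated nursing event the calf strokes faster
(0.41 vs 0.25 strokes/s; the configured ×1.7 gait-frequency effect) and
carries higher ODBA (0.24 vs 0.20 m/s²; the configured ×1.5 amplitude
effect, partly offset by the frequency shift moving energy through the
5 s running-mean separator differently). The same pipeline applied to the
packaged reference tables reproduces the field results: 11 nursing events
averaging 23 s (±7 s), ~0.3% of 20.9 h of good-quality video, calves more
active while nursing and mothers markedly less so.

There is also a CLI (`nursetag simulate|process|phases|sample|analyze`)
over the same functions; `nursetag analyze` writes budget, segment,
comparison and model tables for a directory of deployments.

## Limitations

Speed is consumed as a provided channel (no estimation from tag
vibrations); heading is not computed (magnetometer calibration is
deployment-specific); phase boundaries are an operationalization of a
procedure originally done by visual assessment. See `docs/methods.md` for
the model, parameter defaults, and numerical choices.
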