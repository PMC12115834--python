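# loomstrike

Analysis toolkit for *Drosophila* escape-behaviour experiments under
aerial predation: looming-stimulus modelling, 3D damselfly-attack
kinematics, escape-ethogram timing and mode classification, and
prey-survival competition indices — plus a seeded synthetic-data
generator so every stage is testable without videography.

## Who this is for

Neuroethologists quantifying how the giant-fibre (GF) escape pathway
contributes to survival: the GFs drive the fly's fastest ("short mode")
take-off, and the question is how looming geometry, predator attack
kinematics and take-off timing combine into a survival advantage.

## The models and statistics at the core

**Looming stimulus.** A dark disk mimicking an object of radius *r*
approaching at constant speed *v* subtends, *t* ms before virtual
contact,

θ(t) = 2 tan⁻¹((r/v) / t)

so the whole expansion profile depends only on the size-to-speed ratio
*r/v* (ms). `loom` evaluates this law, inverts it (time to reach a given
angle), and locates the hypothetical time-of-contact so take-off
latencies can be scored against it.

**Attack kinematics.** Digitized per-frame 3D points (damselfly head,
damselfly tail, fly centroid; mm at 1000 fps) are smoothed per axis with
a zero-phase Butterworth filter followed by a Savitzky–Golay filter,
then differentiated centrally into speed (m s⁻¹) and acceleration
(m s⁻²). The attack window starts after the last hover (sustained
near-zero speed) and ends at contact or escape (t = 0). Prey-centered
angles: elevation ∈ [−90°, 90°], azimuth folded into [0°, 180°] by
left–right symmetry (|Y|). The predator's retinal angular size at the
end of the event is θ = 2 tan⁻¹(r/d) with 2r the head width and d the
head-to-prey distance; ~40° is the GF activation threshold.

**Ethograms.** A take-off sequence runs from the first frame of wing
raising (*reaction time*) to the first frame the middle legs leave the
ground (*escape time*); its duration separates short (< 7 ms,
GF-driven) from long (> 7 ms) mode. The 7 ms boundary can be
re-estimated as the posterior-equality point of a two-component Gaussian
mixture on log-durations.

**Competition indices.** With two wing-clip-marked groups competed under
predation, per-trial indices normalize the eaten-count difference:
WCB = (left − right)/(left + right) (marking control) and
PCI = (silenced − control)/(silenced + control); both in [−1, 1], tested
against 0 by one-sample Student *t*. Escape proportions get Wilson score
intervals; group contrasts use two-sample *t* and one-way ANOVA with
Tukey HSD.

## Worked example

Run the bundled study-shaped scenario (two genotypes — GF-intact
`control` and GF-silenced `silenced` — with the silenced group lacking
the short mode and tolerating closer predator approach):

```python
from loomstrike import RunConfig, run_full_analysis

report = run_full_analysis(RunConfig(seed=1, scenario="paper_shaped"))

e, k, c = report["ethogram"], report["kinematics"], report["competition"]
print(f"take-off rate: control {e['control']['takeoff_rate']:.3f}, "
      f"silenced {e['silenced']['takeoff_rate']:.3f}")
print(f"short-mode fraction: {e['control']['short_mode_fraction']:.3f} vs "
      f"{e['silenced']['short_mode_fraction']:.3f}")
print(f"mode boundary estimate: {e['mode_boundary_ms']:.2f} ms")
print(f"reaction-time p {e['timing']['reaction_time']['p']:.3f}, "
      f"escape-time p {e['timing']['escape_time']['p']:.4f}")
print(f"escape proportion: {k['control']['escape_proportion']:.3f} vs "
      f"{k['silenced']['escape_proportion']:.3f}")
print(f"PCI {c['pci']['mean']:.3f} ± {c['pci']['sem']:.3f} (p = {c['pci']['p']:.2e})")
```

prints

```
take-off rate: control 0.863, silenced 0.483
short-mode fraction: 0.609 vs 0.000
mode boundary estimate: 6.93 ms
reaction-time p 0.498, escape-time p 0.0270
escape proportion: 0.933 vs 0.400
PCI 0.370 ± 0.043 (p = 6.10e-05)
```

Reading the numbers: silencing leaves reaction times statistically
indistinguishable (p ≈ 0.5) but lengthens escape times (p ≈ 0.03)
because the short take-off mode disappears (0.61 → 0.00); the escape
proportion against simulated attacks drops to roughly half; and in
competition the silenced flies are eaten preferentially (mean PCI
significantly above 0). The data-driven mixture boundary (6.93 ms)
brackets the fixed 7 ms classification threshold.

The same analyses run from the shell on CSV inputs:

```sh
loomstrike simulate all --scenario paper_shaped --seed 1 --out data/
loomstrike ethogram --in data/ethograms.csv --out etho_summary.json
loomstrike compete --in data/trials.csv --out indices.csv --report comp.json
loomstrike kinematics --traj data/attack_control_000.csv \
    --meta data/attack_control_000.json --out kin/
loomstrike loom --rv 40 --out profile.csv
```

## Layout

- `src/loomstrike/loom.py` — looming angular-size law and contact timing
- `src/loomstrike/kinematics.py` — smoothing, differentiation, windows, angles
- `src/loomstrike/ethogram.py` — take-off timing, mode classification, mixture boundary
- `src/loomstrike/competition.py` — WCB/PCI, t-tests, Wilson intervals, ANOVA+Tukey
- `src/loomstrike/synth.py` — seeded generators and the two scenarios
- `src/loomstrike/config.py`, `pipeline.py`, `cli.py` — configuration, driver, CLI
- `configs/` — the two scenario definitions in YAML
- `docs/methods.md` — modelling assumptions, defaults and limitations
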