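"""The simulator's closed-form anchor: sustained inhibition vs ΔFRET.

With no activity-independent turnover (k_deg = 0), a sustained fractional
inhibition f moves the intact-sensor steady state from k_syn/(k_cl a0) to
k_syn/(k_cl a0 (1-f)), so the measured ΔFRET plateaus at 100 f/(1-f) %.
This script pushes noiseless sessions through the *entire* pipeline and
compares against that closed form.
"""

from photofret import (
    DrugEffectProfile,
    SensorKineticsParams,
    SimulatedCohortSpec,
    TreatmentArm,
    process_experiment,
    simulate_cohort,
)

params = SensorKineticsParams(k_deg=0.0, noise_sd=0.0, bleach_rate=0.0)
print("  f    pipeline ΔFRET(3h)   closed form 100 f/(1-f)")
for f in (0.1, 0.25, 0.5):
    arm = TreatmentArm(
        "inhibitor", DrugEffectProfile("inhibitor", magnitude=f, k_on=50.0, k_off=0.0)
    )
    spec = SimulatedCohortSpec(n_animals=1, treatments=(arm,), jitter_cv=0.0, seed=1)
    sim = simulate_cohort(spec, params)
    res = process_experiment(sim.to_manifest(), recordings=sim.recordings)
    d3 = res.cohort_table.query("hour == 3.0").delta_fret.iloc[0]
    print(f" {f:4.2f}      {d3:8.2f} %            {100 * f / (1 - f):8.2f} %")

# Residual gaps reflect only the finite relaxation time of the sensor pool
# (the slowest case, f = 0.5, has rate k_cl a0 (1-f) = 1.5/h and is ~1% shy
# of its asymptote at 3 h) — the measurement chain itself adds no bias.
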