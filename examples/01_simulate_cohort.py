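"""Simulate a photometry cohort and write its recordings + manifest to disk.

Eight animals each receive vehicle and a calpain inhibitor on separate days
(order balanced by a Latin square), with 2-minute sessions at 0/1/2/3 h
post-dose: a 1-minute dark lead-in then 1 minute of interleaved
excitation/control frames at 41 fps.
"""

import tempfile
from pathlib import Path

from photofret import (
    DrugEffectProfile,
    SessionSchedule,
    SimulatedCohortSpec,
    TreatmentArm,
    load_manifest,
    read_recording,
    simulate_cohort,
    validate_stream,
)

spec = SimulatedCohortSpec(
    n_animals=8,
    treatments=(
        TreatmentArm("vehicle", DrugEffectProfile("vehicle")),
        TreatmentArm("calpeptin", DrugEffectProfile("inhibitor", magnitude=0.25), dose=2.0),
    ),
    seed=42,
)
sim = simulate_cohort(spec)

with tempfile.TemporaryDirectory() as tmp:
    manifest_path = sim.write(tmp)
    manifest = load_manifest(manifest_path)
    print(f"wrote {len(manifest.sessions)} session files under {tmp}")

    first = manifest.sessions[0]
    frames = read_recording(manifest.resolve(first))
    qc = validate_stream(frames, SessionSchedule())
    print(f"first session: {first.animal_id} / {first.treatment} / hour {first.hour:.0f}")
    print(f"  {qc.n_frames} frames over {qc.duration_s:.1f} s, "
          f"{qc.n_on} LED-on vs {qc.n_off} LED-off in the interleaved minute")

# 64 sessions = 8 animals x 2 treatment days x 4 hours; ~1230 frames per LED
# state is the one-minute interleaved window at 41 fps split between
# excitation and control frames.
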