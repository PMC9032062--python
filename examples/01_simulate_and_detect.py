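"""Simulate a small synthetic cohort and run the rule-based rotor detector.

Generates noise-free 30 s, 20-channel unipolar acquisitions (half of
them containing rotor episodes), runs the staircase rule detector, and
compares detections against the simulator's ground truth.
"""

from rotordetect.ruleset import detect_rotational_activity
from rotordetect.simulate import SimConfig, simulate_cohort

config = SimConfig(noise_sd=0.0, farfield_amplitude=0.0, rotor_fraction=0.5,
                   seed=42)
cohort = simulate_cohort(config, n_patients=4, acquisitions_per_patient=2)

tp = fn = fp_acq = 0
for acq, truth in cohort:
    detected = detect_rotational_activity(acq)
    for ev in truth:
        hit = any(
            d.chirality == ev.chirality
            and d.overlap_ms(ev.t_start, ev.t_end) >= 0.5 * ev.duration_ms
            for d in detected
        )
        tp += hit
        fn += not hit
    if not truth and detected:
        fp_acq += 1
    desc = ", ".join(
        f"{e.chirality[:3]} x{e.n_rotations} @ {e.t_start / 1000:.1f}s"
        for e in detected
    ) or "none"
    print(f"{acq.patient_id} acq{acq.acq_index}: "
          f"{len(truth)} true event(s), detected: {desc}")

print(f"\nrecovered {tp}/{tp + fn} simulated rotors; "
      f"{fp_acq} rotor-free acquisitions with false detections")
print("Each detection is a run of >= 3 consecutive same-chirality rotations "
      "whose ring LATs span > 50% of the dominant cycle.")
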