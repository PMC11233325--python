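"""Detect rest bouts and show the exact time accounting.

Rest is any maximal run of frames below the stage's speed threshold
lasting at least 60 s. Every frame of the recording is accounted for:
active + in-bout rest + sub-minute inactivity + tracking gaps = total.
"""

import fishrhythm as fr

schedule = fr.LightSchedule()
params = fr.species_preset("nocturnal", stage="adult", seed=2, fps=5.0)

(traj,), _ = fr.simulate_trajectory(params, schedule)
speed = fr.compute_speed(traj)
threshold = fr.threshold_for_stage("adult")  # 4 cm/s = 40 mm/s
bouts = fr.detect_rest_bouts(speed, threshold)
acc = fr.time_accounting(speed, threshold)

print(f"rest bouts detected : {len(bouts)}")
print(f"longest bout        : {max(b.duration_s for b in bouts):.0f} s")
print(f"total rest          : {acc.rest_s / 3600:.2f} h")
print(f"total active        : {acc.active_s / 3600:.2f} h")
print(f"sub-minute inactive : {acc.submin_inactive_s / 3600:.2f} h")
print(f"tracking gaps       : {acc.gap_s / 3600:.2f} h")
total = acc.active_s + acc.rest_s + acc.submin_inactive_s + acc.gap_s
print(f"sums to             : {total / 3600:.2f} h of {acc.total_s / 3600:.2f} h recorded")
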