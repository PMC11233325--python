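"""Plot 24 h zeitgeber activity traces with the dark period shaded.

Simulates one subject per phenotype and writes a small figure of their
hourly locomotion profiles to ``profiles.png``.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import fishrhythm as fr
from fishrhythm.plotting import plot_profile

schedule = fr.LightSchedule()
fig, axes = plt.subplots(2, 2, figsize=(10, 6), sharex=True)

for ax, phenotype in zip(axes.ravel(), ("diurnal", "nocturnal", "crepuscular", "arrhythmic")):
    params = fr.species_preset(phenotype, stage="juvenile", seed=5, fps=5.0)
    (traj,), _ = fr.simulate_trajectory(params, schedule)
    speed = fr.compute_speed(traj)
    bouts = fr.detect_rest_bouts(speed, fr.threshold_for_stage("juvenile"))
    profile = fr.bin_hourly(traj, bouts, schedule, speed=speed)
    plot_profile(profile, schedule, ax=ax)
    ax.set_title(phenotype)

fig.tight_layout()
fig.savefig("profiles.png", dpi=120)
print("wrote profiles.png: hourly locomotion per phenotype, dark phase shaded")
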