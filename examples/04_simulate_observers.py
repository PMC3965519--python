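"""Simulate a full adjustment-task study with synthetic observers.

Twelve simulated participants adjust the velocity profile until it looks
uniform, in three trajectory orientations, from five starting profiles with
ten repetitions each.  The observer defaults reproduce the published
per-orientation PSE and JND; the staircase replays the forward/backward
button protocol.
"""

import plmotion as plm

obs = plm.ObserverModel()  # defaults: PSE 10.08 / 9.15 / 8.66, JND-matched noise
table = plm.simulate_experiment(obs, seed=42)

print(f"simulated trials: {len(table)} "
      f"(12 participants x 3 orientations x 5 starts x 10 repetitions)")
print(f"mean adjustments per trial: {table['n_adjustments'].mean():.1f}")
print()
print("orientation   median   IQR   start-median range")
for c in ("0", "90", "180"):
    s = plm.summarize(table, c)
    print(f"{c:>8} deg   {s.median:6.1f}  {s.iqr:4.1f}   {s.start_median_range:5.1f}")
print()
print("Responses cluster near K10 (the pendular 1g profile), tightest for the")
print("upright 0 deg orientation -- the pattern the pipeline is built to fit.")
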