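"""Integrate the reference pendulum and characterize its motion.

The virtual pendulum (rod 0.64823 m, release at 45 deg) is solved with
fixed-step RK4 at 10 kHz; the oscillation period is measured from zero
crossings of the angular velocity and compared with the closed-form
elliptic-integral period, and the solution is compared against the
equal-amplitude harmonic motion.
"""

import plmotion as plm

params = plm.REFERENCE_PARAMS
trace = plm.solve_pendulum(params)

T = plm.measure_period(trace)
pos_dev, vel_dev = plm.harmonic_deviation(trace)
energy = trace.energy(params)
drift = abs(energy - energy[0]).max()

print(f"measured period        : {T:.4f} s")
print(f"closed-form period     : {params.T:.4f} s")
print(f"small-angle period     : {params.small_angle_period:.4f} s")
print(f"harmonic deviation     : {pos_dev:.2f} % (position), {vel_dev:.2f} % (velocity)")
print(f"energy drift over trace: {drift:.2e} (specific units)")
print()
print("The large-amplitude period exceeds the small-angle value by ~4%, yet")
print("the motion stays within ~1% of a pure harmonic of the same amplitude")
print("and period -- the '1g' stimulus is quasi-harmonic.")
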