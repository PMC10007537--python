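"""Generate a synthetic reference-IMU trace and score a rollout against it.

Creates the 5 s pelvis-orientation reference (periodic gait oscillation
plus sensor noise), walks the synthetic walker open loop, and prints the
per-axis RMSE between what a pelvis IMU would have recorded and the
reference — the same metric used to evaluate trained agents.
"""

import numpy as np

from gaitrl import (
    SyntheticWalker,
    generate_reference_imu,
    observe_imu,
    reference_gait_excitation,
    rmse_per_axis,
)
from gaitrl.eval_io import align_traces

reference = generate_reference_imu(duration=5.0, dt=0.01, seed=0)
print(f"reference: {len(reference)} samples at {reference.dt} s, "
      f"gait period {reference.metadata['gait_period_s']} s")

walker = SyntheticWalker()
walker.reset()
observed = []
for _ in range(500):
    _, _, done = walker.step(reference_gait_excitation(walker.state.phase))
    observed.append(observe_imu(walker.state).as_array())
    if done:
        break

ref, obs = align_traces(reference, np.array(observed))
roll, pitch, yaw = rmse_per_axis(ref, obs)
print(f"RMSE vs reference: roll {roll:.4f}, pitch {pitch:.4f}, "
      f"yaw {yaw:.4f} rad")
print()
print("Values near the reference oscillation amplitude (~0.04-0.06 rad)")
print("mean the rollout is phase-mismatched but posturally neutral; a")
print("trained IMU-constrained agent is pushed below an unconstrained one.")
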