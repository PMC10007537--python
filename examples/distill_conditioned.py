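"""Stage two: distill a trained policy into target-velocity-conditioned
networks.

Trains a small stage-one agent, then minimizes the KL divergence between
the conditioned student policy and the teacher (and the squared error
between critics) on states replayed from the stage-one experience buffer,
printing the loss trajectory.
"""

import numpy as np

from gaitrl import RewardWeights, SyntheticWalker, generate_reference_imu
from gaitrl.distill import distill_stage_two
from gaitrl.environment import make_target_field
from gaitrl.experiments import desk_train_config
from gaitrl.train import train_stage_one

cfg = desk_train_config(epochs=4)
reference = generate_reference_imu(duration=5.0, dt=0.01, seed=2)
walker = SyntheticWalker()
result = train_stage_one(walker, reference, RewardWeights(), cfg, seed=2)

field = make_target_field(np.zeros(2))  # field for the (5, 0) target
student, history = distill_stage_two(
    result.agent.policy, result.agent.critics[0], result.replay,
    field, RewardWeights(), hidden=(64, 64), steps=120, batch_size=64,
    lr=1e-3, seed=2,
)

print("step   KL(policy)   MSE(critic)")
for k in range(0, len(history), 20):
    h = history[k]
    print(f"{k:4d}   {h['J_pi_s']:10.4f}   {h['J_Q_s']:11.4f}")
h = history[-1]
print(f"{len(history)-1:4d}   {h['J_pi_s']:10.4f}   {h['J_Q_s']:11.4f}")
print(f"\nstudent policy input dim: {student.policy.obs_dim} "
      f"(= {result.agent.policy.obs_dim} state + 242 flattened field)")
print("\nThe KL falls as the conditioned student absorbs the teacher's")
print("behavior while gaining the target-velocity field as an input.")
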