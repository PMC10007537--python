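# Methods

This note documents the models, parameters, numerical choices and known
limitations of `gaitrl`, in the package's own terms.

## Problem setting

A muscle-actuated agent must walk 5 m in a straight line at a comfortable
speed, guided by (a) trajectory-optimization rewards — track a local
target-velocity field with minimal effort while staying upright — and
(b) a bio-inspired constraint: per-axis penalties on the deviation of the
simulated pelvis orientation (roll, pitch, yaw Euler angles, intrinsic
Z-X-Y, wrapped to (−π, π]) from a reference pelvis-IMU trace of the same
task. The scientific question the pipeline operationalizes: does the
reference-motion constraint make the learned gait both more human-like
(lower orientation RMSE) and easier to learn (no loss, ideally a gain, in
return)?

## Reward model

The per-timestep reward is a 10-vector in fixed order
`(r_env, r_clp, r_vdp, r_pvb, r_dep, r_tab, r_entropy, r_IMUroll,
r_IMUpitch, r_IMUyaw)`; the scalar reward is the weighted sum with all
weights defaulting to 1 (IMU weights included). Notes on individual
terms:

* **r_env** over a window is `0.1·(non-fallen steps) + w_step·Σ in-step Δt
  − w_vel·‖Σ in-step (v_vel−v_tgt)Δt‖ − w_eff·Σ in-step Σ_m A_m²Δt`.
  The windowed velocity cost is a norm of a time integral and is not
  additive per step, so online training uses the per-step decomposition
  (norm of the instantaneous deviation); the two agree when deviation is
  zero. `w_step`, `w_vel`, `w_eff` have no published values and default
  to 1, exposed in config.
* **r_clp** (crossing-legs penalty) is `min(0, s)` with `s` the scalar
  triple product `((r_right−r_pelvis) × (r_left−r_pelvis)) ·
  (r_head−r_pelvis)`; in the package's right-handed x-forward/y-left/z-up
  frame this is positive for uncrossed legs and flips sign when the feet
  cross the midline.
* **r_tab** is the stopping bonus: 0 for ‖v_tgt‖ > 0.7, 0.1 for
  0.5 < ‖v_tgt‖ ≤ 0.7, and `1 − 3.5‖v_tgt‖²` at or below 0.5.
* **r_entropy** is `α·(−log π(a|s))` at the sampled action with the
  current temperature. The entropy signal therefore appears both as a
  reward component and (as `α log π`) in the actor objective; both are
  implemented with independent toggles and both are on by default,
  following the printed formulation. The critic bootstrap does *not* add
  a further entropy term by default (`entropy_in_bootstrap = False`),
  since the entropy head already carries it.
* **IMU terms** compare the reference trace, resampled to the 0.01 s
  simulation step and aligned at episode start, with the observed pelvis
  orientation; angle differences are wrapped before the absolute value so
  a ±π seam crossing is not a ~2π error. No gait-phase warping is
  applied.

## Learner

Soft Actor-Critic with one Q head per reward component. The critic loss
is a vector (one squared-error term per head against that head's
bootstrapped target); the actor maximizes the weighted scalar
`Σᵢ wᵢQᵢ(s, a~π)` minus `α log π`. Design points:

* **Twin critics** with element-wise minimum at the bootstrap (and at the
  actor's Q) are the default; a config flag restores the literal
  single-critic formulation.
* **n-step targets** (default n = 5, configurable 1–10) with
  **invertible value rescaling** `h(x) = sign(x)(√(|x|+1)−1) + εx`,
  ε = 10⁻³; targets are decompressed with the closed-form `h⁻¹`,
  discounted, and recompressed. Round trip verified to ≤ 10⁻⁹.
* **Temperature** α is learned against target entropy H̄ = −dim(action)
  (the usual convention; unstated in the source formulation).
* **Head surgery**: removing head i zeroes its output column, bias and
  scalarization weight; adding appends a freshly initialized column.
  Untouched heads are bitwise unchanged, and a zero-weighted head is
  provably equivalent to an absent head in the actor objective (tested).
* **Networks**: dense MLPs in numpy with hand-written reverse-mode
  gradients and Adam. Full-model defaults: four hidden layers, width 256,
  ELU (policy) / ReLU (critic), γ = 0.99, learning rates 3×10⁻⁵ (policy)
  and 10⁻⁴ (critic), batch ≈ 256 transitions, replay capacity 250,000,
  segment length 10. The "256" critic width resolves a width-vs-depth
  ambiguity in the source description in favor of width. Desk-scale runs
  on the synthetic walker use two 64-wide layers and higher learning
  rates (3×10⁻⁴ / 10⁻³), sized to its 27-dim observation.
* The policy is a factorized Gaussian over pre-squash actions with
  `a = (tanh(u)+1)/2` mapping into the excitation box [0,1]^A and the
  exact Jacobian correction in log π; log-σ is smoothly clamped to
  [−5, 2] via a tanh reparametrization so the clamp keeps a gradient.

## Replay

Episodes are stored as fixed-length segments (L = 10) that overlap by
L/2 and never cross episode boundaries; a tail shorter than L is
right-padded by repeating its final transition with a mask that excludes
padding from losses. Priorities are `p = 0.9·max δ + 0.1·mean δ` over the
segment's scalarized n-step TD-error magnitudes; new segments enter at
the current maximum priority so each is sampled at least once. Sampling
is ∝ p^α with importance weights `(N·P)^(−β)` normalized by their
maximum; α = β anneal linearly 0.1 → 0.9 over 3000 updates. Eviction is
FIFO at a transition-count capacity. The parallel data-collection worker
count is a config hook; the shipped mode is single-process and exactly
reproducible.

## Distillation (stage two)

Offline, on states replayed from the saved stage-one buffer: the student
policy π^s(a|s, v) and critic Q^s(s, v, a) receive the flattened 2×11×11
target-velocity field v, jittered per element with zero-mean Gaussian
noise of **variance** 0.1 (the source does not say variance or standard
deviation; variance is chosen and config-exposed). The policy loss is the
closed-form KL between the factorized Gaussians, in the mode-seeking
direction KL(student ‖ teacher) as printed; the critic loss is the
squared error between weighted-scalar Q values at each network's own
sampled action, using one shared pre-squash noise draw (common random
numbers) so exact self-distillation measures exactly zero. Teacher
parameters are never updated (bitwise-frozen, tested). Stage-two
defaults: hidden width 1024 (full model), learning rate 10⁻⁴, batch 128.

## Synthetic walker

A deliberately simple planar biped that preserves the *interface* of a
musculoskeletal simulator: `reset(seed) → obs`,
`step(action) → (obs, kinematics, done)`, six excitation channels (hip
extensor/flexor and ankle per leg) with first-order activation dynamics
(τ = 0.05 s), a phase oscillator whose rate scales with mean activation
(cadence ≈ 1.1 s at the fixture's activity level), alternating foot
contact with a short double-stance window (in-step ⇔ exactly one foot in
contact), thrust from stance-side extensor/ankle drive, braking from
flexors, lateral push and yaw rate from left-right asymmetry, and a
height proxy that decays passively (fall below 0.5 of nominal ends the
episode; zero excitation falls in ~1.5 s with zero displacement).

Pelvis orientation is the walker's scientific payload: roll and pitch
track gait-locked oscillation targets (amplitudes 0.06 / 0.04 rad at
speed), and — critically — sustained drive above a neutral level pitches
the pelvis (lean gain 0.6 rad per unit excess drive, low-passed at
0.5 s) while sustained left-right asymmetry rolls and yaws it. Without
this coupling an orientation-agnostic controller could not *express* an
orientation error and the reference constraint would be vacuous; with
it, speed-greedy or asymmetric gaits visibly tilt and wander, as
unconstrained musculoskeletal agents do. The constants were fixed so
that the shipped symmetric open-loop gait fixture walks ≥ 5 m in ≤ 10 s
with a neutral pelvis.

The target-velocity field is an 11×11 grid of 0.5 m cells centered on
the agent; each cell's vector points at the target with magnitude equal
to a cruise speed (1.25 m/s) tapering linearly to zero from 0.5 m out
and exactly zero inside a 0.36 m stopping radius (which covers any cell
center lying in the target's cell). The walker's observation is a
documented 27-entry layout (velocities, height, orientation and rates,
hip angles/rates, activations, contacts, gait phase, local target
velocity, vector to target). The 97/22/339/361 constants of the full
model are kept as a layout contract and self-check; the composition of
the full 97-dim state is not published and is treated as reconstructed.

## Synthetic reference IMU

Per axis: a sinusoid at the gait frequency (pitch at twice it — two
peaks per stride), plus linear drift and seeded Gaussian noise. Study
defaults: gait period 1.1 s, amplitudes 0.06/0.04/0.05 rad
(roll/pitch/yaw), zero drift, noise 0.005 rad, 5 s at 100 Hz
(500 samples) — pelvic oscillation amplitudes of a few degrees at a
comfortable walk. It emulates a single pelvis-mounted sensor recording
of a straight 5 m walk; it does not model bias instability, soft-tissue
artifact, or stride-to-stride variability. Consequently, passing the
desk-scale comparison shows the *pipeline* responds to a reference
constraint as intended — not that a particular clinical recording would
be reproduced by the full musculoskeletal model.

## Evaluation protocol and scale

Learning curves record per-epoch mean/min/max of episode returns
scalarized with a fixed **evaluation weight vector** — the baseline
weights with IMU components zeroed — so IMU-constrained and baseline
curves live on one scale (each run's own scalarization would make the
comparison ill-posed: the IMU arm carries three extra non-positive
terms). Curve smoothing is a trailing window of 10 epochs. RMSE is
computed per axis on wrapped angular residuals over the first 5 s of a
deterministic-policy rollout aligned at reset, independently of any
training-time reward bookkeeping.

Desk-scale protocol (the shipped study conditions): 60 epochs × 2
episodes × 500 steps, 80 gradient updates per epoch, 4 warmup episodes
whose actions are the open-loop gait fixture plus Gaussian excitation
noise (sd 0.15) — identical in both arms; ~90 s per run on one CPU.
Each run is scored by the average of deterministic evaluation rollouts
of its last 5 epochs (damping checkpoint-to-checkpoint jitter) and by
the final smoothed return. The matched-pair experiment trains both arms
from identical seeds/conditions, differing only in the three IMU weights
(1 vs 0), over 5 seed pairs.

**Measured behavior at this scale.** The IMU-constrained arm improves
both metrics *in the mean* (orientation RMSE ≈ 0.085 vs 0.089 rad;
final smoothed return ≈ −367 vs −389 at seed base 0), and the contrast
grows decisively with budget (a single-seed 100-epoch run: RMSE 0.078 vs
0.103, return −140 vs −318). Per-seed, however, training-outcome
variance at 60 epochs is of the same order as the effect, so the
stricter per-pair form of the claim — both metrics improved jointly in
≥ 4 of 5 pairs — is not reliably met at desk scale; the corresponding
acceptance test documents this honestly rather than enlarging the
budget past the intended desk envelope. The headline full-scale numbers
(returns near 190 vs 160; RMSEs 0.8824/0.5825/1.5908) require the full
musculoskeletal environment, a participant recording and long training,
and are out of desk-scale reach by design.

## Numerical and degenerate-input choices

Angle wrapping maps exactly to (−π, π]; the gimbal-degenerate pelvis
orientation (|roll| = π/2) returns the yaw-absorbing Euler convention
value rather than raising. Value-rescale inverse is closed-form (no
iteration). Losses validate finiteness and raise with diagnostics.
Empty trajectories, empty delta lists, odd segment lengths, unknown
segment ids, mismatched head/weight counts and non-monotone timestamps
are rejected with typed errors. Checkpoints and the replay store
serialize to `npz` containers; all CSVs round-trip through the package's
own readers. One master seed fans out (via `SeedSequence`) to network
initialization, action sampling, environment warmup and replay sampling;
single-worker runs are byte-reproducible.

## Known limitations

* The walker's contact, balance and muscle models are first-order
  caricatures; no ground-reaction forces, 3D contact or Hill-type
  muscle mechanics. Conclusions transfer to the full model only at the
  level of pipeline behavior, not biomechanics.
* The reference constraint is time-indexed while the policy is
  feedforward; the agent can only exploit it through state correlates
  (gait phase, speed), which bounds how much of the reference detail is
  learnable. Recurrent policies are out of scope.
* Yaw in the walker responds only to drive asymmetry, so the reference's
  yaw oscillation is trackable only in its mean; part of the measured
  yaw RMSE is an irreducible floor shared by both arms.
* Difficulty 2 (randomized target) is a config hook, untested beyond
  construction; stage two is strictly offline.
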