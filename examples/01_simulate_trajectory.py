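"""Simulate an Ornstein-Uhlenbeck single-molecule trajectory.

The molecule obeys dX = F X dt + sqrt(2 D) dB with restoring drift
F = -10/s and diffusion D = 1.5 um^2/s, starting at (2.3, 2.3) um. The
exact discrete-time solution is sampled at the (random) photon arrival
times inside a 20 ms exposure.
"""

import numpy as np

import pixtraj as px

rng = np.random.default_rng(0)

model = px.MotionModel.ou(f=-10.0, D=1.5, x0=(2.3, 2.3))
arrivals = px.ArrivalProcess(t0=0.0, t=0.02, rate=200.0)  # ~4 photons

times = arrivals.sample_times_conditional(4, rng)
traj = model.sample_trajectory(times, rng, t0=0.0)

print(traj.to_frame().to_string(index=False))
print()
print("phi(5 ms)  =", model.state_transition(0.005)[0, 0])
print("Q(5 ms)    =", model.process_noise_cov(0.005)[0, 0], "um^2")
# Each row is the molecule position (um) when a photon was emitted. The
# positions relax toward the origin (factor phi per step) while the
# diffusion term adds Gaussian jitter with variance Q per axis.
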