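"""Simulate biased fractionation and watch the run statistics evolve.

A 100,000-gene interval loses duplicate genes through excision events of
geometric mean length mu = 6, three quarters of them (phi = 0.75) striking
homeolog 1.  At each checkpoint theta we print the mean single-copy run
length u_bar, the mean duplicate run length v_bar, and the accounting
identity v_bar = theta/(1-theta) u_bar that links them.
"""

from fractorun import DeletionModel, SimConfig, run_simulation, verify_accounting

cfg = SimConfig(
    length=100_000,
    model=DeletionModel(mu=6.0, phi=0.75),
    seed=17,
    stop_theta=0.1,
    checkpoints=[0.9, 0.7, 0.5, 0.3],
)
traj = run_simulation(cfg)

print("theta   u_bar    v_bar    runs   identity-residual")
for cp in traj.checkpoints:
    s = cp.stats
    print(f"{s.theta:5.3f} {s.u_bar:8.3f} {s.v_bar:8.3f} {s.run_count:6d} "
          f"{verify_accounting(s):+10.4f}")

props = traj.event_type_proportions(0.0, 0.9)
print("\nevent types over the whole trajectory "
      "(A new run, B/C extend, D/E merge two, other merges >=3):")
for name, p in zip("A B C D E other".split(), props):
    print(f"  {name:6s} {p:.3f}")
# u_bar grows as runs merge; the identity residual stays within the slack
# contributed by the two interval-boundary runs.
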