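"""Plan a single treatment with and without the self-restoration model.

The goal system is the healthy bilateral network; the source is a
Gaussian-perturbed diseased variant.  The naive planner scores each
(node, strength) by the distance to goal immediately after treatment;
the restoration-aware planner simulates the recovery each treatment
provokes and scores the *final* state.  The naive choice looks better
on paper but realizes a longer distance once the brain restores itself.
"""

import restormem as rm

goal = rm.make_bilateral_system(rm.SyntheticSpec(seed=1))
source = rm.perturb_system(goal, sd=0.1, seed=7)

problem = rm.ControlProblem(
    source=source, goal=goal,
    strength_grid=(0.1, -0.1, 0.25, -0.25, 0.5, -0.5),
)
d0 = rm.partial_kl(goal, source, problem.goal_support())
print(f"distance of untreated source from goal: D+ = {d0:.4f}\n")

aware = rm.optimize_single(problem)
naive = rm.optimize_naive(problem)

for name, res in (("restoration-aware", aware), ("naive", naive)):
    t, _ = res.plan[0]
    print(f"{name:>18}: treat {goal.region_labels[t.index]} "
          f"with alpha={t.alpha:+.2f} -> realized final D+ = "
          f"{res.best_dplus:.4f}")

print("\nthe realized distance of the restoration-aware plan is never "
      "worse; ignoring restoration picks a treatment the brain undoes")
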