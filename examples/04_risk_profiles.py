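"""Tag clusters and classify every participant into risk classes.

Runs the full rule: per task, the 2-cluster solution is tagged by the
task's hazardous cognitive state (loading vs drowsiness, decided on the
pupil-dilation centre); a task is low risk only for risk-free state AND
performance >= 70%; a participant is low general risk when at least 3 of
the 6 tasks are low risk.
"""

import cogrisk as cr

features, _ = cr.generate_feature_table(cr.GeneratorConfig(seed=1))
solutions = cr.cluster_all_tasks(features, k=2, seed=1)
profiles = cr.build_risk_profiles(features, solutions)

print("per-task tagging (tag 0 = risky cognitive state):")
for spec in cr.DEFAULT_TASKS:
    sol = solutions[spec.task_id]
    tags = cr.tag_clusters(sol, spec)
    risky_idx = [i for i, t in tags.items() if t == 0][0]
    print(f"  {spec.task_id:8s} {spec.risky_direction.value:20s} "
          f"risky cluster pupil centre {sol.centers[risky_idx, 0]:7.2f}%")

summary = profiles.summary()
print("\ntask risk classes (high / low):")
for tid, counts in summary["per_task"].items():
    print(f"  {tid:8s} {counts['high']:3d} / {counts['low']:3d}")

g = summary["general"]
print(f"\ngeneral risk: {g['high']} high / {g['low']} low of "
      f"{g['high'] + g['low']} participants")
print("(a participant is low risk overall only when >= 3 tasks combined a "
      "risk-free cognitive state with >= 70% task performance)")

one = profiles.per_task[profiles.per_task["participant"] == "P01"]
print("\nexample participant P01:")
print(one[["task", "cognitive_tag", "performance_pct", "performance_class",
           "task_risk"]].round(1).to_string(index=False))
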