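"""Per-group symptom trajectories: frequent symptoms ordered by onset age.

At the one-third threshold the inclusion cutoff is 41 patients for the SZ
group and 27 for the MSD group.  Each qualifying symptom is placed at its
mean recorded onset age; the figure draws one circle per symptom with area
proportional to the patient count.
"""

from prodromes import Diagnosis, GeneratorSpec, generate_cohort, plot_trajectory, trajectory_summary

cohort = generate_cohort(GeneratorSpec(seed=1))

for group in (Diagnosis.SZ, Diagnosis.MSD):
    entries = trajectory_summary(cohort, group, threshold=1 / 3)
    print(f"\n{group.value} trajectory ({len(entries)} symptoms):")
    for e in entries[:6]:
        print(f"  {e.mean_onset:5.1f} y  n={e.n_patients:3d} "
              f"({100 * e.prevalence:.0f}%)  {e.symptom}")
    if len(entries) > 6:
        print(f"  ... and {len(entries) - 6} more")
    plot_trajectory(entries, f"trajectory_{group.value.lower()}.svg")
    print(f"  figure: trajectory_{group.value.lower()}.svg")
# Early entries are childhood developmental/anxiety symptoms; adolescent
# mood and positive symptoms appear towards age 15-16.
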