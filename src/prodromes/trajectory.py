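"""Symptom-onset trajectory summaries.

For one diagnosis group, select the symptoms carried by at least a third
(by default) of the group and order them by mean age at onset — a compact
picture of how the typical clinical course unfolds through childhood and
adolescence.  The companion plot places one circle per symptom on an age
axis, with circle area proportional to the number of symptom-positive
patients.

The inclusion cutoff in patients is ``round(threshold * group size)``
(half away from zero): at threshold 1/3 this gives 41 of 123 for the SZ
group and 27 of 82 for the MSD group, matching both published cutoffs
(ceiling would give 28 for the MSD group, floor 41/27 only by accident of
the SZ size being divisible by 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import Cohort, Diagnosis

__all__ = [
    "TrajectoryEntry",
    "inclusion_cutoff",
    "trajectory_summary",
    "plot_trajectory",
]


@dataclass(frozen=True)
class TrajectoryEntry:
    """One symptom on the group's timeline."""

    symptom: str
    n_patients: int
    prevalence: float
    mean_onset: float
    sd_onset: float
    rank: int


def inclusion_cutoff(threshold: float, group_size: int) -> int:
    """Patient-count cutoff: round(threshold * group_size), half away from 0."""
    return int(math.floor(threshold * group_size + 0.5))


def trajectory_summary(
    cohort: Cohort, group: Diagnosis, threshold: float = 1 / 3
) -> list[TrajectoryEntry]:
    """Frequent symptoms of *group*, ordered by mean onset age.

    A symptom qualifies when its symptom-positive count reaches the
    inclusion cutoff; its position on the timeline is the mean recorded
    onset age among positives (symptoms without any recorded onset age
    cannot be placed and are omitted).  Ties in mean onset break by
    catalog order.
    """
    group = Diagnosis(group)
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    members = cohort.group(group)
    if not members:
        raise ValueError(f"group {group.value} is empty")
    cutoff = inclusion_cutoff(threshold, len(members))
    rows = []
    for name in cohort.catalog.names:
        n_pos = sum(p.presence.get(name, 0) for p in members)
        if n_pos < cutoff:
            continue
        ages = cohort.onset_ages(name, group)
        if ages.size == 0:
            continue
        rows.append(
            (
                float(ages.mean()),
                cohort.catalog.position(name),
                name,
                n_pos,
                float(ages.std(ddof=1)) if ages.size > 1 else 0.0,
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    return [
        TrajectoryEntry(
            symptom=name,
            n_patients=n_pos,
            prevalence=n_pos / len(members),
            mean_onset=mean,
            sd_onset=sd,
            rank=rank,
        )
        for rank, (mean, _, name, n_pos, sd) in enumerate(rows)
    ]


def plot_trajectory(entries: list[TrajectoryEntry], path=None, ax=None):
    """Timeline figure: x = mean onset age, circle area ~ patient count.

    Returns the matplotlib Axes; saves to *path* when given.  Layout is
    deterministic (entries keep their onset order on the y axis).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not entries:
        raise ValueError("no trajectory entries to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    xs = [e.mean_onset for e in entries]
    ys = [len(entries) - 1 - e.rank for e in entries]
    # marker area in pt^2, proportional to the patient count
    sizes = [12.0 * e.n_patients for e in entries]
    ax.scatter(xs, ys, s=sizes, alpha=0.6, edgecolor="black", zorder=3)
    ax.set_yticks(ys)
    ax.set_yticklabels([e.symptom for e in entries], fontsize=8)
    ax.set_xlabel("mean age at onset (years)")
    ax.set_xlim(0, 17)
    ax.grid(axis="x", linestyle=":", alpha=0.5)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
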