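"""CHAID: Chi-squared Automatic Interaction Detection, from scratch.

The classifier grows a decision tree over nominal predictors (here: binary
symptom flags) against a two-level diagnosis target.  At each node, every
candidate predictor is processed in two phases:

merging
    While more than two category groups remain, the pair of groups whose
    2 x target sub-table has the largest chi-square p-value is merged,
    provided that p exceeds ``alpha_merge``.

splitting
    The chi-square of the merged-groups x target table gives the raw
    p-value, which is Bonferroni-adjusted by the number of ways to
    partition the ``c`` original categories into the ``r`` merged groups —
    the Stirling number of the second kind, via Kass's alternating-sum
    formula ``B = sum_{i=0}^{r-1} (-1)^i (r-i)^c / (i! (r-i)!)``.

The predictor with the smallest adjusted p splits the node if that p is at
most ``alpha_split`` and each child would hold at least ``min_child``
cases.  For binary predictors the multiplier is 1 and the procedure
reduces to picking the plain 2x2 chi-square argmax.  Ties on adjusted p
break by larger statistic, then catalog order — growth is fully
deterministic.

Risk is reported two ways: resubstitution (the tree, fitted on all data,
classifies its own training patients by leaf majority vote) and stratified
k-fold cross-validated misclassification, the standard companion estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .cohort import Cohort, Diagnosis, PatientRecord

__all__ = [
    "ChaidParams",
    "SplitCandidate",
    "ChaidNode",
    "ChaidTree",
    "ClassificationReport",
    "kass_multiplier",
    "evaluate_predictor",
    "best_split",
    "grow",
    "predict",
    "resubstitution_report",
    "cross_validate",
    "render_tree",
]


@dataclass(frozen=True)
class ChaidParams:
    """Growth and validation parameters.

    ``min_parent``/``min_child`` default to 20/7: the published tree
    reaches nodes far smaller than SPSS's 100/50 defaults, so small
    permissive values are used; both are configurable.
    """

    alpha_split: float = 0.05
    alpha_merge: float = 0.05
    bonferroni: bool = True
    min_parent: int = 20
    min_child: int = 7
    max_depth: int = 6
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("alpha_split", "alpha_merge"):
            a = getattr(self, attr)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{attr} must lie in (0, 1]")
        if self.min_child > self.min_parent:
            raise ValueError("min_child must be <= min_parent")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class SplitCandidate:
    """A merged partition of one predictor's categories with its test."""

    predictor: str
    merged_groups: tuple[tuple[int, ...], ...]
    statistic: float
    raw_p: float
    df: int
    bonferroni_multiplier: int
    adjusted_p: float

    @property
    def n_original_categories(self) -> int:
        return sum(len(g) for g in self.merged_groups)


@dataclass
class ChaidNode:
    """One tree node; a leaf iff ``split`` is None."""

    node_id: int
    depth: int
    class_counts: tuple[int, int]  # (n_sz, n_msd)
    majority: Diagnosis
    split: SplitCandidate | None = None
    children: dict[tuple[int, ...], "ChaidNode"] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return sum(self.class_counts)

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class ChaidTree:
    """A fitted tree with its parameters and ordered predictor set."""

    root: ChaidNode
    params: ChaidParams
    predictor_set: tuple[str, ...]

    def nodes(self) -> list[ChaidNode]:
        """All nodes in node-id (growth, preorder) order."""
        out: list[ChaidNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(list(node.children.values())))
        return sorted(out, key=lambda n: n.node_id)

    @property
    def n_leaves(self) -> int:
        return sum(node.is_leaf for node in self.nodes())


def kass_multiplier(c: int, r: int) -> int:
    """Number of partitions of ``c`` nominal categories into ``r`` groups.

    Kass's Bonferroni multiplier for nominal predictors; equals the
    Stirling number of the second kind S(c, r).  B = 1 whenever c = r
    (in particular for binary predictors split in two).
    """
    if not 1 <= r <= c:
        raise ValueError(f"need 1 <= r <= c, got c={c}, r={r}")
    total = Fraction(0)
    for i in range(r):
        total += Fraction(
            (-1) ** i * (r - i) ** c, math.factorial(i) * math.factorial(r - i)
        )
    assert total.denominator == 1
    return int(total)


def _chi2_counts(counts: np.ndarray) -> tuple[float, float, int]:
    """(statistic, p, df) of an r x 2 count table, no continuity correction.

    A table with a zero column margin (all cases one class) carries no
    association signal: statistic 0, p 1.
    """
    counts = np.asarray(counts, dtype=np.int64)
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    if counts.shape[0] < 2 or (counts.sum(axis=0) == 0).any():
        return 0.0, 1.0, max(counts.shape[0] - 1, 1)
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), float(p), int(df)


def _group_counts(
    x: np.ndarray, y: np.ndarray, groups: list[list[int]]
) -> np.ndarray:
    """r x 2 table: rows = merged groups, columns = (SZ, MSD)."""
    out = np.zeros((len(groups), 2), dtype=np.int64)
    for gi, cats in enumerate(groups):
        mask = np.isin(x, cats)
        out[gi, 0] = int((y[mask] == 1).sum())
        out[gi, 1] = int((y[mask] == 0).sum())
    return out


def evaluate_predictor(
    x: np.ndarray, y: np.ndarray, predictor: str, params: ChaidParams
) -> SplitCandidate | None:
    """Merge categories of one predictor and test the merged partition.

    Parameters
    ----------
    x
        Nominal predictor values (integers) for the node's cases.
    y
        Target: 1 = SZ, 0 = MSD.
    predictor
        Name carried into the returned candidate.

    Returns None when the predictor is constant in the node (nothing to
    split on).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    categories = sorted(int(v) for v in np.unique(x))
    if len(categories) < 2:
        return None
    groups: list[list[int]] = [[c] for c in categories]

    while len(groups) > 2:
        best_pair: tuple[int, int] | None = None
        best_p = -1.0
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                counts = _group_counts(x, y, [groups[i], groups[j]])
                _, p, _ = _chi2_counts(counts)
                if p > best_p:
                    best_p = p
                    best_pair = (i, j)
        assert best_pair is not None
        if best_p <= params.alpha_merge:
            break
        i, j = best_pair
        groups[i] = sorted(groups[i] + groups[j])
        del groups[j]

    counts = _group_counts(x, y, groups)
    stat, raw_p, df = _chi2_counts(counts)
    c, r = len(categories), len(groups)
    multiplier = kass_multiplier(c, r) if params.bonferroni else 1
    adjusted = min(1.0, raw_p * multiplier)
    return SplitCandidate(
        predictor=predictor,
        merged_groups=tuple(tuple(g) for g in groups),
        statistic=stat,
        raw_p=raw_p,
        df=df,
        bonferroni_multiplier=multiplier,
        adjusted_p=adjusted,
    )


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    predictors: list[str],
    params: ChaidParams,
) -> SplitCandidate | None:
    """Best candidate over *predictors* (columns of X), or None.

    The candidate with the smallest adjusted p wins (ties: larger
    statistic, then predictor order, which callers pass in catalog order).
    The winning candidate must satisfy adjusted_p <= alpha_split and give
    every child at least ``min_child`` cases; otherwise the node stays a
    leaf.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    candidates: list[tuple[float, float, int, SplitCandidate]] = []
    for k, name in enumerate(predictors):
        cand = evaluate_predictor(X[:, k], y, name, params)
        if cand is not None:
            candidates.append((cand.adjusted_p, -cand.statistic, k, cand))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    best = candidates[0][3]
    if best.adjusted_p > params.alpha_split:
        return None
    col = predictors.index(best.predictor)
    for group in best.merged_groups:
        if int(np.isin(X[:, col], group).sum()) < params.min_child:
            return None
    return best


def _counts_of(y: np.ndarray) -> tuple[int, int]:
    return int((y == 1).sum()), int((y == 0).sum())


def _majority(counts: tuple[int, int], parent: Diagnosis) -> Diagnosis:
    n_sz, n_msd = counts
    if n_sz > n_msd:
        return Diagnosis.SZ
    if n_msd > n_sz:
        return Diagnosis.MSD
    return parent


def grow(
    cohort: Cohort,
    params: ChaidParams | None = None,
    predictors: list[str] | None = None,
) -> ChaidTree:
    """Fit a CHAID tree on a cohort.

    *predictors* defaults to the full catalog (catalog order, the tie-break
    order); restrict it to, e.g., the battery's significant symptoms for
    the published covariable-selection workflow.
    """
    params = params or ChaidParams()
    names = list(predictors) if predictors is not None else cohort.catalog.names
    X, y = cohort.presence_matrix(names)
    counter = iter(range(10**9))

    def build(idx: np.ndarray, depth: int, parent_majority: Diagnosis) -> ChaidNode:
        counts = _counts_of(y[idx])
        majority = _majority(counts, parent_majority)
        node = ChaidNode(
            node_id=next(counter), depth=depth, class_counts=counts,
            majority=majority,
        )
        pure = counts[0] == 0 or counts[1] == 0
        if idx.size < params.min_parent or depth >= params.max_depth or pure:
            return node
        cand = best_split(X[idx], y[idx], names, params)
        if cand is None:
            return node
        node.split = cand
        col = names.index(cand.predictor)
        for group in cand.merged_groups:
            mask = np.isin(X[idx, col], group)
            node.children[group] = build(idx[mask], depth + 1, majority)
        return node

    root = build(np.arange(len(cohort)), 0, Diagnosis.SZ)
    return ChaidTree(root=root, params=params, predictor_set=tuple(names))


def _route(node: ChaidNode, values: dict[str, int]) -> ChaidNode:
    while not node.is_leaf:
        assert node.split is not None
        v = int(values.get(node.split.predictor, 0))
        child = None
        for group, ch in node.children.items():
            if v in group:
                child = ch
                break
        if child is None:
            # value unseen at training time: follow the largest child
            child = max(node.children.values(), key=lambda ch: ch.n)
        node = child
    return node


def predict(tree: ChaidTree, patient: PatientRecord | dict) -> Diagnosis:
    """Route a patient to its leaf and return the leaf's majority class."""
    values = patient.presence if isinstance(patient, PatientRecord) else dict(patient)
    return _route(tree.root, values).majority


@dataclass
class ClassificationReport:
    """Confusion counts with per-class and overall percent correct."""

    correct_sz: int
    wrong_sz: int
    correct_msd: int
    wrong_msd: int
    cv_risk: float | None = None

    @property
    def n(self) -> int:
        return self.correct_sz + self.wrong_sz + self.correct_msd + self.wrong_msd

    @property
    def n_sz(self) -> int:
        return self.correct_sz + self.wrong_sz

    @property
    def n_msd(self) -> int:
        return self.correct_msd + self.wrong_msd

    @property
    def percent_correct_sz(self) -> float:
        return 100.0 * self.correct_sz / self.n_sz

    @property
    def percent_correct_msd(self) -> float:
        return 100.0 * self.correct_msd / self.n_msd

    @property
    def overall_percent_correct(self) -> float:
        return 100.0 * (self.correct_sz + self.correct_msd) / self.n

    def confusion(self) -> dict[tuple[str, str], int]:
        """(true, predicted) -> count."""
        return {
            ("SZ", "SZ"): self.correct_sz,
            ("SZ", "MSD"): self.wrong_sz,
            ("MSD", "MSD"): self.correct_msd,
            ("MSD", "SZ"): self.wrong_msd,
        }


def resubstitution_report(tree: ChaidTree, cohort: Cohort) -> ClassificationReport:
    """Classify the training cohort by its own tree (resubstitution)."""
    correct = {Diagnosis.SZ: 0, Diagnosis.MSD: 0}
    wrong = {Diagnosis.SZ: 0, Diagnosis.MSD: 0}
    for patient in cohort.patients:
        if predict(tree, patient) is patient.diagnosis:
            correct[patient.diagnosis] += 1
        else:
            wrong[patient.diagnosis] += 1
    return ClassificationReport(
        correct_sz=correct[Diagnosis.SZ],
        wrong_sz=wrong[Diagnosis.SZ],
        correct_msd=correct[Diagnosis.MSD],
        wrong_msd=wrong[Diagnosis.MSD],
    )


def cross_validate(
    cohort: Cohort,
    params: ChaidParams | None = None,
    predictors: list[str] | None = None,
) -> float:
    """Pooled misclassification risk under stratified k-fold CV.

    Fold assignment is seeded (``params.seed``); each training fold grows
    its own tree and classifies the held-out patients.
    """
    params = params or ChaidParams()
    y = np.array(
        [int(p.diagnosis is Diagnosis.SZ) for p in cohort.patients]
    )
    n_min = min(int((y == 1).sum()), int((y == 0).sum()))
    if n_min < params.cv_folds:
        raise ValueError(
            f"cannot stratify {params.cv_folds} folds with a class of "
            f"size {n_min}"
        )
    skf = StratifiedKFold(
        n_splits=params.cv_folds, shuffle=True, random_state=params.seed
    )
    errors = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = Cohort(
            [cohort.patients[i] for i in train_idx], cohort.catalog
        )
        tree = grow(train, params, predictors)
        for i in test_idx:
            patient = cohort.patients[i]
            if predict(tree, patient) is not patient.diagnosis:
                errors += 1
    return errors / len(y)


def _group_label(group: tuple[int, ...]) -> str:
    if len(group) == 1:
        return f"= {group[0]}"
    return "in {" + ", ".join(str(v) for v in group) + "}"


def render_tree(tree: ChaidTree, format: str = "plain") -> str:
    """Deterministic text rendering, ``plain`` (indented) or ``dot``."""
    if format not in ("plain", "dot"):
        raise ValueError(f"unknown format: {format!r}")
    if format == "plain":
        lines: list[str] = []

        def walk(node: ChaidNode, indent: int, edge: str) -> None:
            head = f"{'  ' * indent}node {node.node_id}"
            if edge:
                head += f" [{edge}]"
            head += (
                f": n={node.n} (SZ {node.class_counts[0]}, "
                f"MSD {node.class_counts[1]}) majority={node.majority.value}"
            )
            if node.split is not None:
                head += (
                    f" split='{node.split.predictor}' "
                    f"adj_p={node.split.adjusted_p:.3g}"
                )
            lines.append(head)
            for group, child in node.children.items():
                walk(child, indent + 1, _group_label(group))

        walk(tree.root, 0, "")
        return "\n".join(lines) + "\n"

    lines = ["digraph chaid {", "  node [shape=box];"]
    for node in tree.nodes():
        label = (
            f"node {node.node_id}\\nSZ {node.class_counts[0]} / "
            f"MSD {node.class_counts[1]}\\nmajority {node.majority.value}"
        )
        if node.split is not None:
            label += (
                f"\\n{node.split.predictor}\\n"
                f"adj p = {node.split.adjusted_p:.3g}"
            )
        lines.append(f'  n{node.node_id} [label="{label}"];')
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for group, child in node.children.items():
            lines.append(
                f'  n{node.node_id} -> n{child.node_id} '
                f'[label="{_group_label(group)}"];'
            )
            stack.append(child)
    lines.append("}")
    return "\n".join(lines) + "\n"
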