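"""Fuse multi-expert IC annotations into per-class boolean training targets.

Two voting strategies are provided.  *Majority vote*: each expert casts a
binary vote per class; the per-class probability is the mean vote over the
experts who annotated the component.  *Probabilistic vote*: each expert has
a single vote split equally over the ``k`` classes they chose (1/k each),
so an expert who labels a component {Eyes, Muscle, Heart} contributes 1/3
to each; contributions are then averaged over experts.  Either probability
is compared strictly (``>``) against a class threshold (default 0.33) to
produce the boolean target, so a one-of-three split still counts as a
simple pattern of interest.

Before voting, class labels are merged: horizontal/vertical eye movements
fold into Eyes, line-noise labels are dropped (data without genuine line
noise), and Alpha/Mu labels imply Brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VOCABULARY",
    "TARGET_CLASSES",
    "DEFAULT_THRESHOLD",
    "DEFAULT_PLAN",
    "Annotation",
    "LabelMatrix",
    "AggregatedLabels",
    "AggregationError",
    "merge_classes",
    "build_label_matrix",
    "majority_vote",
    "probabilistic_vote",
    "aggregate",
    "read_annotations",
    "write_annotations",
]

#: The fixed annotation vocabulary.
VOCABULARY = frozenset({
    "Eyes", "Horizontal eye movements", "Vertical eye movements",
    "Line noise", "Channel noise", "Brain", "Alpha", "Mu",
    "Muscle", "Heart", "Other", "Uncertain",
})

#: Classes that receive a trained model / aggregation target by default.
#: Other/Uncertain are annotation-quality flags, not targets.
TARGET_CLASSES = ("Brain", "Alpha", "Mu", "Eyes", "Muscle", "Heart",
                  "Channel noise")

DEFAULT_THRESHOLD = 0.33

#: Default per-class strategy: probabilistic vote for the well-populated
#: classes, majority vote where positives are scarce.
DEFAULT_PLAN = {
    "Brain": ("probabilistic", DEFAULT_THRESHOLD),
    "Alpha": ("majority", DEFAULT_THRESHOLD),
    "Mu": ("majority", DEFAULT_THRESHOLD),
    "Eyes": ("probabilistic", DEFAULT_THRESHOLD),
    "Muscle": ("probabilistic", DEFAULT_THRESHOLD),
    "Heart": ("majority", DEFAULT_THRESHOLD),
    "Channel noise": ("probabilistic", DEFAULT_THRESHOLD),
}

#: Probabilities are rounded to this many decimals before the strict
#: threshold comparison, so 1/3 vs a stored 0.33 threshold is unambiguous.
_ROUND_DECIMALS = 12


class AggregationError(ValueError):
    """Raised for vocabulary, duplication or empty-annotator errors."""


@dataclass(frozen=True)
class Annotation:
    """One expert's label set for one component."""

    component_id: str
    expert_id: str
    labels: frozenset = field(default_factory=frozenset)
    comment: str = ""

    def __post_init__(self):
        object.__setattr__(self, "labels", frozenset(self.labels))
        if not self.labels:
            raise AggregationError(
                f"annotation ({self.component_id}, {self.expert_id}) has an "
                f"empty label set")
        unknown = self.labels - VOCABULARY
        if unknown:
            raise AggregationError(
                f"annotation ({self.component_id}, {self.expert_id}) uses "
                f"labels outside the vocabulary: {sorted(unknown)}")


def merge_classes(table: list[Annotation]) -> list[Annotation]:
    """Apply the class-merging rules to every annotation.

    - Horizontal/Vertical eye movements -> Eyes (deduplicated).
    - Line noise dropped; an annotation left empty becomes {Uncertain}.
    - Alpha or Mu implies Brain.
    - Other/Uncertain pass through.
    """
    merged = []
    for ann in table:
        labels = set(ann.labels)
        if labels & {"Horizontal eye movements", "Vertical eye movements"}:
            labels -= {"Horizontal eye movements", "Vertical eye movements"}
            labels.add("Eyes")
        labels.discard("Line noise")
        if labels & {"Alpha", "Mu"}:
            labels.add("Brain")
        if not labels:
            labels = {"Uncertain"}
        merged.append(Annotation(ann.component_id, ann.expert_id,
                                 frozenset(labels), ann.comment))
    return merged


@dataclass
class LabelMatrix:
    """Binary votes per (component, expert, class), NaN where an expert
    did not annotate a component."""

    components: list[str]
    experts: list[str]
    classes: list[str]
    votes: np.ndarray  # (n_components, n_experts, n_classes); 0/1/NaN

    def expert_slice(self, component_id: str, expert_id: str) -> np.ndarray:
        i = self.components.index(component_id)
        j = self.experts.index(expert_id)
        return self.votes[i, j]


def build_label_matrix(table: list[Annotation],
                       classes=None) -> LabelMatrix:
    """Arrange annotations as a component x expert x class vote array.

    ``classes`` defaults to every label appearing in the table, ordered by
    :data:`TARGET_CLASSES` first then alphabetically.
    """
    seen = {}
    for ann in table:
        key = (ann.component_id, ann.expert_id)
        if key in seen:
            raise AggregationError(
                f"duplicate annotation for component {ann.component_id!r} by "
                f"expert {ann.expert_id!r}")
        seen[key] = ann

    components = sorted({a.component_id for a in table})
    experts = sorted({a.expert_id for a in table})
    if classes is None:
        present = {lab for a in table for lab in a.labels}
        classes = [c for c in TARGET_CLASSES if c in present]
        classes += sorted(present - set(TARGET_CLASSES))
    classes = list(classes)

    votes = np.full((len(components), len(experts), len(classes)), np.nan)
    cidx = {c: i for i, c in enumerate(components)}
    eidx = {e: j for j, e in enumerate(experts)}
    kidx = {k: l for l, k in enumerate(classes)}
    for ann in table:
        i, j = cidx[ann.component_id], eidx[ann.expert_id]
        votes[i, j, :] = 0.0
        for lab in ann.labels:
            if lab in kidx:
                votes[i, j, kidx[lab]] = 1.0
    return LabelMatrix(components, experts, classes, votes)


@dataclass
class AggregatedLabels:
    """Per-component weighted probabilities and boolean targets per class."""

    components: list[str]
    classes: list[str]
    probabilities: pd.DataFrame  # index=component_id, columns=classes
    targets: pd.DataFrame        # same shape, bool
    plan: dict                   # class -> (strategy, threshold)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one probability and one target column per class."""
        out = pd.DataFrame(index=self.probabilities.index)
        for cls in self.classes:
            out[f"p_{cls}"] = self.probabilities[cls]
            out[f"target_{cls}"] = self.targets[cls].astype(int)
        return out


def _check_annotated(m: LabelMatrix) -> np.ndarray:
    """Boolean (component, expert) mask of cast votes; errors on orphans."""
    annotated = ~np.isnan(m.votes).all(axis=2)
    orphans = [c for c, row in zip(m.components, annotated) if not row.any()]
    if orphans:
        raise AggregationError(
            f"components with zero annotators: {orphans}")
    return annotated


def _threshold(probs: np.ndarray, thr: float) -> np.ndarray:
    return np.round(probs, _ROUND_DECIMALS) > thr


def _finalize(m, probs, strategy, threshold) -> AggregatedLabels:
    probs_df = pd.DataFrame(probs, index=pd.Index(m.components, name="component_id"),
                            columns=m.classes)
    targets = pd.DataFrame(_threshold(probs, threshold),
                           index=probs_df.index, columns=m.classes)
    plan = {cls: (strategy, threshold) for cls in m.classes}
    return AggregatedLabels(list(m.components), list(m.classes),
                            probs_df, targets, plan)


def majority_vote(m: LabelMatrix,
                  threshold: float = DEFAULT_THRESHOLD) -> AggregatedLabels:
    """Mean of binary votes over the experts who annotated each component."""
    _check_annotated(m)
    with np.errstate(invalid="ignore"):
        probs = np.nanmean(m.votes, axis=1)
    return _finalize(m, probs, "majority", threshold)


def probabilistic_vote(m: LabelMatrix,
                       threshold: float = DEFAULT_THRESHOLD) -> AggregatedLabels:
    """Each expert's vote split 1/k over their k chosen classes, averaged."""
    _check_annotated(m)
    k = np.nansum(m.votes, axis=2, keepdims=True)  # labels per (comp, expert)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = m.votes / k
        probs = np.nanmean(contrib, axis=1)
    return _finalize(m, probs, "probabilistic", threshold)


_STRATEGIES = {"majority": majority_vote, "probabilistic": probabilistic_vote}


def aggregate(table: list[Annotation], plan: dict | None = None,
              classes=None) -> AggregatedLabels:
    """Merge classes, build the vote matrix, and apply the per-class plan.

    ``plan`` maps class -> (strategy, threshold); defaults to
    :data:`DEFAULT_PLAN`.  ``classes`` defaults to the plan's classes that
    actually occur in the merged table.
    """
    if plan is None:
        plan = DEFAULT_PLAN
    merged = merge_classes(table)
    if classes is None:
        present = {lab for a in merged for lab in a.labels}
        classes = [c for c in plan if c in present]
    missing = [c for c in classes if c not in plan]
    if missing:
        raise AggregationError(f"aggregation plan missing classes: {missing}")
    m = build_label_matrix(merged, classes=classes)

    probs = pd.DataFrame(index=pd.Index(m.components, name="component_id"),
                         columns=m.classes, dtype=float)
    targets = pd.DataFrame(index=probs.index, columns=m.classes, dtype=bool)
    used = {}
    for cls in m.classes:
        strategy, threshold = plan[cls]
        if strategy not in _STRATEGIES:
            raise AggregationError(f"unknown strategy {strategy!r} for {cls!r}")
        agg = _STRATEGIES[strategy](m, threshold)
        probs[cls] = agg.probabilities[cls]
        targets[cls] = agg.targets[cls]
        used[cls] = (strategy, threshold)
    return AggregatedLabels(list(m.components), list(m.classes), probs,
                            targets, used)


def read_annotations(path) -> list[Annotation]:
    """Read a delimited annotation table.

    Columns: ``component_id``, ``expert_id``, ``labels`` (semicolon-separated
    vocabulary tokens), optional ``comment``.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"component_id", "expert_id", "labels"}
    missing = required - set(df.columns)
    if missing:
        raise AggregationError(f"annotation table missing columns: "
                               f"{sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        labels = frozenset(tok.strip() for tok in row.labels.split(";")
                           if tok.strip())
        comment = getattr(row, "comment", "")
        out.append(Annotation(row.component_id, row.expert_id, labels, comment))
    return out


def write_annotations(table: list[Annotation], path) -> None:
    rows = [{
        "component_id": a.component_id,
        "expert_id": a.expert_id,
        "labels": ";".join(sorted(a.labels)),
        "comment": a.comment,
    } for a in table]
    pd.DataFrame(rows, columns=["component_id", "expert_id", "labels",
                                "comment"]).to_csv(path, index=False)
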