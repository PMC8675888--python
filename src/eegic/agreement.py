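"""Inter-expert annotation concordance: Cohen's and Fleiss' kappa, and the
mean inter-expert correlation (IEC).

Kappa is chance-corrected agreement, ``(p0 - pe) / (1 - pe)``: ``p0`` is the
observed fraction of agreeing ratings and ``pe`` the agreement expected if
both raters labeled at random with their marginal frequencies.  The IEC is
the mean over jointly annotated components of the Pearson correlation
between two experts' per-component binary label vectors; components where
either vector is constant (correlation undefined) are skipped and counted.

Both kappas are implemented from the formulas directly so degenerate cases
(identical constant raters, ``pe == 1``) have defined behavior; tests
cross-check them against the scikit-learn and statsmodels implementations.
Agreement is conventionally computed after class merging, on the final
class set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import (Annotation, LabelMatrix, build_label_matrix,
                          merge_classes)

__all__ = [
    "AgreementError",
    "AgreementReport",
    "cohens_kappa",
    "fleiss_kappa",
    "inter_expert_correlation",
    "agreement_report",
]


class AgreementError(ValueError):
    pass


def cohens_kappa(a, b) -> float:
    """Cohen's kappa between two binary rating vectors.

    Degenerate case ``pe == 1`` (both raters constant with identical
    marginals): returns 1.0 on perfect agreement, else 0.0, with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("cohens_kappa needs two equal-length 1-D vectors")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("ratings must be binary (0/1)")
    p0 = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        warnings.warn("degenerate kappa: chance agreement pe == 1",
                      stacklevel=2)
        return 1.0 if p0 == 1.0 else 0.0
    return (p0 - pe) / (1 - pe)


def fleiss_kappa(counts, n_raters: int) -> float:
    """Fleiss' kappa from a component x class matrix of rater counts.

    Every row must sum to ``n_raters`` (subsampling to a common rater count
    is the caller's job).  Per-item agreement is
    ``P_i = (sum_k n_ik^2 - n) / (n (n - 1))``; ``p0`` is its mean and
    ``pe = sum_k p_k^2`` with ``p_k`` the pooled class proportions.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 1:
        raise ValueError("counts must be a 2-D item x class matrix")
    if n_raters < 2:
        raise ValueError("fleiss_kappa needs >= 2 raters")
    row_sums = counts.sum(axis=1)
    if not np.all(row_sums == n_raters):
        bad = np.flatnonzero(row_sums != n_raters)
        raise ValueError(
            f"rows {bad.tolist()} are not rated by exactly {n_raters} raters")
    n = float(n_raters)
    p_i = (np.sum(counts ** 2, axis=1) - n) / (n * (n - 1))
    p0 = p_i.mean()
    p_k = counts.sum(axis=0) / counts.sum()
    pe = float(np.sum(p_k ** 2))
    if pe >= 1.0:
        warnings.warn("degenerate kappa: chance agreement pe == 1",
                      stacklevel=2)
        return 1.0 if p0 == 1.0 else 0.0
    return (p0 - pe) / (1 - pe)


def inter_expert_correlation(m: LabelMatrix, expert1: str, expert2: str,
                             return_skipped: bool = False):
    """Mean Pearson correlation between two experts' binary label vectors.

    Averaged over components annotated by both experts; components where
    either vector is constant are skipped (correlation undefined) and
    their number reported when ``return_skipped`` is true.
    """
    j1, j2 = m.experts.index(expert1), m.experts.index(expert2)
    v1 = m.votes[:, j1, :]
    v2 = m.votes[:, j2, :]
    joint = ~(np.isnan(v1).all(axis=1) | np.isnan(v2).all(axis=1))
    if not joint.any():
        raise AgreementError(
            f"no components jointly annotated by {expert1!r} and {expert2!r}")
    corrs = []
    skipped = 0
    for i in np.flatnonzero(joint):
        x, y = v1[i], v2[i]
        if np.std(x) == 0 or np.std(y) == 0:
            skipped += 1
            continue
        corrs.append(float(np.corrcoef(x, y)[0, 1]))
    iec = float(np.mean(corrs)) if corrs else float("nan")
    if return_skipped:
        return iec, skipped
    return iec


@dataclass
class AgreementReport:
    """Per-class kappa plus pairwise inter-expert correlations."""

    per_class: pd.DataFrame      # columns: class, statistic, value, n
    iec_pairs: pd.DataFrame      # columns: expert1, expert2, iec, n_skipped
    iec_mean: float

    def to_frame(self) -> pd.DataFrame:
        rows = self.per_class.copy()
        for r in self.iec_pairs.itertuples(index=False):
            rows = pd.concat([rows, pd.DataFrame([{
                "class": f"{r.expert1}|{r.expert2}", "statistic": "iec",
                "value": r.iec, "n": r.n_skipped}])], ignore_index=True)
        rows = pd.concat([rows, pd.DataFrame([{
            "class": "overall", "statistic": "iec_mean",
            "value": self.iec_mean, "n": len(self.iec_pairs)}])],
            ignore_index=True)
        return rows


def agreement_report(table: list[Annotation], classes=None,
                     merge: bool = True) -> AgreementReport:
    """Compute per-class kappas and pairwise IEC for an annotation table.

    With two experts the per-class statistic is Cohen's kappa over the
    components both annotated; with three or more it is Fleiss' kappa over
    components annotated by every expert.
    """
    if merge:
        table = merge_classes(table)
    m = build_label_matrix(table, classes=classes)
    n_experts = len(m.experts)
    if n_experts < 2:
        raise AgreementError("agreement needs at least two experts")

    annotated = ~np.isnan(m.votes).all(axis=2)     # component x expert
    complete = annotated.all(axis=1)               # rated by every expert
    rows = []
    for l, cls in enumerate(m.classes):
        if n_experts == 2:
            joint = annotated[:, 0] & annotated[:, 1]
            a = m.votes[joint, 0, l]
            b = m.votes[joint, 1, l]
            value = cohens_kappa(a, b) if joint.any() else float("nan")
            rows.append({"class": cls, "statistic": "cohens_kappa",
                         "value": value, "n": int(joint.sum())})
        else:
            votes = m.votes[complete][:, :, l]     # items x experts, 0/1
            pos = votes.sum(axis=1)
            counts = np.stack([n_experts - pos, pos], axis=1)
            value = (fleiss_kappa(counts, n_experts)
                     if complete.any() else float("nan"))
            rows.append({"class": cls, "statistic": "fleiss_kappa",
                         "value": value, "n": int(complete.sum())})

    pair_rows = []
    iecs = []
    for i in range(n_experts):
        for j in range(i + 1, n_experts):
            try:
                iec, skipped = inter_expert_correlation(
                    m, m.experts[i], m.experts[j], return_skipped=True)
            except AgreementError:
                continue
            pair_rows.append({"expert1": m.experts[i], "expert2": m.experts[j],
                              "iec": iec, "n_skipped": skipped})
            if np.isfinite(iec):
                iecs.append(iec)
    iec_mean = float(np.mean(iecs)) if iecs else float("nan")
    return AgreementReport(
        per_class=pd.DataFrame(rows, columns=["class", "statistic", "value", "n"]),
        iec_pairs=pd.DataFrame(pair_rows, columns=["expert1", "expert2", "iec",
                                                   "n_skipped"]),
        iec_mean=iec_mean,
    )
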