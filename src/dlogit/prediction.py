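"""Posterior classification of labeled controls and ROC summaries.

After fitting, each z = 0 row gets the posterior probability
P(y = 1 | z = 0, x) of being a mislabeled case; rows with a score
strictly above a chosen cutoff are flagged as probable cases.  Rows
already labeled z = 1 are known cases and are scored with P(y = 1 | x).
When the true labels are known (validation experiments) the report also
tabulates how many truly mislabeled cases were caught and how many true
controls were left alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .data import ContaminatedDataset

__all__ = ["classify", "ClassificationReport", "classification_report", "RocCurve", "roc_curve"]

_MIXING_CAVEAT = (
    "the intercept depends on the design's case:control mixing proportions; "
    "interpret predicted probabilities cautiously"
)


def classify(probs, cutoff: float) -> np.ndarray:
    """1 where prob strictly exceeds the cutoff, else 0 (ties -> control)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities outside [0, 1]")
    return (probs > cutoff).astype(np.int8)


@dataclass(frozen=True)
class ClassificationReport:
    """Cutoff classification of the z = 0 (labeled-control) group.

    Confusion counts refer to z = 0 rows only and are present when true
    labels are available: sensitivity is the fraction of truly mislabeled
    cases flagged, specificity the fraction of true controls unflagged.
    """

    cutoff: float
    n_controls: int
    n_controls_flagged: int
    n_mislabeled: int | None = None
    n_mislabeled_flagged: int | None = None
    n_true_controls: int | None = None
    n_true_controls_unflagged: int | None = None
    caveat: str = _MIXING_CAVEAT

    @property
    def sensitivity(self) -> float | None:
        if self.n_mislabeled in (None, 0):
            return None
        return self.n_mislabeled_flagged / self.n_mislabeled

    @property
    def specificity(self) -> float | None:
        if self.n_true_controls in (None, 0):
            return None
        return self.n_true_controls_unflagged / self.n_true_controls

    def __str__(self):
        lines = [
            f"cutoff {self.cutoff:g}: {self.n_controls_flagged} of "
            f"{self.n_controls} labeled controls flagged as probable cases"
        ]
        if self.n_mislabeled is not None:
            lines.append(
                f"  truly mislabeled cases flagged: {self.n_mislabeled_flagged} of "
                f"{self.n_mislabeled} (sensitivity {self.sensitivity:.2f})"
                if self.n_mislabeled
                else "  no truly mislabeled cases in the control group"
            )
            lines.append(
                f"  true controls left unflagged: {self.n_true_controls_unflagged} of "
                f"{self.n_true_controls} (specificity {self.specificity:.2f})"
            )
        lines.append(f"  note: {self.caveat}")
        return "\n".join(lines)

    def to_record(self) -> dict:
        d = {
            "cutoff": self.cutoff,
            "n_controls": self.n_controls,
            "n_controls_flagged": self.n_controls_flagged,
        }
        if self.n_mislabeled is not None:
            d.update(
                n_mislabeled=self.n_mislabeled,
                n_mislabeled_flagged=self.n_mislabeled_flagged,
                n_true_controls=self.n_true_controls,
                n_true_controls_unflagged=self.n_true_controls_unflagged,
                sensitivity=self.sensitivity,
                specificity=self.specificity,
            )
        return d


def classification_report(fit, data: ContaminatedDataset, cutoff: float) -> ClassificationReport:
    """Flag z = 0 rows whose posterior P(y=1|z=0,x) strictly exceeds the
    cutoff; when data.y_true is present, judge flags against the truth."""
    ctrl = data.z == 0
    scores = fit.predict(data.X[ctrl], which="case_given_control")
    flags = classify(scores, cutoff)
    rep = dict(
        cutoff=float(cutoff),
        n_controls=int(ctrl.sum()),
        n_controls_flagged=int(flags.sum()),
    )
    if data.y_true is not None:
        mis = data.y_true[ctrl] == 1
        rep.update(
            n_mislabeled=int(mis.sum()),
            n_mislabeled_flagged=int(flags[mis].sum()),
            n_true_controls=int((~mis).sum()),
            n_true_controls_unflagged=int((flags[~mis] == 0).sum()),
        )
    return ClassificationReport(**rep)


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr)
        ax.plot([0, 1], [0, 1], ls=":", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"AUC = {self.auc:.3f}")
        return ax

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(scores, y_true) -> RocCurve:
    """Empirical ROC over all distinct score thresholds with trapezoidal AUC."""
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise ValueError("ROC needs both label values present in y_true")
    fpr, tpr, thr = _skm.roc_curve(y_true, np.asarray(scores, dtype=float))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr)))
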