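"""Virtual-screening evaluation: ROC/AUROC, resampled negative sets,
score-distribution summaries, and the QED comparator.

AUROC is the probability that a randomly chosen positive outscores a
randomly chosen negative, with ties credited 1/2 (the Mann-Whitney
convention) — equivalently the trapezoidal area under the ROC curve.
The resampling protocol mirrors a screening study design where the
negative pool vastly exceeds the test-set size: several independently
seeded negative samples are drawn and AUROC is reported as mean ± sd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn import metrics

__all__ = ["ScoredDataset", "EvaluationReport", "auroc", "roc_curve",
           "resampled_evaluation", "distribution_summary", "qed_scores"]


@dataclass(frozen=True)
class ScoredDataset:
    """Named score list with an optional class label."""

    name: str
    scores: tuple[float, ...]
    label: str = "unlabeled"  # positive | negative | unlabeled
    ids: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if not self.scores:
            raise ValueError("a ScoredDataset cannot be empty")
        arr = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("scores must be finite")


@dataclass(frozen=True)
class EvaluationReport:
    auroc_mean: float
    auroc_sd: float
    n_resamples: int
    auroc_values: tuple[float, ...]
    distribution_summaries: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "auroc_mean": self.auroc_mean, "auroc_sd": self.auroc_sd,
            "n_resamples": self.n_resamples,
            "auroc_values": list(self.auroc_values),
            "distribution_summaries": self.distribution_summaries,
        }, indent=2)


def auroc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Mann-Whitney AUROC (ties count 1/2)."""
    pos, neg = np.asarray(pos_scores, float), np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(metrics.roc_auc_score(y, np.concatenate([pos, neg])))


def roc_curve(pos_scores: Sequence[float], neg_scores: Sequence[float]
              ) -> np.ndarray:
    """(FPR, TPR) pairs from (0,0) to (1,1); trapezoid area equals auroc."""
    pos, neg = np.asarray(pos_scores, float), np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = metrics.roc_curve(y, np.concatenate([pos, neg]))
    return np.column_stack([fpr, tpr])


def resampled_evaluation(scorer: Callable[[Sequence[str]], Sequence[float]],
                         pos: Sequence[str], neg_pool: Sequence[str],
                         n_resamples: int = 5, sample_size: int = 1000,
                         seed: int = 0,
                         summarize: bool = True) -> EvaluationReport:
    """AUROC over independently drawn negative samples.

    Resample i uses seed+i; the positive set is fixed and scored once.
    """
    neg_pool = list(neg_pool)
    if sample_size > len(neg_pool):
        raise ValueError("negative pool is smaller than sample_size")
    pos_scores = np.asarray(scorer(pos), float)
    values = []
    summaries = {}
    for i in range(n_resamples):
        rng = np.random.default_rng(seed + i)
        pick = rng.choice(len(neg_pool), size=sample_size, replace=False)
        neg_scores = np.asarray(scorer([neg_pool[j] for j in pick]), float)
        values.append(auroc(pos_scores, neg_scores))
        if summarize:
            summaries[f"negative_resample_{i}"] = distribution_summary(
                ScoredDataset(f"neg_{i}", tuple(neg_scores), "negative"))
    if summarize:
        summaries["positive"] = distribution_summary(
            ScoredDataset("pos", tuple(pos_scores), "positive"))
    values = np.asarray(values)
    return EvaluationReport(
        auroc_mean=float(values.mean()), auroc_sd=float(values.std(ddof=0)),
        n_resamples=n_resamples, auroc_values=tuple(float(v) for v in values),
        distribution_summaries=summaries)


def distribution_summary(dataset: ScoredDataset,
                         high_cutoff: float = 0.9,
                         low_cutoff: float = 0.1) -> dict:
    """Location/shape summary plus the polarization audit (fractions of
    scores above/below the cutoffs, relevant for sigmoid outputs)."""
    x = np.asarray(dataset.scores, float)
    q5, q25, med, q75, q95 = np.percentile(x, [5, 25, 50, 75, 95])
    return {
        "name": dataset.name, "label": dataset.label, "n": int(x.size),
        "mean": float(x.mean()), "median": float(med),
        "q5": float(q5), "q25": float(q25), "q75": float(q75), "q95": float(q95),
        "skewness": float(stats.skew(x)) if x.size > 1 and x.std() > 0 else 0.0,
        "frac_above_high": float((x > high_cutoff).mean()),
        "frac_below_low": float((x < low_cutoff).mean()),
    }


def qed_scores(smiles_list: Sequence[str], name: str = "qed",
               label: str = "unlabeled") -> ScoredDataset:
    """QED desirability scores (the traditional comparator), in [0, 1]."""
    from rdkit import Chem
    from rdkit.Chem import QED

    scores = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            from .chem import SmilesParseError
            raise SmilesParseError(f"not a valid SMILES: {s!r}")
        scores.append(float(QED.qed(mol)))
    return ScoredDataset(name=name, scores=tuple(scores), label=label,
                         ids=tuple(smiles_list))


def write_report(report: EvaluationReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json())
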