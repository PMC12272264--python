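"""Association battery: Pearson screening of ROI typicality against
dimensional scores, permutation-tested AUC against binary diagnosis, and
Bonferroni control over the whole family of (region, target) hypotheses.

Orientation convention for AUC: scores are likelihoods of TYPICALITY, so
diagnosed subjects are expected to score LOWER.  AUC is reported for the
negated score predicting the positive class, so discriminative regions
show AUC > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class PermutationSpec:
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class AssociationResult:
    roi_name: str
    target_name: str
    statistic_kind: Literal["pearson_r", "auc"]
    effect: float
    p_raw: float
    p_corrected: float
    n: int
    significant: bool


def pearson_association(scores: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p (t transform, n-2 df)."""
    scores = np.asarray(scores, dtype=float)
    target = np.asarray(target, dtype=float)
    if scores.shape != target.shape or scores.ndim != 1:
        raise ValueError("scores and target must be 1-D vectors of equal length")
    n = scores.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(scores)) and np.all(np.isfinite(target))):
        raise ValueError("non-finite values in correlation inputs")
    if np.all(scores == scores[0]) or np.all(target == target[0]):
        raise ValueError("Pearson correlation undefined: zero variance input")
    r, p = stats.pearsonr(scores, target)
    return float(r), float(p)


def bonferroni_adjust(p_values: Sequence[float] | np.ndarray, m: int) -> np.ndarray:
    """p_corr = min(1, m * p).  `m` is the family size and may exceed the
    number of p-values passed."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of p-values {p.size}")
    return np.minimum(1.0, m * p)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC of (-scores) predicting labels==1: typicality runs low in cases,
    so detectable atypicality gives AUC > 0.5.  Ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    return float(roc_auc_score(labels == classes.max(), -scores))


def permutation_auc_pvalue(
    scores: np.ndarray,
    labels: np.ndarray,
    spec: PermutationSpec = PermutationSpec(),
) -> tuple[float, float]:
    """One-sided permutation p for the observed AUC.

    p = (1 + #{permuted AUC >= observed}) / (B + 1) over B uniform label
    permutations (add-one estimator, so p >= 1/(B+1) and never 0).
    Returns (observed AUC, p).
    """
    observed = roc_auc(scores, labels)
    rng = np.random.default_rng(spec.seed)
    labels = np.asarray(labels)
    exceed = 0
    for _ in range(spec.n_permutations):
        exceed += roc_auc(scores, rng.permutation(labels)) >= observed
    p = (1.0 + exceed) / (spec.n_permutations + 1.0)
    return observed, float(p)


def evaluate_dataset(
    roi_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    targets: dict[str, Literal["numeric", "binary"]],
    alpha: float = 0.05,
    family_rule: Literal["dataset", "per_target"] = "dataset",
    permutation: PermutationSpec = PermutationSpec(),
) -> list[AssociationResult]:
    """Run the full screen: every (region + whole_brain, target) pair.

    Numeric targets get Pearson r / t-test p; binary targets get AUC with
    a permutation p.  All raw p-values are pooled per `family_rule`
    ("dataset": one Bonferroni family across every pair; "per_target":
    one family per target) and flagged at `alpha`.

    `roi_table` is indexed by subject_id; `phenotypes` must contain a
    subject_id column covering exactly the scored subjects.
    """
    pheno = phenotypes.set_index("subject_id") if "subject_id" in phenotypes.columns else phenotypes
    missing = roi_table.index.difference(pheno.index)
    if len(missing):
        raise ValueError(f"phenotypes missing for subjects: {sorted(missing)}")
    pheno = pheno.loc[roi_table.index]

    results: list[AssociationResult] = []
    for target_name, kind in targets.items():
        if target_name not in pheno.columns:
            raise ValueError(f"unknown target {target_name!r}")
        y = pheno[target_name].to_numpy()
        for roi_name in roi_table.columns:
            x = roi_table[roi_name].to_numpy(dtype=float)
            if kind == "numeric":
                stat = "pearson_r"
                try:
                    effect, p_raw = pearson_association(x, y.astype(float))
                except ValueError as exc:
                    if "zero variance" not in str(exc):
                        raise
                    # a constant column carries no evidence either way
                    warnings.warn(
                        f"({roi_name}, {target_name}): {exc}; recorded as null",
                        stacklevel=2,
                    )
                    effect, p_raw = float("nan"), 1.0
            elif kind == "binary":
                effect, p_raw = permutation_auc_pvalue(x, y.astype(int), permutation)
                stat = "auc"
            else:
                raise ValueError(f"unknown target type {kind!r} for {target_name!r}")
            results.append(
                AssociationResult(roi_name, target_name, stat, effect, p_raw,
                                  p_corrected=np.nan, n=len(x), significant=False)
            )

    if family_rule == "dataset":
        m = len(results)
        corrected = bonferroni_adjust([r.p_raw for r in results], m)
        for res, pc in zip(results, corrected):
            res.p_corrected = float(pc)
            res.significant = bool(pc < alpha)
    elif family_rule == "per_target":
        for target_name in targets:
            group = [r for r in results if r.target_name == target_name]
            corrected = bonferroni_adjust([r.p_raw for r in group], len(group))
            for res, pc in zip(group, corrected):
                res.p_corrected = float(pc)
                res.significant = bool(pc < alpha)
    else:
        raise ValueError(f"unknown family rule {family_rule!r}")
    return results


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def significant_effect_matrix(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Wide region x target matrix of effects, blank where non-significant
    (the layout of the published association tables)."""
    frame = results_to_frame(results)
    frame["cell"] = np.where(frame["significant"], frame["effect"].round(3), np.nan)
    return frame.pivot(index="roi_name", columns="target_name", values="cell")


def save_results(results: Sequence[AssociationResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(Path(path), index=False, float_format="%.10g")
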