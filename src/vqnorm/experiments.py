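"""Canned phantom experiments: parameter recovery and diagnosis recovery.

These are the package's reference study conditions: a 240-subject cohort
on a 32^3 grid with 10 regions, tokenizer vocabulary K=32 and a small
causal transformer, with atypicality injected as a gray-matter density
*reduction* (the usual direction of structural findings) in the two
regions with the highest baseline density.  High-baseline regions are
used because a downward shift there traverses the full span of typical
codebook clusters and is therefore detectable at any moderate magnitude;
a shift pushing intensities outside the typical range saturates into the
nearest extreme code (see the methods note on the detectability window).

The effect sizes are calibrated for a moderate effect: per unit of
symptom score the reduction is 0.012 density units, so a subject one
cohort standard deviation (~19 points) above the mean loses ~0.23 — one
to three codebook cluster spacings; the diagnosis effect is a flat 0.35
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .associations import AssociationResult, PermutationSpec, evaluate_dataset
from .autoregressive import TransformerConfig, serialize, train_autoregressor
from .cohort import (
    CohortSpec,
    EffectSpec,
    _cohort_region_params,
    phenotypes_to_frame,
    select_typical,
    simulate_cohort,
)
from .pipeline import assert_no_leak, split_cohort
from .scoring import ModelBundle, score_cohort
from .tokenizer import TokenizerConfig, tokenize, train_tokenizer

SCALE_GAMMA = -0.012  # density units per symptom-score point
DIAGNOSIS_GAMMA = -0.35  # flat density reduction in diagnosed subjects
COUPLED_SCALE = "total"
SPLITS = {"train": 0.5, "val": 0.2, "test": 0.3}


def highest_baseline_rois(spec: CohortSpec, k: int = 2) -> tuple[int, ...]:
    """Labels of the k regions with the highest baseline density."""
    baselines, _, _ = _cohort_region_params(spec)
    order = np.argsort(baselines)[::-1][:k] + 1
    return tuple(int(r) for r in sorted(order))


def parameter_recovery_spec(seed: int) -> CohortSpec:
    """Cohort with a symptom-coupled density reduction in two regions."""
    base = CohortSpec(seed=seed)
    rois = highest_baseline_rois(base)
    return CohortSpec(effects=(EffectSpec(COUPLED_SCALE, rois, SCALE_GAMMA),), seed=seed)


def diagnosis_recovery_spec(seed: int) -> CohortSpec:
    """Cohort with a diagnosis-coupled density reduction in two regions."""
    base = CohortSpec(seed=seed)
    rois = highest_baseline_rois(base)
    return CohortSpec(
        effects=(EffectSpec("diagnosis", rois, DIAGNOSIS_GAMMA),),
        diagnosis_prevalence=0.3,
        seed=seed,
    )


@dataclass
class RecoveryRun:
    spec: CohortSpec
    affected_rois: tuple[int, ...]
    roi_table: pd.DataFrame  # held-out test split scores
    phenotypes: pd.DataFrame
    results: list[AssociationResult]

    def roi_name(self, label: int) -> str:
        return f"ROI_{label:03d}"


def run_recovery(
    spec: CohortSpec,
    seed: int,
    epochs_tokenizer: int = 30,
    epochs_ar: int = 12,
    n_permutations: int = 1000,
) -> RecoveryRun:
    """Train the normative models on the typical lower-quartile subset and
    evaluate the association battery on the held-out test split."""
    atlas, phenotypes, volumes = simulate_cohort(spec)
    split_cohort(phenotypes, SPLITS, seed)
    train = [p for p in phenotypes if p.split == "train"]
    typical = select_typical(train, COUPLED_SCALE, 0.25)
    typical_volumes = [volumes[p.subject_id] for p in typical]

    tok_config = TokenizerConfig(epochs=epochs_tokenizer, seed=seed + 1)
    tok, _ = train_tokenizer(typical_volumes, tok_config)
    sequences = [
        serialize(tokenize(v, tok), subject_id=p.subject_id)
        for v, p in zip(typical_volumes, typical)
    ]
    ar_config = TransformerConfig(
        vocabulary_size=tok_config.vocabulary_size,
        context_length=len(sequences[0]),
        epochs=epochs_ar,
        seed=seed + 2,
    )
    model, _ = train_autoregressor(sequences, ar_config)

    test = [p for p in phenotypes if p.split == "test"]
    assert_no_leak([p.subject_id for p in typical], [p.subject_id for p in test])
    table = score_cohort(
        ModelBundle(tok, model), {p.subject_id: volumes[p.subject_id] for p in test}, atlas
    )

    targets = {name: "numeric" for name in spec.scales}
    targets["age"] = "numeric"
    if spec.diagnosis_prevalence is not None:
        targets["diagnosis"] = "binary"
    pheno_frame = phenotypes_to_frame(phenotypes)
    results = evaluate_dataset(
        table,
        pheno_frame,
        targets,  # type: ignore[arg-type]
        permutation=PermutationSpec(n_permutations, seed=seed + 3),
    )
    affected = tuple(sorted({r for e in spec.effects for r in e.rois}))
    return RecoveryRun(spec, affected, table, pheno_frame, results)


def familywise_error_rate(
    run: RecoveryRun,
    n_repeats: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Bonferroni validity check: re-run the association stage against
    independently permuted phenotypes (breaking every score-phenotype
    coupling, i.e. an effect-free null) and report the fraction of
    repeats with at least one significant pair."""
    rng = np.random.default_rng(seed)
    pheno = run.phenotypes[run.phenotypes["subject_id"].isin(run.roi_table.index)]
    targets = {name: "numeric" for name in run.spec.scales}
    targets["age"] = "numeric"
    hits = 0
    for _ in range(n_repeats):
        permuted = pheno.copy()
        cols = list(targets)
        permuted[cols] = pheno[cols].to_numpy()[rng.permutation(len(pheno))]
        results = evaluate_dataset(run.roi_table, permuted, targets, alpha=alpha)  # type: ignore[arg-type]
        hits += any(r.significant for r in results)
    return hits / n_repeats
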