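"""End-to-end orchestration: simulate -> train tokenizer -> train
autoregressor -> score -> associate.

Every stage reads its inputs from, and writes its artifacts to, a run
directory, together with a JSON manifest (config echo, seed, stage
timing).  Stages check that upstream artifacts exist and name the
producing stage when they do not.  Training uses only the typical
(lower-quantile) subset of the train split; evaluation uses the held-out
test split, and the train/test subject-id intersection is asserted empty
on every association run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import tokenizer as tk
from .associations import PermutationSpec, evaluate_dataset, save_results, significant_effect_matrix
from .autoregressive import (
    CausalTransformer,
    OrderingSpec,
    TransformerConfig,
    serialize,
    train_autoregressor,
)
from .scoring import ModelBundle, score_cohort, save_table
from .types import Volume3D

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train-tokenizer", "train-ar", "score", "associate")


@dataclass
class RunConfig:
    outdir: str = "vqnorm_run"
    cohort: ch.CohortSpec = field(default_factory=ch.CohortSpec)
    tokenizer: tk.TokenizerConfig = field(default_factory=tk.TokenizerConfig)
    autoregressor: TransformerConfig = field(default_factory=TransformerConfig)
    ordering: OrderingSpec = field(default_factory=OrderingSpec)
    split_fractions: dict[str, float] = field(
        default_factory=lambda: {"train": 0.5, "val": 0.2, "test": 0.3}
    )
    typical_scale: str = "total"
    typical_quantile: float = 0.25
    targets: dict[str, str] = field(default_factory=lambda: {"total": "numeric", "age": "numeric"})
    alpha: float = 0.05
    family_rule: Literal["dataset", "per_target"] = "dataset"
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed drives every stage through fixed offsets
        self.cohort.seed = self.seed
        self.tokenizer.seed = self.seed + 1
        self.autoregressor.seed = self.seed + 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        if "cohort" in raw:
            raw["cohort"] = ch.spec_from_jsonable(_fill_cohort_defaults(raw["cohort"]))
        if "tokenizer" in raw:
            raw["tokenizer"] = tk.TokenizerConfig(**raw["tokenizer"])
        if "autoregressor" in raw:
            raw["autoregressor"] = TransformerConfig(**raw["autoregressor"])
        if "ordering" in raw:
            o = raw["ordering"]
            raw["ordering"] = OrderingSpec(tuple(o["axis_order"]), tuple(o.get("reverse", (False,) * 3)))
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["cohort"] = ch._spec_to_jsonable(self.cohort)
        return d


def _fill_cohort_defaults(raw: Mapping) -> dict:
    base = ch._spec_to_jsonable(ch.CohortSpec())
    base.update(raw)
    return base


# ---------------------------------------------------------------------------
# split


def split_cohort(
    phenotypes: list[ch.SubjectPhenotype],
    fractions: Mapping[str, float],
    seed: int,
) -> list[ch.SubjectPhenotype]:
    """Assign each subject exactly one split; disjoint and exhaustive."""
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {total}")
    n = len(phenotypes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5F17]))
    order = rng.permutation(n)
    names = list(fractions)
    counts = [int(round(fractions[s] * n)) for s in names]
    counts[-1] = n - sum(counts[:-1])
    if any(c <= 0 for c in counts):
        raise ValueError(f"split produced an empty subset: {dict(zip(names, counts))}")
    bounds = np.cumsum([0] + counts)
    for s, lo, hi in zip(names, bounds[:-1], bounds[1:]):
        for i in order[lo:hi]:
            phenotypes[i].split = s
    return phenotypes


def assert_no_leak(train_ids, eval_ids) -> None:
    leak = set(train_ids) & set(eval_ids)
    if leak:
        raise RuntimeError(f"information leak: subjects in both training and evaluation: {sorted(leak)}")


# ---------------------------------------------------------------------------
# disk I/O helpers


def load_cohort(cohort_dir: Path):
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    atlas_img = nib.load(str(cohort_dir / manifest["files"]["atlas"]))
    spec = ch.spec_from_jsonable(manifest["spec"])
    atlas = ch.PhantomAtlas(
        np.asarray(atlas_img.dataobj).astype(np.int32),
        manifest["roi_names"],
        spec.voxel_size,
    )
    pheno = pd.read_csv(cohort_dir / manifest["files"]["phenotypes"])
    volumes = {}
    for sid, fname in manifest["files"]["volumes"].items():
        img = nib.load(str(cohort_dir / fname))
        volumes[sid] = Volume3D(np.asarray(img.dataobj, dtype=np.float64), spec.voxel_size)
    return spec, atlas, pheno, volumes


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{producing_stage}' stage first"
        )
    return path


def _write_manifest(outdir: Path, stage: str, config: RunConfig, started: float, extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "config": config.to_jsonable(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - started, 3),
    }
    if extra:
        manifest.update(extra)
    (outdir / f"manifest_{stage.replace('-', '_')}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> Path:
    started = time.time()
    outdir = Path(config.outdir)
    cohort_dir = outdir / "cohort"
    spec = config.cohort
    spec.validate()
    atlas, phenotypes, volumes = ch.simulate_cohort(spec)
    split_cohort(phenotypes, config.split_fractions, config.seed)
    ch.generate_cohort(spec, cohort_dir)  # writes volumes/atlas/manifest
    # overwrite the phenotype table with split assignments
    frame = ch.phenotypes_to_frame(phenotypes)
    frame.to_csv(cohort_dir / "phenotypes.csv", index=False, float_format="%.10g")
    _write_manifest(outdir, "simulate", config, started, {"n_subjects": len(phenotypes)})
    return cohort_dir


def _typical_training_volumes(config: RunConfig):
    cohort_dir = _require(Path(config.outdir) / "cohort", "simulate")
    spec, atlas, pheno, volumes = load_cohort(cohort_dir)
    train = pheno[pheno["split"] == "train"]
    subjects = [
        ch.SubjectPhenotype(
            r.subject_id, r.age, r.sex,
            {s: getattr(r, s) for s in spec.scales}, getattr(r, "diagnosis", None), r.split,
        )
        for r in train.itertuples(index=False)
    ]
    typical = ch.select_typical(subjects, config.typical_scale, config.typical_quantile)
    typical_ids = [p.subject_id for p in typical]
    return spec, atlas, pheno, volumes, typical_ids


def stage_train_tokenizer(config: RunConfig) -> Path:
    started = time.time()
    outdir = Path(config.outdir)
    spec, atlas, pheno, volumes, typical_ids = _typical_training_volumes(config)
    tok, report = tk.train_tokenizer([volumes[s] for s in typical_ids], config.tokenizer)
    path = outdir / "tokenizer.npz"
    tok.save(path)
    _write_manifest(outdir, "train-tokenizer", config, started, {
        "n_training_subjects": len(typical_ids),
        "initial_loss": report["initial_loss"],
        "final_loss": report["final_loss"],
        "n_dead_codes": report["n_dead_codes"],
    })
    return path


def stage_train_ar(config: RunConfig) -> Path:
    started = time.time()
    outdir = Path(config.outdir)
    tok = tk.VQTokenizer.load(_require(outdir / "tokenizer.npz", "train-tokenizer"))
    spec, atlas, pheno, volumes, typical_ids = _typical_training_volumes(config)

    sequences = [
        serialize(tk.tokenize(volumes[s], tok), config.ordering, subject_id=s)
        for s in typical_ids
    ]
    arc = dataclasses.replace(
        config.autoregressor,
        vocabulary_size=config.tokenizer.vocabulary_size,
        context_length=len(sequences[0]),
    )
    model, report = train_autoregressor(sequences, arc)
    path = outdir / "autoregressor.npz"
    model.save(path, ordering=config.ordering, latent_shape=sequences[0].latent_shape)
    _write_manifest(outdir, "train-ar", config, started, {
        "sequence_length": len(sequences[0]),
        "initial_loss": report["initial_loss"],
        "final_loss": report["final_loss"],
    })
    return path


def stage_score(config: RunConfig, split: str = "test") -> Path:
    started = time.time()
    outdir = Path(config.outdir)
    tok = tk.VQTokenizer.load(_require(outdir / "tokenizer.npz", "train-tokenizer"))
    model, ordering, _ = CausalTransformer.load(_require(outdir / "autoregressor.npz", "train-ar"))
    spec, atlas, pheno, volumes, typical_ids = _typical_training_volumes(config)
    eval_ids = pheno.loc[pheno["split"] == split, "subject_id"].tolist()
    if not eval_ids:
        raise ValueError(f"no subjects in split {split!r}")
    assert_no_leak(typical_ids, eval_ids)
    bundle = ModelBundle(tok, model, ordering or config.ordering)
    table = score_cohort(bundle, {s: volumes[s] for s in eval_ids}, atlas)
    path = outdir / f"scores_{split}.csv"
    save_table(table, path)
    _write_manifest(outdir, "score", config, started, {"split": split, "n_scored": len(table)})
    return path


def stage_associate(config: RunConfig, split: str = "test") -> Path:
    started = time.time()
    outdir = Path(config.outdir)
    scores_path = _require(outdir / f"scores_{split}.csv", "score")
    cohort_dir = _require(outdir / "cohort", "simulate")
    table = pd.read_csv(scores_path, index_col="subject_id")
    pheno = pd.read_csv(cohort_dir / "phenotypes.csv")
    pheno = pheno[pheno["split"] == split]
    train_ids = pd.read_csv(cohort_dir / "phenotypes.csv").query("split == 'train'")["subject_id"]
    assert_no_leak(train_ids, table.index)

    results = evaluate_dataset(
        table,
        pheno,
        targets=dict(config.targets),  # type: ignore[arg-type]
        alpha=config.alpha,
        family_rule=config.family_rule,
        permutation=PermutationSpec(config.n_permutations, seed=config.seed + 3),
    )
    path = outdir / f"associations_{split}.csv"
    save_results(results, path)
    significant_effect_matrix(results).to_csv(outdir / f"association_matrix_{split}.csv", float_format="%.3f")
    _write_manifest(outdir, "associate", config, started, {
        "split": split,
        "n_hypotheses": len(results),
        "n_significant": int(sum(r.significant for r in results)),
    })
    return path


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "train-tokenizer": stage_train_tokenizer,
    "train-ar": stage_train_ar,
    "score": stage_score,
    "associate": stage_associate,
}


def run_stage(stage_name: str, config: RunConfig) -> Path:
    if stage_name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage_name!r}; choose from {STAGES}")
    logger.info("running stage %s (seed=%d)", stage_name, config.seed)
    return _STAGE_FUNCS[stage_name](config)


def run_all(config: RunConfig) -> Path:
    for stage in STAGES:
        run_stage(stage, config)
    return Path(config.outdir)
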