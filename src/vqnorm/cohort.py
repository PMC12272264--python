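"""Synthetic phantom cohorts: atlas, phenotypes, gray-matter-like volumes.

Generates everything the downstream normative-modeling stages consume —
an integer-labelled parcellation, per-subject phenotype rows (age, sex,
right-skewed symptom-scale scores, optional binary diagnosis) and
VBM-style intensity volumes in which atypicality is injected as an
additive intensity shift in chosen regions, coupled either to a symptom
scale or to the diagnosis label.

Design notes
------------
* Scale scores follow a zero-inflated gamma: a point mass at zero plus a
  gamma tail, which reproduces the floor-heavy shape of caregiver-report
  symptom scales with two interpretable parameters.
* The deterministic signal (per-region baseline + age drift + injected
  effect) is piecewise-defined per region and is NOT spatially smoothed;
  only the noise field is smoothed.  This keeps two identities exact and
  testable: the mean intensity difference per unit score inside affected
  regions equals gamma, and group differences vanish identically outside
  affected regions.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .types import Volume3D

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PhantomAtlas:
    """Integer parcellation: 0 = background, 1..R = connected regions."""

    label_volume: np.ndarray
    roi_names: list[str]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0


@dataclass
class SubjectPhenotype:
    subject_id: str
    age: float
    sex: str  # "F" or "M"
    scale_scores: dict[str, float]
    diagnosis: int | None = None
    split: str = "unassigned"


@dataclass(frozen=True)
class ScaleModel:
    """Zero-inflated gamma for one symptom scale."""

    zero_inflation: float = 0.3
    shape: float = 1.5
    scale: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Additive intensity shift in `rois`, per unit of `target`.

    `target` is a scale name, or "diagnosis" for a shift applied to
    diagnosed subjects only.
    """

    target: str
    rois: tuple[int, ...]
    gamma: float


@dataclass
class CohortSpec:
    n_subjects: int = 240
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_rois: int = 10
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    effects: tuple[EffectSpec, ...] = ()
    # scale-score generative models; "total" is calibrated to a raw
    # caregiver-report total score (mean ~18, sd ~19) in a general-population
    # pediatric cohort, the subscales to roughly a third of that
    scales: Mapping[str, ScaleModel] = field(
        default_factory=lambda: {
            "total": ScaleModel(0.3, 2.0, 12.9),
            "social": ScaleModel(0.3, 1.5, 5.0),
            "internalizing": ScaleModel(0.3, 1.5, 5.0),
            "externalizing": ScaleModel(0.3, 1.5, 5.0),
        }
    )
    age_range: tuple[float, float] = (8.9, 10.9)
    male_fraction: float = 0.52
    diagnosis_prevalence: float | None = None  # None -> no diagnosis column
    # diagnosed subjects are the top-`prevalence` fraction of a liability
    # (total score + Gaussian noise of this sd), so diagnosis co-occurs
    # with elevated symptom scores as it does in clinical cohorts and is
    # largely excluded by lower-quantile typical selection
    diagnosis_liability_sd: float = 10.0
    baseline_range: tuple[float, float] = (0.3, 0.8)
    # subject-invariant smooth "anatomical" field added inside the brain
    # mask: real gray-matter maps have stable spatial structure shared
    # across subjects that dwarfs inter-subject noise; it also gives each
    # voxel patch a distinctive signature, so code assignment is driven by
    # anatomy rather than knife-edge scalar intensity
    texture_sd: float = 0.08
    texture_fwhm: float = 6.0  # mm
    age_slope_sd: float = 0.005  # intensity units per year, per region
    noise_sd: float = 0.02
    smoothing_fwhm: float = 4.0  # mm, applied to the noise field
    site_effect_sd: float = 0.0  # optional per-site additive offset
    n_sites: int = 1
    atlas_block: int = 4  # region boundaries drawn on this voxel lattice
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        for d in (self.noise_sd, self.age_slope_sd, self.site_effect_sd, self.smoothing_fwhm):
            if d < 0:
                raise ValueError("dispersions must be >= 0")
        for e in self.effects:
            if not set(e.rois) <= set(range(1, self.n_rois + 1)):
                raise ValueError(f"effect rois {e.rois} not within 1..{self.n_rois}")
            if e.target != "diagnosis" and e.target not in self.scales:
                raise ValueError(f"effect target {e.target!r} is not a declared scale")
            if e.target == "diagnosis" and self.diagnosis_prevalence is None:
                raise ValueError("diagnosis-coupled effect requires diagnosis_prevalence")


# ---------------------------------------------------------------------------
# atlas


def make_atlas(
    grid_shape: tuple[int, int, int],
    n_rois: int,
    seed: int,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    block: int = 1,
) -> PhantomAtlas:
    """Build a phantom parcellation: geodesic Voronoi cells of an
    ellipsoidal mask.

    Region seeds are drawn uniformly from the mask and regions grow
    outward from their seeds at equal speed (competitive dilation) until
    the mask is covered.  Every cell added is face-adjacent to its own
    region, so regions are connected by construction, and every seed owns
    at least its own cell, so all labels 1..n_rois are nonempty.

    With ``block`` > 1 the partition is computed on a lattice of
    block^3-voxel cells and upsampled, so region boundaries fall on that
    lattice.  Aligning ``block`` with the tokenizer's downsampling factor
    gives every latent token a unique region, which keeps injected
    regional effects exactly attributable to their region in token space
    (real parcellations do not have this property; see the methods note).
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if any(d < 8 for d in grid_shape):
        raise ValueError(f"each grid dimension must be >= 8, got {grid_shape}")
    if block < 1 or any(d % block for d in grid_shape):
        raise ValueError(f"block {block} must divide every grid dimension {grid_shape}")

    shape = tuple(int(d) for d in grid_shape)
    cell_shape = tuple(d // block for d in shape)
    center = (np.array(cell_shape) - 1) / 2.0
    semi = np.array(cell_shape) * 0.45
    ix = np.indices(cell_shape, dtype=np.float64)
    d2 = sum(((ix[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    mask = d2 <= 1.0

    coords = np.argwhere(mask)
    if len(coords) < n_rois:
        raise ValueError(
            f"cannot place ROIs: mask has {len(coords)} cells for {n_rois} regions"
        )
    rng = np.random.default_rng(seed)
    centroids = coords[rng.choice(len(coords), size=n_rois, replace=False)]

    cells = np.zeros(cell_shape, dtype=np.int32)
    cells[tuple(centroids.T)] = np.arange(1, n_rois + 1)
    structure = ndimage.generate_binary_structure(3, 1)
    while True:
        unlabeled = mask & (cells == 0)
        if not unlabeled.any():
            break
        # frontier cells adopt the largest neighboring label (deterministic)
        grown = ndimage.grey_dilation(cells, footprint=structure)
        frontier = unlabeled & (grown > 0)
        if not frontier.any():  # pragma: no cover - mask is connected
            raise RuntimeError("mask has cells unreachable from any seed")
        cells[frontier] = grown[frontier]

    labels = cells
    for axis in range(3):
        labels = np.repeat(labels, block, axis=axis)
    names = [f"ROI_{i:03d}" for i in range(1, n_rois + 1)]
    return PhantomAtlas(labels, names, tuple(voxel_size))


# ---------------------------------------------------------------------------
# phenotypes


def _sample_scale(rng: np.random.Generator, model: ScaleModel, n: int) -> np.ndarray:
    zero = rng.random(n) < model.zero_inflation
    values = rng.gamma(model.shape, model.scale, size=n)
    values[zero] = 0.0
    return values


def sample_phenotypes(spec: CohortSpec) -> list[SubjectPhenotype]:
    """Draw the phenotype table: ages uniform over the spec range, sex by
    the male fraction, each scale an independent zero-inflated gamma, and
    an optional independent Bernoulli diagnosis."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9E37]))
    n = spec.n_subjects
    ages = rng.uniform(*spec.age_range, size=n)
    sexes = np.where(rng.random(n) < spec.male_fraction, "M", "F")
    scores = {name: _sample_scale(rng, model, n) for name, model in spec.scales.items()}
    if spec.diagnosis_prevalence is not None:
        liability_base = scores.get("total")
        if liability_base is None:
            liability_base = scores[next(iter(scores))]
        liability = liability_base + rng.normal(0.0, spec.diagnosis_liability_sd, size=n)
        n_cases = int(round(spec.diagnosis_prevalence * n))
        diagnosis = np.zeros(n, dtype=int)
        diagnosis[np.argsort(liability)[n - n_cases :]] = 1
    else:
        diagnosis = None
    width = max(4, len(str(n)))
    return [
        SubjectPhenotype(
            subject_id=f"sub-{i:0{width}d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            scale_scores={k: float(v[i]) for k, v in scores.items()},
            diagnosis=None if diagnosis is None else int(diagnosis[i]),
        )
        for i in range(n)
    ]


def phenotypes_to_frame(cohort: Sequence[SubjectPhenotype]) -> pd.DataFrame:
    scale_names = list(cohort[0].scale_scores)
    rows = []
    for p in cohort:
        if list(p.scale_scores) != scale_names:
            raise ValueError("scale names must be identical across the cohort")
        row: dict = {
            "subject_id": p.subject_id,
            "age": p.age,
            "sex": p.sex,
            "split": p.split,
            "diagnosis": p.diagnosis,
        }
        row.update(p.scale_scores)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# volume rendering


def _cohort_region_params(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-region baseline intensity, age slope, and per-site offsets —
    fixed for the whole cohort by the cohort seed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA71A5]))
    lo, hi = spec.baseline_range
    baselines = rng.uniform(lo, hi, size=spec.n_rois)
    slopes = rng.normal(0.0, spec.age_slope_sd, size=spec.n_rois)
    site_offsets = rng.normal(0.0, spec.site_effect_sd, size=spec.n_sites)
    return baselines, slopes, site_offsets


def _noise_norm_factor(sigma_vox: np.ndarray, shape: tuple[int, int, int]) -> float:
    """Std-reduction factor of a discrete Gaussian filter (sqrt of the sum of
    squared kernel weights), measured on an impulse."""
    impulse = np.zeros(shape)
    impulse[tuple(d // 2 for d in shape)] = 1.0
    k = ndimage.gaussian_filter(impulse, sigma=sigma_vox)
    return float(np.sqrt(np.sum(k * k)))


def _subject_seed(spec_seed: int, subject_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([spec_seed, zlib.crc32(subject_id.encode())])


def _cohort_texture(spec: CohortSpec, atlas: PhantomAtlas) -> np.ndarray:
    """Smooth zero-mean field, identical for every subject, sd=texture_sd
    inside the brain mask, zero outside."""
    if spec.texture_sd <= 0:
        return np.zeros(atlas.label_volume.shape)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7E47]))
    field = rng.normal(0.0, 1.0, size=atlas.label_volume.shape)
    if spec.texture_fwhm > 0:
        sigma_vox = spec.texture_fwhm / (_FWHM_TO_SIGMA * np.asarray(atlas.voxel_size))
        field = ndimage.gaussian_filter(field, sigma=sigma_vox)
    mask = atlas.brain_mask
    inside = field[mask]
    field = (field - inside.mean()) / inside.std() * spec.texture_sd
    return field * mask


def render_volume(
    atlas: PhantomAtlas,
    phenotype: SubjectPhenotype,
    spec: CohortSpec,
    site: int = 0,
) -> Volume3D:
    """Render one subject's gray-matter-like volume.

    intensity(voxel) = region baseline + age_slope * (age - age0)
                       + sum of gamma * target over effects hitting the voxel
                       (+ site offset), plus spatially smoothed Gaussian
                       noise inside the brain mask, clipped to >= 0.
    """
    for e in spec.effects:
        if e.target != "diagnosis" and e.target not in phenotype.scale_scores:
            raise ValueError(
                f"phenotype of {phenotype.subject_id} lacks scale {e.target!r} "
                "referenced by the effect model"
            )

    labels = atlas.label_volume
    baselines, slopes, site_offsets = _cohort_region_params(spec)
    age0 = 0.5 * (spec.age_range[0] + spec.age_range[1])

    region_value = np.zeros(spec.n_rois + 1)
    region_value[1:] = baselines + slopes * (phenotype.age - age0)
    for e in spec.effects:
        if e.target == "diagnosis":
            amount = e.gamma * float(phenotype.diagnosis or 0)
        else:
            amount = e.gamma * phenotype.scale_scores[e.target]
        for r in e.rois:
            region_value[r] += amount
    if spec.site_effect_sd > 0:
        region_value[1:] += site_offsets[site % spec.n_sites]

    vol = region_value[labels] + _cohort_texture(spec, atlas)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(_subject_seed(spec.seed, phenotype.subject_id))
        noise = rng.normal(0.0, spec.noise_sd, size=labels.shape)
        if spec.smoothing_fwhm > 0:
            sigma_vox = spec.smoothing_fwhm / (_FWHM_TO_SIGMA * np.asarray(atlas.voxel_size))
            norm = _noise_norm_factor(sigma_vox, labels.shape)
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox) / norm
        vol = vol + noise * atlas.brain_mask

    return Volume3D(np.maximum(vol, 0.0), atlas.voxel_size)


# ---------------------------------------------------------------------------
# typical-subject selection


def select_typical(
    cohort: Sequence[SubjectPhenotype],
    scale_name: str = "total",
    quantile: float = 0.25,
) -> list[SubjectPhenotype]:
    """Normative training subset: subjects at or below the cohort's
    empirical `quantile` of `scale_name` (lower-quartile selection by
    default).  Ties at the threshold are kept."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    scores = np.array([p.scale_scores[scale_name] for p in cohort], dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError(f"non-finite {scale_name!r} scores; cannot select typical subset")
    threshold = float(np.quantile(scores, quantile))
    selected = [p for p, s in zip(cohort, scores) if s <= threshold]
    if not selected:
        raise ValueError("typical-subject selection is empty")
    if np.all(scores == scores[0]):
        warnings.warn(
            f"all {scale_name!r} scores are tied; typical subset is the whole cohort",
            stacklevel=2,
        )
    return selected


# ---------------------------------------------------------------------------
# full cohort generation


def simulate_cohort(
    spec: CohortSpec, atlas: PhantomAtlas | None = None
) -> tuple[PhantomAtlas, list[SubjectPhenotype], dict[str, Volume3D]]:
    """In-memory cohort: (atlas, phenotypes, subject_id -> volume)."""
    spec.validate()
    if atlas is None:
        atlas = make_atlas(
            spec.grid_shape, spec.n_rois, spec.seed, spec.voxel_size, block=spec.atlas_block
        )
    phenotypes = sample_phenotypes(spec)
    rng_site = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x517E]))
    sites = rng_site.integers(0, spec.n_sites, size=len(phenotypes))
    volumes = {
        p.subject_id: render_volume(atlas, p, spec, site=int(sites[i]))
        for i, p in enumerate(phenotypes)
    }
    return atlas, phenotypes, volumes


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["scales"] = {k: asdict(v) for k, v in spec.scales.items()}
    d["effects"] = [asdict(e) for e in spec.effects]
    return d


def spec_from_jsonable(d: Mapping) -> CohortSpec:
    d = dict(d)
    d["scales"] = {k: ScaleModel(**v) for k, v in d["scales"].items()}
    d["effects"] = tuple(EffectSpec(target=e["target"], rois=tuple(e["rois"]), gamma=e["gamma"]) for e in d["effects"])
    for key in ("grid_shape", "voxel_size", "age_range", "baseline_range"):
        d[key] = tuple(d[key])
    return CohortSpec(**d)


def generate_cohort(spec: CohortSpec, outdir: str | Path) -> dict:
    """Write the cohort to disk: one NIfTI per subject, the atlas NIfTI,
    a phenotype CSV and a JSON manifest (spec + seed + checksums) that
    suffices to regenerate the cohort byte-identically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas, phenotypes, volumes = simulate_cohort(spec)

    def _save_nifti(data: np.ndarray, path: Path) -> None:
        affine = np.diag(list(spec.voxel_size) + [1.0])
        img = nib.Nifti1Image(np.asarray(data), affine)
        img.header.set_zooms(spec.voxel_size)
        try:
            nib.save(img, str(path))
        except OSError as exc:  # pragma: no cover - environment-dependent
            raise OSError(f"failed to write {path}: {exc}") from exc

    _save_nifti(atlas.label_volume.astype(np.int16), outdir / "atlas.nii")
    for sid, vol in volumes.items():
        _save_nifti(vol.intensities.astype(np.float32), outdir / f"{sid}.nii")

    frame = phenotypes_to_frame(phenotypes)
    pheno_path = outdir / "phenotypes.csv"
    frame.to_csv(pheno_path, index=False, float_format="%.10g")

    files = {
        "atlas": "atlas.nii",
        "phenotypes": "phenotypes.csv",
        "volumes": {sid: f"{sid}.nii" for sid in volumes},
    }
    checksums = {"atlas.nii": _sha256(outdir / "atlas.nii"), "phenotypes.csv": _sha256(pheno_path)}
    checksums.update({f"{sid}.nii": _sha256(outdir / f"{sid}.nii") for sid in volumes})
    manifest = {
        "spec": _spec_to_jsonable(spec),
        "seed": spec.seed,
        "roi_names": atlas.roi_names,
        "files": files,
        "checksums": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
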