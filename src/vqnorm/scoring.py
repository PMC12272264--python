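"""From per-token likelihoods to voxel maps, ROI scores and whole-brain scores.

Each token's observed likelihood is replicated over the voxel block it was
encoded from (nearest-neighbor upscaling, no interpolation), giving a
voxel-resolution likelihood-of-typicality map.  The atlas is applied at
voxel resolution, so a token straddling two regions contributes to each in
proportion to its voxel overlap.  ROI scores are arithmetic means of the
map inside each label; the whole-brain score is the mean over all labelled
voxels, which excludes background blocks (trivially predictable background
would otherwise inflate typicality).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from . import tokenizer as tk
from .autoregressive import (
    CausalTransformer,
    OrderingSpec,
    PositionLikelihoods,
    deserialize,
    observed_token_likelihoods,
    serialize,
)
from .cohort import PhantomAtlas
from .types import Volume3D

logger = logging.getLogger(__name__)

WHOLE_BRAIN = "whole_brain"


@dataclass
class VoxelLikelihoodMap:
    values: np.ndarray  # 3-D, in [0, 1]
    subject_id: str | None = None

    def to_nifti(self, voxel_size=(2.0, 2.0, 2.0)) -> nib.Nifti1Image:
        affine = np.diag(list(voxel_size) + [1.0])
        return nib.Nifti1Image(self.values.astype(np.float32), affine)


def upscale_to_voxels(
    likelihoods: PositionLikelihoods,
    latent_shape: tuple[int, int, int],
    ordering: OrderingSpec,
    target_shape: tuple[int, int, int],
    subject_id: str | None = None,
) -> VoxelLikelihoodMap:
    """Reshape the likelihood sentence back onto the latent grid and
    block-replicate each value over its voxel block.

    The block-mean of the output recovers the input exactly.
    """
    factors = []
    for t, l in zip(target_shape, latent_shape):
        if t % l != 0:
            raise ValueError(
                f"target shape {target_shape} is not an integer multiple of "
                f"latent shape {latent_shape}"
            )
        factors.append(t // l)
    # likelihood values form a "grid" indexed exactly like the codes were
    grid = deserialize(
        np.arange(len(likelihoods)), latent_shape, ordering
    )  # position index at each grid location
    values = likelihoods.observed[grid.codes]
    for axis, f in enumerate(factors):
        values = np.repeat(values, f, axis=axis)
    return VoxelLikelihoodMap(values, subject_id=subject_id)


def aggregate_by_roi(voxel_map: VoxelLikelihoodMap, atlas: PhantomAtlas) -> dict[str, float]:
    """One subject's table row: ROI name -> mean likelihood, plus the
    whole-brain mean over all labelled voxels.  Empty ROIs are omitted
    (absent, not zero) with a warning."""
    values = voxel_map.values
    labels = atlas.label_volume
    if values.shape != labels.shape:
        raise ValueError(f"map shape {values.shape} != atlas shape {labels.shape}")
    row: dict[str, float] = {}
    for r, name in enumerate(atlas.roi_names, start=1):
        mask = labels == r
        if not mask.any():
            warnings.warn(f"ROI {name!r} has no voxels in the atlas; omitted", stacklevel=2)
            continue
        row[name] = float(values[mask].mean())
    row[WHOLE_BRAIN] = float(values[labels > 0].mean())
    return row


@dataclass
class ModelBundle:
    """Everything needed to score a subject: tokenizer, autoregressor and
    the serialization ordering they were trained with."""

    tokenizer: tk.VQTokenizer
    autoregressor: CausalTransformer
    ordering: OrderingSpec = OrderingSpec()


def score_volume(bundle: ModelBundle, volume: Volume3D, atlas: PhantomAtlas, subject_id: str | None = None) -> dict[str, float]:
    """encode -> quantize -> serialize -> likelihoods -> upscale -> aggregate."""
    grid = tk.tokenize(volume, bundle.tokenizer)
    seq = serialize(grid, bundle.ordering, subject_id=subject_id)
    lik = observed_token_likelihoods(bundle.autoregressor, seq)
    vmap = upscale_to_voxels(lik, grid.latent_shape, bundle.ordering, volume.shape, subject_id)
    return aggregate_by_roi(vmap, atlas)


def score_cohort(
    bundle: ModelBundle,
    volumes: Mapping[str, Volume3D],
    atlas: PhantomAtlas,
) -> pd.DataFrame:
    """ROI typicality table: one row per subject, columns = ROI names +
    whole_brain.  Per-subject failures are logged and the subject is
    excluded; the run continues."""
    rows = {}
    for sid, vol in volumes.items():
        try:
            rows[sid] = score_volume(bundle, vol, atlas, subject_id=sid)
        except Exception:
            logger.exception("scoring failed for subject %s; excluded", sid)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    return table


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), float_format="%.10g")
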