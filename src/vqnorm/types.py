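"""Shared domain containers for volumes and discrete latents."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Volume3D:
    """A 3-D grid of non-negative intensities with voxel geometry.

    The working representation of a gray-matter density map: values are
    tissue densities in arbitrary units (>= 0), ``voxel_size`` is the edge
    length of one voxel in millimetres along each axis.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.intensities.shape}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class LatentGrid:
    """A 3-D grid of discrete codebook indices (the tokenized brain)."""

    codes: np.ndarray
    vocabulary_size: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 3:
            raise ValueError(f"expected a 3-D code grid, got shape {self.codes.shape}")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("codes must be integers")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= self.vocabulary_size):
            raise ValueError(
                f"codes must lie in [0, {self.vocabulary_size}); "
                f"found range [{self.codes.min()}, {self.codes.max()}]"
            )

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        return self.codes.shape  # type: ignore[return-value]
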