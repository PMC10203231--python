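"""The in-memory BOLD acquisition container shared by every stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BoldRun"]


@dataclass
class BoldRun:
    """One 4D BOLD acquisition.

    Attributes
    ----------
    data : np.ndarray, shape (x, y, z, t)
        Signal intensities.
    tr : float
        Repetition time in seconds.
    mask : np.ndarray of bool, shape (x, y, z)
        Brain (analysis) mask.
    affine : np.ndarray, shape (4, 4)
        Voxel-to-mm map.
    meta : dict
        Subject/run labels and free-form metadata.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial shape of data")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def volume_times(self) -> np.ndarray:
        """Acquisition time of each volume (sampled at volume onset)."""
        return np.arange(self.n_volumes) * self.tr
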