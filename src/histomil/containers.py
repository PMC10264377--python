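"""In-memory containers flowing through the pipeline.

A :class:`SlideBag` is the universal unit: one slide represented as an ordered
bag of per-tile feature vectors plus per-tile grid metadata.  Patient-level
labels (binary molecular class, four continuous component scores, survival)
live in :class:`PatientRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .exceptions import ShapeMismatchError

#: canonical order of the four molecular components
COMPONENT_NAMES = ("classical", "basal", "stroma_active", "stroma_inactive")


@dataclass(frozen=True)
class ComponentScores:
    """Four continuous molecular component scores of one sample.

    ``classical`` and ``basal`` summarize the tumor-cell phenotype,
    ``stroma_active`` / ``stroma_inactive`` the fibrous compartment.
    """

    classical: float
    basal: float
    stroma_active: float
    stroma_inactive: float

    def as_array(self) -> np.ndarray:
        return np.array([self.classical, self.basal,
                         self.stroma_active, self.stroma_inactive])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "ComponentScores":
        a = np.asarray(a, dtype=float)
        if a.shape != (4,) or not np.all(np.isfinite(a)):
            raise ValueError("component scores must be 4 finite values")
        return cls(*a.tolist())


@dataclass
class SlideBag:
    """One slide as an ordered set of tile feature vectors.

    Attributes
    ----------
    slide_id, patient_id : str
    features : (n_tiles, d) float array
    tile_index : original tile indices (for traceability through gating)
    rows, cols : grid coordinates of each tile, row-major order
    """

    slide_id: str
    patient_id: str
    features: np.ndarray
    tile_index: np.ndarray = None
    rows: Optional[np.ndarray] = None
    cols: Optional[np.ndarray] = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ShapeMismatchError(
                f"slide {self.slide_id}: features must be 2-D, "
                f"got shape {self.features.shape}")
        if self.tile_index is None:
            self.tile_index = np.arange(self.n_tiles)
        self.tile_index = np.asarray(self.tile_index)
        if len(self.tile_index) != self.n_tiles:
            raise ShapeMismatchError(
                f"slide {self.slide_id}: tile_index length "
                f"{len(self.tile_index)} != n_tiles {self.n_tiles}")

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "SlideBag":
        """New bag keeping tiles ``idx`` (original indices preserved)."""
        idx = np.asarray(idx)
        return SlideBag(
            slide_id=self.slide_id,
            patient_id=self.patient_id,
            features=self.features[idx],
            tile_index=self.tile_index[idx],
            rows=None if self.rows is None else np.asarray(self.rows)[idx],
            cols=None if self.cols is None else np.asarray(self.cols)[idx],
        )


@dataclass
class PatientRecord:
    """Patient-level labels: binary subtype, component scores, survival."""

    patient_id: str
    purist_class: str                     # "classical" | "basal"
    components: ComponentScores
    time: float
    event: int
    slide_ids: List[str] = field(default_factory=list)
    # latent ground truth, present only for synthetic cohorts
    archetype: Optional[str] = None
    basal_fraction: Optional[float] = None

    @property
    def label(self) -> int:
        """Binary training label: basal-like = 1, classical = 0."""
        return int(self.purist_class == "basal")
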