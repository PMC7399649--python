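"""Streamline container and TCK/TRK round-trip.

Streamlines are ordered 3D polylines in world mm. TCK (the MRtrix dialect)
stores world coordinates directly and is the canonical on-disk format here;
TRK is accepted with nibabel handling its voxel-space header convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from nibabel.streamlines import Tractogram as _NibTractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile


@dataclass
class Tractogram:
    """A list of streamlines with optional per-streamline labels.

    ``labels`` entries are free-form dicts (e.g. ``{"is_true": True,
    "pair": (2, 5)}`` for phantom-generated streamlines).
    """

    streamlines: list[np.ndarray]
    labels: list[dict] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sls = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, np.float64)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (n>=2, 3) point array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} has non-finite coordinates")
            sls.append(arr)
        self.streamlines = sls
        if self.labels is not None and len(self.labels) != len(sls):
            raise ValueError("labels length must match number of streamlines")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def endpoints(self) -> np.ndarray:
        """(n, 2, 3) array of first/last points of each streamline."""
        return np.asarray([[s[0], s[-1]] for s in self.streamlines])

    def subset(self, indices) -> "Tractogram":
        idx = np.asarray(indices)
        idx = np.flatnonzero(idx) if idx.dtype == bool else idx.astype(np.int64)
        labels = [self.labels[i] for i in idx] if self.labels is not None else None
        return Tractogram([self.streamlines[i] for i in idx], labels, dict(self.meta))

    # ---- I/O ----------------------------------------------------------------

    def save(self, path) -> None:
        path = str(path)
        nt = _NibTractogram([s.astype(np.float32) for s in self.streamlines],
                            affine_to_rasmm=np.eye(4))
        if path.endswith(".tck"):
            TckFile(nt).save(path)
        elif path.endswith(".trk"):
            TrkFile(nt).save(path)
        else:
            raise ValueError(f"unsupported tractogram extension: {path}")

    @classmethod
    def load(cls, path) -> "Tractogram":
        tf = nib.streamlines.load(str(path))
        return cls([np.asarray(s, np.float64) for s in tf.tractogram.streamlines])


def arc_length(points: np.ndarray) -> float:
    pts = np.asarray(points, float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
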