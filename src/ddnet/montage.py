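"""Sensor montage: labels, 2-D positions, hemisphere assignment, adjacency.

The default montage is the 40-sensor dry-electrode layout used for the
word/pseudoword discrimination recordings: a mixture of 10-10 and 10-20
positions spanning frontal, central, temporal, parietal and occipital
sites.  Positions are taken from the standard 10-05 template (head-frame
coordinates, projected to the x-y plane), which is sufficient for the
spatial-neighbourhood graph the cluster-mass statistics need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

#: The 40 sensors of the recording system (10-10 ∪ 10-20 subset).
CHANNELS_40: tuple[str, ...] = (
    "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC3", "FC4", "FC6", "FT9", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP3", "CP1", "CP2", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8",
    "O1", "Oz", "O2",
)


def _hemisphere(label: str) -> str:
    """Classify a 10-10 label as left / right / midline from its suffix.

    Odd terminal digits are left hemisphere, even are right, 'z' is midline
    (FT9/FT10 follow the same odd/even rule).
    """
    tail = label.rstrip("0123456789")
    digits = label[len(tail):]
    if not digits:
        if label.endswith("z") or label.endswith("Z"):
            return "M"
        raise ValueError(f"cannot infer hemisphere for label {label!r}")
    return "L" if int(digits) % 2 == 1 else "R"


@dataclass(frozen=True)
class Montage:
    """An ordered sensor set with planar positions and hemisphere labels.

    Attributes
    ----------
    labels : tuple of str
        Channel names, fixing the channel order of every epoch array.
    positions : ndarray, shape (n, 2)
        Planar coordinates (meters in the template head frame).
    hemispheres : tuple of str
        One of ``'L'``, ``'R'``, ``'M'`` per channel.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    hemispheres: tuple[str, ...] = field(default=())

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_channels, 2)")
        object.__setattr__(self, "positions", pos)
        if not self.hemispheres:
            object.__setattr__(
                self, "hemispheres", tuple(_hemisphere(l) for l in self.labels)
            )
        if len(self.hemispheres) != len(self.labels):
            raise ValueError("hemispheres must match labels")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def hemisphere_indices(self, side: str) -> np.ndarray:
        """Channel indices on one side (``'L'``, ``'R'`` or ``'M'``)."""
        return np.flatnonzero(np.asarray(self.hemispheres) == side)

    def subset(self, labels) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(
            tuple(labels),
            self.positions[idx],
            tuple(np.asarray(self.hemispheres)[idx]),
        )

    def neighbor_matrix(self, prune_factor: float = 1.5) -> np.ndarray:
        """Boolean sensor-adjacency matrix for cluster formation.

        Delaunay triangulation of the planar positions, pruned by dropping
        edges longer than ``prune_factor`` times the median Delaunay edge
        length (long exterior edges of the convex hull would otherwise
        connect e.g. prefrontal and occipital rim sensors).
        """
        n = self.n_channels
        if n < 3:
            raise ValueError("need at least 3 sensors for a neighbourhood graph")
        tri = Delaunay(self.positions)
        adj = np.zeros((n, n), dtype=bool)
        for simplex in tri.simplices:
            for a in range(3):
                i, j = simplex[a], simplex[(a + 1) % 3]
                adj[i, j] = adj[j, i] = True
        lengths = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        cut = prune_factor * np.median(lengths[adj])
        adj &= lengths <= cut
        np.fill_diagonal(adj, False)
        return adj


def standard_montage(labels=CHANNELS_40) -> Montage:
    """Build a :class:`Montage` from the 10-05 electrode template.

    Parameters
    ----------
    labels : sequence of str
        Channel names; must exist in the 10-05 nomenclature.  Defaults to
        the 40-sensor recording layout.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos3d = std.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in pos3d]
    if missing:
        raise ValueError(f"labels not in 10-05 template: {missing}")
    xy = np.array([pos3d[l][:2] for l in labels], dtype=float)
    return Montage(tuple(labels), xy)
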