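"""Conformational ensembles: a topology plus stacked coordinate frames."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import Topology

__all__ = ["Ensemble"]


@dataclass
class Ensemble:
    """A labelled set of conformations of one structure.

    Parameters
    ----------
    topology:
        Shared atom table; every frame has the same atom order.
    coords:
        ``(F, N, 3)`` array of coordinates in Å.
    frame_labels:
        One label per frame (simulation time in ns, or a plain index).
        Window filtering operates on these labels, so an equilibrated
        segment such as 100–1000 ns can be cut out regardless of how many
        frames were stored.
    state:
        State label, e.g. ``"oxy"`` / ``"deoxy"``.
    replicate:
        Replicate index (0-based).
    """

    topology: Topology
    coords: np.ndarray
    frame_labels: np.ndarray = field(default=None)
    state: str = ""
    replicate: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if self.frame_labels is None:
            self.frame_labels = np.arange(1, self.coords.shape[0] + 1, dtype=float)
        else:
            self.frame_labels = np.asarray(self.frame_labels, dtype=float)
            if self.frame_labels.shape[0] != self.coords.shape[0]:
                raise ValueError("frame_labels length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def window(self, lo: float = None, hi: float = None, stride: int = 1) -> "Ensemble":
        """Restrict to frames whose label lies in [lo, hi], then stride.

        The stride is applied after the window cut, so ``window(100, 1000,
        10)`` keeps every tenth frame of the equilibrated segment.
        """
        mask = np.ones(self.n_frames, dtype=bool)
        if lo is not None:
            mask &= self.frame_labels >= lo
        if hi is not None:
            mask &= self.frame_labels <= hi
        idx = np.flatnonzero(mask)[::max(int(stride), 1)]
        return Ensemble(
            topology=self.topology,
            coords=self.coords[idx],
            frame_labels=self.frame_labels[idx],
            state=self.state,
            replicate=self.replicate,
        )

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]
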