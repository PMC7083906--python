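"""Localization tables: the coordinate lists SMLM pipelines exchange.

A localization table is nothing more than a list of emitter positions in
nanometres, 2D or 3D.  Every stage of the pipeline consumes and produces
this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LocalizationTable"]


@dataclass
class LocalizationTable:
    """Point coordinates in nanometres.

    Parameters
    ----------
    coords:
        ``(n, 2)`` or ``(n, 3)`` float array of positions in nm.
    point_id:
        Integer identifiers, one per point.  Assigned from row order when
        not supplied.
    """

    coords: np.ndarray
    point_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError(
                f"coords must be (n, 2) or (n, 3); got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("a localization table needs at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.point_id is None:
            self.point_id = np.arange(len(self.coords))
        else:
            self.point_id = np.asarray(self.point_id, dtype=int)
            if self.point_id.shape != (len(self.coords),):
                raise ValueError("point_id must align 1:1 with coords")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dims(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n
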