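"""The in-memory container for volumetric scans.

A :class:`Volume` holds a 3-D array of A-scan samples indexed ``(x, y, t)``:
``data[i, j, :]`` is the time-domain echo recorded at raster position
``(i, j)``.  Values are stored as float32 (the native precision of the file
format); all arithmetic elsewhere promotes to float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3-D real-valued scan volume with minimal acquisition metadata.

    Parameters
    ----------
    data:
        Real array of shape ``(nx, ny, nt)``; cast to float32 on construction.
    dt:
        Sampling interval of the time axis, in time units.
    provenance:
        Free-form label describing where the volume came from
        (e.g. ``"phantom:clean"`` or a file path).
    """

    data: np.ndarray
    dt: float = 1.0
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ParameterError(
                f"volume data must be 3-D (x, y, t); got ndim={arr.ndim}"
            )
        if arr.size == 0:
            raise ParameterError("volume data must be non-empty")
        arr = arr.astype(np.float32, copy=False)
        if not np.all(np.isfinite(arr)):
            raise ParameterError("volume data contains non-finite values")
        if not self.dt > 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        self.data = arr

    @property
    def nx(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nt(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), dt=self.dt, provenance=self.provenance,
                      meta=dict(self.meta))

    def with_data(self, data: np.ndarray, provenance: str | None = None) -> "Volume":
        """Return a new Volume sharing this one's metadata."""
        return Volume(
            np.asarray(data, dtype=np.float32),
            dt=self.dt,
            provenance=self.provenance if provenance is None else provenance,
            meta=dict(self.meta),
        )
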