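"""1D sampled quantities along axial or radial cuts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ProfileSeries"]


@dataclass
class ProfileSeries:
    """A quantity sampled along one coordinate, with units and metadata."""

    coordinate: np.ndarray
    values: np.ndarray
    quantity: str
    units: str
    coordinate_name: str = "z"
    coordinate_units: str = "m"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinate = np.asarray(self.coordinate, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.coordinate.shape != self.values.shape:
            raise ValueError("coordinate and values must have matching length")
        d = np.diff(self.coordinate)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("coordinates must be strictly monotone")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            f"{self.coordinate_name} [{self.coordinate_units}]": self.coordinate,
            f"{self.quantity} [{self.units}]": self.values,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def argmax_coordinate(self) -> float:
        return float(self.coordinate[np.nanargmax(self.values)])

    def argmin_coordinate(self) -> float:
        return float(self.coordinate[np.nanargmin(self.values)])
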