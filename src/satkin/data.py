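"""The XYDataSet container: (x, y) observations with units and replicates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["XYDataSet"]


@dataclass
class XYDataSet:
    """Paired observations of an independent variable x and response y.

    x may include 0 (the curve passes through the origin); y must be
    strictly positive wherever x > 0.  Unit labels are opaque strings.
    """

    x: np.ndarray
    y: np.ndarray
    x_unit: str = ""
    y_unit: str = ""
    replicate_ids: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise InputError("x and y must be one-dimensional")
        if self.x.shape != self.y.shape:
            raise InputError(
                f"x and y lengths differ: {self.x.size} vs {self.y.size}"
            )
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise InputError("x and y must be finite")
        if np.any(self.x < 0):
            idx = int(np.argmax(self.x < 0))
            raise InputError(f"x must be non-negative; offending index {idx}")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)
            if self.replicate_ids.shape != self.x.shape:
                raise InputError("replicate_ids length must match x")

    def __len__(self) -> int:
        return self.x.size

    @property
    def n_positive(self) -> int:
        """Number of points with x > 0 and y > 0 (usable in any fit)."""
        return int(np.sum((self.x > 0) & (self.y > 0)))

    def require_fittable(self, min_points: int = 3) -> None:
        """Raise InputError unless there are >= min_points distinct usable x."""
        usable = np.unique(self.x[(self.x > 0) & (self.y > 0)])
        if usable.size < min_points:
            raise InputError(
                f"fewer than {min_points} usable points: need at least "
                f"{min_points} distinct strictly positive x with y > 0, "
                f"found {usable.size}"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x_col: str = "x",
        y_col: str = "y",
        replicate_col: str = "replicate",
        **meta,
    ) -> "XYDataSet":
        for col in (x_col, y_col):
            if col not in df.columns:
                raise InputError(f"missing column {col!r}")
        reps = df[replicate_col].to_numpy() if replicate_col in df.columns else None
        return cls(
            x=df[x_col].to_numpy(dtype=float),
            y=df[y_col].to_numpy(dtype=float),
            replicate_ids=reps,
            **meta,
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"x": self.x, "y": self.y})
        if self.replicate_ids is not None:
            out["replicate"] = self.replicate_ids
        return out

    def averaged_replicates(self) -> "XYDataSet":
        """Pre-average replicate y values at each x (classical-plot option)."""
        df = self.to_dataframe().groupby("x", as_index=False)["y"].mean()
        return XYDataSet(
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            x_unit=self.x_unit,
            y_unit=self.y_unit,
            source=self.source + " (replicates averaged)",
        )
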