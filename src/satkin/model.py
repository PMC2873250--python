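"""Model/Results front end for saturation-curve fitting.

``SaturationModel`` wraps an :class:`~satkin.data.XYDataSet`; ``fit()``
returns a :class:`~satkin.estimation.FitResult` carrying the estimated
curve, residual diagnostics, optional bootstrap intervals, ``summary()``
and ``plot()``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .core import SaturationCurve
from .data import XYDataSet
from .estimation import FitResult, bootstrap_ci, fit_linear_transform, fit_nls

__all__ = ["SaturationModel"]


class SaturationModel:
    """Hyperbolic saturation model y = x/(1/kappa0 + x/y_sat) for a data set.

    Examples
    --------
    >>> import numpy as np
    >>> from satkin import SaturationModel
    >>> x = np.array([1., 2., 4., 8., 16.])
    >>> y = 10 * x / (5 + x)
    >>> res = SaturationModel(x, y).fit()
    >>> round(res.kappa0, 6), round(res.y_sat, 6)
    (2.0, 10.0)
    """

    def __init__(self, x, y=None, *, x_unit="", y_unit="",
                 replicate_ids=None, source=""):
        if isinstance(x, XYDataSet) and y is None:
            self.data = x
        else:
            self.data = XYDataSet(
                x=np.asarray(x, dtype=float),
                y=np.asarray(y, dtype=float),
                x_unit=x_unit, y_unit=y_unit,
                replicate_ids=replicate_ids, source=source,
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x_col="x", y_col="y", **meta):
        return cls(XYDataSet.from_dataframe(df, x_col=x_col, y_col=y_col, **meta))

    @classmethod
    def from_csv(cls, path) -> "SaturationModel":
        from .io import read_xy_csv

        return cls(read_xy_csv(path))

    def fit(
        self,
        method: str = "nls",
        weights: str = "uniform",
        init: Optional[SaturationCurve] = None,
        average_replicates: bool = False,
        n_boot: int = 0,
        seed: int = 0,
    ) -> FitResult:
        """Fit the two empirical constants.

        method : "nls" (default) or "linear_transform"
        weights : NLS residual weighting (uniform, inverse_y,
            inverse_y_squared)
        average_replicates : pre-average replicate y at each x before
            fitting (classical-plot compatibility); default fits raw points
        n_boot : if > 0, attach case-resampling bootstrap percentile
            intervals using ``seed``
        """
        data = self.data.averaged_replicates() if average_replicates else self.data
        if n_boot:
            return bootstrap_ci(data, method=method, n_boot=n_boot,
                                seed=seed, weights=weights)
        if method == "linear_transform":
            return fit_linear_transform(data)
        if method == "nls":
            return fit_nls(data, init=init, weights=weights)
        raise ValueError(f"unknown method {method!r}")
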