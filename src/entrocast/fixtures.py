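"""Packaged reference data: a published ten-day forecast comparison.

``guangzhou_jan2015`` is a ten-day table of observed daily PM2.5
concentrations in Guangzhou (22–31 January 2015) together with the
forecasts published for those days by an ARIMA model, a feed-forward
neural network, Brown quadratic exponential smoothing, and their
entropy-weighted combination.  ``REFERENCE_WEIGHTS`` is the combination
weight triple published alongside it.

These values are used as fixed *inputs* for replay-style checks — the
combination arithmetic and the error indexes can be reproduced from them
exactly — never as fitting targets.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_guangzhou_jan2015", "REFERENCE_WEIGHTS", "METHOD_COLUMNS"]

#: published combination weights for (arima, ann, esm)
REFERENCE_WEIGHTS = np.array([0.2399, 0.5419, 0.2182])

#: base-method column names in weight order
METHOD_COLUMNS = ("arima", "ann", "esm")


def load_guangzhou_jan2015() -> pd.DataFrame:
    """Load the ten-day reference table.

    Columns: ``date`` (datetime), ``actual``, ``arima``, ``ann``, ``esm``,
    ``cfm`` — all concentrations in µg/m³.
    """
    with resources.files("entrocast.data").joinpath("guangzhou_jan2015.csv").open() as fh:
        df = pd.read_csv(fh)
    df["date"] = pd.to_datetime(df["date"], format="mixed")
    return df
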