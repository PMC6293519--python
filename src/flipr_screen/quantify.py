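"""Reduce kinetic traces to the scalar total Ca2+ response.

The readout is the total agonist-induced change in fluorescence.  Two
reductions are provided: ``auc`` (default) integrates the
baseline-subtracted trace over the response window (a.u.·s) and captures
both the store-release and entry phases; ``peak`` takes the maximum
baseline-subtracted value (a.u.).  Negative excursions are kept, so
vehicle wells scatter around zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .errors import ConfigurationError
from .io import WellTrace

METHODS = ("auc", "peak")

MEASUREMENT_COLUMNS = ["plate_id", "replicate", "well", "role",
                       "amplicon_id", "gene_id", "baseline_f0", "ca_total",
                       "method"]


@dataclass(frozen=True)
class CaMeasurement:
    """Scalar total-Ca2+ readout for one well."""

    plate_id: str
    replicate: int
    well: str
    role: str
    amplicon_id: str
    gene_id: str
    baseline_f0: float
    ca_total: float
    method: str


def baseline(trace: WellTrace, window_end: float) -> float:
    """Mean fluorescence over samples strictly before ``window_end``."""
    mask = trace.times < window_end
    if mask.sum() < 2:
        raise ConfigurationError(
            f"baseline window before t={window_end} holds "
            f"{int(mask.sum())} samples; need >= 2")
    return float(trace.values[mask].mean())


def ca_total(
    trace: WellTrace,
    add_time: float,
    window_end: float | None = None,
    method: str = "auc",
    *,
    baseline_window_end: float | None = None,
    median_filter_width: int = 0,
) -> CaMeasurement:
    """Total agonist-induced fluorescence change for one well.

    The baseline is the pre-addition mean (window configurable); the
    response window runs from ``add_time`` to ``window_end`` (default: end
    of trace).  ``median_filter_width`` (odd, 0 = off) optionally smooths
    the trace before reduction.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}")
    if add_time >= trace.times[-1]:
        raise ConfigurationError("add_time is at or past the last sample")
    values = trace.values
    if median_filter_width:
        values = medfilt(values, kernel_size=median_filter_width)
    if window_end is None:
        window_end = float(trace.times[-1])
    f0 = baseline(trace, baseline_window_end
                  if baseline_window_end is not None else add_time)
    mask = (trace.times >= add_time) & (trace.times <= window_end)
    if mask.sum() < 2:
        raise ConfigurationError("response window holds fewer than 2 samples")
    dev = values[mask] - f0
    if method == "auc":
        total = float(np.trapezoid(dev, trace.times[mask]))
    else:
        total = float(dev.max())
    return CaMeasurement(trace.plate_id, trace.replicate, trace.well,
                         trace.role, trace.amplicon_id, trace.gene_id,
                         f0, total, method)


def quantify_traces(
    traces: list[WellTrace],
    add_time: float,
    window_end: float | None = None,
    method: str = "auc",
    **kwargs,
) -> pd.DataFrame:
    """One measurement row per trace (columns MEASUREMENT_COLUMNS)."""
    rows = [ca_total(t, add_time, window_end, method, **kwargs)
            for t in traces]
    return pd.DataFrame([m.__dict__ for m in rows],
                        columns=MEASUREMENT_COLUMNS)
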