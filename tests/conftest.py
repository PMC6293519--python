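import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from flipr_screen import (TraceModelParams, WellTrace, generate_design,
                          quantify_traces, simulate_plate)

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def noise_free_params():
    return TraceModelParams(well_cv=0.0, read_noise_sd=0.0)


@pytest.fixture
def small_design():
    """20 genes on a single layout plate, no planted effects."""
    return generate_design(20, frac_suppressor=0.0, frac_enhancer=0.0,
                           frac_two_amplicons=0.0, seed=11)


def make_trace(times, values, *, well="A01", role="library",
               amplicon="AMP00000", gene="SYN00000"):
    return WellTrace("P001", 1, well, role, amplicon, gene,
                     np.asarray(times, float), np.asarray(values, float))


@pytest.fixture
def step_trace():
    """Baseline 1.0 then a 2.0-high pulse held for 10 samples at 1 s,
    with one baseline sample on each side of the pulse inside the
    response window (agonist added at t = 2 s)."""
    times = np.arange(14.0)
    values = np.array([1.0, 1.0, 1.0] + [3.0] * 10 + [1.0])
    return make_trace(times, values)


def measurement_frame(ca_totals, roles=None, plate="P001", replicate=1):
    """Minimal measurements table from raw ca_total values."""
    n = len(ca_totals)
    roles = roles or ["library"] * n
    return pd.DataFrame({
        "plate_id": [plate] * n,
        "replicate": [replicate] * n,
        "well": [f"{chr(65 + i // 24)}{i % 24 + 1:02d}" for i in range(n)],
        "role": roles,
        "amplicon_id": [f"AMP{i:05d}" if r == "library" else ""
                        for i, r in enumerate(roles)],
        "gene_id": [f"SYN{i:05d}" if r == "library" else ""
                    for i, r in enumerate(roles)],
        "baseline_f0": [1000.0] * n,
        "ca_total": list(ca_totals),
        "method": ["auc"] * n,
    })


def simulate_measurements(design, truth, params, seed=0, replicates=(1,)):
    """Quantified measurements for every plate of a design."""
    frames = []
    for p in range(design.n_layout_plates):
        for r in replicates:
            traces = simulate_plate(design, p, r, truth, params, seed)
            frames.append(quantify_traces(traces,
                                          params.agonist_add_time))
    return pd.concat(frames, ignore_index=True)
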