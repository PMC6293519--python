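"""Kinetic fluorescence trace simulation for synthetic screening plates.

Each well's trace is a flat baseline with additive Gaussian read noise;
at the agonist-addition time a difference-of-exponentials Ca2+ transient is
added whose amplitude encodes the planted knockdown effect:

    amplitude = peak_amplitude * (1 - plate_efficiency * (1 - multiplier))
                * lognormal(cv = well_cv)

A multiplier of 1 (no effect) gives the full response; 0 with perfect
knockdown efficiency abolishes it; multipliers above 1 model enhancers.
``plate_efficiency`` scales every knockdown on a plate toward null,
modelling plates whose dsRNA treatment failed — the internal positive
control (true multiplier 0) on such a plate shows weak inhibition, which
is what the downstream QC gate detects.  Vehicle wells receive no
transient.  Per-plate RNG streams are derived from
(seed, plate_index, replicate), so any plate is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import GroundTruth, LibraryDesign
from .errors import ConfigurationError
from .io import WellTrace


@dataclass(frozen=True)
class TraceModelParams:
    """Trace-model parameters (fluorescence in arbitrary units, time in s)."""

    baseline_f0: float = 1000.0
    agonist_add_time: float = 30.0
    n_timepoints: int = 90
    dt: float = 1.0
    peak_amplitude: float = 500.0
    rise_tau: float = 3.0
    decay_tau: float = 15.0
    well_cv: float = 0.05
    read_noise_sd: float = 5.0
    plate_efficiency: float = 1.0

    def __post_init__(self):
        if self.dt <= 0 or self.n_timepoints < 2:
            raise ConfigurationError("need dt > 0 and n_timepoints >= 2")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ConfigurationError("time constants must be positive")
        if self.rise_tau >= self.decay_tau:
            raise ConfigurationError("rise_tau must be below decay_tau")
        if self.well_cv < 0 or self.read_noise_sd < 0:
            raise ConfigurationError("noise parameters must be non-negative")
        if not 0.0 <= self.plate_efficiency <= 1.0:
            raise ConfigurationError("plate_efficiency must be in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt

    def unit_transient(self) -> np.ndarray:
        """Peak-normalized transient sampled on the time grid (0 before
        agonist addition, maximum value 1 in continuous time)."""
        s = self.times - self.agonist_add_time
        s = np.where(s > 0, s, np.inf)  # inf -> exp() underflows to 0
        tr, td = self.rise_tau, self.decay_tau
        s_peak = tr * td / (td - tr) * math.log(td / tr)
        g_peak = math.exp(-s_peak / td) - math.exp(-s_peak / tr)
        return (np.exp(-s / td) - np.exp(-s / tr)) / g_peak


def response_amplitude(effect_multiplier: float,
                       params: TraceModelParams) -> float:
    """Noise-free transient amplitude for one well (a.u.)."""
    if effect_multiplier < 0:
        raise ConfigurationError("effect_multiplier must be >= 0")
    return params.peak_amplitude * (
        1.0 - params.plate_efficiency * (1.0 - effect_multiplier))


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       n: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def simulate_trace(
    effect_multiplier: float,
    params: TraceModelParams,
    rng: np.random.Generator | None = None,
    *,
    plate_id: str = "P001",
    replicate: int = 1,
    well: str = "A01",
    role: str = "library",
    amplicon_id: str = "",
    gene_id: str = "",
) -> WellTrace:
    """Simulate a single well.  Vehicle wells get baseline + read noise only."""
    if rng is None:
        rng = np.random.default_rng(0)
    if role == "vehicle":
        amp = 0.0
    else:
        amp = response_amplitude(effect_multiplier, params) \
            * _lognormal_factors(rng, params.well_cv, 1)[0]
    values = params.baseline_f0 + amp * params.unit_transient()
    if params.read_noise_sd > 0:
        values = values + rng.normal(0, params.read_noise_sd,
                                     size=params.n_timepoints)
    return WellTrace(plate_id, replicate, well, role, amplicon_id, gene_id,
                     params.times, values)


def _plate_rng(seed: int, plate_index: int, replicate: int
               ) -> np.random.Generator:
    return np.random.default_rng((seed, plate_index, replicate))


def simulate_plate(
    design: LibraryDesign,
    plate_index: int,
    replicate: int,
    truth: GroundTruth,
    params: TraceModelParams,
    seed: int = 0,
) -> list[WellTrace]:
    """Simulate every laid-out well of one plate (one replicate).

    Internal-control wells use the design's internal-control multiplier
    (default 0: full pathway block), attenuated only by the plate's
    knockdown efficiency; control-dsRNA wells have multiplier 1.
    """
    if not 0 <= plate_index < design.n_layout_plates:
        raise ConfigurationError(
            f"plate_index {plate_index} outside 0..{design.n_layout_plates - 1}")
    pid = design.plate_ids[plate_index]
    sub = design.plate_layout(pid)
    rng = _plate_rng(seed, plate_index, replicate)

    mult = np.empty(len(sub))
    for i, (role, gene) in enumerate(zip(sub["role"], sub["gene_id"])):
        if role == "library":
            mult[i] = truth.effect[gene]
        elif role == "internal_control":
            mult[i] = design.internal_control_multiplier
        else:  # control_dsRNA or vehicle
            mult[i] = 1.0
    amp = params.peak_amplitude * (
        1.0 - params.plate_efficiency * (1.0 - mult))
    amp = amp * _lognormal_factors(rng, params.well_cv, len(sub))
    amp[(sub["role"] == "vehicle").to_numpy()] = 0.0

    g = params.unit_transient()
    values = params.baseline_f0 + amp[:, None] * g[None, :]
    if params.read_noise_sd > 0:
        values = values + rng.normal(
            0, params.read_noise_sd, size=(len(sub), params.n_timepoints))

    times = params.times
    return [
        WellTrace(pid, replicate, w, role, a, gn, times, v)
        for w, role, a, gn, v in zip(sub["well"], sub["role"],
                                     sub["amplicon_id"], sub["gene_id"],
                                     values)
    ]


@dataclass(frozen=True)
class PlateEfficiencyModel:
    """Two-component mixture for per-plate knockdown efficiency: most
    plates are good (efficiency near 1); a ``p_fail`` fraction failed
    (efficiency below the QC-detectable range)."""

    p_fail: float = 0.05
    good_mean: float = 0.95
    good_sd: float = 0.03
    fail_low: float = 0.2
    fail_high: float = 0.55

    def __post_init__(self):
        if not 0.0 <= self.p_fail <= 1.0:
            raise ConfigurationError("p_fail must be in [0, 1]")
        if not 0.0 <= self.fail_low <= self.fail_high <= 1.0:
            raise ConfigurationError("failed-range bounds must be in [0, 1]")

    def draw(self, rng: np.random.Generator) -> float:
        if rng.random() < self.p_fail:
            return float(rng.uniform(self.fail_low, self.fail_high))
        return float(np.clip(rng.normal(self.good_mean, self.good_sd), 0, 1))


def simulate_library(
    design: LibraryDesign,
    truth: GroundTruth,
    params: TraceModelParams,
    seed: int = 0,
    efficiency_model: PlateEfficiencyModel | None = None,
) -> tuple[dict[tuple[str, int], list[WellTrace]], pd.DataFrame]:
    """Simulate every (layout plate × replicate) dataset of the library.

    Returns the trace collections keyed by (plate_id, replicate) and a
    table of the drawn per-plate knockdown efficiencies.  When no
    efficiency model is given, ``params.plate_efficiency`` applies to all
    plates.
    """
    eff_rows = []
    datasets: dict[tuple[str, int], list[WellTrace]] = {}
    eff_rng = np.random.default_rng((seed, 999_983))
    for p in range(design.n_layout_plates):
        for r in range(1, design.n_replicates + 1):
            if efficiency_model is not None:
                pe = efficiency_model.draw(eff_rng)
                plate_params = replace(params, plate_efficiency=pe)
            else:
                pe = params.plate_efficiency
                plate_params = params
            pid = design.plate_ids[p]
            datasets[(pid, r)] = simulate_plate(
                design, p, r, truth, plate_params, seed)
            eff_rows.append({"plate_id": pid, "replicate": r,
                             "plate_efficiency": pe})
    eff = pd.DataFrame(eff_rows,
                       columns=["plate_id", "replicate", "plate_efficiency"])
    return datasets, eff
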