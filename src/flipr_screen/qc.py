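"""Internal-control plate gate.

A plate is trusted only if its internal positive-control dsRNA (an
IP3-receptor-class construct that should abolish the response) inhibits
the agonist response of the control-dsRNA wells by at least the cutoff
(default 60%).  All data from failing plates are discarded; every decision
is recorded so discards are auditable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import InvalidControlError, QCNotEvaluableError
from .stats import percent_inhibition

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 60.0

QC_COLUMNS = ["plate_id", "replicate", "control_inhibition", "cutoff",
              "passed", "n_internal_control_wells", "n_control_wells",
              "reason"]


@dataclass(frozen=True)
class QCResult:
    plate_id: str
    replicate: int
    control_inhibition: float  # percent; NaN if not evaluable
    cutoff: float
    passed: bool
    n_internal_control_wells: int
    n_control_wells: int
    reason: str = ""


def qc_plate(measurements: pd.DataFrame,
             cutoff: float = DEFAULT_CUTOFF) -> QCResult:
    """Gate one plate dataset on internal-control percent inhibition.

    Inhibition is computed from the mean ca_total of internal-control
    wells against the mean of control-dsRNA wells on the same plate
    (vehicle wells play no part).  The boundary is inclusive: exactly the
    cutoff passes.
    """
    groups = measurements.groupby(["plate_id", "replicate"])
    if len(groups) != 1:
        raise ValueError("qc_plate expects exactly one plate dataset")
    (pid, rep), = groups.groups
    ic = measurements[measurements["role"] == "internal_control"]
    cd = measurements[measurements["role"] == "control_dsRNA"]
    if ic.empty or cd.empty:
        raise QCNotEvaluableError(
            f"plate {pid} replicate {rep}: "
            f"{len(ic)} internal-control and {len(cd)} control wells")
    inhibition = percent_inhibition(ic["ca_total"].mean(),
                                    cd["ca_total"].mean())
    return QCResult(pid, int(rep), float(inhibition), cutoff,
                    passed=inhibition >= cutoff - 1e-9,
                    n_internal_control_wells=len(ic),
                    n_control_wells=len(cd))


def filter_plates(measurements: pd.DataFrame,
                  cutoff: float = DEFAULT_CUTOFF
                  ) -> tuple[pd.DataFrame, list[QCResult]]:
    """Drop every measurement from plates failing the control gate.

    A QCResult is emitted for every plate dataset, including those that
    cannot be evaluated (missing control wells, non-positive control
    mean), which are discarded with the reason recorded.
    """
    if measurements.empty:
        return measurements.copy(), []
    results: list[QCResult] = []
    kept = []
    for (pid, rep), grp in measurements.groupby(["plate_id", "replicate"],
                                                sort=False):
        try:
            res = qc_plate(grp, cutoff)
        except (QCNotEvaluableError, InvalidControlError) as exc:
            res = QCResult(pid, int(rep), float("nan"), cutoff, False,
                           n_internal_control_wells=int(
                               (grp["role"] == "internal_control").sum()),
                           n_control_wells=int(
                               (grp["role"] == "control_dsRNA").sum()),
                           reason=str(exc))
        results.append(res)
        if res.passed:
            kept.append(grp)
        else:
            why = res.reason or (
                f"inhibition {res.control_inhibition:.1f}% < {cutoff:.0f}%")
            log.info("discarding plate %s replicate %s: %s", pid, rep, why)
    if kept:
        surviving = pd.concat(kept, ignore_index=True)
    else:
        surviving = measurements.iloc[0:0].copy()
    return surviving, results


def qc_report(results: list[QCResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = r.__dict__.copy()
        if isinstance(d["control_inhibition"], float) and \
                math.isnan(d["control_inhibition"]):
            d["control_inhibition"] = float("nan")
        rows.append(d)
    return pd.DataFrame(rows, columns=QC_COLUMNS)
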