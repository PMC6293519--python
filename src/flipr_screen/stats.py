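"""Per-plate Z-scores, percent inhibition and replicate merging.

The screen's hit statistic is the per-plate Z-score of a dsRNA:

    Z = (well Ca_total - plate mean Ca_total) / plate SD of Ca_total

By default the mean and SD are taken over library wells only
(``policy="library_only"``), so dedicated control wells cannot bias the
null center; ``policy="all_wells"`` reproduces the alternative reading.
The SD is the sample (n-1) standard deviation.  Replicate plates are
merged by the unweighted arithmetic mean of an amplicon's per-plate
Z-scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (DegeneratePlateError, InsufficientDataError,
                     InvalidControlError)

POLICIES = ("library_only", "all_wells")

ZSCORE_COLUMNS = ["plate_id", "replicate", "amplicon_id", "gene_id", "z"]


def plate_zscores(measurements: pd.DataFrame,
                  policy: str = "library_only") -> pd.DataFrame:
    """Z-scores for the library wells of one plate dataset.

    ``measurements`` must hold a single (plate_id, replicate) group with a
    ``ca_total`` column.  Control and vehicle wells never receive a Z but
    may enter the centering population under ``policy="all_wells"``.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    groups = measurements.groupby(["plate_id", "replicate"])
    if len(groups) != 1:
        raise ValueError("plate_zscores expects exactly one plate dataset")
    lib = measurements[measurements["role"] == "library"]
    if len(lib) < 3:
        raise DegeneratePlateError(
            f"plate has {len(lib)} library wells; need >= 3")
    pop = lib if policy == "library_only" else measurements
    center = pop["ca_total"].mean()
    sd = pop["ca_total"].std(ddof=1)
    if not sd > 0:
        (pid, rep), = groups.groups
        raise DegeneratePlateError(
            f"plate {pid} replicate {rep}: zero spread in ca_total")
    out = lib[["plate_id", "replicate", "amplicon_id", "gene_id"]].copy()
    out["z"] = (lib["ca_total"] - center) / sd
    return out.reset_index(drop=True)


def screen_zscores(measurements: pd.DataFrame,
                   policy: str = "library_only"
                   ) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Z-scores for every plate dataset; degenerate plates are flagged
    (returned, not scored) rather than raising."""
    frames = []
    degenerate: list[tuple[str, int]] = []
    for (pid, rep), grp in measurements.groupby(["plate_id", "replicate"],
                                                sort=False):
        try:
            frames.append(plate_zscores(grp, policy))
        except DegeneratePlateError:
            degenerate.append((pid, int(rep)))
    if frames:
        z = pd.concat(frames, ignore_index=True)
    else:
        z = pd.DataFrame(columns=ZSCORE_COLUMNS)
    return z, degenerate


def percent_inhibition(test_mean: float, control_mean: float) -> float:
    """100 × (1 − test/control); negative = potentiation, >100 = below
    vehicle."""
    if not control_mean > 0:
        raise InvalidControlError(
            f"control mean must be positive, got {control_mean}")
    return 100.0 * (1.0 - test_mean / control_mean)


MERGED_COLUMNS = ["amplicon_id", "gene_id", "mean_z", "n_replicates",
                  "per_replicate_z"]


def merge_replicates(records: pd.DataFrame,
                     amplicon_universe: list[str] | None = None
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Replicate-averaged Z per amplicon.

    Returns the merged table plus the list of unmeasured amplicons (those
    in ``amplicon_universe`` with no surviving replicate — plates can have
    been discarded by QC).  Surviving extra assays of the same amplicon
    (replacement plates) enter the mean as additional replicates.
    """
    if records.empty:
        merged = pd.DataFrame(columns=MERGED_COLUMNS)
    else:
        rows = []
        for amp, grp in records.groupby("amplicon_id", sort=False):
            zs = grp["z"].to_list()
            rows.append({"amplicon_id": amp,
                         "gene_id": grp["gene_id"].iloc[0],
                         "mean_z": float(np.mean(zs)),
                         "n_replicates": len(zs),
                         "per_replicate_z": zs})
        merged = pd.DataFrame(rows, columns=MERGED_COLUMNS)
    unmeasured = []
    if amplicon_universe is not None:
        measured = set(merged["amplicon_id"])
        unmeasured = [a for a in amplicon_universe if a not in measured]
    return merged, unmeasured


def replicate_scatter(records: pd.DataFrame, replicate_a: int,
                      replicate_b: int) -> tuple[pd.DataFrame, float]:
    """Paired per-amplicon Z table for two replicates plus their Pearson
    correlation (the screen's reproducibility check)."""
    a = records[records["replicate"] == replicate_a]
    b = records[records["replicate"] == replicate_b]
    pairs = a.merge(b, on="amplicon_id", suffixes=("_a", "_b"))
    pairs = pairs[["amplicon_id", "z_a", "z_b"]]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"only {len(pairs)} amplicons present in both replicates; "
            "need >= 3")
    r = float(np.corrcoef(pairs["z_a"], pairs["z_b"])[0, 1])
    return pairs.reset_index(drop=True), r
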