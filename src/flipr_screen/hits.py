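"""Hit calling from replicate-merged Z-scores.

An amplicon is a suppressor ("down") hit when its mean Z is strictly below
the low threshold (default −3) and an enhancer ("up") hit when strictly
above the high threshold (default +3); the fixed cutoffs deliberately
trade sensitivity for a low false-positive rate.  Gene-level calls
aggregate amplicons (default policy: any one suffices); genes whose
amplicons disagree in direction are quarantined in a conflict report
rather than resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .design import GroundTruth
from .errors import MappingError

CALL_COLUMNS = ["amplicon_id", "gene_id", "mean_z", "n_replicates", "call"]
HIT_COLUMNS = ["gene_id", "direction", "amplicon_ids", "mean_zs",
               "n_hit_amplicons", "n_tested_amplicons"]


@dataclass(frozen=True)
class HitRecord:
    gene_id: str
    direction: str  # "down" | "up"
    amplicon_evidence: tuple[tuple[str, float], ...] = field(default=())
    n_hit_amplicons: int = 0
    n_tested_amplicons: int = 0


def call_amplicons(merged: pd.DataFrame, low: float = -3.0,
                   high: float = 3.0) -> pd.DataFrame:
    """Per-amplicon calls: down (mean_z < low), up (mean_z > high), none."""
    if not low < 0 < high:
        raise ValueError("thresholds must satisfy low < 0 < high")
    out = merged.copy()
    out["call"] = "none"
    out.loc[out["mean_z"] < low, "call"] = "down"
    out.loc[out["mean_z"] > high, "call"] = "up"
    return out


def aggregate_genes(calls: pd.DataFrame, policy: str = "any"
                    ) -> tuple[list[HitRecord], pd.DataFrame]:
    """Gene-level hits from amplicon calls.

    ``policy="any"``: one called amplicon makes the gene a hit (the
    published tables list single-amplicon hits, so one must suffice);
    ``policy="all"``: every tested amplicon must agree.  Genes with
    amplicons called in opposite directions go to the conflict table and
    to neither hit list.
    """
    if policy not in ("any", "all"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    if calls["gene_id"].isna().any() or (calls["gene_id"] == "").any():
        bad = calls.loc[calls["gene_id"].isna() | (calls["gene_id"] == ""),
                        "amplicon_id"].tolist()
        raise MappingError(f"amplicons without a gene mapping: {bad}")

    hits: list[HitRecord] = []
    conflicts = []
    for gene, grp in calls.groupby("gene_id", sort=False):
        called = grp[grp["call"] != "none"]
        if called.empty:
            continue
        directions = set(called["call"])
        if len(directions) > 1:
            conflicts.append({
                "gene_id": gene,
                "amplicon_ids": ";".join(grp["amplicon_id"]),
                "mean_zs": ";".join(f"{z:.2f}" for z in grp["mean_z"]),
                "calls": ";".join(grp["call"]),
            })
            continue
        direction = directions.pop()
        if policy == "all" and len(called) != len(grp):
            continue
        hits.append(HitRecord(
            gene_id=gene,
            direction=direction,
            amplicon_evidence=tuple(
                zip(called["amplicon_id"], called["mean_z"])),
            n_hit_amplicons=len(called),
            n_tested_amplicons=len(grp),
        ))
    conflicts_df = pd.DataFrame(
        conflicts, columns=["gene_id", "amplicon_ids", "mean_zs", "calls"])
    return hits, conflicts_df


def hits_table(hits: list[HitRecord], direction: str | None = None
               ) -> pd.DataFrame:
    """Flatten HitRecords to a TSV-ready table (semicolon list columns)."""
    rows = []
    for h in hits:
        if direction is not None and h.direction != direction:
            continue
        rows.append({
            "gene_id": h.gene_id,
            "direction": h.direction,
            "amplicon_ids": ";".join(a for a, _ in h.amplicon_evidence),
            "mean_zs": ";".join(f"{z:.2f}" for _, z in h.amplicon_evidence),
            "n_hit_amplicons": h.n_hit_amplicons,
            "n_tested_amplicons": h.n_tested_amplicons,
        })
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def recovery_report(hits: list[HitRecord], truth: GroundTruth,
                    tested_genes: set[str] | None = None) -> pd.DataFrame:
    """Confusion summary of gene-level calls against the planted truth.

    Suppressors (multiplier < 1) are expected "down", enhancers
    (multiplier > 1) "up".  ``tested_genes`` defaults to every gene in the
    truth map.
    """
    tested = set(tested_genes) if tested_genes is not None \
        else set(truth.effect)
    called = {"down": {h.gene_id for h in hits if h.direction == "down"},
              "up": {h.gene_id for h in hits if h.direction == "up"}}
    expected = {"down": truth.suppressors & tested,
                "up": truth.enhancers & tested}
    rows = []
    for direction in ("down", "up"):
        exp, got = expected[direction], called[direction] & tested
        tp = len(exp & got)
        fp = len(got - exp)
        fn = len(exp - got)
        tn = len(tested) - tp - fp - fn
        sens = tp / len(exp) if exp else float("nan")
        fdr = fp / len(got) if got else 0.0
        rows.append({"direction": direction, "tp": tp, "fp": fp, "fn": fn,
                     "tn": tn, "sensitivity": sens, "fdr": fdr})
    return pd.DataFrame(rows, columns=["direction", "tp", "fp", "fn", "tn",
                                       "sensitivity", "fdr"])
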