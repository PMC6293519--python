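"""Readers and writers for every on-disk artifact of the pipeline.

Plate-trace dialect
-------------------
One CSV file per physical plate (one layout plate assayed once).  The first
row is ``time_s`` followed by the shared time axis in seconds; each
subsequent row is ``well,role,amplicon,gene`` followed by that well's
fluorescence values.  Plate identity and replicate index are not part of the
row schema; they are encoded in the file name as ``<plate_id>_rep<k>.csv``
and may be overridden when reading.

All other artifacts are UTF-8 TSV: the layout map, two-column gene→GO
annotations (or GAF 2.x), the packaged reference hit tables from the
genome-wide GBP/PLC dsRNA screen, and every stage output table.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, TraceFormatError

ROLES = ("library", "control_dsRNA", "internal_control", "vehicle")

#: wells of a 384-well plate: rows A..P, columns 01..24
WELL_RE = re.compile(r"^[A-P](0[1-9]|1[0-9]|2[0-4])$")
GO_RE = re.compile(r"^GO:\d{7}$")

_TRACE_SUFFIX_RE = re.compile(r"^(?P<plate>.+)_rep(?P<rep>\d+)$")


@dataclass
class WellTrace:
    """One well's kinetic fluorescence read-out plus its identity.

    ``amplicon_id`` and ``gene_id`` are empty strings for wells that carry
    no dsRNA (vehicle) or a non-library control construct.
    """

    plate_id: str
    replicate: int
    well: str
    role: str
    amplicon_id: str
    gene_id: str
    times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not WELL_RE.match(self.well):
            raise ValueError(f"not a 384-well coordinate: {self.well!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown well role: {self.role!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.size < 2:
            raise ValueError("times and values must be equal length >= 2")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def trace_filename(plate_id: str, replicate: int) -> str:
    return f"{plate_id}_rep{replicate}.csv"


def write_plate_traces(traces: list[WellTrace], path) -> None:
    """Write one plate's traces in the documented CSV dialect.

    All traces must share one plate, replicate and time axis.
    """
    if not traces:
        raise ValueError("cannot write an empty trace collection")
    t0 = traces[0]
    for tr in traces:
        if (tr.plate_id, tr.replicate) != (t0.plate_id, t0.replicate):
            raise ValueError("traces span more than one plate/replicate")
        if not np.array_equal(tr.times, t0.times):
            raise ValueError("traces do not share a time axis")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s"] + [repr(float(t)) for t in t0.times])
        for tr in traces:
            w.writerow(
                [tr.well, tr.role, tr.amplicon_id, tr.gene_id]
                + [repr(float(v)) for v in tr.values]
            )


def read_plate_traces(path, plate_id: str | None = None,
                      replicate: int | None = None) -> list[WellTrace]:
    """Read one plate file; identity defaults to the file-name convention."""
    path = Path(path)
    if plate_id is None or replicate is None:
        m = _TRACE_SUFFIX_RE.match(path.stem)
        if m is None:
            raise TraceFormatError(
                "file name does not encode <plate>_rep<k> and no identity "
                "was supplied", path)
        plate_id = plate_id or m.group("plate")
        replicate = replicate if replicate is not None else int(m.group("rep"))

    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:1] != ["time_s"]:
        raise TraceFormatError("missing 'time_s' header row", path, 1)
    try:
        times = np.array([float(x) for x in rows[0][1:]], dtype=float)
    except ValueError as exc:
        raise TraceFormatError(f"bad time value: {exc}", path, 1) from None
    if times.size < 2 or not np.all(np.diff(times) > 0):
        raise TraceFormatError("time header not strictly increasing", path, 1)

    traces: list[WellTrace] = []
    seen: set[str] = set()
    for ln, row in enumerate(rows[1:], start=2):
        if len(row) != 4 + times.size:
            raise TraceFormatError(
                f"ragged row: {len(row)} fields, expected {4 + times.size}",
                path, ln)
        well, role, amplicon, gene = row[:4]
        if well in seen:
            raise TraceFormatError(f"duplicate well {well}", path, ln)
        seen.add(well)
        try:
            values = np.array([float(x) for x in row[4:]], dtype=float)
        except ValueError as exc:
            raise TraceFormatError(f"bad value: {exc}", path, ln) from None
        try:
            traces.append(WellTrace(plate_id, replicate, well, role,
                                    amplicon, gene, times.copy(), values))
        except ValueError as exc:
            raise TraceFormatError(str(exc), path, ln) from None
    return traces


# ---------------------------------------------------------------------------
# layout / ground truth

LAYOUT_COLUMNS = ["plate_id", "well", "role", "amplicon_id", "gene_id"]


def write_layout(layout: pd.DataFrame, path) -> None:
    layout.to_csv(path, sep="\t", index=False, columns=LAYOUT_COLUMNS)


def read_layout(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"layout file missing columns {sorted(missing)}")
    return df


def write_ground_truth(truth, path) -> None:
    rows = [
        {"gene_id": g, "multiplier": m,
         "housekeeping_flag": truth.housekeeping_flag.get(g, False)}
        for g, m in truth.effect.items()
    ]
    pd.DataFrame(rows, columns=["gene_id", "multiplier", "housekeeping_flag"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO annotations


def write_annotations(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_annotations(path, format: str = "tsv2col") -> dict[str, set[str]]:
    """Gene → set of GO ids from a two-column TSV or a GAF 2.x file.

    GAF comment lines (leading ``!``) are skipped; the gene symbol is taken
    from GAF column 2 and the GO id from column 5.  Genes absent from the
    file are absent from the map.
    """
    if format not in ("tsv2col", "gaf"):
        raise ValueError(f"unknown annotation format {format!r}")
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (format == "gaf" and line.startswith("!")):
                continue
            parts = line.split("\t")
            if format == "tsv2col":
                if len(parts) < 2:
                    raise ParseError(f"line {ln}: expected 2 columns")
                gene, term = parts[0], parts[1]
            else:
                if len(parts) < 5:
                    raise ParseError(f"line {ln}: truncated GAF record")
                gene, term = parts[1], parts[4]
            if not GO_RE.match(term):
                raise ParseError(f"line {ln}: malformed GO id {term!r}")
            out.setdefault(gene, set()).add(term)
    return out


# ---------------------------------------------------------------------------
# reference hit tables

HIT_TABLE_COLUMNS = ["flybase_id", "gene", "amplicons", "mean_z"]


@dataclass
class HitTableFixture:
    """A published filtered hit list: one row per gene, 1–2 amplicons."""

    direction: str  # "down" | "up"
    rows: pd.DataFrame  # flybase_id, gene, amplicon_ids(list), mean_z(list)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def amplicon_z(self) -> np.ndarray:
        """All amplicon-level mean Z values, flattened."""
        return np.array([z for zs in self.rows["mean_z"] for z in zs])


def read_hit_table(path, direction: str) -> HitTableFixture:
    """Parse a filtered hit-table TSV with semicolon-joined list columns.

    A row whose single amplicon id carries two Z values (one such row is
    printed in the published down-table) is accepted by repeating the id,
    with a warning; any other length mismatch is an error.  Amplicon ids
    shared between gene rows (the published up-table has two) draw a
    warning, not an error.
    """
    if direction not in ("down", "up"):
        raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        return HitTableFixture(direction, pd.DataFrame(
            columns=["flybase_id", "gene", "amplicon_ids", "mean_z"]))
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"hit table missing columns {sorted(missing)}")

    records = []
    seen_amplicons: dict[str, str] = {}
    for _, row in df.iterrows():
        amps = [a for a in row["amplicons"].split(";") if a]
        try:
            zs = [float(z) for z in row["mean_z"].split(";") if z]
        except ValueError:
            raise ParseError(f"row {row['flybase_id']}: non-numeric Z") from None
        if len(amps) == 1 and len(zs) == 2:
            warnings.warn(
                f"row {row['flybase_id']} ({row['gene']}): one amplicon id "
                "with two Z values; id repeated as printed in the source "
                "table", stacklevel=2)
            amps = amps * 2
        elif len(amps) != len(zs) or not amps:
            raise ParseError(
                f"row {row['flybase_id']}: {len(amps)} amplicons vs "
                f"{len(zs)} Z values")
        for a in amps:
            if a in seen_amplicons and seen_amplicons[a] != row["flybase_id"]:
                warnings.warn(
                    f"amplicon {a} listed under both {seen_amplicons[a]} "
                    f"and {row['flybase_id']}", stacklevel=2)
            seen_amplicons.setdefault(a, row["flybase_id"])
        records.append({"flybase_id": row["flybase_id"], "gene": row["gene"],
                        "amplicon_ids": amps, "mean_z": zs})
    return HitTableFixture(direction, pd.DataFrame.from_records(records))


def packaged_hit_table(direction: str) -> HitTableFixture:
    """The packaged reference hit table ('down' or 'up')."""
    name = {"down": "gbp_screen_down_hits.tsv",
            "up": "gbp_screen_up_hits.tsv"}[direction]
    ref = resources.files("flipr_screen") / "data" / name
    with resources.as_file(ref) as p:
        return read_hit_table(p, direction)


# ---------------------------------------------------------------------------
# generic stage tables


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[""], **kwargs)
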