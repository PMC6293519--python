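"""End-to-end pipeline: simulate → quantify → QC → Z-score → merge →
call → filter → report.

Each stage writes its table into a run directory; a manifest records the
config, seed, per-stage row counts and output digests so every printed
summary can be audited, and a rerun with the same config and seed
reproduces all outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import gofilter, hits as hits_mod, io, qc as qc_mod, quantify, stats
from .errors import IncompleteRunError, InsufficientDataError, ScreenError
from .simulate import PlateEfficiencyModel, TraceModelParams, simulate_library

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignConfig:
    n_genes: int = 2000
    frac_suppressor: float = 0.01
    frac_enhancer: float = 0.01
    frac_two_amplicons: float = 0.25
    frac_housekeeping: float = 0.15
    n_layout_plates: int | None = None
    n_replicates: int = 2
    wells_per_plate: int = 384
    n_control_dsrna_wells: int = 8
    n_internal_control_wells: int = 4
    n_vehicle_wells: int = 4
    suppressor_range: tuple[float, float] = (0.1, 0.5)
    enhancer_range: tuple[float, float] = (1.5, 2.5)


@dataclass(frozen=True)
class QuantifyConfig:
    method: str = "auc"
    baseline_window_end: float | None = None   # default: agonist add time
    response_window_end: float | None = None   # default: end of trace


@dataclass(frozen=True)
class CallConfig:
    low: float = -3.0
    high: float = 3.0
    policy: str = "any"


@dataclass(frozen=True)
class PipelineConfig:
    """Structured configuration for a full synthetic-screen run."""

    seed: int = 0
    design: DesignConfig = field(default_factory=DesignConfig)
    trace: TraceModelParams = field(default_factory=TraceModelParams)
    efficiency: PlateEfficiencyModel | None = field(
        default_factory=PlateEfficiencyModel)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    zscore_policy: str = "library_only"
    qc_cutoff: float = qc_mod.DEFAULT_CUTOFF
    call: CallConfig = field(default_factory=CallConfig)
    housekeeping_terms: tuple[str, ...] = gofilter.DEFAULT_HOUSEKEEPING_TERMS
    write_traces: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kw: dict = {}
        if "design" in d:
            dd = dict(d.pop("design"))
            for k in ("suppressor_range", "enhancer_range"):
                if k in dd:
                    dd[k] = tuple(dd[k])
            kw["design"] = DesignConfig(**dd)
        if "trace" in d:
            kw["trace"] = TraceModelParams(**d.pop("trace"))
        if "efficiency" in d:
            eff = d.pop("efficiency")
            kw["efficiency"] = None if eff is None \
                else PlateEfficiencyModel(**eff)
        if "quantify" in d:
            kw["quantify"] = QuantifyConfig(**d.pop("quantify"))
        if "call" in d:
            kw["call"] = CallConfig(**d.pop("call"))
        if "housekeeping_terms" in d:
            kw["housekeeping_terms"] = tuple(d.pop("housekeeping_terms"))
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hist_table(z: pd.Series, lo: float = -10, hi: float = 10,
                width: float = 0.5) -> pd.DataFrame:
    edges = np.arange(lo, hi + width / 2, width)
    edges = np.concatenate([[-np.inf], edges, [np.inf]])
    counts, _ = np.histogram(z, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage into ``out_dir`` and return it.

    Any stage error aborts the run with the stage named; the manifest is
    written only on success, so a directory without ``manifest.json`` is
    an invalid (partial) run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("flipr_screen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "configure"
    counts: dict[str, int] = {}
    try:
        # -- simulate -----------------------------------------------------
        stage = "simulate"
        dc = config.design
        design, truth = design_mod.generate_design(
            n_genes=dc.n_genes,
            frac_suppressor=dc.frac_suppressor,
            frac_enhancer=dc.frac_enhancer,
            effect_params=design_mod.EffectParams(
                suppressor=dc.suppressor_range,
                enhancer=dc.enhancer_range),
            frac_two_amplicons=dc.frac_two_amplicons,
            seed=config.seed,
            n_layout_plates=dc.n_layout_plates,
            n_replicates=dc.n_replicates,
            wells_per_plate=dc.wells_per_plate,
            n_control_dsrna_wells=dc.n_control_dsrna_wells,
            n_internal_control_wells=dc.n_internal_control_wells,
            n_vehicle_wells=dc.n_vehicle_wells,
            frac_housekeeping=dc.frac_housekeeping,
            housekeeping_terms=config.housekeeping_terms,
        )
        io.write_layout(design.layout, out / "layout.tsv")
        io.write_ground_truth(truth, out / "ground_truth.tsv")
        io.write_annotations(
            {g: set(a) for g, a in truth.go_annotations.items()},
            out / "annotations.tsv")
        datasets, efficiencies = simulate_library(
            design, truth, config.trace, config.seed, config.efficiency)
        io.write_table(efficiencies, out / "plate_efficiencies.tsv")
        counts["plate_datasets"] = len(datasets)
        if config.write_traces:
            tdir = out / "traces"
            tdir.mkdir(exist_ok=True)
            for (pid, rep), traces in datasets.items():
                io.write_plate_traces(traces,
                                      tdir / io.trace_filename(pid, rep))
        log.info("simulated %d plate datasets", len(datasets))

        # -- quantify -----------------------------------------------------
        stage = "quantify"
        qcfg = config.quantify
        frames = [
            quantify.quantify_traces(
                traces, config.trace.agonist_add_time,
                qcfg.response_window_end, qcfg.method,
                baseline_window_end=qcfg.baseline_window_end)
            for traces in datasets.values()
        ]
        measurements = pd.concat(frames, ignore_index=True)
        io.write_table(measurements, out / "measurements.tsv")
        counts["measurements"] = len(measurements)

        # -- qc -----------------------------------------------------------
        stage = "qc"
        surviving, qc_results = qc_mod.filter_plates(measurements,
                                                     config.qc_cutoff)
        io.write_table(qc_mod.qc_report(qc_results), out / "qc_report.tsv")
        counts["plates_discarded"] = sum(not r.passed for r in qc_results)
        counts["surviving_measurements"] = len(surviving)

        # -- zscore -------------------------------------------------------
        stage = "zscore"
        zscores, degenerate = stats.screen_zscores(surviving,
                                                   config.zscore_policy)
        io.write_table(zscores, out / "zscores.tsv")
        counts["zscores"] = len(zscores)
        counts["degenerate_plates"] = len(degenerate)

        # replicate reproducibility + Z distribution (report tables)
        try:
            pairs, corr = stats.replicate_scatter(zscores, 1, 2)
            io.write_table(pairs, out / "scatter_pairs.tsv")
        except InsufficientDataError:
            corr = float("nan")
        io.write_table(_hist_table(zscores["z"]), out / "z_histogram.tsv")

        # -- merge --------------------------------------------------------
        stage = "merge"
        merged, unmeasured = stats.merge_replicates(zscores,
                                                    design.amplicons)
        merged_out = merged.copy()
        merged_out["per_replicate_z"] = [
            ";".join(f"{z:.6g}" for z in zs)
            for zs in merged_out["per_replicate_z"]]
        io.write_table(merged_out, out / "merged_z.tsv")
        pd.DataFrame({"amplicon_id": unmeasured}).to_csv(
            out / "unmeasured.tsv", sep="\t", index=False)
        counts["amplicons_measured"] = len(merged)
        counts["amplicons_unmeasured"] = len(unmeasured)

        # -- call ---------------------------------------------------------
        stage = "call"
        calls = hits_mod.call_amplicons(merged, config.call.low,
                                        config.call.high)
        io.write_table(calls.drop(columns=["per_replicate_z"]),
                       out / "amplicon_calls.tsv")
        hit_records, conflicts = hits_mod.aggregate_genes(calls,
                                                          config.call.policy)
        down = hits_mod.hits_table(hit_records, "down")
        up = hits_mod.hits_table(hit_records, "up")
        io.write_table(down, out / "down_hits.tsv")
        io.write_table(up, out / "up_hits.tsv")
        io.write_table(conflicts, out / "conflicts.tsv")
        counts["down_hits"] = len(down)
        counts["up_hits"] = len(up)
        counts["conflicts"] = len(conflicts)

        # -- filter -------------------------------------------------------
        stage = "filter"
        annotations = {g: set(a) for g, a in truth.go_annotations.items()}
        filtered = {}
        for name, table in (("down", down), ("up", up)):
            kept, removed = gofilter.filter_housekeeping(
                table, annotations, config.housekeeping_terms)
            io.write_table(kept, out / f"filtered_{name}_hits.tsv")
            io.write_table(removed, out / f"removed_{name}_hits.tsv")
            filtered[name] = kept
        summary_tbl = gofilter.filter_summary(
            {"down": len(down), "up": len(up)},
            {"down": len(filtered["down"]), "up": len(filtered["up"])})
        io.write_table(summary_tbl, out / "filter_summary.tsv")
        counts["filtered_down_hits"] = len(filtered["down"])
        counts["filtered_up_hits"] = len(filtered["up"])

        # -- report -------------------------------------------------------
        stage = "report"
        summary = {
            "amplicons_tested": len(merged),
            "amplicons_unmeasured": len(unmeasured),
            "plates_discarded": counts["plates_discarded"],
            "replicate_correlation": corr,
            "hits": {
                "down": {"pre_filter": len(down),
                         "post_filter": len(filtered["down"])},
                "up": {"pre_filter": len(up),
                       "post_filter": len(filtered["up"])},
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    except ScreenError:
        log.error("stage %r failed", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "row_counts": counts,
        "discarded_plates": [
            {"plate_id": r.plate_id, "replicate": r.replicate,
             "control_inhibition": r.control_inhibition,
             "reason": r.reason}
            for r in qc_results if not r.passed],
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def screen_summary(run_dir) -> dict:
    """Recompute the headline screen counts from a run directory's stage
    outputs (never from the manifest)."""
    run = Path(run_dir)
    needed = ["layout.tsv", "qc_report.tsv", "zscores.tsv", "merged_z.tsv",
              "down_hits.tsv", "up_hits.tsv",
              "filtered_down_hits.tsv", "filtered_up_hits.tsv"]
    for name in needed:
        if not (run / name).exists():
            raise IncompleteRunError(f"missing stage output {name}")
    layout = io.read_layout(run / "layout.tsv")
    qc = io.read_table(run / "qc_report.tsv")
    z = io.read_table(run / "zscores.tsv")
    merged = io.read_table(run / "merged_z.tsv")
    down = io.read_table(run / "down_hits.tsv")
    up = io.read_table(run / "up_hits.tsv")
    fdown = io.read_table(run / "filtered_down_hits.tsv")
    fup = io.read_table(run / "filtered_up_hits.tsv")

    designed = set(layout.loc[layout["role"] == "library", "amplicon_id"])
    measured = set(merged["amplicon_id"]) if len(merged) else set()
    try:
        _, corr = stats.replicate_scatter(z, 1, 2)
    except InsufficientDataError:
        corr = float("nan")
    return {
        "amplicons_designed": len(designed),
        "amplicons_tested": len(measured),
        "coverage": len(measured & designed) / len(designed)
        if designed else float("nan"),
        "unmeasured_amplicons": sorted(designed - measured),
        "plates_discarded": int((~qc["passed"].astype(bool)).sum()),
        "replicate_correlation": corr,
        "hits": {
            "down": {"pre_filter": len(down), "post_filter": len(fdown)},
            "up": {"pre_filter": len(up), "post_filter": len(fup)},
        },
    }
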