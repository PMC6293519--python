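"""Synthetic dsRNA screening library design and planted ground truth.

The generator emulates the structure of a genome-wide dsRNA library laid
out on 384-well plates: every library well carries one dsRNA amplicon,
every amplicon targets one gene, genes carry one or two amplicons, and each
plate reserves wells for a null-control dsRNA, an internal positive-control
dsRNA (an IP3-receptor-class construct whose knockdown abolishes the Ca2+
response) and vehicle.  Planted multiplicative knockdown effects and GO
annotations form the ground truth against which hit recovery is scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SizingError
from .gofilter import DEFAULT_HOUSEKEEPING_TERMS

#: pseudo-identifiers for the non-library construct wells
INTERNAL_CONTROL_GENE = "SYN-ITPR-CTRL"
INTERNAL_CONTROL_AMPLICON = "AMP-IC"
CONTROL_GENE = "SYN-NULL-CTRL"
CONTROL_AMPLICON = "AMP-CTRL"

#: innocuous (non-housekeeping) GO terms for background annotation
_BACKGROUND_GO = ("GO:0005524", "GO:0016020", "GO:0005509", "GO:0007165")

_ROWS = "ABCDEFGHIJKLMNOP"


def well_names(wells_per_plate: int = 384) -> list[str]:
    """Row-major well coordinates A01..P24 (or a leading subset)."""
    if wells_per_plate < 1 or wells_per_plate > 384:
        raise ConfigurationError("wells_per_plate must be in 1..384")
    names = [f"{r}{c:02d}" for r in _ROWS for c in range(1, 25)]
    return names[:wells_per_plate]


@dataclass(frozen=True)
class EffectParams:
    """Uniform ranges for planted multiplicative knockdown effects."""

    suppressor: tuple[float, float] = (0.1, 0.5)
    enhancer: tuple[float, float] = (1.5, 2.5)

    def __post_init__(self):
        lo, hi = self.suppressor
        if not (0 <= lo <= hi < 1):
            raise ConfigurationError("suppressor range must lie in [0, 1)")
        lo, hi = self.enhancer
        if not (1 < lo <= hi):
            raise ConfigurationError("enhancer range must lie above 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-gene effects and annotations for recovery scoring."""

    effect: dict[str, float]
    housekeeping_flag: dict[str, bool]
    go_annotations: dict[str, frozenset[str]]

    @property
    def suppressors(self) -> set[str]:
        return {g for g, m in self.effect.items() if m < 1.0}

    @property
    def enhancers(self) -> set[str]:
        return {g for g, m in self.effect.items() if m > 1.0}


@dataclass
class LibraryDesign:
    """Plate layouts for one screening library.

    ``layout`` holds one row per laid-out well of every layout plate
    (columns plate_id, well, role, amplicon_id, gene_id); replicate plates
    share the layout and differ only in noise realizations.
    """

    n_layout_plates: int
    n_replicates: int
    wells_per_plate: int
    genes: list[str]
    amplicons: list[str]
    amplicon_to_gene: dict[str, str]
    layout: pd.DataFrame
    seed: int
    internal_control_multiplier: float = 0.0

    @property
    def plate_ids(self) -> list[str]:
        return [f"P{i + 1:03d}" for i in range(self.n_layout_plates)]

    @property
    def well_roles(self) -> dict[str, dict[str, str]]:
        """plate_id → {well → role} for every laid-out well."""
        return {
            pid: dict(zip(grp["well"], grp["role"]))
            for pid, grp in self.layout.groupby("plate_id", sort=False)
        }

    def plate_layout(self, plate_id: str) -> pd.DataFrame:
        sub = self.layout[self.layout["plate_id"] == plate_id]
        if sub.empty:
            raise ConfigurationError(f"no such layout plate: {plate_id}")
        return sub.reset_index(drop=True)

    def validate(self) -> None:
        """Check the structural invariants of the design."""
        lib = self.layout[self.layout["role"] == "library"]
        if lib["amplicon_id"].eq("").any():
            raise ConfigurationError("library well without an amplicon")
        if set(lib["amplicon_id"]) - set(self.amplicon_to_gene):
            raise ConfigurationError("amplicon without a gene mapping")
        for pid, grp in self.layout.groupby("plate_id"):
            counts = grp["role"].value_counts()
            if counts.get("control_dsRNA", 0) < 4:
                raise ConfigurationError(f"{pid}: fewer than 4 control wells")
            if counts.get("internal_control", 0) < 2:
                raise ConfigurationError(f"{pid}: fewer than 2 internal controls")
            if counts.get("vehicle", 0) < 2:
                raise ConfigurationError(f"{pid}: fewer than 2 vehicle wells")


def _round_count(n: int, frac: float) -> int:
    return int(math.floor(n * frac + 0.5))


def generate_design(
    n_genes: int,
    frac_suppressor: float = 0.01,
    frac_enhancer: float = 0.01,
    effect_params: EffectParams | None = None,
    frac_two_amplicons: float = 0.25,
    seed: int = 0,
    *,
    n_layout_plates: int | None = None,
    n_replicates: int = 2,
    wells_per_plate: int = 384,
    n_control_dsrna_wells: int = 8,
    n_internal_control_wells: int = 4,
    n_vehicle_wells: int = 4,
    frac_housekeeping: float = 0.15,
    housekeeping_terms: tuple[str, ...] = DEFAULT_HOUSEKEEPING_TERMS,
) -> tuple[LibraryDesign, GroundTruth]:
    """Generate a library design plus its planted ground truth.

    Suppressor/enhancer counts follow ``round(n_genes * fraction)``;
    suppressors are assigned first from a seed-shuffled gene order, so the
    planted counts are deterministic for a fixed seed.  Housekeeping GO
    terms are planted on a random ``frac_housekeeping`` of genes
    (hits included) so the annotation filter is exercised end to end.
    """
    for name, frac in [("frac_suppressor", frac_suppressor),
                       ("frac_enhancer", frac_enhancer),
                       ("frac_two_amplicons", frac_two_amplicons),
                       ("frac_housekeeping", frac_housekeeping)]:
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1]")
    if frac_suppressor + frac_enhancer > 1.0:
        raise ConfigurationError("suppressor + enhancer fractions exceed 1")
    if n_genes < 0:
        raise ConfigurationError("n_genes must be non-negative")
    n_controls = (n_control_dsrna_wells + n_internal_control_wells
                  + n_vehicle_wells)
    if n_control_dsrna_wells < 4 or n_internal_control_wells < 2 \
            or n_vehicle_wells < 2:
        raise ConfigurationError(
            "need >=4 control_dsRNA, >=2 internal_control, >=2 vehicle wells")
    lib_capacity = wells_per_plate - n_controls
    if lib_capacity <= 0:
        raise ConfigurationError("control wells leave no library wells")

    effect_params = effect_params or EffectParams()
    rng = np.random.default_rng(seed)

    genes = [f"SYN{i:05d}" for i in range(n_genes)]

    # planted effects: suppressors first from a seed-shuffled order
    shuffled = list(rng.permutation(genes)) if genes else []
    n_supp = _round_count(n_genes, frac_suppressor)
    n_enh = _round_count(n_genes, frac_enhancer)
    effect = {g: 1.0 for g in genes}
    lo, hi = effect_params.suppressor
    for g in shuffled[:n_supp]:
        effect[g] = float(rng.uniform(lo, hi))
    lo, hi = effect_params.enhancer
    for g in shuffled[n_supp:n_supp + n_enh]:
        effect[g] = float(rng.uniform(lo, hi))

    # amplicons: 1 per gene, plus a second for a seed-chosen subset
    n_two = _round_count(n_genes, frac_two_amplicons)
    two_amp = set(rng.permutation(genes)[:n_two]) if genes else set()
    amplicons: list[str] = []
    amplicon_to_gene: dict[str, str] = {}
    j = 0
    for g in genes:
        for _ in range(2 if g in two_amp else 1):
            amp = f"AMP{j:05d}"
            amplicons.append(amp)
            amplicon_to_gene[amp] = g
            j += 1

    # GO annotations
    n_hk = _round_count(n_genes, frac_housekeeping)
    hk_genes = set(rng.permutation(genes)[:n_hk]) if genes else set()
    go_annotations: dict[str, frozenset[str]] = {}
    housekeeping_flag: dict[str, bool] = {}
    terms = list(housekeeping_terms)
    for g in genes:
        ann = {_BACKGROUND_GO[int(rng.integers(len(_BACKGROUND_GO)))]}
        if g in hk_genes:
            k = 1 + int(rng.integers(2))
            ann.update(rng.choice(terms, size=k, replace=False))
        go_annotations[g] = frozenset(ann)
        housekeeping_flag[g] = bool(ann & set(terms))

    # plate layouts
    needed = max(1, math.ceil(len(amplicons) / lib_capacity))
    if n_layout_plates is None:
        n_layout_plates = needed
    elif len(amplicons) > n_layout_plates * lib_capacity:
        raise SizingError(
            f"{len(amplicons)} amplicons do not fit {n_layout_plates} plates "
            f"of {lib_capacity} library wells")

    order = list(rng.permutation(amplicons)) if amplicons else []
    wells = well_names(wells_per_plate)
    # control block fills the tail of the plate (last wells, row-major)
    ctrl_wells = wells[-n_controls:]
    ic_wells = ctrl_wells[:n_internal_control_wells]
    cd_wells = ctrl_wells[n_internal_control_wells:
                          n_internal_control_wells + n_control_dsrna_wells]
    veh_wells = ctrl_wells[n_internal_control_wells + n_control_dsrna_wells:]
    lib_wells = wells[:-n_controls]

    rows = []
    for p in range(n_layout_plates):
        pid = f"P{p + 1:03d}"
        chunk = order[p * lib_capacity:(p + 1) * lib_capacity]
        for w, amp in zip(lib_wells, chunk):
            rows.append((pid, w, "library", amp, amplicon_to_gene[amp]))
        for w in ic_wells:
            rows.append((pid, w, "internal_control",
                         INTERNAL_CONTROL_AMPLICON, INTERNAL_CONTROL_GENE))
        for w in cd_wells:
            rows.append((pid, w, "control_dsRNA", CONTROL_AMPLICON,
                         CONTROL_GENE))
        for w in veh_wells:
            rows.append((pid, w, "vehicle", "", ""))
    layout = pd.DataFrame(
        rows, columns=["plate_id", "well", "role", "amplicon_id", "gene_id"])

    design = LibraryDesign(
        n_layout_plates=n_layout_plates,
        n_replicates=n_replicates,
        wells_per_plate=wells_per_plate,
        genes=genes,
        amplicons=amplicons,
        amplicon_to_gene=amplicon_to_gene,
        layout=layout,
        seed=seed,
    )
    truth = GroundTruth(effect=effect, housekeeping_flag=housekeeping_flag,
                        go_annotations=go_annotations)
    return design, truth


def full_library_design(seed: int = 0, **kwargs
                        ) -> tuple[LibraryDesign, GroundTruth]:
    """The default genome-wide configuration: 13,900 genes with one or two
    amplicons each, filling 66 layout plates screened in duplicate
    (132 plate datasets)."""
    kwargs.setdefault("n_genes", 13_900)
    kwargs.setdefault("frac_two_amplicons", 0.74)
    kwargs.setdefault("n_replicates", 2)
    return generate_design(seed=seed, **kwargs)
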