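"""Housekeeping-gene filter over GO annotations.

Hits annotated to general transcription/translation machinery depress the
fluorescent reporter itself rather than the Ca2+ signal, so the screen
removes genes carrying any of eleven GO categories: mRNA splicing,
ribosome structural constituents, translation and its initiation/elongation
factors, and the RNA-polymerase-II transcription apparatus.
"""

from __future__ import annotations

import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .io import GO_RE

#: the eleven housekeeping GO categories, in the screen's order
DEFAULT_HOUSEKEEPING_TERMS: tuple[str, ...] = (
    "GO:0000398",  # mRNA splicing, via spliceosome
    "GO:0003735",  # structural constituent of ribosome
    "GO:0003743",  # translation initiation factor activity
    "GO:0003700",  # transcription factor activity, sequence-specific DNA binding
    "GO:0001104",  # RNA polymerase II transcription cofactor activity
    "GO:0001055",  # RNA polymerase II activity
    "GO:0003899",  # DNA-directed RNA polymerase activity
    "GO:0008134",  # transcription factor binding
    "GO:0001077",  # transcriptional activator activity, RNAP II proximal region
    "GO:0006412",  # translation
    "GO:0003746",  # translation elongation factor activity
)


def _ancestors(term: str, edges: dict[str, set[str]]) -> set[str]:
    """Transitive parents of ``term`` under an is_a/part_of edge map."""
    out: set[str] = set()
    stack = [term]
    while stack:
        for parent in edges.get(stack.pop(), ()):
            if parent not in out:
                out.add(parent)
                stack.append(parent)
    return out


def read_ontology_edges(path) -> dict[str, set[str]]:
    """Child→parents edge map from a two-column TSV (child, parent)."""
    edges: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not GO_RE.match(parts[0]) \
                    or not GO_RE.match(parts[1]):
                raise ConfigurationError(
                    f"ontology edge file line {ln}: expected two GO ids")
            edges.setdefault(parts[0], set()).add(parts[1])
    return edges


def filter_housekeeping(
    hits: pd.DataFrame,
    annotations: dict[str, set[str]],
    terms: tuple[str, ...] = DEFAULT_HOUSEKEEPING_TERMS,
    closure: dict[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split hits into (kept, removed-with-matched-terms).

    A hit is removed iff its gene's annotation set intersects ``terms``.
    By default only direct annotations count; passing an ontology edge map
    as ``closure`` also matches ancestor terms.  Genes missing from the
    annotation map are unannotated and kept.
    """
    if not terms:
        raise ConfigurationError("housekeeping term list is empty")
    for t in terms:
        if not GO_RE.match(t):
            raise ConfigurationError(f"malformed GO id in term list: {t!r}")
    term_set = set(terms)

    matched_col = []
    removed_mask = []
    for gene in hits["gene_id"]:
        ann = set(annotations.get(gene, ()))
        if closure is not None:
            for a in tuple(ann):
                ann |= _ancestors(a, closure)
        matched = sorted(ann & term_set)
        matched_col.append(";".join(matched))
        removed_mask.append(bool(matched))
    removed_mask = pd.Series(removed_mask, index=hits.index, dtype=bool)
    kept = hits[~removed_mask].reset_index(drop=True)
    removed = hits[removed_mask].reset_index(drop=True)
    removed = removed.assign(
        matched_terms=[m for m, r in zip(matched_col, removed_mask) if r])
    return kept, removed


def filter_summary(before: dict[str, int], after: dict[str, int]
                   ) -> pd.DataFrame:
    """Before/after/removed hit counts per direction."""
    rows = []
    for direction in sorted(set(before) | set(after)):
        b = int(before.get(direction, 0))
        a = int(after.get(direction, 0))
        if a > b:
            raise ConsistencyError(
                f"direction {direction}: {a} hits after filtering but only "
                f"{b} before")
        rows.append({"direction": direction, "before": b, "after": a,
                     "removed": b - a})
    return pd.DataFrame(rows, columns=["direction", "before", "after",
                                       "removed"])
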