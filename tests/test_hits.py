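import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from flipr_screen import (GroundTruth, aggregate_genes, call_amplicons,
                          hits_table, recovery_report)
from flipr_screen.errors import MappingError


def merged_frame(rows):
    """rows: (amplicon, gene, mean_z)"""
    return pd.DataFrame(
        [{"amplicon_id": a, "gene_id": g, "mean_z": z, "n_replicates": 2,
          "per_replicate_z": [z, z]} for a, g, z in rows])


def test_thresholds_are_strict():
    merged = merged_frame([("A1", "g1", -3.0), ("A2", "g2", -3.0001),
                           ("A3", "g3", 3.0), ("A4", "g4", 3.5),
                           ("A5", "g5", -6.95), ("A6", "g6", 0.0)])
    calls = call_amplicons(merged)
    got = dict(zip(calls["amplicon_id"], calls["call"]))
    assert got == {"A1": "none", "A2": "down", "A3": "none", "A4": "up",
                   "A5": "down", "A6": "none"}


def test_invalid_thresholds_rejected():
    with pytest.raises(ValueError):
        call_amplicons(merged_frame([("A1", "g1", 0.0)]), low=1.0, high=3.0)


def test_gene_hit_with_two_supporting_amplicons():
    merged = merged_frame([("A1", "g1", -3.32), ("A2", "g1", -3.09)])
    hits, conflicts = aggregate_genes(call_amplicons(merged))
    assert conflicts.empty
    (h,) = hits
    assert h.direction == "down"
    assert h.n_hit_amplicons == 2 and h.n_tested_amplicons == 2
    assert dict(h.amplicon_evidence) == {"A1": -3.32, "A2": -3.09}


def test_any_policy_one_amplicon_suffices():
    merged = merged_frame([("A1", "g1", -3.5), ("A2", "g1", -1.0)])
    hits, _ = aggregate_genes(call_amplicons(merged), policy="any")
    (h,) = hits
    assert h.direction == "down"
    assert h.n_hit_amplicons == 1 and h.n_tested_amplicons == 2
    assert dict(h.amplicon_evidence) == {"A1": -3.5}


def test_all_policy_requires_every_amplicon():
    merged = merged_frame([("A1", "g1", -3.5), ("A2", "g1", -1.0)])
    hits, _ = aggregate_genes(call_amplicons(merged), policy="all")
    assert hits == []


def test_opposite_directions_quarantined():
    merged = merged_frame([("A1", "g1", -3.5), ("A2", "g1", 3.5)])
    hits, conflicts = aggregate_genes(call_amplicons(merged))
    assert hits == []
    assert conflicts["gene_id"].tolist() == ["g1"]


def test_unmapped_amplicon_rejected():
    merged = merged_frame([("A1", "", -3.5)])
    with pytest.raises(MappingError):
        aggregate_genes(call_amplicons(merged))


@given(widen=st.floats(min_value=0.0, max_value=5.0))
def test_widening_thresholds_never_adds_hits(widen):
    rng = np.random.default_rng(17)
    merged = merged_frame([(f"A{i}", f"g{i}", z)
                           for i, z in enumerate(rng.normal(0, 3, 50))])
    base = call_amplicons(merged, -3.0, 3.0)
    wider = call_amplicons(merged, -3.0 - widen, 3.0 + widen)
    base_hits = set(base.loc[base["call"] != "none", "amplicon_id"])
    wider_hits = set(wider.loc[wider["call"] != "none", "amplicon_id"])
    assert wider_hits <= base_hits


def _truth(effects):
    return GroundTruth(effect=effects,
                       housekeeping_flag={g: False for g in effects},
                       go_annotations={g: frozenset() for g in effects})


def test_perfect_recovery():
    truth = _truth({"g1": 0.2, "g2": 1.8, "g3": 1.0})
    merged = merged_frame([("A1", "g1", -5.0), ("A2", "g2", 5.0),
                           ("A3", "g3", 0.1)])
    hits, _ = aggregate_genes(call_amplicons(merged))
    report = recovery_report(hits, truth).set_index("direction")
    assert report.loc["down", "sensitivity"] == 1.0
    assert report.loc["down", "fdr"] == 0.0
    assert report.loc["up", "sensitivity"] == 1.0
    assert report.loc["up", "tn"] == 2  # g1 and g3 not called up


def test_no_calls_gives_zero_sensitivity():
    truth = _truth({"g1": 0.2, "g2": 1.0})
    report = recovery_report([], truth).set_index("direction")
    assert report.loc["down", "sensitivity"] == 0.0
    assert report.loc["down", "fn"] == 1


def test_recovery_matches_brute_force_recount():
    """Confusion counts equal an independent recount from the joined
    truth/hit tables on a simulated screen."""
    import flipr_screen as fs
    from tests.conftest import simulate_measurements
    design, truth = fs.generate_design(
        400, frac_suppressor=0.02, frac_enhancer=0.02,
        effect_params=fs.EffectParams(suppressor=(0.2, 0.2),
                                      enhancer=(1.8, 1.8)),
        frac_two_amplicons=0.25, seed=31)
    m = simulate_measurements(design, truth, fs.TraceModelParams(),
                              seed=31, replicates=(1, 2))
    z, _ = fs.screen_zscores(m)
    merged, _ = fs.merge_replicates(z)
    hits, _ = aggregate_genes(call_amplicons(merged))
    report = recovery_report(hits, truth).set_index("direction")

    called_down = {h.gene_id for h in hits if h.direction == "down"}
    for direction, expected in [("down", truth.suppressors),
                                ("up", truth.enhancers)]:
        called = {h.gene_id for h in hits if h.direction == direction}
        tp = len(called & expected)
        assert report.loc[direction, "tp"] == tp
        assert report.loc[direction, "fp"] == len(called - expected)
        assert report.loc[direction, "fn"] == len(expected - called)
        if called:
            assert report.loc[direction, "fdr"] == pytest.approx(
                len(called - expected) / len(called))
    assert called_down  # the planted 0.2 suppressors are detectable


def test_hits_table_round_trip_columns():
    merged = merged_frame([("A1", "g1", -3.32), ("A2", "g1", -3.09),
                           ("A3", "g2", 4.0)])
    hits, _ = aggregate_genes(call_amplicons(merged))
    down = hits_table(hits, "down")
    assert down.loc[0, "amplicon_ids"] == "A1;A2"
    assert down.loc[0, "mean_zs"] == "-3.32;-3.09"
    up = hits_table(hits, "up")
    assert up["gene_id"].tolist() == ["g2"]
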