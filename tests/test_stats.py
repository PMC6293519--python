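import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from flipr_screen import (merge_replicates, percent_inhibition,
                          plate_zscores, replicate_scatter, screen_zscores)
from flipr_screen.errors import (DegeneratePlateError, InsufficientDataError,
                                 InvalidControlError)
from tests.conftest import measurement_frame


def test_hand_computed_zscore():
    """Plate values [10, 8, 6, 4, 2]: mean 6, sample SD sqrt(10), so the
    well at 2 scores (2-6)/sqrt(10) = -1.2649."""
    m = measurement_frame([10, 8, 6, 4, 2])
    z = plate_zscores(m)
    assert z.loc[4, "z"] == pytest.approx(-4 / math.sqrt(10), abs=1e-4)
    assert z.loc[2, "z"] == 0.0  # well at the plate mean


def test_constant_plate_is_degenerate():
    with pytest.raises(DegeneratePlateError):
        plate_zscores(measurement_frame([5.0] * 10))


def test_too_few_library_wells_degenerate():
    with pytest.raises(DegeneratePlateError):
        plate_zscores(measurement_frame([1.0, 2.0]))


def test_emitted_zscores_have_mean_zero_sd_one():
    rng = np.random.default_rng(1)
    m = measurement_frame(rng.normal(100, 20, size=300))
    z = plate_zscores(m)["z"]
    assert abs(z.mean()) < 1e-9
    assert abs(z.std(ddof=1) - 1) < 1e-9


def test_controls_excluded_from_z_under_library_only_policy():
    roles = ["library"] * 5 + ["control_dsRNA"] * 4 + \
        ["internal_control"] * 2 + ["vehicle"] * 2
    vals = [10, 8, 6, 4, 2] + [100] * 4 + [0] * 2 + [0] * 2
    m = measurement_frame(vals, roles=roles)
    z_lib = plate_zscores(m, policy="library_only")
    assert len(z_lib) == 5  # controls never receive a Z
    assert z_lib.loc[4, "z"] == pytest.approx(-4 / math.sqrt(10), abs=1e-4)
    z_all = plate_zscores(m, policy="all_wells")
    assert len(z_all) == 5
    assert not np.allclose(z_all["z"], z_lib["z"])


@given(scale=st.floats(min_value=0.01, max_value=100.0),
       shift=st.floats(min_value=-1e3, max_value=1e3))
def test_affine_invariance_of_zscores(scale, shift):
    vals = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
    z1 = plate_zscores(measurement_frame(vals))["z"]
    z2 = plate_zscores(measurement_frame(scale * vals + shift))["z"]
    np.testing.assert_allclose(z2, z1, rtol=1e-9, atol=1e-9)


def test_zscores_match_two_pass_oracle():
    """Brute-force mean/SD recomputation in plain Python, to 1e-12."""
    rng = np.random.default_rng(7)
    vals = list(rng.normal(50, 10, size=40))
    z = plate_zscores(measurement_frame(vals))["z"].to_numpy()
    mean = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
    oracle = [(v - mean) / sd for v in vals]
    np.testing.assert_allclose(z, oracle, rtol=1e-12)


def test_screen_zscores_flags_degenerate_plates():
    good = measurement_frame([1, 2, 3, 4], plate="P001")
    flat = measurement_frame([5, 5, 5, 5], plate="P002")
    z, degenerate = screen_zscores(pd.concat([good, flat]))
    assert set(z["plate_id"]) == {"P001"}
    assert degenerate == [("P002", 1)]


# --- percent inhibition ---------------------------------------------------

@pytest.mark.parametrize("test,control,expected", [
    (40.0, 100.0, 60.0),
    (100.0, 100.0, 0.0),
    (0.0, 100.0, 100.0),
    (150.0, 100.0, -50.0),   # potentiation
    (-10.0, 100.0, 110.0),   # below-vehicle response
])
def test_percent_inhibition_arithmetic(test, control, expected):
    assert percent_inhibition(test, control) == pytest.approx(expected)


def test_nonpositive_control_mean_rejected():
    with pytest.raises(InvalidControlError):
        percent_inhibition(10.0, 0.0)


# --- replicate merging ----------------------------------------------------

def zrec(amp, gene, z, rep=1, plate="P001"):
    return {"plate_id": plate, "replicate": rep, "amplicon_id": amp,
            "gene_id": gene, "z": z}


def test_merge_is_arithmetic_mean():
    records = pd.DataFrame([zrec("A1", "g1", -4.0, rep=1),
                            zrec("A1", "g1", -2.0, rep=2)])
    merged, unmeasured = merge_replicates(records)
    assert merged.loc[0, "mean_z"] == pytest.approx(-3.0)
    assert merged.loc[0, "n_replicates"] == 2
    assert unmeasured == []


def test_single_surviving_replicate_kept_as_is():
    records = pd.DataFrame([zrec("A1", "g1", -6.95)])
    merged, unmeasured = merge_replicates(records, ["A1", "A2"])
    assert merged.loc[0, "mean_z"] == pytest.approx(-6.95)
    assert merged.loc[0, "n_replicates"] == 1
    assert unmeasured == ["A2"]  # amplicon with no surviving replicate


def test_merge_empty_input():
    merged, unmeasured = merge_replicates(
        pd.DataFrame(columns=["plate_id", "replicate", "amplicon_id",
                              "gene_id", "z"]))
    assert merged.empty and unmeasured == []


# --- replicate scatter ----------------------------------------------------

def test_identical_replicates_correlate_perfectly():
    recs = pd.DataFrame([zrec(f"A{i}", f"g{i}", z, rep=r)
                         for r in (1, 2) for i, z in enumerate([1, 2, 3, 4])])
    pairs, r = replicate_scatter(recs, 1, 2)
    assert len(pairs) == 4
    assert r == pytest.approx(1.0)


def test_anticorrelated_replicates():
    recs = pd.DataFrame(
        [zrec(f"A{i}", f"g{i}", z, rep=1) for i, z in enumerate([1, 2, 3])]
        + [zrec(f"A{i}", f"g{i}", -z, rep=2)
           for i, z in enumerate([1, 2, 3])])
    _, r = replicate_scatter(recs, 1, 2)
    assert r == pytest.approx(-1.0)


def test_scatter_correlation_matches_brute_force(small_design):
    import flipr_screen as fs
    from tests.conftest import simulate_measurements
    design, truth = small_design
    m = simulate_measurements(design, truth, fs.TraceModelParams(),
                              seed=5, replicates=(1, 2))
    z, _ = screen_zscores(m)
    pairs, r = replicate_scatter(z, 1, 2)
    a, b = pairs["z_a"].to_numpy(), pairs["z_b"].to_numpy()
    ca, cb = a - a.mean(), b - b.mean()
    oracle = (ca * cb).sum() / math.sqrt((ca ** 2).sum() * (cb ** 2).sum())
    assert r == pytest.approx(oracle, rel=1e-12)


def test_fewer_than_three_pairs_rejected():
    recs = pd.DataFrame([zrec("A1", "g1", 1.0, rep=1),
                         zrec("A1", "g1", 1.0, rep=2)])
    with pytest.raises(InsufficientDataError):
        replicate_scatter(recs, 1, 2)
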