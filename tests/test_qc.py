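import dataclasses

import numpy as np
import pandas as pd
import pytest

from flipr_screen import (TraceModelParams, filter_plates, generate_design,
                          qc_plate)
from flipr_screen.errors import QCNotEvaluableError
from tests.conftest import measurement_frame, simulate_measurements


def qc_frame(ic_vals, ctrl_vals, plate="P001", replicate=1):
    roles = (["library"] * 4 + ["internal_control"] * len(ic_vals)
             + ["control_dsRNA"] * len(ctrl_vals))
    vals = [1.0, 2.0, 3.0, 4.0] + list(ic_vals) + list(ctrl_vals)
    return measurement_frame(vals, roles=roles, plate=plate,
                             replicate=replicate)


def test_inhibition_exactly_at_cutoff_passes():
    res = qc_plate(qc_frame([40.0], [100.0]))
    assert res.control_inhibition == pytest.approx(60.0)
    assert res.passed  # "at least 60%" is inclusive


def test_inhibition_below_cutoff_discards():
    res = qc_plate(qc_frame([41.0], [100.0]))
    assert res.control_inhibition == pytest.approx(59.0)
    assert not res.passed


def test_full_block_passes():
    res = qc_plate(qc_frame([0.0], [100.0]))
    assert res.control_inhibition == pytest.approx(100.0)
    assert res.passed


def test_qc_uses_group_means():
    res = qc_plate(qc_frame([30.0, 50.0], [90.0, 110.0]))
    assert res.control_inhibition == pytest.approx(60.0)
    assert res.n_internal_control_wells == 2
    assert res.n_control_wells == 2


def test_missing_control_group_not_evaluable():
    m = measurement_frame([1, 2, 3], roles=["library"] * 3)
    with pytest.raises(QCNotEvaluableError):
        qc_plate(m)


def test_filter_plates_removes_exactly_the_failed_plate(noise_free_params):
    """A plate with 40% knockdown efficiency shows 40% internal-control
    inhibition and is the only one discarded."""
    design, truth = generate_design(40, frac_two_amplicons=0.0, seed=13,
                                    n_layout_plates=2)
    frames = []
    for p, pe in [(0, 1.0), (1, 0.4)]:
        params = dataclasses.replace(noise_free_params, plate_efficiency=pe)
        frames.append(simulate_measurements(
            design, truth, params, seed=13, replicates=(1,)
        ).query(f"plate_id == 'P{p + 1:03d}'"))
    m = pd.concat(frames, ignore_index=True)
    surviving, results = filter_plates(m)
    by_plate = {r.plate_id: r for r in results}
    assert by_plate["P001"].passed
    assert by_plate["P002"].control_inhibition == pytest.approx(40.0,
                                                                abs=1e-9)
    assert not by_plate["P002"].passed
    assert set(surviving["plate_id"]) == {"P001"}


def test_no_plates_discarded_at_full_efficiency(small_design,
                                                noise_free_params):
    design, truth = small_design
    m = simulate_measurements(design, truth, noise_free_params, seed=1)
    surviving, results = filter_plates(m)
    assert all(r.passed for r in results)
    assert len(surviving) == len(m)


def test_filter_is_idempotent(small_design):
    design, truth = small_design
    m = simulate_measurements(design, truth, TraceModelParams(), seed=2)
    once, _ = filter_plates(m)
    twice, _ = filter_plates(once)
    pd.testing.assert_frame_equal(once, twice)


def test_empty_input_gives_empty_output():
    empty = measurement_frame([]).iloc[0:0]
    surviving, results = filter_plates(empty)
    assert surviving.empty and results == []


def test_unevaluable_plate_discarded_with_reason():
    lib_only = measurement_frame([1, 2, 3, 4], plate="P009")
    surviving, results = filter_plates(lib_only)
    assert surviving.empty
    assert len(results) == 1
    assert not results[0].passed
    assert "internal-control" in results[0].reason


def test_separation_noise_free(noise_free_params):
    """Without noise a plate is discarded iff efficiency < cutoff/100."""
    design, truth = generate_design(10, frac_two_amplicons=0.0, seed=3)
    for pe, expect_pass in [(0.3, False), (0.59, False), (0.6, True),
                            (0.9, True), (1.0, True)]:
        params = dataclasses.replace(noise_free_params, plate_efficiency=pe)
        m = simulate_measurements(design, truth, params, seed=3)
        _, results = filter_plates(m)
        assert results[0].passed == expect_pass, pe
        assert results[0].control_inhibition == pytest.approx(100 * pe,
                                                              abs=1e-9)


def test_qc_classification_reliable_under_default_noise():
    """Plates at 30% and 90% efficiency classify correctly in >=99% of
    1,000 seeded simulations (default noise, small plates)."""
    design, truth = generate_design(10, frac_two_amplicons=0.0, seed=21)
    params = TraceModelParams(n_timepoints=40, agonist_add_time=10.0)
    correct = 0
    n = 1000
    rng = np.random.default_rng(2024)
    for i in range(n):
        pe = 0.3 if i % 2 == 0 else 0.9
        p = dataclasses.replace(params, plate_efficiency=pe)
        m = simulate_measurements(design, truth, p,
                                  seed=int(rng.integers(2 ** 31)))
        _, results = filter_plates(m)
        if results[0].passed == (pe >= 0.6):
            correct += 1
    assert correct / n >= 0.99
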