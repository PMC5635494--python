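"""The interaction-perturbation engine."""

import numpy as np
import pandas as pd
import pytest

from oscperturb.errors import StructuralLinkError, ValidationError
from oscperturb.models import build_model
from oscperturb.perturbation import (
    DEFAULT_WEAKENING_FACTORS,
    PerturbationResult,
    PerturbationSpec,
    perturb_once,
    perturbed_jacobian_modifier,
    run_campaign,
)


def test_default_weakening_factors():
    assert DEFAULT_WEAKENING_FACTORS == (0.99, 0.98, 0.96, 0.92)


def test_modifier_addresses_row_and_column_by_label():
    model = build_model("simple_nfo", 4)
    # Lyx: target Y (row 2), source X (col 1) -> zero-based (1, 0)
    assert perturbed_jacobian_modifier(model, PerturbationSpec("Lyx", 0.99, 0)) == (
        1,
        0,
        0.99,
    )
    # diagonal addressing follows the same rule
    assert perturbed_jacobian_modifier(model, PerturbationSpec("Lxx", 0.92, 0)) == (
        0,
        0,
        0.92,
    )


def test_modifier_rejects_structurally_absent_link():
    model = build_model("simple_nfo", 4)
    with pytest.raises(StructuralLinkError):
        perturbed_jacobian_modifier(model, PerturbationSpec("Lxy", 0.99, 0))


def test_spec_validation():
    with pytest.raises(ValidationError):
        PerturbationSpec("Lyx", 0.0, 0)  # factor must be positive
    with pytest.raises(ValidationError):
        PerturbationSpec("Lyx", 1.5, 0)  # no strengthening by default
    with pytest.raises(ValidationError):
        PerturbationSpec("Lyx", 0.99, 40, phase_count=40)  # phase out of range


def test_result_schema_integrity():
    with pytest.raises(ValidationError):
        PerturbationResult(0, "Lyx", 0.99, 0, 1.0, None, "sustained")
    with pytest.raises(ValidationError):
        PerturbationResult(0, "Lyx", 0.99, 0, 1.0, 1.0, "damped")
    with pytest.raises(ValidationError):
        PerturbationResult(0, "Lyx", 0.99, 0, -1.0, 1.0, "sustained")


def test_null_perturbation_returns_unit_ratios(simple_nfo_case, perturbation_config):
    model, ps, cyc = simple_nfo_case
    res = perturb_once(model, ps, cyc, PerturbationSpec("Lyx", 1.0, 0), perturbation_config)
    assert res.status == "sustained"
    assert res.frequency_ratio == pytest.approx(1.0, abs=1e-3)
    assert res.amplitude_ratio == pytest.approx(1.0, abs=1e-3)


def test_one_percent_weakening_all_phases_sustained_and_bounded(
    simple_nfo_case, perturbation_config
):
    """Class I robustness: every phase of a 1% weakening of the feedback
    link survives with ratios inside a wide (0.9, 1.1) sanity bracket."""
    model, ps, cyc = simple_nfo_case
    n_phases = 8
    from oscperturb.perturbation import resample_cycle_states

    states = resample_cycle_states(model, ps, cyc, n_phases, perturbation_config.dynamics)
    for phase in range(n_phases):
        res = perturb_once(
            model,
            ps,
            cyc,
            PerturbationSpec("Lyx", 0.99, phase, n_phases),
            perturbation_config,
            cycle_states=states,
        )
        assert res.status == "sustained"
        assert 0.9 < res.frequency_ratio < 1.1
        assert 0.9 < res.amplitude_ratio < 1.1


def test_campaign_row_count_and_determinism(simple_nfo_case, perturbation_config):
    model, ps, cyc = simple_nfo_case
    # simple NFO: 3 off-diagonal links + 3 diagonals = 6 perturbable elements
    assert len(model.perturbable_labels()) == 6
    tbl = run_campaign(
        model, [ps], [cyc], factors=[0.99], phase_count=1, config=perturbation_config
    )
    assert len(tbl) == 6
    assert set(tbl.columns) == {
        "model",
        "parameter_set_id",
        "link",
        "factor",
        "phase_index",
        "frequency_ratio",
        "amplitude_ratio",
        "status",
    }
    tbl2 = run_campaign(
        model, [ps], [cyc], factors=[0.99], phase_count=1, config=perturbation_config
    )
    pd.testing.assert_frame_equal(tbl, tbl2)


def test_campaign_sharding_concatenates_to_serial_result(
    simple_nfo_case, perturbation_config
):
    """Per-link shards concatenate to the same table as the serial sweep."""
    model, ps, cyc = simple_nfo_case
    labels = model.perturbable_labels()
    serial = run_campaign(
        model, [ps], [cyc], factors=[0.99], phase_count=2, config=perturbation_config
    )
    shards = [
        run_campaign(
            model,
            [ps],
            [cyc],
            factors=[0.99],
            phase_count=2,
            config=perturbation_config,
            links=[lab],
        )
        for lab in labels
    ]
    merged = pd.concat(shards, ignore_index=True)
    key = ["link", "phase_index"]
    pd.testing.assert_frame_equal(
        serial.sort_values(key).reset_index(drop=True),
        merged.sort_values(key).reset_index(drop=True),
    )


def test_campaign_input_validation(simple_nfo_case, perturbation_config):
    model, ps, cyc = simple_nfo_case
    with pytest.raises(ValidationError):
        run_campaign(model, [], [], config=perturbation_config)
    with pytest.raises(ValidationError):
        run_campaign(model, [ps], [cyc], factors=[1.2], config=perturbation_config)


def test_ratios_only_on_sustained_rows(campaign_tables):
    sus = campaign_tables["status"] == "sustained"
    assert campaign_tables.loc[sus, "frequency_ratio"].notna().all()
    assert campaign_tables.loc[sus, "amplitude_ratio"].notna().all()
    assert (campaign_tables.loc[sus, "frequency_ratio"] > 0).all()
    assert campaign_tables.loc[~sus, "frequency_ratio"].isna().all()
    assert campaign_tables.loc[~sus, "amplitude_ratio"].isna().all()
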