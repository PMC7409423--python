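"""Comparative-Ct and CCK-8 analytics: closed forms and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zfxquant import ddct_fold_change, knockdown_efficiency, viability_curves
from zfxquant.assays import normalized_series


def _ct_table(control_dcts, treated_dcts, ct_ref=15.0):
    rows = []
    for grp, dcts in (("NC", control_dcts), ("si", treated_dcts)):
        for i, dct in enumerate(dcts):
            rows.append(
                {
                    "sample_id": f"{grp}{i}",
                    "group": grp,
                    "target_gene": "LINC00152",
                    "reference_gene": "GAPDH",
                    "ct_target": ct_ref + dct,
                    "ct_reference": ct_ref,
                    "replicate": i,
                }
            )
    return pd.DataFrame(rows)


def test_ddct_closed_forms():
    # ΔΔCt of 0, +1, -1 map to folds 1, 0.5, 2 exactly
    folds = ddct_fold_change(_ct_table([5.0], [5.0, 6.0, 4.0]), "NC")
    assert folds.loc[folds["group"] == "NC", "fold_change"].iloc[0] == 1.0
    assert folds.loc[folds["group"] == "si", "fold_change"].tolist() == [1.0, 0.5, 2.0]


def test_ddct_replicate_table_hand_arithmetic():
    folds = ddct_fold_change(_ct_table([5.0, 5.0], [7.0, 7.0]), "NC")
    si = folds.loc[folds["group"] == "si", "fold_change"]
    assert si.tolist() == [0.25, 0.25]
    assert knockdown_efficiency(folds, "si", "NC") == pytest.approx(75.0)


def test_missing_reference_ct_excluded_with_flag():
    table = _ct_table([5.0, 5.0], [7.0])
    table.loc[0, "ct_reference"] = np.nan
    folds = ddct_fold_change(table, "NC")
    assert folds["excluded"].tolist() == [True, False, False]
    assert np.isnan(folds.loc[0, "fold_change"])
    # baseline uses only the surviving control replicate
    assert folds.loc[2, "fold_change"] == pytest.approx(0.25)


def test_missing_control_group_is_an_error():
    with pytest.raises(ValueError, match="control"):
        ddct_fold_change(_ct_table([5.0], [6.0]), "mock")


@given(ddct=st.floats(-10, 10))
def test_fold_change_strictly_decreasing_in_ddct(ddct):
    folds = ddct_fold_change(_ct_table([0.0], [ddct, ddct + 0.5]), "NC")
    si = folds.loc[folds["group"] == "si", "fold_change"].to_numpy()
    assert si[0] > si[1]
    assert si[0] == pytest.approx(2.0**-ddct)


@given(fold=st.floats(0.0, 2.0))
def test_efficiency_identity_holds_for_any_fold(fold):
    """efficiency + 100·fold = 100 whenever the control folds are exactly 1."""
    ddct = -np.log2(fold) if fold > 0 else 40.0
    folds = ddct_fold_change(_ct_table([3.0, 3.0], [3.0 + ddct]), "NC")
    if fold > 1.0:
        with pytest.warns(UserWarning, match="failed"):
            eff = knockdown_efficiency(folds, "si", "NC")
    else:
        eff = knockdown_efficiency(folds, "si", "NC")
    assert eff + 100.0 * fold == pytest.approx(100.0, abs=1e-9)


def test_efficiency_endpoints():
    f0 = ddct_fold_change(_ct_table([2.0, 2.0], [2.0]), "NC")
    assert knockdown_efficiency(f0, "si", "NC") == pytest.approx(0.0)
    f100 = ddct_fold_change(_ct_table([2.0, 2.0], [42.0]), "NC")
    assert knockdown_efficiency(f100, "si", "NC") == pytest.approx(100.0, abs=1e-9)


# ---------------------------------------------------------------------------
# CCK-8


def _od_table(series: dict[str, list[float]], blank=0.08, times=(0, 24, 48, 72)):
    rows = []
    for sid, vals in series.items():
        for t, od in zip(times, vals):
            rows.append(
                {"sample_id": sid, "group": sid.rstrip("0123456789"), "time_h": t,
                 "od450": od, "is_blank": False}
            )
    for t in times:
        rows.append(
            {"sample_id": "blank", "group": "blank", "time_h": t, "od450": blank,
             "is_blank": True}
        )
    return pd.DataFrame(rows)


def test_wells_equal_to_blanks_correct_to_zero():
    table = _od_table({"NC1": [0.08] * 4, "NC2": [0.08] * 4})
    curves = viability_curves(table)
    assert (curves["mean"] == 0.0).all()
    # idempotence: re-correcting already-zero blanks changes nothing
    again = table.copy()
    again.loc[again["is_blank"], "od450"] = 0.0
    again.loc[~again["is_blank"], "od450"] -= 0.08
    assert (viability_curves(again)["mean"] == 0.0).all()


def test_normalized_mode_starts_every_sample_at_one():
    table = _od_table({"NC1": [0.3, 0.5, 0.9, 1.4], "si1": [0.3, 0.4, 0.5, 0.6]})
    curves = viability_curves(table, normalize=True)
    t0 = curves[curves["time_h"] == 0]
    assert (t0["mean"] == 1.0).all()


def test_synthetic_exponential_growth_normalizes_to_doublings():
    od = [0.1 * 2 ** (t / 24) + 0.08 for t in (0, 24, 48, 72)]
    table = _od_table({"NC1": od})
    curves = viability_curves(table, normalize=True)
    assert curves.sort_values("time_h")["mean"].tolist() == pytest.approx([1, 2, 4, 8])
    series = normalized_series(table, "NC1")
    assert series.tolist() == pytest.approx([1, 2, 4, 8])


def test_blank_correction_requires_blanks():
    table = _od_table({"NC1": [0.3, 0.5, 0.9, 1.4]})
    with pytest.raises(ValueError, match="blank"):
        viability_curves(table[~table["is_blank"]])


def test_nonpositive_t0_sample_flagged_and_dropped():
    table = _od_table({"NC1": [0.05, 0.5, 0.9, 1.4], "NC2": [0.3, 0.5, 0.9, 1.4]})
    with pytest.warns(UserWarning, match="NC1"):
        curves = viability_curves(table, normalize=True)
    assert (curves["n"] == 1).all()  # only NC2 survives


def test_group_mean_and_sem_shape():
    table = _od_table({"NC1": [0.3, 0.5, 0.9, 1.4], "NC2": [0.4, 0.6, 1.0, 1.5]})
    curves = viability_curves(table)
    assert set(curves.columns) == {"group", "time_h", "n", "mean", "sem"}
    row = curves[(curves["group"] == "NC") & (curves["time_h"] == 0)].iloc[0]
    assert row["n"] == 2
    assert row["mean"] == pytest.approx(0.27)  # (0.22 + 0.32) / 2
    assert row["sem"] == pytest.approx(np.std([0.22, 0.32], ddof=1) / np.sqrt(2))
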