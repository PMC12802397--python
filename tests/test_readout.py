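"""Secondary-assay readouts: gating, integrated activity, ΔF/F0,
dose–response fitting, ΔΔCt, and relative secretion."""

import numpy as np
import pandas as pd
import pytest

from sortscreen import (
    ddct_knockdown,
    dff_traces,
    fit_4pl,
    gate_tails,
    integrated_activity,
    normalized_response,
    percent_change,
    relative_secretion,
    simulate_dose_response,
    simulate_flow_events,
    simulate_traces,
)
from sortscreen.simulate import ImagingTraceSet, simulate_ct_table


# --- gating -----------------------------------------------------------------

def _events(ratios):
    return pd.DataFrame({"green": np.ones(len(ratios)), "red": np.asarray(ratios, float)})


def test_gate_tails_sizes_and_order():
    ev = _events(np.arange(1, 11))
    hi, lo = gate_tails(ev, 0.35)
    assert sorted(lo["red"]) == [1, 2, 3]
    assert sorted(hi["red"]) == [8, 9, 10]
    # invariant: disjoint, ordered, bounded
    assert lo["red"].max() < hi["red"].min()
    assert len(hi) + len(lo) <= len(ev)


def test_gate_tails_large_distinct_sample(rng):
    ev = _events(rng.permutation(np.linspace(0.01, 5, 10_000)))
    hi, lo = gate_tails(ev, 0.35)
    assert len(hi) == len(lo) == 3_500
    middle_min = ev["red"][~ev.index.isin(hi.index) & ~ev.index.isin(lo.index)].min()
    assert lo["red"].max() <= middle_min


def test_gate_tails_ties_and_bad_q():
    with pytest.warns(UserWarning, match="tails"):
        hi, lo = gate_tails(_events(np.ones(100)), 0.35)
    assert len(hi) == len(lo) == 0
    with pytest.raises(ValueError, match="0, 0.5"):
        gate_tails(_events(np.arange(10)), 0.5)
    with pytest.raises(ValueError, match="too few"):
        gate_tails(_events([1.0, 2.0]), 0.35)


# --- integrated calcium activity ---------------------------------------------

def _flow_panel(scale=1.0):
    frames = []
    for i in range(3):
        e = simulate_flow_events(500, 0.05, seed=10 + i, sample_id=f"ref{i}",
                                 condition="buffer")
        frames.append(e)
    for i in range(3):
        e = simulate_flow_events(500, 0.6, seed=20 + i, sample_id=f"stim{i}",
                                 condition="tryptone")
        frames.append(e)
    ev = pd.concat(frames, ignore_index=True)
    ev[["green", "red"]] *= scale
    return ev


def test_integrated_activity_reference_is_one_and_scale_invariant():
    act1 = integrated_activity(_flow_panel(), "buffer")
    ref = act1.per_condition.set_index("condition")
    assert ref.loc["buffer", "relative"] == pytest.approx(1.0)
    assert ref.loc["tryptone", "relative"] > 2.0
    act2 = integrated_activity(_flow_panel(scale=37.0), "buffer")
    assert np.allclose(act1.per_condition["relative"],
                       act2.per_condition["relative"])


def test_integrated_activity_median_robust_and_green_guard():
    ev = pd.DataFrame({
        "sample_id": ["s"] * 3 + ["ref"],
        "condition": ["x"] * 3 + ["r"],
        "green": [1.0, 1.0, 1.0, 1.0],
        "red": [1.0, 2.0, 100.0, 2.0],
    })
    act = integrated_activity(ev, "r")
    med = act.per_sample.set_index("sample_id").loc["s", "median_ratio"]
    assert med == 2.0
    dropped = ev.copy()
    dropped.loc[0, "green"] = 0.0
    act2 = integrated_activity(dropped, "r")
    assert act2.per_sample.set_index("sample_id").loc["s", "n_dropped"] == 1
    with pytest.raises(ValueError, match="absent"):
        integrated_activity(ev, "nope")


# --- ΔF/F0 -------------------------------------------------------------------

def test_dff_constant_trace_is_zero():
    tr = simulate_traces(2, peak_dff=0.0, noise_sd=0.0, seed=0)
    _, peaks = dff_traces(tr)
    assert np.allclose(peaks["peak_dff"], 0.0)


def test_dff_noiseless_peak_exact():
    tr = simulate_traces(4, peak_dff=2.0, noise_sd=0.0, seed=1)
    dff, peaks = dff_traces(tr)
    assert np.allclose(peaks["peak_dff"], 2.0)
    # explicit arithmetic: F0 = 100, max F = 300 → peak 2.0
    assert dff["dff"].max() == pytest.approx(2.0)


def test_dff_noisy_flat_trace_within_noise_band():
    tr = simulate_traces(50, peak_dff=0.0, noise_sd=0.05, seed=2)
    _, peaks = dff_traces(tr)
    assert (peaks["peak_dff"].abs() < 3 * 0.05 * 2.5).all()


def test_dff_peak_recovery_smoothed_at_snr10():
    """Savitzky–Golay peak extraction is unbiased within ±5% over 500
    noisy transients at SNR 10."""
    tr = simulate_traces(500, peak_dff=2.0, noise_sd=0.2, seed=4)
    _, peaks = dff_traces(tr, smooth_window=11)
    assert peaks["peak_dff"].mean() == pytest.approx(2.0, rel=0.05)


def test_dff_excludes_nonpositive_baseline():
    frame = pd.DataFrame({
        "cell_id": ["c1"] * 30,
        "frame": np.arange(30),
        "F": np.concatenate([np.zeros(10), np.ones(20)]),
    })
    tr = ImagingTraceSet(frame=frame, stim_frame=10, baseline_window=(0, 10))
    _, peaks = dff_traces(tr)
    assert peaks.loc[0, "excluded"] == "F0 <= 0"


def test_normalized_response_and_percent_change():
    a = pd.Series([1.0, 2.0, 0.5], index=["c1", "c2", "c3"])
    b = pd.Series([1.0, 2.0, 0.0], index=["c1", "c2", "c3"])
    norm = normalized_response(a, b)
    assert norm.loc["c1"] == 1.0 and norm.loc["c2"] == 1.0
    assert "c3" not in norm.index  # reference peak <= 0 excluded
    pc = percent_change(pd.Series({"c1": 0.8}), pd.Series({"c1": 0.2}))
    assert pc.loc["c1"] == pytest.approx(-75.0)


def test_blocked_stimulus_normalizes_to_zero():
    """Full block of stimulus A with intact reference B gives normalized
    responses near 0."""
    a = simulate_traces(50, peak_dff=0.0, noise_sd=0.05, seed=5)
    b = simulate_traces(50, peak_dff=1.5, noise_sd=0.05, seed=6)
    _, pa = dff_traces(a)
    _, pb = dff_traces(b)
    norm = normalized_response(pa.set_index("cell_id")["peak_dff"],
                               pb.set_index("cell_id")["peak_dff"])
    assert abs(norm.mean()) < 0.25


# --- 4PL ---------------------------------------------------------------------

def test_fit_4pl_noiseless_exact_fixed_point():
    doses = np.geomspace(0.01, 10, 8)
    tbl = simulate_dose_response(doses, bottom=1, top=7, ec50=0.35, hill=1.2,
                                 noise_sd=0.0, n_reps=2, seed=0)
    fit = fit_4pl(tbl)
    assert fit.converged and not fit.non_monotone
    assert fit.sse < 1e-12
    for got, want in [(fit.bottom, 1), (fit.top, 7), (fit.ec50, 0.35),
                      (fit.hill, 1.2)]:
        assert got == pytest.approx(want, rel=1e-6)
    # midpoint identity: response at fitted EC50 is (top+bottom)/2
    mid = fit.predict(np.array([fit.ec50]))[0]
    assert mid == pytest.approx((fit.top + fit.bottom) / 2)


def test_fit_4pl_flags_decreasing_data():
    doses = np.geomspace(0.01, 10, 6)
    tbl = simulate_dose_response(doses, bottom=1, top=7, ec50=0.35, hill=1.0,
                                 noise_sd=0.0, n_reps=1, seed=0)
    tbl["response"] = tbl["response"].iloc[::-1].to_numpy()
    fit = fit_4pl(tbl)
    assert fit.non_monotone
    with pytest.raises(ValueError, match="distinct doses"):
        fit_4pl(pd.DataFrame({"dose": [1, 1, 2, 2], "response": [1, 1, 2, 2]}))


# --- ΔΔCt and secretion ------------------------------------------------------

def test_ddct_closed_form_cases():
    ct = pd.DataFrame({
        "sample_id": list("abcd"),
        "condition": ["NTC", "NTC", "KD", "KD"],
        "gene": ["Cs", "Gapdh", "Cs", "Gapdh"],
        "ct": [18.0, 15.0, 20.0, 15.0],
    })
    res = ddct_knockdown(ct, "Cs", "Gapdh", "NTC")
    assert res["ddct"] == pytest.approx(2.0)
    assert res["relative_expression"] == pytest.approx(0.25)
    assert res["knockdown_pct"] == pytest.approx(75.0)
    # ΔΔCt = 0 → relative 1, knockdown 0
    same = ct.copy()
    same["ct"] = [18.0, 15.0, 18.0, 15.0]
    res0 = ddct_knockdown(same, "Cs", "Gapdh", "NTC")
    assert res0["relative_expression"] == pytest.approx(1.0)
    assert res0["knockdown_pct"] == pytest.approx(0.0)


def test_ddct_inverts_forward_simulated_fold_change():
    ct = simulate_ct_table(0.07, seed=0, noise_sd=0.0)
    res = ddct_knockdown(ct, "Cs", "Gapdh", "NTC")
    assert res["relative_expression"] == pytest.approx(0.07, abs=1e-12)
    assert res["knockdown_pct"] == pytest.approx(93.0, abs=1e-9)


def test_ddct_flags_wide_triplicates_and_missing_reference():
    ct = simulate_ct_table(0.5, seed=1, noise_sd=0.0)
    ct.loc[ct.index[0], "ct"] += 3.0  # blow up one replicate
    res = ddct_knockdown(ct, "Cs", "Gapdh", "NTC")
    assert res["flagged_triplicates"]
    with pytest.raises(ValueError, match="missing Ct"):
        ddct_knockdown(ct[ct["gene"] != "Gapdh"], "Cs", "Gapdh", "NTC")


def test_relative_secretion_folds():
    wells = pd.DataFrame({
        "condition": ["buffer"] * 3 + ["tryptone"] * 3,
        "value": [1.0, 1.2, 0.8, 7.0, 7.0, 7.0],
    })
    out = relative_secretion(wells, "buffer").set_index("condition")
    assert out.loc["buffer", "fold_mean"] == pytest.approx(1.0)
    assert out.loc["tryptone", "fold_mean"] == pytest.approx(7.0)
    # homogeneity: rescaling all wells leaves folds unchanged
    out2 = relative_secretion(wells.assign(value=wells["value"] * 13), "buffer")
    assert np.allclose(out2.set_index("condition")["fold_mean"], out["fold_mean"])
    with pytest.raises(ValueError, match="reference"):
        relative_secretion(wells, "nope")
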