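"""Secondary-assay readout quantification.

Covers the cellular readouts around a photoconversion screen: quantile
gating of flow events on the red/green ratio, *integrated calcium
activity* (per-sample median red/green ratio, normalized to a reference
condition), ΔF/F0 trace extraction from calcium imaging, four-parameter
logistic (4PL) dose–response fitting, ΔΔCt qPCR knockdown, and relative
hormone secretion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import ImagingTraceSet, four_pl


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------

def gate_tails(
    events: pd.DataFrame, q: float = 0.35
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split events into top and bottom ``q`` tails of the red/green ratio.

    With all-distinct ratios each bin holds floor(q·n) events. A tie group
    spanning a cut is kept together in the middle (not split into a bin), so
    a sample whose ratios are all equal yields two empty bins with a
    warning. Returns (high_bin, low_bin).
    """
    if not 0 < q < 0.5:
        raise ValueError("gate quantile q must lie in (0, 0.5)")
    ev = events[events["green"] > 0].copy()
    n = len(ev)
    if n < 1.0 / q:
        raise ValueError(f"too few events ({n}) for q={q}")
    ratio = (ev["red"] / ev["green"]).to_numpy()
    order = np.sort(ratio)
    k = int(np.floor(q * n))
    low_cut = order[k]           # strict: ratio < (k+1)-th smallest
    high_cut = order[n - 1 - k]  # strict: ratio > (k+1)-th largest
    low = ev[ratio < low_cut]
    high = ev[ratio > high_cut]
    if len(low) == 0 and len(high) == 0:
        warnings.warn("no separable tails (ratios tied across the cuts)", stacklevel=2)
    return high, low


@dataclass
class IntegratedCalciumActivity:
    """Per-sample medians and per-condition summaries of the red/green ratio."""

    per_sample: pd.DataFrame   # sample_id, condition, median_ratio, n_events, n_dropped
    per_condition: pd.DataFrame  # condition, mean, sem, n_samples, relative
    reference_condition: str


def integrated_activity(
    events: pd.DataFrame, reference_condition: str
) -> IntegratedCalciumActivity:
    """Median red/green ratio per sample; mean ± SEM per condition over
    samples; relative activity = condition mean / reference-condition mean.

    Events with green ≤ 0 are dropped and counted. SEM is over biological
    samples, not cells.
    """
    needed = {"sample_id", "condition", "green", "red"}
    missing = needed - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    rows = []
    for (sample, cond), grp in events.groupby(["sample_id", "condition"], sort=False):
        ok = grp["green"] > 0
        n_drop = int((~ok).sum())
        kept = grp[ok]
        if len(kept) == 0:
            raise ValueError(f"sample {sample!r}: no retained events")
        med = float((kept["red"] / kept["green"]).median())
        rows.append((sample, cond, med, len(kept), n_drop))
    per_sample = pd.DataFrame(
        rows, columns=["sample_id", "condition", "median_ratio", "n_events", "n_dropped"]
    )
    if reference_condition not in set(per_sample["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} absent")
    agg = per_sample.groupby("condition")["median_ratio"].agg(["mean", "sem", "count"])
    agg = agg.rename(columns={"count": "n_samples"}).reset_index()
    ref_mean = float(agg.loc[agg["condition"] == reference_condition, "mean"].iloc[0])
    agg["relative"] = agg["mean"] / ref_mean
    return IntegratedCalciumActivity(
        per_sample=per_sample, per_condition=agg, reference_condition=reference_condition
    )


# ---------------------------------------------------------------------------
# calcium imaging
# ---------------------------------------------------------------------------

def dff_traces(
    traces: ImagingTraceSet,
    peak_window: tuple[int, int] | None = None,
    smooth_window: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell ΔF/F0(t) = (F − F0)/F0 with F0 the mean over the baseline
    window; peak = max over the post-stimulation window (stim frame to end
    of trace unless given). Cells with F0 ≤ 0 are excluded with a reason.

    ``smooth_window`` applies a Savitzky–Golay filter (polyorder 2) to the
    post-stimulation ΔF/F0 before peak extraction — recommended ~1/3 of
    the transient decay constant for noisy recordings, where the raw
    maximum is biased upward by noise; the default (no smoothing) keeps
    noiseless traces exact.

    Returns (long-form ΔF/F0 table, per-cell peak table with an
    ``excluded`` reason column for dropped cells).
    """
    b0, b1 = traces.baseline_window
    if not (0 <= b0 < b1 <= traces.stim_frame):
        raise ValueError("baseline window must precede the stimulation frame")
    dff_rows = []
    peak_rows = []
    for cell, grp in traces.frame.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        F = grp["F"].to_numpy()
        frames = grp["frame"].to_numpy()
        base = F[(frames >= b0) & (frames < b1)]
        f0 = float(base.mean())
        if f0 <= 0:
            peak_rows.append((cell, np.nan, "F0 <= 0"))
            continue
        dff = (F - f0) / f0
        if peak_window is None:
            post = frames >= traces.stim_frame
        else:
            post = (frames >= peak_window[0]) & (frames < peak_window[1])
        seg = dff[post]
        if smooth_window is not None and smooth_window > 2 and seg.size >= smooth_window:
            from scipy.signal import savgol_filter

            seg = savgol_filter(seg, smooth_window, 2)
        peak = float(seg.max())
        dff_rows.append(pd.DataFrame({"cell_id": cell, "frame": frames, "dff": dff}))
        peak_rows.append((cell, peak, ""))
    out = pd.concat(dff_rows, ignore_index=True) if dff_rows else pd.DataFrame(
        columns=["cell_id", "frame", "dff"]
    )
    peaks = pd.DataFrame(peak_rows, columns=["cell_id", "peak_dff", "excluded"])
    return out, peaks


def normalized_response(
    peaks_a: pd.Series, peaks_b: pd.Series
) -> pd.Series:
    """Per-cell normalized response: peak of stimulus A over peak of
    reference stimulus B, paired by cell; cells with reference peak ≤ 0 are
    excluded."""
    common = peaks_a.index.intersection(peaks_b.index)
    if len(common) == 0:
        raise ValueError("no cells measured under both stimuli")
    a = peaks_a.loc[common]
    b = peaks_b.loc[common]
    ok = b > 0
    return (a[ok] / b[ok]).rename("normalized_response")


def percent_change(pre: pd.Series, post: pd.Series) -> pd.Series:
    """Per-cell percent change across a treatment: (post − pre)/pre × 100."""
    common = pre.index.intersection(post.index)
    pre, post = pre.loc[common], post.loc[common]
    ok = pre != 0
    return ((post[ok] - pre[ok]) / pre[ok] * 100.0).rename("percent_change")


# ---------------------------------------------------------------------------
# dose–response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    sse: float
    converged: bool
    non_monotone: bool = False  # hill < 0 flagged, not hidden

    def predict(self, x: np.ndarray) -> np.ndarray:
        return four_pl(x, self.bottom, self.top, self.ec50, self.hill)


def fit_4pl(
    table: pd.DataFrame, fix_hill: float | None = None
) -> DoseResponseFit:
    """Least-squares 4PL fit r(x) = bottom + (top−bottom)/(1+(ec50/x)^hill).

    EC50 is parameterized on the log scale and top ≥ bottom ≥ 0 is enforced
    by fitting (bottom, span) with non-negative bounds. Five deterministic
    initializations (EC50 spread across the dose range) are tried and the
    best SSE kept.
    """
    x = table["dose"].to_numpy(dtype=float)
    y = table["response"].to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("doses must be > 0")
    if len(np.unique(x)) < 4:
        raise ValueError("need ≥ 4 distinct doses to fit a 4PL")

    span0 = max(float(y.max() - y.min()), 1e-12)
    bottom0 = max(float(y.min()), 0.0)
    log_doses = np.log(np.unique(x))
    ec50_inits = np.exp(np.linspace(log_doses.min(), log_doses.max(), 5))

    def residuals(theta: np.ndarray) -> np.ndarray:
        bottom, span, log_ec50 = theta[:3]
        hill = fix_hill if fix_hill is not None else theta[3]
        return four_pl(x, bottom, bottom + span, np.exp(log_ec50), hill) - y

    best = None
    for ec0 in ec50_inits:
        theta0 = [bottom0, span0, np.log(ec0)]
        lo = [0.0, 0.0, np.log(ec0) - 20.0]
        hi = [np.inf, np.inf, np.log(ec0) + 20.0]
        if fix_hill is None:
            theta0.append(1.0)
            lo.append(-10.0)
            hi.append(10.0)
        res = optimize.least_squares(
            residuals, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
        )
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res)
    sse, res = best
    bottom, span, log_ec50 = res.x[:3]
    hill = fix_hill if fix_hill is not None else float(res.x[3])
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(bottom + span),
        ec50=float(np.exp(log_ec50)),
        hill=float(hill),
        sse=sse,
        converged=bool(res.success),
        non_monotone=hill < 0,
    )


# ---------------------------------------------------------------------------
# qPCR and secretion
# ---------------------------------------------------------------------------

def ddct_knockdown(
    ct: pd.DataFrame,
    target: str,
    reference: str = "Gapdh",
    control_condition: str = "NTC",
    test_condition: str | None = None,
    flag_sd: float = 0.5,
) -> dict:
    """ΔΔCt relative expression and percent knockdown.

    ΔCt = Ct_target − Ct_reference per condition (means over replicate
    wells); ΔΔCt = ΔCt_test − ΔCt_control; relative expression =
    2^(−ΔΔCt); knockdown% = (1 − relative) × 100. Replicate groups with Ct
    SD > ``flag_sd`` cycles are flagged.
    """
    conditions = ct["condition"].unique().tolist()
    if test_condition is None:
        others = [c for c in conditions if c != control_condition]
        if len(others) != 1:
            raise ValueError(f"ambiguous test condition among {others}; specify one")
        test_condition = others[0]
    flagged = []

    def mean_ct(cond: str, gene: str) -> float:
        sel = ct[(ct["condition"] == cond) & (ct["gene"] == gene)]["ct"]
        if sel.empty:
            raise ValueError(f"missing Ct values for gene {gene!r} in {cond!r}")
        if len(sel) > 1 and sel.std(ddof=1) > flag_sd:
            flagged.append((cond, gene, float(sel.std(ddof=1))))
        return float(sel.mean())

    dct_test = mean_ct(test_condition, target) - mean_ct(test_condition, reference)
    dct_ctrl = mean_ct(control_condition, target) - mean_ct(control_condition, reference)
    ddct = dct_test - dct_ctrl
    rel = 2.0 ** (-ddct)
    return {
        "ddct": ddct,
        "relative_expression": rel,
        "knockdown_pct": (1.0 - rel) * 100.0,
        "flagged_triplicates": flagged,
        "test_condition": test_condition,
    }


def relative_secretion(
    wells: pd.DataFrame, reference_condition: str
) -> pd.DataFrame:
    """Per-well hormone level as fold of the reference-condition mean, with
    per-condition mean ± SEM over wells."""
    needed = {"condition", "value"}
    if not needed.issubset(wells.columns):
        raise ValueError(f"well table must have columns {sorted(needed)}")
    ref = wells.loc[wells["condition"] == reference_condition, "value"]
    if len(ref) < 1:
        raise ValueError(f"no wells for reference condition {reference_condition!r}")
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise ValueError("reference mean must be > 0")
    folds = wells.assign(fold=wells["value"] / ref_mean)
    out = folds.groupby("condition")["fold"].agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"count": "n_wells", "mean": "fold_mean", "sem": "fold_sem"})
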