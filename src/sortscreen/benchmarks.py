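"""End-to-end benchmark routines exercising the whole pipeline.

Each function simulates a screen (or assay) under the study conditions,
runs the analysis, and measures a calibration / recovery / concordance
quantity. They are used by the validation test suite, the acceptance
script, and the analysis drivers, so the numbers those report all come
from the same code paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as ss

from .compare import ScreenPair, phenotype_correlation
from .readout import dff_traces, fit_4pl
from .simulate import (
    SimConfig,
    make_truth,
    simulate_dose_response,
    simulate_screen,
    simulate_traces,
    synthetic_manifest,
)
from .stats import run_screen_stats


def null_calibration(
    n_runs: int = 20,
    n_genes: int = 500,
    sgrnas_per_gene: int = 5,
    n_ntc: int = 50,
    seed: int = 0,
) -> dict:
    """All-neutral screens: KS uniformity of gene p-values per run and the
    fraction of genes called strong hits (FDR < 0.05) under the null."""
    ks_p = []
    strong_frac = []
    for i in range(n_runs):
        run_seed = seed + 1000 + i
        m = synthetic_manifest(n_genes, sgrnas_per_gene, n_ntc, seed=run_seed)
        cfg = SimConfig(seed=run_seed, n_genes=n_genes,
                        sgrnas_per_gene=sgrnas_per_gene, n_ntc=n_ntc)
        sim = simulate_screen(m, cfg, truth=make_truth(m, cfg), screen_id="null")
        gene_df, _, _ = run_screen_stats(sim.counts, sim.sample_sheet, m,
                                         "null", seed=run_seed)
        ks_p.append(float(ss.kstest(gene_df["p_value"], "uniform").pvalue))
        strong_frac.append(float((gene_df["fdr"] < 0.05).mean()))
    strong = np.asarray(strong_frac)
    se = strong.std(ddof=1) / np.sqrt(n_runs) if n_runs > 1 else 0.0
    return {
        "ks_pvalues": ks_p,
        "ks_pass": int(sum(p > 0.01 for p in ks_p)),
        "n_runs": n_runs,
        "mean_strong_fraction": float(strong.mean()),
        "strong_fraction_bound": float(0.05 + 2 * se),
    }


def _planted_screen(
    seed: int,
    n_genes: int,
    planted_genes: list[str],
    odds_multiplier: float = 0.1,
    min_kd: float = 0.8,
    n_ntc: int | None = None,
    screen_id: str = "sim",
    manifest=None,
):
    n_ntc = n_ntc if n_ntc is not None else max(50, int(0.025 * n_genes * 5 / (1 - 0.025)))
    if manifest is None:
        manifest = synthetic_manifest(n_genes, 5, n_ntc, seed=seed)
    cfg = SimConfig(seed=seed, n_genes=n_genes, sgrnas_per_gene=5, n_ntc=n_ntc)
    truth = make_truth(manifest, cfg,
                       positive_genes={g: odds_multiplier for g in planted_genes},
                       min_kd_planted=min_kd)
    sim = simulate_screen(manifest, cfg, truth=truth, screen_id=screen_id)
    gene_df, _, _ = run_screen_stats(sim.counts, sim.sample_sheet, manifest,
                                     screen_id, seed=seed)
    return manifest, gene_df


def planted_recovery(
    n_genes: int = 2000,
    n_planted: int = 50,
    odds_multiplier: float = 0.1,
    seed: int = 0,
) -> dict:
    """Sensitivity and precision for planted positive regulators at
    FDR < 0.05 (coverage 1000, depth 1000 reads/element, kd ≥ 0.8)."""
    planted = [f"gene{i:05d}" for i in range(n_planted)]
    _, gene_df = _planted_screen(seed + 2, n_genes, planted, odds_multiplier)
    called = set(gene_df.loc[gene_df["fdr"] < 0.05, "gene"])
    tp = len(called & set(planted))
    return {
        "sensitivity": tp / n_planted,
        "precision": tp / max(len(called), 1),
        "n_called": len(called),
        "n_genes": n_genes,
    }


def concordance_pattern(n_genes: int = 2000, n_planted: int = 50, seed: int = 0) -> dict:
    """Pearson r of phenotype scores for two screens sharing planted genes
    (expected high) and for screens with disjoint mechanisms (expected ~0)."""
    shared = [f"gene{i:05d}" for i in range(n_planted)]
    disjoint = [f"gene{i:05d}" for i in range(1000, 1000 + n_planted)]
    m, g1 = _planted_screen(seed + 3, n_genes, shared, screen_id="a")
    _, g2 = _planted_screen(seed + 4, n_genes, shared, screen_id="b", manifest=m)
    _, g3 = _planted_screen(seed + 5, n_genes, disjoint, screen_id="c", manifest=m)
    r_shared = phenotype_correlation(ScreenPair(g1, g2, "a", "b"))
    r_disjoint = phenotype_correlation(ScreenPair(g1, g3, "a", "c"))
    return {
        "r_shared": r_shared["r"],
        "r_disjoint": r_disjoint["r"],
        "n": r_shared["n"],
    }


def counting_oracle(seed: int = 0, n_reads: int = 10_000, workdir=None) -> dict:
    """Agreement between the fast protospacer matcher and the exhaustive
    Hamming-scan oracle on simulated reads, both policies."""
    import tempfile
    from pathlib import Path

    from .counting import brute_force_count, count_sample
    from .simulate import write_fastq

    m = synthetic_manifest(30, 5, 5, seed=seed + 6)
    cfg = SimConfig(seed=seed + 6, n_genes=30, sgrnas_per_gene=5, n_ntc=5,
                    reads_per_sample=n_reads)
    sim = simulate_screen(m, cfg)
    col = sim.counts.iloc[:, 0]
    out = {}
    with tempfile.TemporaryDirectory(dir=workdir) as d:
        fq = str(Path(d) / "reads.fastq")
        write_fastq(col, m, fq, read_length=50, offset=10, error_rate=0.01,
                    seed=seed + 6)
        for policy in ("exact", "one_mismatch"):
            fast = count_sample(fq, m, "s", offset=10, policy=policy)
            oracle = brute_force_count(fq, m, "s", offset=10, policy=policy)
            agree = bool(
                fast.counts.equals(oracle.counts)
                and int(fast.unmapped.iloc[0]) == int(oracle.unmapped.iloc[0])
            )
            out[policy] = {"agree": agree, "n_reads": n_reads}
    return out


def ec50_recovery(seed: int = 0, n_datasets: int = 30) -> dict:
    """Monte-Carlo 4PL fit recovery: mean fitted EC50 vs truth at 8
    two-fold dilution doses × 3 replicates, noise 5% of the range."""
    truth = 0.35
    doses = 5.0 / 2 ** np.arange(8)
    est = [
        fit_4pl(simulate_dose_response(doses, bottom=1, top=7, ec50=truth,
                                       hill=1.0, noise_sd=0.3, n_reps=3,
                                       seed=seed + 7 + i)).ec50
        for i in range(n_datasets)
    ]
    mean = float(np.mean(est))
    return {"ec50_truth": truth, "ec50_mean_estimate": mean,
            "rel_error": abs(mean - truth) / truth, "n_datasets": n_datasets}


def dff_peak_recovery(seed: int = 0, n_cells: int = 500) -> dict:
    """Mean extracted peak ΔF/F0 (Savitzky–Golay window 11) over noisy
    transients at SNR 10, against the generating peak of 2.0."""
    tr = simulate_traces(n_cells, peak_dff=2.0, noise_sd=0.2, seed=seed + 8)
    _, peaks = dff_traces(tr, smooth_window=11)
    mean = float(peaks["peak_dff"].mean())
    return {"peak_truth": 2.0, "peak_mean_estimate": mean,
            "rel_bias": mean / 2.0 - 1.0, "n_cells": n_cells}


def ddct_inversion(seed: int = 0, fold_change: float = 0.07) -> dict:
    """Noiseless ΔΔCt inversion of a forward-simulated fold change."""
    from .readout import ddct_knockdown
    from .simulate import simulate_ct_table

    ct = simulate_ct_table(fold_change, seed=seed + 9, noise_sd=0.0)
    res = ddct_knockdown(ct, "Cs", "Gapdh", "NTC")
    return {
        "fold_truth": fold_change,
        "relative_expression": res["relative_expression"],
        "knockdown_pct": res["knockdown_pct"],
        "abs_error": abs(res["relative_expression"] - fold_change),
    }


def enrichment_oracle(seed: int = 0) -> dict:
    """Hypergeometric p vs exhaustive enumeration on universes ≤ 25 genes."""
    from itertools import combinations

    from .compare import geneset_enrichment

    rng = np.random.default_rng(seed + 10)
    max_abs_diff = 0.0
    n_cases = 0
    for _ in range(8):
        N = int(rng.integers(8, 14))
        K = int(rng.integers(2, N - 2))
        n = int(rng.integers(2, N - 2))
        universe = [f"u{i}" for i in range(N)]
        hits = list(rng.choice(universe, size=n, replace=False))
        df = geneset_enrichment(hits, {"S": universe[:K]}, universe)
        k_obs = int(df.loc[0, "k_hits_in_set"])
        in_set = set(universe[:K])
        total = ge = 0
        for combo in combinations(universe, n):
            total += 1
            ge += len(in_set.intersection(combo)) >= k_obs
        max_abs_diff = max(max_abs_diff, abs(df.loc[0, "p_value"] - ge / total))
        n_cases += 1
    return {"max_abs_diff": max_abs_diff, "n_cases": n_cases}


def survival_recall(
    n_genes: int = 500, n_lethal: int = 100, fitness: float = 0.6, seed: int = 0
) -> dict:
    """Survival-arm recall of planted low-fitness (essential-like) genes at
    the phenotype-score threshold maximizing Youden's index."""
    m = synthetic_manifest(n_genes, 5, 50, seed=seed + 11)
    cfg = SimConfig(seed=seed + 11, n_genes=n_genes, sgrnas_per_gene=5, n_ntc=50)
    lethal = [f"gene{i:05d}" for i in range(n_lethal)]
    truth = make_truth(m, cfg, fitness={g: fitness for g in lethal},
                       min_kd_planted=0.8)
    sim = simulate_screen(m, cfg, truth=truth)
    gene_df, _, _ = run_screen_stats(sim.counts, sim.sample_sheet, m, "sim",
                                     arm="survival", seed=seed + 11)
    # dropout orientation: endpoint/day0 < 1 for lethal genes, so knockdown
    # of an essential-like gene gives a *negative* effect; score on -score
    scores = -gene_df.set_index("gene")["phenotype_score"]
    is_lethal = scores.index.isin(lethal)
    best = None
    for t in np.unique(scores):
        tpr = float((scores[is_lethal] >= t).mean())
        fpr = float((scores[~is_lethal] >= t).mean())
        j = tpr - fpr
        if best is None or j > best[0]:
            best = (j, t, tpr)
    _, threshold, recall = best
    return {"recall": recall, "threshold": float(threshold),
            "n_lethal": n_lethal, "n_genes": n_genes}
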