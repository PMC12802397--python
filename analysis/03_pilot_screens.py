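#!/usr/bin/env python
"""Parallel pilot screens: two nutrient stimuli sharing mechanisms vs a
depolarization control with a disjoint mechanism, plus the paired survival
(dropout) arm.

Plants one set of 40 positive-regulator genes shared by the two nutrient
screens and a disjoint set of 40 for the control screen, calls hits per
screen, and measures the concordance pattern: nutrient-vs-nutrient
phenotype scores should correlate strongly, nutrient-vs-control and
nutrient-vs-survival should not. Writes gene-stats, rank and correlation
tables under results/.
"""

from pathlib import Path

import pandas as pd

from sortscreen import (
    ScreenPair,
    SimConfig,
    hitset_overlap,
    make_truth,
    phenotype_correlation,
    rank_by_phenotype,
    simulate_screen,
)
from sortscreen.simulate import synthetic_manifest
from sortscreen.stats import run_screen_stats

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_GENES, N_NTC, SEED = 1000, 125, 31
manifest = synthetic_manifest(N_GENES, 5, N_NTC, seed=SEED)
shared = [f"gene{i:05d}" for i in range(40)]           # nutrient-sensing genes
disjoint = [f"gene{i:05d}" for i in range(500, 540)]    # depolarization genes
lethal = {f"gene{i:05d}": 0.75 for i in range(900, 950)}  # fitness confounders

stats = {}
for screen_id, planted, seed in [("tryptone", shared, SEED + 1),
                                 ("phenylalanine", shared, SEED + 2),
                                 ("kcl", disjoint, SEED + 3)]:
    cfg = SimConfig(seed=seed, n_genes=N_GENES, sgrnas_per_gene=5, n_ntc=N_NTC)
    truth = make_truth(manifest, cfg,
                       positive_genes={g: 0.1 for g in planted},
                       fitness=lethal, min_kd_planted=0.8)
    sim = simulate_screen(manifest, cfg, truth=truth, screen_id=screen_id)
    for arm in ("facs", "survival"):
        label = screen_id if arm == "facs" else f"{screen_id}_survival"
        gene_df, _, _ = run_screen_stats(sim.counts, sim.sample_sheet,
                                         manifest, screen_id, arm=arm, seed=seed)
        stats[label] = gene_df
        gene_df.to_csv(OUT / f"pilot_{label}_gene_stats.tsv", sep="\t", index=False)
    n_hits = (stats[screen_id]["fdr"] < 0.05).sum()
    pos = ((stats[screen_id]["fdr"] < 0.05) & (stats[screen_id]["effect"] > 0)).sum()
    print(f"{screen_id}: {n_hits} hits at FDR<0.05 ({pos} positive regulators)")
    top = rank_by_phenotype(stats[screen_id], top_n=10)
    print(top[["gene", "effect", "p_value", "fdr", "phenotype_score"]]
          .to_string(), "\n")

rows = []
for a, b, note in [
    ("tryptone", "phenylalanine", "shared nutrient mechanism"),
    ("tryptone", "kcl", "disjoint mechanism"),
    ("tryptone", "tryptone_survival", "survival confound check"),
    ("phenylalanine", "phenylalanine_survival", "survival confound check"),
]:
    res = phenotype_correlation(ScreenPair(stats[a], stats[b], a, b))
    rows.append((a, b, note, res["r"], res["p"], res["n"]))
    print(f"phenotype-score Pearson r({a}, {b}) = {res['r']:.3f}  ({note})")
corr = pd.DataFrame(rows, columns=["screen_a", "screen_b", "note", "r", "p", "n"])
corr.to_csv(OUT / "pilot_correlations.tsv", sep="\t", index=False)

overlap = hitset_overlap({k: stats[k] for k in ("tryptone", "phenylalanine", "kcl")},
                         "tryptone", top_n=30)
overlap.to_csv(OUT / "pilot_top30_overlap.tsv", sep="\t", index=False)
shared_top = overlap["phenylalanine_hit_class"].str.contains("regulator").sum()
kcl_top = overlap["kcl_hit_class"].str.contains("regulator").sum()
print(f"top 30 tryptone hits: {shared_top}/30 are phenylalanine hits, "
      f"{kcl_top}/30 are KCl hits")
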