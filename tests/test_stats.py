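"""Hit-calling statistics: normalization, fold changes, the rank-sum test
vs NTCs, the quasi-gene empirical FDR, and ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from sortscreen import (
    SimConfig,
    classify_hits,
    empirical_fdr,
    gene_stats,
    make_truth,
    normalize,
    rank_by_phenotype,
    rank_sum_p,
    run_screen_stats,
    sgrna_log2fc,
    simulate_screen,
)
from sortscreen.library import SampleSheet
from sortscreen.simulate import synthetic_manifest
from sortscreen.stats import rank_sum_p_many


# --- normalization ---------------------------------------------------------

def test_normalize_cpm_columns():
    counts = pd.DataFrame({"s": [5]}, index=["e1"])
    assert normalize(counts, pseudocount=0).loc["e1", "s"] == pytest.approx(1e6)
    counts = pd.DataFrame({"s": [1, 3]}, index=["e1", "e2"])
    out = normalize(counts, pseudocount=0)
    assert out["s"].tolist() == pytest.approx([2.5e5, 7.5e5])
    zero = pd.DataFrame({"s": [0, 4], "t": [2, 2]}, index=["e1", "e2"])
    assert normalize(zero, pseudocount=1).loc["e1", "s"] > 0
    with pytest.raises(ValueError, match="bad_col"):
        normalize(pd.DataFrame({"bad_col": [0, 0]}), pseudocount=0)


def test_normalize_column_sums_are_1e6(neutral_screen):
    sim, _ = neutral_screen
    norm = normalize(sim.counts)
    assert np.allclose(norm.sum(axis=0), 1e6)


# --- sgRNA log2 fold change ------------------------------------------------

def _two_sample_sheet():
    return SampleSheet(pd.DataFrame(
        [("hi", "x", "facs", "high_bin", "s", 1),
         ("lo", "x", "facs", "low_bin", "s", 1)],
        columns=["sample_id", "screen_id", "arm", "role", "stimulus", "replicate"],
    ))


def test_log2fc_orientation_and_values():
    # element depleted from the responder (high) bin 1:4 scores +2
    counts = pd.DataFrame({"hi": [100, 400], "lo": [400, 100]},
                          index=["e1", "e2"])
    norm = normalize(counts, pseudocount=0)
    lfc = sgrna_log2fc(norm, _two_sample_sheet(), "x")
    assert lfc["e1"] == pytest.approx(2.0)
    assert lfc["e2"] == pytest.approx(-2.0)
    equal = normalize(pd.DataFrame({"hi": [7, 7], "lo": [7, 7]},
                                   index=["e1", "e2"]), pseudocount=0)
    assert sgrna_log2fc(equal, _two_sample_sheet(), "x").abs().max() == 0


def test_log2fc_missing_role_errors():
    counts = normalize(pd.DataFrame({"hi": [1, 2]}, index=["e1", "e2"]))
    sheet = SampleSheet(pd.DataFrame(
        [("hi", "x", "facs", "high_bin", "s", 1),
         ("lo", "x", "facs", "low_bin", "s", 1)],
        columns=["sample_id", "screen_id", "arm", "role", "stimulus", "replicate"],
    ))
    with pytest.raises(ValueError, match="missing role"):
        sgrna_log2fc(counts, sheet, "y")


# --- rank-sum p vs scipy oracle --------------------------------------------

def test_rank_sum_matches_scipy_exact(rng):
    for n1, n2 in [(3, 8), (5, 20), (5, 50), (4, 30)]:
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        ours = rank_sum_p(x, y)
        ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


def test_rank_sum_ties_fall_back_to_corrected_normal(rng):
    x = np.array([1.0, 1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 1.0])
    ours = rank_sum_p(x, y)
    ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    assert ours == pytest.approx(ref, abs=1e-9)


def test_rank_sum_vectorised_equals_scalar(rng):
    pool = rng.normal(size=40)
    groups = rng.normal(size=(20, 5))
    many = rank_sum_p_many(groups, pool)
    each = [rank_sum_p(g, pool) for g in groups]
    assert np.allclose(many, each)


# --- gene stats ------------------------------------------------------------

def _manifest_lfc(n_genes=20, sgrnas=5, n_ntc=30, seed=0, shift_gene=None,
                  shift=0.0):
    m = synthetic_manifest(n_genes, sgrnas, n_ntc, seed=seed)
    rng = np.random.default_rng(seed)
    lfc = pd.Series(rng.normal(size=len(m)), index=m.element_ids)
    if shift_gene is not None:
        lfc[m.gene_of() == shift_gene] += shift
    return m, lfc


def test_gene_identical_to_ntc_pool_scores_null():
    """A gene whose sgRNA log2FCs equal the NTC values is maximally
    unsurprising: p = 1, phenotype score 0."""
    m = synthetic_manifest(1, 5, 10, seed=1)
    vals = np.array([0.3, -0.2, 0.8, -0.9, 0.1])
    lfc = pd.Series(np.concatenate([vals, vals, vals]), index=m.element_ids)
    gene_df, _ = gene_stats(lfc, m, seed=0)
    assert gene_df.loc[0, "p_value"] == pytest.approx(1.0)
    assert gene_df.loc[0, "phenotype_score"] == pytest.approx(0.0)


def test_phenotype_score_is_effect_times_neglog10p():
    m, lfc = _manifest_lfc(shift_gene="gene00000", shift=2.0)
    gene_df, _ = gene_stats(lfc, m, seed=1)
    expected = gene_df["effect"] * (-np.log10(gene_df["p_value"]))
    assert np.allclose(gene_df["phenotype_score"], expected)
    # an effect of 2 with p = 0.01 would give a score of 4 by that formula
    assert 2.0 * (-np.log10(0.01)) == pytest.approx(4.0)


def test_shifted_gene_detected():
    m, lfc = _manifest_lfc(shift_gene="gene00000", shift=3.0)
    gene_df, _ = gene_stats(lfc, m, seed=1)
    row = gene_df.set_index("gene").loc["gene00000"]
    assert row["effect"] > 2.0
    assert row["fdr"] < 0.05
    assert row["hit_class"] == "strong_positive_regulator"


def test_no_ntc_errors():
    m = synthetic_manifest(3, 5, 0, seed=2)
    lfc = pd.Series(np.zeros(len(m)), index=m.element_ids)
    with pytest.raises(ValueError, match="NTC"):
        gene_stats(lfc, m, seed=0)


def test_quasi_null_deterministic_under_seed():
    m, lfc = _manifest_lfc()
    g1, n1 = gene_stats(lfc, m, seed=42)
    g2, n2 = gene_stats(lfc, m, seed=42)
    pd.testing.assert_frame_equal(n1.table, n2.table)
    pd.testing.assert_frame_equal(g1, g2)
    _, n3 = gene_stats(lfc, m, seed=43)
    assert not n3.table["effect"].equals(n1.table["effect"])


def test_sign_flip_negates_effects_and_scores():
    """Swapping bin labels negates every effect and phenotype score."""
    m = synthetic_manifest(15, 5, 20, seed=3)
    cfg = SimConfig(seed=3, n_genes=15, sgrnas_per_gene=5, n_ntc=20)
    sim = simulate_screen(m, cfg, truth=make_truth(m, cfg))
    norm = normalize(sim.counts)
    lfc = sgrna_log2fc(norm, sim.sample_sheet, "sim")
    flipped_sheet = SampleSheet(
        sim.sample_sheet.frame.assign(
            role=sim.sample_sheet.frame["role"].map(
                {"high_bin": "low_bin", "low_bin": "high_bin",
                 "day0": "day0", "endpoint": "endpoint"}
            )
        )
    )
    lfc_flip = sgrna_log2fc(norm, flipped_sheet, "sim")
    assert np.allclose(lfc, -lfc_flip)
    g, _ = gene_stats(lfc, m, seed=5)
    gf, _ = gene_stats(lfc_flip, m, seed=5)
    merged = g.merge(gf, on="gene", suffixes=("", "_f"))
    assert np.allclose(merged["effect"], -merged["effect_f"])
    assert np.allclose(merged["phenotype_score"], -merged["phenotype_score_f"])
    assert np.allclose(merged["p_value"], merged["p_value_f"])


def test_null_pvalues_uniform_and_quasi_indistinguishable():
    """All-neutral screen: gene p-values consistent with Uniform(0,1); real
    genes and quasi-genes have indistinguishable phenotype scores."""
    m = synthetic_manifest(200, 5, 50, seed=13)
    cfg = SimConfig(seed=13, n_genes=200, sgrnas_per_gene=5, n_ntc=50)
    sim = simulate_screen(m, cfg, truth=make_truth(m, cfg))
    gene_df, lfc, null = run_screen_stats(sim.counts, sim.sample_sheet, m,
                                          "sim", seed=13)
    assert ss.kstest(gene_df["p_value"], "uniform").pvalue > 0.01
    ks2 = ss.ks_2samp(gene_df["phenotype_score"], null.table["phenotype_score"])
    assert ks2.pvalue > 0.01
    assert (gene_df["fdr"] < 0.05).mean() <= 0.05


# --- FDR machinery ---------------------------------------------------------

def test_empirical_fdr_directional_and_monotone():
    scores = np.array([5.0, 3.0, 1.0, -1.0, -4.0, 0.5])
    null = np.concatenate([np.zeros(50), [2.0, -2.0]])
    fdr = empirical_fdr(scores, null)
    assert np.all((fdr >= 0) & (fdr <= 1))
    # more extreme positive scores never have larger FDR
    pos = scores >= 0
    order = np.argsort(-scores[pos])
    assert np.all(np.diff(fdr[pos][order]) >= 0)
    # extreme tail beyond all null mass
    assert fdr[0] < fdr[2]


def test_classify_hits_thresholds():
    df = pd.DataFrame({
        "gene": list("abcd"),
        "effect": [1.0, -1.0, 2.0, 0.5],
        "fdr": [0.03, 0.07, 0.5, 0.1],
    })
    out = classify_hits(df)
    assert out["hit_class"].tolist() == [
        "strong_positive_regulator",
        "weak_negative_regulator",
        "none",
        "none",
    ]


def test_rank_by_phenotype_order_and_ties():
    df = pd.DataFrame({
        "gene": ["b", "c", "a", "d"],
        "phenotype_score": [3.0, 1.0, 2.0, 1.0],
    })
    ranked = rank_by_phenotype(df)
    assert ranked["gene"].tolist() == ["b", "a", "c", "d"]
    assert ranked["phenotype_score"].tolist() == [3.0, 2.0, 1.0, 1.0]
    assert rank_by_phenotype(df, top_n=2)["gene"].tolist() == ["b", "a"]
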