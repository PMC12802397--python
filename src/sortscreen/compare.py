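"""Cross-screen concordance, recall against reference gene lists, and
gene-set over-representation.

Two parallel screens probing the same biology should correlate on
phenotype scores; a screen against an unrelated stimulus, or the internal
survival (dropout) screen, should not — the standard sanity checks that a
sort-based screen measured stimulus-specific signal rather than toxicity.
The enrichment universe is the set of genes targeted by the library, since
the screen can only nominate tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ScreenPair:
    """Two gene tables restricted to their common genes."""

    a: pd.DataFrame
    b: pd.DataFrame
    label_a: str = "screen_a"
    label_b: str = "screen_b"

    def __post_init__(self) -> None:
        common = pd.Index(self.a["gene"]).intersection(self.b["gene"])
        if len(common) < 3:
            raise ValueError(f"only {len(common)} shared genes; need ≥ 3")
        self.a = self.a.set_index("gene").loc[common].reset_index()
        self.b = self.b.set_index("gene").loc[common].reset_index()

    @property
    def n(self) -> int:
        return len(self.a)


def phenotype_correlation(pair: ScreenPair) -> dict:
    """Pearson r (with two-sided p) between the two screens' phenotype
    scores over their shared genes."""
    x = pair.a["phenotype_score"].to_numpy()
    y = pair.b["phenotype_score"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in phenotype scores; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": pair.n}


def recall_at_threshold(
    gene_df: pd.DataFrame,
    reference_set: list[str],
    threshold: float,
    grid: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of reference genes (present in the screen) at or above a
    phenotype-score threshold, plus a sweep curve over a score grid."""
    scores = gene_df.set_index("gene")["phenotype_score"]
    present = scores.index.intersection(reference_set)
    if len(present) == 0:
        raise ValueError("reference set does not intersect screen genes")
    ref_scores = scores.loc[present].to_numpy()

    def recall(t: float) -> float:
        return float((ref_scores >= t).mean())

    if grid is None:
        grid = np.unique(np.concatenate([scores.to_numpy(), [threshold]]))
    sweep = pd.DataFrame({"threshold": grid, "recall": [recall(t) for t in grid]})
    return recall(threshold), sweep


def hitset_overlap(
    screens: dict[str, pd.DataFrame], primary: str, top_n: int
) -> pd.DataFrame:
    """Hit status of the primary screen's top-`top_n` genes in every screen.

    Rows: the top genes of ``screens[primary]`` by phenotype score; columns:
    ``<label>_score`` and ``<label>_hit_class`` per screen.
    """
    base = screens[primary]
    if top_n > len(base):
        raise ValueError(f"top_n {top_n} exceeds gene count {len(base)}")
    top = (
        base.sort_values(["phenotype_score", "gene"], ascending=[False, True])
        .head(top_n)["gene"]
        .tolist()
    )
    out = pd.DataFrame({"gene": top})
    for label, df in screens.items():
        idx = df.set_index("gene")
        out[f"{label}_score"] = idx["phenotype_score"].reindex(top).to_numpy()
        out[f"{label}_hit_class"] = idx["hit_class"].reindex(top).to_numpy()
    return out


def geneset_enrichment(
    hits: list[str],
    sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set among the hits.

    p = P(X ≥ k) for X ~ Hypergeom(N=|universe|, K=|set|, n=|hits|);
    q = Benjamini–Hochberg across sets; fold = (k/n)/(K/N).
    """
    uni = set(universe)
    hitset = set(hits)
    stray = hitset - uni
    if stray:
        raise ValueError(f"hits outside universe: {sorted(stray)[:5]}")
    offenders = {name: sorted(set(genes) - uni) for name, genes in sets.items()}
    offenders = {k: v for k, v in offenders.items() if v}
    if offenders:
        raise ValueError(f"gene sets outside universe: {offenders}")
    N, n = len(uni), len(hitset)
    rows = []
    for name, genes in sets.items():
        gs = set(genes)
        K = len(gs)
        k = len(gs & hitset)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
        rows.append((name, k, K, n, N, fold, p))
    df = pd.DataFrame(
        rows, columns=["set_name", "k_hits_in_set", "set_size", "n_hits",
                       "universe_size", "fold_enrichment", "p_value"]
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def load_gene_sets(path: str) -> dict[str, list[str]]:
    """Read a (set_name, gene) TSV into named gene lists."""
    df = pd.read_csv(path, sep="\t")
    return {name: grp["gene"].tolist() for name, grp in df.groupby("set_name")}
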