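"""Hit-calling statistics for sort-based pooled screens.

Pipeline: counts → counts-per-million with pseudocount → per-sgRNA log2
fold change between the non-responder and responder bins (or
endpoint/day0 for a survival arm) → per-gene effect, rank-sum p-value
against the pooled non-targeting-control (NTC) sgRNAs, empirical FDR from
NTC *quasi-genes*, phenotype score = effect × −log10(p), and hit classes
at FDR < 0.05 (strong) / < 0.1 (weak).

Orientation: enrichment is non-responder over responder bin, so a gene
whose knockdown *decreases* the stimulus response (a positive regulator)
gets a positive effect and ranks at the top.

The quasi-gene null: pseudo-genes are assembled by resampling NTC sgRNAs
(without replacement within a draw, with replacement across draws) in
groups of the modal per-gene sgRNA count, and scored exactly like real
genes; the empirical FDR at score threshold t is the quasi-gene tail
fraction over the real-gene tail fraction, computed per direction, capped
at 1, and monotonized from the extreme tail inward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .library import NTC_GENE, LibraryManifest, SampleSheet

HIT_CLASSES = (
    "strong_positive_regulator",
    "weak_positive_regulator",
    "strong_negative_regulator",
    "weak_negative_regulator",
    "none",
)


# ---------------------------------------------------------------------------
# normalization and sgRNA fold changes
# ---------------------------------------------------------------------------

def normalize(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Counts-per-million after adding a pseudocount to every element.

    Each column of the result sums to 10^6. An all-zero column (with
    pseudocount 0) is rejected by name.
    """
    shifted = counts.astype(float) + pseudocount
    totals = shifted.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return shifted / totals * 1e6


def sgrna_log2fc(
    norm: pd.DataFrame,
    sheet: SampleSheet,
    screen_id: str,
    arm: str = "facs",
) -> pd.Series:
    """Replicate-averaged per-element log2 fold change for one screen.

    facs arm: log2(low_bin / high_bin) — sgRNAs depleted from the responder
    (high red/green) bin score positive. survival arm: log2(endpoint/day0).
    Replicates are paired by replicate number when both roles share the
    same replicate set (per-replicate log-ratio, then mean); otherwise
    frequencies are averaged per role first.
    """
    if arm == "facs":
        num_role, den_role = "low_bin", "high_bin"
    elif arm == "survival":
        num_role, den_role = "endpoint", "day0"
    else:
        raise ValueError(f"unknown arm {arm!r}")
    num = sheet.samples_for(screen_id, num_role)
    den = sheet.samples_for(screen_id, den_role)
    if num.empty or den.empty:
        raise ValueError(
            f"screen {screen_id!r}: missing role "
            f"{num_role if num.empty else den_role!r}"
        )
    num_by_rep = dict(zip(num["replicate"], num["sample_id"]))
    den_by_rep = dict(zip(den["replicate"], den["sample_id"]))
    if (
        set(num_by_rep) == set(den_by_rep)
        and len(num_by_rep) == len(num)
        and len(den_by_rep) == len(den)
    ):
        lfcs = [
            np.log2(norm[num_by_rep[r]] / norm[den_by_rep[r]]) for r in num_by_rep
        ]
        out = pd.concat(lfcs, axis=1).mean(axis=1)
    else:
        out = np.log2(
            norm[list(num["sample_id"])].mean(axis=1)
            / norm[list(den["sample_id"])].mean(axis=1)
        )
    out.name = f"{screen_id}_log2fc"
    return out


# ---------------------------------------------------------------------------
# rank-sum test vs the pooled NTC sgRNAs
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _exact_u_sf(n1: int, n2: int) -> np.ndarray:
    """Survival function P(U >= u), u = 0..n1*n2, of the exact
    Mann–Whitney U null for group sizes (n1, n2).

    Uses the Mann–Whitney counting recurrence
    N(u; m, n) = N(u − n; m − 1, n) + N(u; m, n − 1): the largest combined
    observation is either a group member (contributing n pairs) or a pool
    member. Vectorized over u; cached per group-size pair.
    """
    max_u = n1 * n2
    # counts[m][u] = N(u; m, n) for the current n; start at n = 0
    counts = [np.zeros(max_u + 1) for _ in range(n1 + 1)]
    for m in range(n1 + 1):
        counts[m][0] = 1.0
    for n in range(1, n2 + 1):
        new = [np.zeros(max_u + 1) for _ in range(n1 + 1)]
        new[0][0] = 1.0
        for m in range(1, n1 + 1):
            new[m][n:] = new[m - 1][: max_u + 1 - n]
            new[m] += counts[m]
        counts = new
    pmf = counts[n1] / counts[n1].sum()
    return np.cumsum(pmf[::-1])[::-1]  # sf[u] = P(U >= u)


def rank_sum_p(values: np.ndarray, null_pool: np.ndarray) -> float:
    """Two-sided Mann–Whitney rank-sum p of ``values`` against
    ``null_pool``: exact null pmf when there are no cross-group ties and
    the table is small, normal approximation with tie correction otherwise.
    """
    return float(rank_sum_p_many(values[None, :], null_pool)[0])


def rank_sum_p_many(groups: np.ndarray, null_pool: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p for many equal-size groups against
    one shared pool. ``groups``: (n_groups, n1) array."""
    groups = np.asarray(groups, dtype=float)
    pool = np.sort(np.asarray(null_pool, dtype=float))
    n1 = groups.shape[1]
    n2 = pool.size
    if n2 == 0:
        raise ValueError("empty NTC pool: null unconstructible")
    lo = np.searchsorted(pool, groups, side="left")
    hi = np.searchsorted(pool, groups, side="right")
    U = (lo + 0.5 * (hi - lo)).sum(axis=1)  # midrank ties
    has_ties = (hi != lo).any(axis=1)
    p = np.empty(groups.shape[0])
    exact_ok = n1 * n2 <= 20000
    if exact_ok:
        sf = _exact_u_sf(n1, n2)
        max_u = n1 * n2
        Ui = U
        # exact path only valid for integer U (no cross ties)
        u_int = np.round(Ui).astype(int)
        p_hi = sf[np.minimum(u_int, max_u)]
        # P(U <= u) = P(U' >= max_u - u) by symmetry
        p_lo = sf[np.minimum(max_u - u_int, max_u)]
        p_exact = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
        p[:] = p_exact
        use_normal = has_ties | (np.abs(Ui - u_int) > 1e-9)
    else:
        use_normal = np.ones(groups.shape[0], dtype=bool)
    if use_normal.any():
        mu = n1 * n2 / 2.0
        # tie correction over the combined sample, per group
        idx = np.nonzero(use_normal)[0]
        for i in idx:
            combined = np.concatenate([groups[i], pool])
            _, cnt = np.unique(combined, return_counts=True)
            n = n1 + n2
            tie_term = (cnt**3 - cnt).sum() / (n * (n - 1))
            sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
            if sigma2 <= 0:
                p[i] = 1.0
                continue
            z = (U[i] - mu - 0.5 * np.sign(U[i] - mu)) / math.sqrt(sigma2)
            p[i] = min(1.0, 2.0 * _norm_sf(abs(z)))
    return p


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# gene-level statistics and the quasi-gene empirical FDR
# ---------------------------------------------------------------------------

@dataclass
class QuasiGeneNull:
    """Scored NTC pseudo-genes forming the empirical null."""

    table: pd.DataFrame        # columns: quasi_gene, effect, p_value, phenotype_score
    group_size: int
    seed: int


def _aggregate(vals: np.ndarray, aggregation: str, top_k: int = 3) -> float:
    if aggregation == "mean_all":
        return float(np.mean(vals))
    if aggregation == "mean_top_k":
        k = min(top_k, vals.size)
        idx = np.argsort(np.abs(vals))[::-1][:k]
        return float(np.mean(vals[idx]))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _phenotype_score(effect: np.ndarray, p: np.ndarray) -> np.ndarray:
    return effect * (-np.log10(np.maximum(p, 1e-300)))


def gene_stats(
    sg_lfc: pd.Series,
    manifest: LibraryManifest,
    aggregation: str = "mean_all",
    top_k: int = 3,
    quasi_factor: int = 10,
    seed: int = 0,
    strong_fdr: float = 0.05,
    weak_fdr: float = 0.1,
) -> tuple[pd.DataFrame, QuasiGeneNull]:
    """Per-gene effect, rank-sum p vs pooled NTC sgRNAs, quasi-gene
    empirical FDR, phenotype score, and hit class.

    Returns (gene table, quasi-gene null). The gene table columns are
    gene, n_sgrnas, effect, p_value, phenotype_score, fdr, hit_class.
    """
    gene_of = manifest.gene_of()
    lfc = sg_lfc.reindex(gene_of.index)
    if lfc.isna().any():
        missing = list(lfc.index[lfc.isna()][:5])
        raise ValueError(f"log2fc missing for manifest elements, e.g. {missing}")
    ntc_mask = (gene_of == NTC_GENE).to_numpy()
    ntc_vals = lfc.to_numpy()[ntc_mask]
    if ntc_vals.size == 0:
        raise ValueError("no NTC elements in manifest: null unconstructible")

    genes: list[str] = []
    effects: list[float] = []
    pvals: list[float] = []
    n_sg: list[int] = []
    per_gene_counts = manifest.per_gene_count
    sizes = pd.Series(per_gene_counts)
    modal_size = int(sizes.mode().iloc[0])

    # group genes by sgRNA count so equal-size genes share one vectorized test
    by_size: dict[int, tuple[list[str], list[np.ndarray]]] = {}
    gvals = lfc.groupby(gene_of).agg(list)
    for gene, vals in gvals.items():
        if gene == NTC_GENE:
            continue
        arr = np.asarray(vals, dtype=float)
        by_size.setdefault(arr.size, ([], []))
        by_size[arr.size][0].append(gene)
        by_size[arr.size][1].append(arr)
    for size, (names, arrs) in sorted(by_size.items()):
        if size < 2:
            raise ValueError(
                f"gene(s) with < 2 sgRNAs cannot be rank-tested: {names[:5]}"
            )
        mat = np.vstack(arrs)
        p = rank_sum_p_many(mat, ntc_vals)
        for name, arr, pv in zip(names, arrs, p):
            genes.append(name)
            effects.append(_aggregate(arr, aggregation, top_k))
            pvals.append(float(pv))
            n_sg.append(size)

    gene_df = pd.DataFrame(
        {"gene": genes, "n_sgrnas": n_sg, "effect": effects, "p_value": pvals}
    )
    gene_df["phenotype_score"] = _phenotype_score(
        gene_df["effect"].to_numpy(), gene_df["p_value"].to_numpy()
    )

    # --- quasi-gene null -------------------------------------------------
    rng = np.random.default_rng(seed)
    n_quasi = max(quasi_factor * len(gene_df), 10)
    if ntc_vals.size < modal_size + 2:
        raise ValueError(
            f"too few NTC sgRNAs ({ntc_vals.size}) for quasi-genes of size {modal_size}"
        )
    q_effects = np.empty(n_quasi)
    q_p = np.empty(n_quasi)
    idx_all = np.arange(ntc_vals.size)
    draws = np.empty((n_quasi, modal_size), dtype=int)
    for j in range(n_quasi):
        draws[j] = rng.choice(idx_all, size=modal_size, replace=False)
    member_mask = np.zeros((n_quasi, ntc_vals.size), dtype=bool)
    member_mask[np.arange(n_quasi)[:, None], draws] = True
    vals_mat = ntc_vals[draws]
    if aggregation == "mean_all":
        q_effects = vals_mat.mean(axis=1)
    else:
        for j in range(n_quasi):
            q_effects[j] = _aggregate(vals_mat[j], aggregation, top_k)
    # each quasi-gene is tested against the NTC pool minus its own members,
    # mirroring real genes (whose sgRNAs are never in the pool)
    pool_size = ntc_vals.size - modal_size
    rest = np.empty((n_quasi, pool_size))
    for j in range(n_quasi):
        rest[j] = ntc_vals[~member_mask[j]]
    # all quasi-genes share group size; pools differ per row, so loop in
    # blocks of identical pools is impossible — use the exact pmf per row
    sf = _exact_u_sf(modal_size, pool_size) if modal_size * pool_size <= 20000 else None
    for j in range(n_quasi):
        pool = np.sort(rest[j])
        loj = np.searchsorted(pool, vals_mat[j], side="left")
        hij = np.searchsorted(pool, vals_mat[j], side="right")
        U = float((loj + 0.5 * (hij - loj)).sum())
        if sf is not None and (hij == loj).all():
            u = int(round(U))
            mx = modal_size * pool_size
            q_p[j] = min(1.0, 2.0 * min(sf[min(u, mx)], sf[min(mx - u, mx)]))
        else:
            q_p[j] = rank_sum_p(vals_mat[j], rest[j])
    quasi_df = pd.DataFrame(
        {
            "quasi_gene": [f"quasi{j:05d}" for j in range(n_quasi)],
            "effect": q_effects,
            "p_value": q_p,
        }
    )
    quasi_df["phenotype_score"] = _phenotype_score(
        quasi_df["effect"].to_numpy(), quasi_df["p_value"].to_numpy()
    )
    null = QuasiGeneNull(table=quasi_df, group_size=modal_size, seed=seed)

    gene_df["fdr"] = empirical_fdr(
        gene_df["phenotype_score"].to_numpy(),
        quasi_df["phenotype_score"].to_numpy(),
    )
    gene_df = classify_hits(gene_df, strong_fdr=strong_fdr, weak_fdr=weak_fdr)
    return gene_df, null


def empirical_fdr(scores: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """Directional empirical FDR from a null score sample.

    For a gene with score s ≥ 0 (positive tail):
    FDR(s) = [fraction of null scores ≥ s] / [fraction of real scores ≥ s],
    and symmetrically with ≤ for the negative tail; capped at 1 and
    monotonized by cumulative minimum from the extreme tail inward (a more
    extreme score never has a larger FDR).
    """
    scores = np.asarray(scores, dtype=float)
    null_scores = np.asarray(null_scores, dtype=float)
    n = scores.size
    fdr = np.ones(n)
    for sign in (1, -1):
        mask = scores >= 0 if sign == 1 else scores < 0
        if not mask.any():
            continue
        s = scores[mask] * sign
        order = np.argsort(-s)  # most extreme first
        sorted_s = s[order]
        null_tail = np.searchsorted(np.sort(null_scores * sign), sorted_s, side="left")
        frac_null = (null_scores.size - null_tail) / null_scores.size
        real_tail = np.searchsorted(np.sort(scores * sign), sorted_s, side="left")
        frac_real = (n - real_tail) / n
        raw = np.minimum(1.0, frac_null / np.maximum(frac_real, 1e-300))
        # q-value-style monotonization: a gene's FDR is the best (smallest)
        # estimate over all thresholds that still include it, so FDR is
        # non-increasing in score extremity
        mono = np.minimum.accumulate(raw[::-1])[::-1]
        vals = np.empty_like(mono)
        vals[order] = mono
        fdr[mask] = vals
    return fdr


def classify_hits(
    gene_df: pd.DataFrame, strong_fdr: float = 0.05, weak_fdr: float = 0.1
) -> pd.DataFrame:
    """Assign hit classes from FDR thresholds and effect sign."""
    df = gene_df.copy()
    direction = np.where(df["effect"] >= 0, "positive_regulator", "negative_regulator")
    cls = np.full(len(df), "none", dtype=object)
    strong = df["fdr"].to_numpy() < strong_fdr
    weak = (~strong) & (df["fdr"].to_numpy() < weak_fdr)
    cls[strong] = np.char.add("strong_", direction[strong].astype(str))
    cls[weak] = np.char.add("weak_", direction[weak].astype(str))
    df["hit_class"] = cls
    return df


def rank_by_phenotype(gene_df: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Genes in descending phenotype-score order, ties broken by symbol."""
    ranked = gene_df.sort_values(
        ["phenotype_score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked.index = ranked.index + 1
    ranked.index.name = "rank"
    if top_n is not None:
        ranked = ranked.head(top_n)
    return ranked


def run_screen_stats(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    manifest: LibraryManifest,
    screen_id: str,
    arm: str = "facs",
    pseudocount: float = 1.0,
    seed: int = 0,
    **gene_kwargs,
) -> tuple[pd.DataFrame, pd.Series, QuasiGeneNull]:
    """Counts → normalized → sgRNA log2FC → gene stats, in one call."""
    norm = normalize(counts, pseudocount=pseudocount)
    lfc = sgrna_log2fc(norm, sheet, screen_id, arm=arm)
    gene_df, null = gene_stats(lfc, manifest, seed=seed, **gene_kwargs)
    return gene_df, lfc, null
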