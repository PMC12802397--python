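"""Synthetic pooled-screen generator with planted gene effects.

Emulates the statistical structure of a sort-based CRISPRi activity screen
in a photoconversion reporter line:

* a library of sgRNA elements infected at low MOI (cells with more than one
  integration are discarded, so each cell carries one element),
* a per-cell binary *responder* state — whether the cell photoconverts
  (green→red) under stimulus — whose odds are multiplied by a planted
  per-gene effect, attenuated by per-sgRNA knockdown efficacy,
* a red/green ratio drawn from responder / non-responder log-normal
  components, sorted into top and bottom population-quantile gates
  (default 35%), mirroring the physical order FACS-then-PCR,
* a parallel dropout (survival) arm comparing day-0 to endpoint abundance
  after a fixed number of doublings, with per-gene fitness effects,
* sequencing counts drawn multinomially over elements (optionally
  gamma-overdispersed, a negative-binomial-like model).

The default *aggregate* mode partitions each element's cell mass with
binomial draws rather than simulating individual cells, which preserves the
sampling distribution at a fraction of the cost; a per-cell mode exists for
small-n cross-checks.

The module also generates the secondary-assay fixtures: per-cell flow
events, calcium-imaging ΔF/F0 traces, and four-parameter-logistic
dose–response tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .library import (
    CATEGORY_NTC,
    CATEGORY_TARGETING,
    NTC_GENE,
    LibraryElement,
    LibraryManifest,
    SampleSheet,
)

EFFECT_POSITIVE = "positive_regulator"
EFFECT_NEGATIVE = "negative_regulator"
EFFECT_NEUTRAL = "neutral"

_BASE_ARR = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for a simulated screen.

    Defaults follow the screening protocol being emulated: MOI 0.4 (low, so
    essentially all retained cells are single-integration), >1000× cells per
    element, >6 doublings before sorting, top/bottom 35% gates on the
    red/green ratio, and sequencing depth of 1000 reads per element per
    sorted sample.
    """

    seed: int = 0
    n_genes: int = 500
    sgrnas_per_gene: int = 5
    n_ntc: int = 50
    moi: float = 0.4
    coverage: float = 1000.0
    doublings: int = 6
    base_responder_fraction: float = 0.5
    gate_quantile: float = 0.35
    reads_per_sample: int | None = None  # default 1000 × n_elements
    dispersion: float = 0.0
    n_replicates: int = 2
    # per-sgRNA knockdown efficacy ~ Beta(a, b); mean 0.8, matching well-
    # designed top-5 CRISPRi guides
    kd_beta_a: float = 6.0
    kd_beta_b: float = 1.5
    # red/green log-ratio components (natural-log mean, sd)
    nonresponder_logratio: tuple[float, float] = (-1.0, 0.6)
    responder_logratio: tuple[float, float] = (1.0, 0.6)
    protospacer_length: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.gate_quantile < 0.5:
            raise ValueError("gate_quantile must lie in (0, 0.5)")
        if not 0.0 <= self.base_responder_fraction <= 1.0:
            raise ValueError("base_responder_fraction must lie in [0, 1]")
        if not 0.05 <= self.moi <= 1.0:
            raise ValueError("moi must lie in [0.05, 1.0]")
        if self.doublings < 6:
            raise ValueError("doublings must be ≥ 6")

    @property
    def singlet_fraction(self) -> float:
        """P(one integration | infected) under Poisson(MOI)."""
        return self.moi * math.exp(-self.moi) / (1.0 - math.exp(-self.moi))


@dataclass
class SimTruth:
    """Planted ground truth: per-gene effects and per-sgRNA efficacies.

    ``genes`` columns: gene, effect_class, odds_multiplier, fitness.
    ``sgrnas`` columns: element_id, gene, kd_efficacy.
    NTC rows have odds_multiplier 1, fitness 1, kd_efficacy 0 by construction.
    """

    genes: pd.DataFrame
    sgrnas: pd.DataFrame

    def planted(self, effect_class: str) -> list[str]:
        g = self.genes
        return g.loc[g["effect_class"] == effect_class, "gene"].tolist()


@dataclass
class SimOutput:
    """Counts, sample sheet, truth, and a provenance echo of the config."""

    counts: pd.DataFrame          # elements × samples, manifest row order
    sample_sheet: SampleSheet
    truth: SimTruth
    manifest: LibraryManifest
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# synthetic manifests
# ---------------------------------------------------------------------------

def synthetic_manifest(
    n_genes: int,
    sgrnas_per_gene: int,
    n_ntc: int,
    seed: int = 0,
    length: int = 20,
    name: str = "synthetic",
    per_gene_counts: list[int] | None = None,
) -> LibraryManifest:
    """Build a synthetic library manifest with random unique protospacers.

    ``per_gene_counts`` overrides the uniform ``sgrnas_per_gene`` to emulate
    libraries with unequal guides per gene.
    """
    rng = np.random.default_rng(seed)
    if per_gene_counts is None:
        per_gene_counts = [sgrnas_per_gene] * n_genes
    if len(per_gene_counts) != n_genes:
        raise ValueError("per_gene_counts must have one entry per gene")
    n_total = sum(per_gene_counts) + n_ntc
    protos = _unique_protospacers(n_total, length, rng)
    elements: list[LibraryElement] = []
    k = 0
    for g in range(n_genes):
        gene = f"gene{g:05d}"
        for j in range(per_gene_counts[g]):
            elements.append(
                LibraryElement(f"{gene}_sg{j}", gene, protos[k], CATEGORY_TARGETING)
            )
            k += 1
    for j in range(n_ntc):
        elements.append(
            LibraryElement(f"NTC_sg{j}", NTC_GENE, protos[k], CATEGORY_NTC)
        )
        k += 1
    return LibraryManifest(elements, name=name)


def _unique_protospacers(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seen: set[bytes] = set()
    out: list[bytes] = []
    while len(out) < n:
        batch = _BASE_ARR[rng.integers(0, 4, size=(n, length))]
        for row in batch.view(f"S{length}").ravel():
            if row not in seen:
                seen.add(row)
                out.append(row)
                if len(out) == n:
                    break
    return [b.decode() for b in out]


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def make_truth(
    manifest: LibraryManifest,
    cfg: SimConfig,
    positive_genes: dict[str, float] | None = None,
    negative_genes: dict[str, float] | None = None,
    fitness: dict[str, float] | None = None,
    min_kd_planted: float | None = None,
) -> SimTruth:
    """Plant per-gene effects and draw per-sgRNA knockdown efficacies.

    ``positive_genes`` / ``negative_genes`` map gene → odds multiplier on the
    responder state (< 1 blunts the response: knocking the gene down
    *decreases* stimulus-induced calcium, the positive-regulator phenotype;
    > 1 is a negative regulator). ``fitness`` maps gene → growth multiplier
    per doubling. ``min_kd_planted`` optionally floors the efficacy of
    sgRNAs targeting planted genes (draws are rescaled into
    [min_kd_planted, 1]).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7271]))
    positive_genes = positive_genes or {}
    negative_genes = negative_genes or {}
    overlap = set(positive_genes) & set(negative_genes)
    if overlap:
        raise ValueError(f"genes planted in both directions: {sorted(overlap)}")
    fitness = fitness or {}
    genes = manifest.genes
    rows = []
    for g in genes:
        if g in positive_genes:
            rows.append((g, EFFECT_POSITIVE, float(positive_genes[g]), fitness.get(g, 1.0)))
        elif g in negative_genes:
            rows.append((g, EFFECT_NEGATIVE, float(negative_genes[g]), fitness.get(g, 1.0)))
        else:
            rows.append((g, EFFECT_NEUTRAL, 1.0, fitness.get(g, 1.0)))
    gene_df = pd.DataFrame(rows, columns=["gene", "effect_class", "odds_multiplier", "fitness"])

    planted = set(positive_genes) | set(negative_genes) | set(fitness)
    el_gene = np.array([e.gene for e in manifest.elements])
    kd = rng.beta(cfg.kd_beta_a, cfg.kd_beta_b, size=len(manifest))
    is_ntc = el_gene == NTC_GENE
    kd[is_ntc] = 0.0
    if min_kd_planted is not None:
        in_planted = np.isin(el_gene, list(planted))
        kd[in_planted] = min_kd_planted + kd[in_planted] * (1.0 - min_kd_planted)
    sg_df = pd.DataFrame(
        {"element_id": manifest.element_ids, "gene": el_gene, "kd_efficacy": kd}
    )
    return SimTruth(genes=gene_df, sgrnas=sg_df)


# ---------------------------------------------------------------------------
# core screen simulation
# ---------------------------------------------------------------------------

def _mixture_quantile(q_upper: float, w_resp: float, params_r, params_n) -> float:
    """Log-ratio threshold t with P(ratio ≥ t) = q_upper under the mixture."""
    mu_r, sd_r = params_r
    mu_n, sd_n = params_n

    def surv(t: float) -> float:
        return w_resp * stats.norm.sf(t, mu_r, sd_r) + (1 - w_resp) * stats.norm.sf(
            t, mu_n, sd_n
        )

    lo = min(mu_r, mu_n) - 8 * max(sd_r, sd_n)
    hi = max(mu_r, mu_n) + 8 * max(sd_r, sd_n)
    return optimize.brentq(lambda t: surv(t) - q_upper, lo, hi)


def _draw_counts(
    rng: np.random.Generator, weights: np.ndarray, reads: int, dispersion: float
) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("all-zero bin mass; cannot draw counts")
    if dispersion > 0:
        # gamma-mixed multinomial ≈ negative-binomial marginal noise
        shape = 1.0 / dispersion
        w = w * rng.gamma(shape, dispersion, size=w.shape)
    p = w / w.sum()
    return rng.multinomial(reads, p)


def simulate_screen(
    manifest: LibraryManifest,
    cfg: SimConfig,
    truth: SimTruth | None = None,
    screen_id: str = "sim",
) -> SimOutput:
    """Simulate one FACS screen plus its paired survival screen.

    For element *i* with gene odds multiplier *m* and knockdown efficacy
    *k*, the responder probability is
    ``p_i = sigmoid(logit(p0) + k·ln(m))`` — neutral genes and NTCs stay
    exactly at the wild-type responder fraction ``p0``. Each element's cell
    mass after growth is split binomially into responders/non-responders;
    red/green ratios follow the two log-normal components; the top and
    bottom ``gate_quantile`` of the *population* ratio distribution define
    the bins; reads are multinomial over each bin's element masses.
    """
    if truth is None:
        truth = make_truth(manifest, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5C12]))
    n_el = len(manifest)
    reads = cfg.reads_per_sample or 1000 * n_el
    if reads < n_el:
        import warnings

        warnings.warn(
            f"reads_per_sample={reads} below library size {n_el}: coverage < 1x",
            stacklevel=2,
        )

    el_gene = truth.sgrnas["gene"].to_numpy()
    kd = truth.sgrnas["kd_efficacy"].to_numpy()
    gene_idx = truth.genes.set_index("gene")
    mult = np.where(
        el_gene == NTC_GENE,
        1.0,
        gene_idx["odds_multiplier"].reindex(el_gene).fillna(1.0).to_numpy(),
    )
    fit = np.where(
        el_gene == NTC_GENE,
        1.0,
        gene_idx["fitness"].reindex(el_gene).fillna(1.0).to_numpy(),
    )

    p0 = cfg.base_responder_fraction
    if p0 in (0.0, 1.0):
        p_i = np.full(n_el, p0)
    else:
        logit0 = math.log(p0 / (1 - p0))
        with np.errstate(divide="ignore"):
            log_mult = np.where(mult > 0, np.log(np.maximum(mult, 1e-300)), -np.inf)
        z = logit0 + kd * log_mult
        p_i = 1.0 / (1.0 + np.exp(-z))
        p_i[np.isneginf(z)] = 0.0

    # fitness acts per doubling, attenuated by knockdown on the log scale
    growth = np.power(fit, kd * cfg.doublings)

    # infected single-integration cells per element at day 0
    lam0 = cfg.coverage * cfg.singlet_fraction
    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for rep in range(1, cfg.n_replicates + 1):
        n0 = rng.poisson(lam0, size=n_el)                      # day-0 cells
        m_grown = n0 * growth                                   # endpoint mass
        n_sort = rng.poisson(np.maximum(m_grown, 0.0))          # cells at sort
        resp = rng.binomial(n_sort, p_i)
        nonresp = n_sort - resp
        w_resp = resp.sum() / max(n_sort.sum(), 1)
        t_hi = _mixture_quantile(
            cfg.gate_quantile, w_resp, cfg.responder_logratio, cfg.nonresponder_logratio
        )
        t_lo = _mixture_quantile(
            1.0 - cfg.gate_quantile, w_resp, cfg.responder_logratio,
            cfg.nonresponder_logratio,
        )
        s_r_hi = stats.norm.sf(t_hi, *cfg.responder_logratio)
        s_n_hi = stats.norm.sf(t_hi, *cfg.nonresponder_logratio)
        f_r_lo = stats.norm.cdf(t_lo, *cfg.responder_logratio)
        f_n_lo = stats.norm.cdf(t_lo, *cfg.nonresponder_logratio)
        high_mass = resp * s_r_hi + nonresp * s_n_hi
        low_mass = resp * f_r_lo + nonresp * f_n_lo

        for role, mass in (
            ("high_bin", high_mass),
            ("low_bin", low_mass),
            ("day0", n0.astype(float)),
            ("endpoint", m_grown),
        ):
            arm = "facs" if role in ("high_bin", "low_bin") else "survival"
            sample = f"{screen_id}_{role}_r{rep}"
            columns[sample] = _draw_counts(rng, mass, reads, cfg.dispersion)
            sheet_rows.append(
                (sample, screen_id, arm, role, "stimulus", rep)
            )

    counts = pd.DataFrame(columns, index=pd.Index(manifest.element_ids, name="element_id"))
    sheet = SampleSheet(
        pd.DataFrame(
            sheet_rows,
            columns=["sample_id", "screen_id", "arm", "role", "stimulus", "replicate"],
        )
    )
    prov = {"config": asdict(cfg), "screen_id": screen_id, "mode": "aggregate"}
    return SimOutput(counts=counts, sample_sheet=sheet, truth=truth,
                     manifest=manifest, provenance=prov)


def simulate_screen_percell(
    manifest: LibraryManifest,
    cfg: SimConfig,
    truth: SimTruth | None = None,
    screen_id: str = "sim",
) -> SimOutput:
    """Exact per-cell FACS-arm simulation for small instances.

    Draws an explicit red/green log-ratio for every cell and gates at the
    empirical population quantiles — the brute-force cross-check for the
    aggregate mode's binomial-mass shortcut. Survival arm is omitted
    (sample sheet covers the facs arm only).
    """
    if truth is None:
        truth = make_truth(manifest, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5C12]))
    n_el = len(manifest)
    reads = cfg.reads_per_sample or 1000 * n_el
    kd = truth.sgrnas["kd_efficacy"].to_numpy()
    el_gene = truth.sgrnas["gene"].to_numpy()
    gene_idx = truth.genes.set_index("gene")
    mult = np.where(
        el_gene == NTC_GENE, 1.0,
        gene_idx["odds_multiplier"].reindex(el_gene).fillna(1.0).to_numpy(),
    )
    p0 = cfg.base_responder_fraction
    logit0 = math.log(p0 / (1 - p0)) if 0 < p0 < 1 else None
    if logit0 is None:
        p_i = np.full(n_el, p0)
    else:
        with np.errstate(divide="ignore"):
            z = logit0 + kd * np.where(mult > 0, np.log(np.maximum(mult, 1e-300)), -np.inf)
        p_i = np.where(np.isneginf(z), 0.0, 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700))))

    lam0 = cfg.coverage * cfg.singlet_fraction
    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    mu_r, sd_r = cfg.responder_logratio
    mu_n, sd_n = cfg.nonresponder_logratio
    for rep in range(1, cfg.n_replicates + 1):
        n_cells = rng.poisson(lam0, size=n_el)
        owner = np.repeat(np.arange(n_el), n_cells)
        is_resp = rng.random(owner.size) < p_i[owner]
        ratio = np.where(
            is_resp,
            rng.normal(mu_r, sd_r, size=owner.size),
            rng.normal(mu_n, sd_n, size=owner.size),
        )
        k = int(math.floor(cfg.gate_quantile * owner.size))
        order = np.argsort(ratio, kind="stable")
        low_members = owner[order[:k]]
        high_members = owner[order[owner.size - k:]]
        high_mass = np.bincount(high_members, minlength=n_el).astype(float)
        low_mass = np.bincount(low_members, minlength=n_el).astype(float)
        for role, mass in (("high_bin", high_mass), ("low_bin", low_mass)):
            sample = f"{screen_id}_{role}_r{rep}"
            columns[sample] = _draw_counts(rng, mass, reads, cfg.dispersion)
            sheet_rows.append((sample, screen_id, "facs", role, "stimulus", rep))

    counts = pd.DataFrame(columns, index=pd.Index(manifest.element_ids, name="element_id"))
    sheet = SampleSheet(
        pd.DataFrame(
            sheet_rows,
            columns=["sample_id", "screen_id", "arm", "role", "stimulus", "replicate"],
        )
    )
    prov = {"config": asdict(cfg), "screen_id": screen_id, "mode": "per_cell"}
    return SimOutput(counts=counts, sample_sheet=sheet, truth=truth,
                     manifest=manifest, provenance=prov)


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

def write_fastq(
    counts: pd.Series,
    manifest: LibraryManifest,
    path: str,
    read_length: int = 50,
    offset: int = 10,
    error_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write reads embedding each element's protospacer at ``offset`` in a
    fixed-length read, one read per count; returns reads written.

    Flanks are random sequence; ``error_rate`` applies independent
    substitutions across the whole read.
    """
    L = manifest.protospacer_length
    if offset + L > read_length:
        raise ValueError("offset + protospacer length exceeds read length")
    rng = np.random.default_rng(seed)
    protos = [e.protospacer for e in manifest.elements]
    counts = counts.reindex(manifest.element_ids).fillna(0).astype(int)
    n_reads = int(counts.sum())
    owners = np.repeat(np.arange(len(manifest)), counts.to_numpy())
    rng.shuffle(owners)
    qual = "I" * read_length
    written = 0
    with open(path, "w") as fh:
        flanks = _BASE_ARR[rng.integers(0, 4, size=(n_reads, read_length))]
        for ridx, oi in enumerate(owners):
            read = flanks[ridx].copy()
            read[offset : offset + L] = np.frombuffer(
                protos[oi].encode(), dtype="S1"
            )
            if error_rate > 0:
                errs = np.nonzero(rng.random(read_length) < error_rate)[0]
                if errs.size:
                    read[errs] = _BASE_ARR[rng.integers(0, 4, size=errs.size)]
            seq = read.tobytes().decode()
            fh.write(f"@read{written} element={manifest.element_ids[oi]}\n{seq}\n+\n{qual}\n")
            written += 1
    return written


# ---------------------------------------------------------------------------
# secondary-assay fixtures
# ---------------------------------------------------------------------------

def simulate_flow_events(
    n_cells: int,
    responder_fraction: float,
    ratio_params: tuple[tuple[float, float], tuple[float, float]] = (
        (1.0, 0.6),
        (-1.0, 0.6),
    ),
    seed: int = 0,
    sample_id: str = "s1",
    condition: str = "stimulus",
    green_mean: float = 1000.0,
) -> pd.DataFrame:
    """Per-cell flow events: green intensity and red = ratio × green, with
    the red/green ratio drawn from responder / non-responder log-normal
    components. The hidden component label is kept in ``is_responder``."""
    if n_cells < 1:
        raise ValueError("n_cells must be ≥ 1")
    rng = np.random.default_rng(seed)
    (mu_r, sd_r), (mu_n, sd_n) = ratio_params
    is_resp = rng.random(n_cells) < responder_fraction
    log_ratio = np.where(
        is_resp, rng.normal(mu_r, sd_r, n_cells), rng.normal(mu_n, sd_n, n_cells)
    )
    green = green_mean * rng.lognormal(0.0, 0.25, n_cells)
    red = np.exp(log_ratio) * green
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "condition": condition,
            "green": green,
            "red": red,
            "is_responder": is_resp,
        }
    )


@dataclass
class ImagingTraceSet:
    """Per-cell fluorescence time series with acquisition metadata."""

    frame: pd.DataFrame            # columns: cell_id, frame, F
    stim_frame: int
    baseline_window: tuple[int, int]
    truth_peaks: pd.Series | None = None


def simulate_traces(
    n_cells: int,
    peak_dff: float,
    onset_frame: int = 20,
    decay_tau: float = 30.0,
    noise_sd: float = 0.05,
    n_frames: int = 120,
    f0: float = 100.0,
    seed: int = 0,
) -> ImagingTraceSet:
    """Step-then-exponential-decay calcium transients plus white noise.

    ``noise_sd`` is in ΔF/F0 units; SNR = peak_dff / noise_sd.
    """
    if decay_tau <= 0:
        raise ValueError("decay_tau must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    dff = np.zeros(n_frames)
    post = t >= onset_frame
    dff[post] = peak_dff * np.exp(-(t[post] - onset_frame) / decay_tau)
    F = f0 * (1.0 + dff)[None, :] + f0 * noise_sd * rng.standard_normal((n_cells, n_frames))
    df = pd.DataFrame(
        {
            "cell_id": np.repeat([f"cell{i}" for i in range(n_cells)], n_frames),
            "frame": np.tile(t, n_cells),
            "F": F.ravel(),
        }
    )
    peaks = pd.Series(peak_dff, index=[f"cell{i}" for i in range(n_cells)], name="peak_dff")
    return ImagingTraceSet(
        frame=df,
        stim_frame=onset_frame,
        baseline_window=(0, onset_frame),
        truth_peaks=peaks,
    )


def simulate_dose_response(
    doses: np.ndarray,
    bottom: float = 1.0,
    top: float = 7.0,
    ec50: float = 0.35,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Responses from a four-parameter logistic plus Gaussian noise."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0) or ec50 <= 0:
        raise ValueError("doses and ec50 must be > 0")
    rng = np.random.default_rng(seed)
    d = np.repeat(doses, n_reps)
    r = four_pl(d, bottom, top, ec50, hill)
    r = r + noise_sd * rng.standard_normal(d.size)
    return pd.DataFrame({"dose": d, "response": r})


def four_pl(x: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    """4PL: bottom + (top − bottom) / (1 + (ec50/x)^hill)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def simulate_ct_table(
    fold_change: float,
    target: str = "Cs",
    reference: str = "Gapdh",
    control_condition: str = "NTC",
    test_condition: str = "KD",
    base_ct_target: float = 22.0,
    base_ct_ref: float = 16.0,
    noise_sd: float = 0.0,
    n_triplicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-simulate qPCR Ct values for a known expression fold change.

    A fold change *f* in the test condition shifts the target Ct by
    −log2(f) cycles relative to control (reference gene unchanged), so the
    ΔΔCt inversion should recover exactly *f* in the noiseless limit.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond, shift in ((control_condition, 0.0), (test_condition, -math.log2(fold_change))):
        for i in range(n_triplicates):
            rows.append((f"{cond}_{i}", cond, target,
                         base_ct_target + shift + noise_sd * rng.standard_normal()))
            rows.append((f"{cond}_{i}", cond, reference,
                         base_ct_ref + noise_sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct"])
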