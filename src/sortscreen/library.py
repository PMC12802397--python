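"""sgRNA library manifests and screen sample sheets.

A pooled CRISPRi screen is defined by a *library manifest* — the ordered
list of sgRNA elements, each a unique protospacer assigned to a target gene
or to the non-targeting control (NTC) pseudo-gene — and a *sample sheet*
pairing the sequenced samples of each screen (sorted high/low fluorescence
bins for a FACS arm, day-0/endpoint for a survival arm).

Manifests are headered TSV with columns ``element_id, gene, protospacer,
category``; sample sheets are headered CSV. The reserved gene token for
non-targeting controls is the literal string ``NTC``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

NTC_GENE = "NTC"
CATEGORY_TARGETING = "targeting"
CATEGORY_NTC = "non_targeting"

MANIFEST_COLUMNS = ["element_id", "gene", "protospacer", "category"]
SHEET_COLUMNS = ["sample_id", "screen_id", "arm", "role", "stimulus", "replicate"]

_VALID_ARMS = {"facs", "survival"}
_ROLES_BY_ARM = {"facs": {"high_bin", "low_bin"}, "survival": {"day0", "endpoint"}}
_ALLOWED_LENGTHS = (19, 20)
_BASES = set("ACGT")


class LibraryValidationError(ValueError):
    """Raised when a manifest or sample sheet violates a library invariant."""


@dataclass(frozen=True)
class LibraryElement:
    """One sgRNA in the library: a protospacer tied to a gene (or NTC)."""

    element_id: str
    gene: str
    protospacer: str
    category: str


@dataclass
class LibraryManifest:
    """Ordered, validated collection of library elements."""

    elements: list[LibraryElement]
    name: str = "library"

    def __post_init__(self) -> None:
        _validate_elements(self.elements, self.name)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def element_ids(self) -> list[str]:
        return [e.element_id for e in self.elements]

    @property
    def genes(self) -> list[str]:
        """Targeted genes (NTC excluded), in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.elements:
            if e.gene != NTC_GENE:
                seen.setdefault(e.gene, None)
        return list(seen)

    @property
    def per_gene_count(self) -> dict[str, int]:
        return dict(Counter(e.gene for e in self.elements if e.gene != NTC_GENE))

    @property
    def protospacer_length(self) -> int:
        return len(self.elements[0].protospacer)

    def gene_of(self) -> pd.Series:
        """element_id -> gene mapping as a Series (manifest order)."""
        return pd.Series(
            [e.gene for e in self.elements], index=self.element_ids, name="gene"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.element_id, e.gene, e.protospacer, e.category) for e in self.elements],
            columns=MANIFEST_COLUMNS,
        )


def _validate_elements(elements: list[LibraryElement], name: str) -> None:
    if not elements:
        raise LibraryValidationError(f"manifest {name!r} is empty")
    seen_ids: dict[str, int] = {}
    seen_protos: dict[str, int] = {}
    length = len(elements[0].protospacer)
    if length not in _ALLOWED_LENGTHS:
        raise LibraryValidationError(
            f"protospacer length {length} not in {_ALLOWED_LENGTHS} (row 0)"
        )
    for i, e in enumerate(elements):
        if e.element_id in seen_ids:
            raise LibraryValidationError(
                f"duplicate element_id {e.element_id!r} at rows "
                f"{seen_ids[e.element_id]} and {i}"
            )
        seen_ids[e.element_id] = i
        if e.protospacer in seen_protos:
            raise LibraryValidationError(
                f"duplicate protospacer {e.protospacer!r} at rows "
                f"{seen_protos[e.protospacer]} and {i} "
                f"({elements[seen_protos[e.protospacer]].element_id!r}, {e.element_id!r})"
            )
        seen_protos[e.protospacer] = i
        if len(e.protospacer) != length:
            raise LibraryValidationError(
                f"mixed protospacer lengths: row {i} ({e.element_id!r}) has "
                f"{len(e.protospacer)} nt, expected {length}"
            )
        if not _BASES.issuperset(e.protospacer):
            raise LibraryValidationError(
                f"protospacer of {e.element_id!r} (row {i}) has bases outside ACGT"
            )
        is_ntc = e.gene == NTC_GENE
        if is_ntc != (e.category == CATEGORY_NTC):
            raise LibraryValidationError(
                f"row {i} ({e.element_id!r}): category {e.category!r} inconsistent "
                f"with gene {e.gene!r} (category must be {CATEGORY_NTC!r} iff gene is "
                f"{NTC_GENE!r})"
            )
        if e.category not in (CATEGORY_TARGETING, CATEGORY_NTC):
            raise LibraryValidationError(
                f"row {i}: unknown category {e.category!r}"
            )


def load_manifest(path: str, name: str | None = None) -> LibraryManifest:
    """Read a headered TSV manifest, enforcing all library invariants.

    Row order is preserved. Duplicate element IDs or protospacers, mixed
    protospacer lengths, and gene/category inconsistencies raise
    :class:`LibraryValidationError` naming the offending rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryValidationError(f"manifest {path} missing columns {missing}")
    elements = [
        LibraryElement(r.element_id, r.gene, r.protospacer, r.category)
        for r in df.itertuples(index=False)
    ]
    return LibraryManifest(elements, name=name or str(path))


def write_manifest(manifest: LibraryManifest, path: str) -> None:
    """Write a manifest as UTF-8 tab-delimited TSV with LF line endings."""
    manifest.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class CompositionSummary:
    """Library composition: totals, NTC fraction, per-gene element counts."""

    n_total: int
    n_targeting: int
    n_ntc: int
    n_genes: int
    ntc_fraction: float
    per_gene_histogram: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_total", self.n_total),
            ("n_targeting", self.n_targeting),
            ("n_ntc", self.n_ntc),
            ("n_genes", self.n_genes),
            ("ntc_fraction", self.ntc_fraction),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def composition_summary(manifest: LibraryManifest) -> CompositionSummary:
    """Summarise a manifest: element totals, gene count, NTC fraction, and a
    histogram of elements-per-gene (e.g. ``{5: 3744}`` for a uniform
    top-5-guides design)."""
    n_total = len(manifest)
    n_ntc = sum(1 for e in manifest.elements if e.gene == NTC_GENE)
    n_targeting = n_total - n_ntc
    counts = manifest.per_gene_count
    hist = dict(sorted(Counter(counts.values()).items()))
    return CompositionSummary(
        n_total=n_total,
        n_targeting=n_targeting,
        n_ntc=n_ntc,
        n_genes=len(counts),
        ntc_fraction=n_ntc / n_total,
        per_gene_histogram=hist,
    )


@dataclass
class SampleSheet:
    """Validated sample sheet: one row per sequenced sample.

    Columns: sample_id, screen_id, arm (facs|survival), role
    (high_bin|low_bin|day0|endpoint), stimulus, replicate, and optionally
    fastq_path / counts_path.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise LibraryValidationError(f"sample sheet missing columns {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise LibraryValidationError(f"duplicate sample_id(s): {dups}")
        for (screen, arm), grp in df.groupby(["screen_id", "arm"]):
            if arm not in _VALID_ARMS:
                raise LibraryValidationError(
                    f"screen {screen!r}: unknown arm {arm!r}"
                )
            roles = set(grp["role"])
            bad = roles - _ROLES_BY_ARM[arm]
            if bad:
                raise LibraryValidationError(
                    f"screen {screen!r} ({arm} arm): invalid role(s) {sorted(bad)}"
                )
            needed = _ROLES_BY_ARM[arm] - roles
            if needed:
                raise LibraryValidationError(
                    f"screen {screen!r} ({arm} arm) is missing role(s) "
                    f"{sorted(needed)}"
                )

    def samples_for(self, screen_id: str, role: str) -> pd.DataFrame:
        df = self.frame
        return df[(df["screen_id"] == screen_id) & (df["role"] == role)]

    def screens(self) -> list[tuple[str, str]]:
        """Distinct (screen_id, arm) pairs in sheet order."""
        return list(
            self.frame[["screen_id", "arm"]].drop_duplicates().itertuples(
                index=False, name=None
            )
        )


def load_sample_sheet(path: str, manifest: LibraryManifest | None = None) -> SampleSheet:
    """Read a headered CSV sample sheet and validate arm/role structure.

    The manifest argument is accepted for interface symmetry (future
    per-sample count files can be cross-checked against it); validation of
    the sheet itself does not need it.
    """
    df = pd.read_csv(path, dtype={"replicate": int, "sample_id": str})
    return SampleSheet(df)
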