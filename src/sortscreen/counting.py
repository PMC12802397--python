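"""Protospacer counting: FASTQ reads → element × sample count matrix.

Reads are matched on the forward strand at a fixed offset (auto-detected by
default from the first 1,000 reads). Two policies:

* ``exact`` — the substring at the offset must equal a library protospacer;
* ``one_mismatch`` — unique best match at Hamming distance ≤ 1; a read whose
  minimal-distance match is not unique is discarded as unmapped.

Quality scores are ignored. Conservation holds per sample:
mapped + unmapped = total reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .library import LibraryManifest

POLICIES = ("exact", "one_mismatch")
_AMBIGUOUS = -2


@dataclass
class CountMatrix:
    """Element × sample integer counts with per-sample unmapped totals."""

    counts: pd.DataFrame              # index element_id (manifest order)
    unmapped: pd.Series               # per sample
    manifest_name: str
    policy: str = "exact"
    meta: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.unmapped


class _Matcher:
    """Hash-based protospacer matcher for exact and 1-mismatch lookup."""

    def __init__(self, manifest: LibraryManifest):
        self.length = manifest.protospacer_length
        self.exact: dict[str, int] = {
            e.protospacer: i for i, e in enumerate(manifest.elements)
        }
        # neighbor index: every sequence at Hamming distance exactly 1 from a
        # protospacer → owning element, or _AMBIGUOUS on collision
        self.neighbors: dict[str, int] = {}
        for proto, idx in self.exact.items():
            b = bytearray(proto, "ascii")
            for pos in range(self.length):
                orig = b[pos]
                for alt in b"ACGT":
                    if alt == orig:
                        continue
                    b[pos] = alt
                    key = bytes(b).decode()
                    if key in self.exact:
                        pass  # distance-0 match always wins; no entry needed
                    elif key in self.neighbors and self.neighbors[key] != idx:
                        self.neighbors[key] = _AMBIGUOUS
                    else:
                        self.neighbors[key] = idx
                b[pos] = orig

    def match(self, seq: str, policy: str) -> int:
        """Element index, or -1 unmapped (including ambiguous)."""
        hit = self.exact.get(seq)
        if hit is not None:
            return hit
        if policy == "one_mismatch":
            hit = self.neighbors.get(seq, -1)
            return -1 if hit == _AMBIGUOUS else hit
        return -1


def detect_offset(
    fastq: str, manifest: LibraryManifest, n_scan: int = 1000
) -> int:
    """Offset maximizing exact protospacer matches over the first reads."""
    matcher = _Matcher(manifest)
    L = matcher.length
    seqs = []
    with pysam.FastxFile(fastq) as fh:
        for rec in fh:
            seqs.append(rec.sequence)
            if len(seqs) >= n_scan:
                break
    if not seqs:
        raise ValueError(f"{fastq}: no reads to scan for offset")
    max_off = max(len(s) for s in seqs) - L
    if max_off < 0:
        raise ValueError(f"{fastq}: reads shorter than protospacer length {L}")
    best, best_hits = 0, -1
    for off in range(max_off + 1):
        hits = sum(1 for s in seqs if s[off : off + L] in matcher.exact)
        if hits > best_hits:
            best, best_hits = off, hits
    return best


def count_sample(
    fastq: str,
    manifest: LibraryManifest,
    sample_id: str,
    offset: int | None = None,
    policy: str = "exact",
) -> CountMatrix:
    """Count one FASTQ into a single-sample CountMatrix column."""
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    if offset is None:
        offset = detect_offset(fastq, manifest)
    matcher = _Matcher(manifest)
    L = matcher.length
    counts = np.zeros(len(manifest), dtype=np.int64)
    unmapped = 0
    n_reads = 0
    with pysam.FastxFile(fastq) as fh:
        for rec in fh:
            n_reads += 1
            seq = rec.sequence
            if seq is None or offset + L > len(seq):
                raise ValueError(
                    f"{fastq}: unreadable/short record at read index {n_reads - 1}"
                )
            idx = matcher.match(seq[offset : offset + L], policy)
            if idx < 0:
                unmapped += 1
            else:
                counts[idx] += 1
    if n_reads == 0:
        import warnings

        warnings.warn(f"{fastq}: no reads; emitting empty column", stacklevel=2)
    df = pd.DataFrame(
        {sample_id: counts}, index=pd.Index(manifest.element_ids, name="element_id")
    )
    return CountMatrix(
        counts=df,
        unmapped=pd.Series({sample_id: unmapped}),
        manifest_name=manifest.name,
        policy=policy,
        meta={"offset": offset},
    )


def merge_columns(*columns: CountMatrix) -> CountMatrix:
    """Merge single-sample columns counted against the same manifest."""
    if not columns:
        raise ValueError("no columns to merge")
    names = {c.manifest_name for c in columns}
    if len(names) > 1:
        raise ValueError(f"columns counted against different manifests: {sorted(names)}")
    policies = {c.policy for c in columns}
    counts = pd.concat([c.counts for c in columns], axis=1)
    if counts.isna().any().any():
        raise ValueError("column row keys disagree despite shared manifest")
    unmapped = pd.concat([c.unmapped for c in columns])
    return CountMatrix(
        counts=counts.astype(np.int64),
        unmapped=unmapped,
        manifest_name=names.pop(),
        policy=policies.pop() if len(policies) == 1 else "mixed",
    )


def brute_force_count(
    fastq: str,
    manifest: LibraryManifest,
    sample_id: str,
    offset: int,
    policy: str = "exact",
) -> CountMatrix:
    """Exhaustive all-pairs Hamming-distance oracle for the fast matcher.

    Computes the distance from every read substring to every protospacer
    with a vectorized scan; same assignment rule (unique minimal distance
    within the policy radius) but no hashing shortcuts. Intended for small
    instances (≤ ~10^4 reads).
    """
    L = manifest.protospacer_length
    protos = np.frombuffer(
        "".join(e.protospacer for e in manifest.elements).encode(), dtype="S1"
    ).reshape(len(manifest), L)
    radius = 0 if policy == "exact" else 1
    counts = np.zeros(len(manifest), dtype=np.int64)
    unmapped = 0
    with pysam.FastxFile(fastq) as fh:
        for rec in fh:
            sub = np.frombuffer(rec.sequence[offset : offset + L].encode(), dtype="S1")
            dists = (protos != sub[None, :]).sum(axis=1)
            dmin = dists.min()
            if dmin > radius or (dists == dmin).sum() > 1:
                unmapped += 1
            else:
                counts[int(np.argmin(dists))] += 1
    df = pd.DataFrame(
        {sample_id: counts}, index=pd.Index(manifest.element_ids, name="element_id")
    )
    return CountMatrix(
        counts=df,
        unmapped=pd.Series({sample_id: unmapped}),
        manifest_name=manifest.name,
        policy=policy,
    )


def write_counts(cm: CountMatrix, path: str) -> None:
    cm.counts.to_csv(path, sep="\t", lineterminator="\n")


def load_counts(path: str, manifest: LibraryManifest | None = None) -> pd.DataFrame:
    """Read a counts TSV (first column element_id); zero-fill and reorder to
    the manifest's element set when a manifest is given."""
    df = pd.read_csv(path, sep="\t", index_col="element_id")
    if manifest is not None:
        extra = df.index.difference(manifest.element_ids)
        if len(extra):
            raise ValueError(f"counts contain elements not in manifest: {list(extra[:5])}")
        df = df.reindex(manifest.element_ids).fillna(0)
    return df.astype(np.int64)
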