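"""FASTQ read counting and count-table / manifest I/O.

Reads are assigned to library variants by exact matching: both anchor
sequences (by default the 5' and 3' homology arms) are located in the
read, the intervening nucleotide string is extracted and looked up
against the library's design index.  Where two categories share a
nucleotide design (possible because deduplication is per category, e.g.
a scrambled window coinciding with a double substitution), the subpool
barcode immediately upstream of the 5' anchor disambiguates.  Reads
matching nothing are tallied as unassigned; there is no mismatch
tolerance and no alignment.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from loopdms.library import VariantLibrary

CONDITIONS = ("unsorted", "gfp_neg", "gfp_pos")


class ManifestError(ValueError):
    pass


class CountTableError(ValueError):
    pass


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    condition: str
    replicate: int
    fastq_path: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ManifestError(
                f"{self.sample_id}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if self.replicate < 1:
            raise ManifestError(f"{self.sample_id}: replicate must be >= 1")


@dataclass
class SampleManifest:
    """Sample sheet: one row per sequenced population."""

    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ManifestError("sample_ids must be unique")
        pairs = [(e.condition, e.replicate) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ManifestError("every (condition, replicate) pair must be unique")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def replicates(self) -> list[int]:
        return sorted({e.replicate for e in self.entries})

    def sample(self, condition: str, replicate: int) -> SampleEntry | None:
        for e in self.entries:
            if e.condition == condition and e.replicate == replicate:
                return e
        return None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tcondition\treplicate\tfastq_path\n")
            for e in self.entries:
                fh.write(f"{e.sample_id}\t{e.condition}\t{e.replicate}\t{e.fastq_path}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleManifest":
        df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
        required = {"sample_id", "condition", "replicate", "fastq_path"}
        missing = required - set(df.columns)
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        return cls(
            entries=[
                SampleEntry(r.sample_id, r.condition, int(r.replicate), str(r.fastq_path))
                for r in df.itertuples()
            ]
        )


@dataclass
class CountTable:
    """Per-sample, per-variant raw read counts.

    ``counts`` is samples x variants (rows indexed by sample_id);
    ``samples`` carries (condition, replicate) metadata; ``unassigned``
    is the per-sample number of reads matching no library variant.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame  # index sample_id; columns condition, replicate
    unassigned: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.unassigned is None:
            self.unassigned = pd.Series(0, index=self.counts.index, dtype=int)
        if (self.counts.values < 0).any():
            raise CountTableError("negative counts")
        if list(self.samples.index) != list(self.counts.index):
            raise CountTableError("samples metadata does not match count rows")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def assigned_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total_reads(self) -> pd.Series:
        return self.assigned_totals() + self.unassigned

    def to_tsv(self, path: str | Path) -> None:
        df = self.samples.copy()
        df.insert(2, "unassigned", self.unassigned)
        df = pd.concat([df, self.counts], axis=1)
        df.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        for col in ("condition", "replicate", "unassigned"):
            if col not in df.columns:
                raise CountTableError(f"counts file missing column {col!r}")
        samples = df[["condition", "replicate"]].copy()
        samples["replicate"] = samples["replicate"].astype(int)
        unassigned = df["unassigned"].astype(int)
        counts = df.drop(columns=["condition", "replicate", "unassigned"])
        bad = counts.apply(lambda c: ~c.astype(str).str.fullmatch(r"\d+"))
        if bad.values.any():
            rows = np.nonzero(bad.values.any(axis=1))[0]
            raise CountTableError(
                f"non-integer or negative count at data line {rows[0] + 2} of {path}"
            )
        return cls(counts=counts.astype(int), samples=samples, unassigned=unassigned)


def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _build_region_index(
    library: VariantLibrary, anchor5: str, anchor3: str
) -> dict[str, list]:
    """Map nt_design -> variants, validating anchor uniqueness per oligo."""
    index: dict[str, list] = {}
    for v in library:
        oligo = library.oligo(v)
        if oligo.count(anchor5) != 1 or oligo.count(anchor3) != 1:
            raise CountTableError(
                f"anchor ambiguous or absent in oligo of {v.variant_id}: "
                "anchors must occur exactly once in every library oligo"
            )
        i5 = oligo.find(anchor5) + len(anchor5)
        i3 = oligo.find(anchor3)
        if i3 < i5:
            raise CountTableError(
                f"anchors out of order in oligo of {v.variant_id}"
            )
        region = oligo[i5:i3]
        index.setdefault(region, []).append(v)
    return index


def count_reads(
    manifest: SampleManifest,
    library: VariantLibrary,
    match_window: tuple[str, str] | None = None,
    scan_reverse_complement: bool = False,
) -> CountTable:
    """Count exact-matching amplicon reads per sample and variant.

    Each read contributes to at most one variant: both anchors are
    located, the intervening string is looked up in the design index,
    and ambiguity between subpools is resolved by the forward barcode
    preceding the 5' anchor.  Anything else is unassigned.
    """
    w = library.window
    anchor5, anchor3 = match_window or (w.flank5, w.flank3)
    index = _build_region_index(library, anchor5, anchor3)
    fwd_barcodes = {v.variant_id: library.subpool_barcodes[v.subpool][0] for v in library}

    variant_ids = [v.variant_id for v in library]
    col_of = {vid: j for j, vid in enumerate(variant_ids)}
    counts = np.zeros((len(manifest), len(variant_ids)), dtype=np.int64)
    unassigned = np.zeros(len(manifest), dtype=np.int64)

    for row, entry in enumerate(manifest):
        n_reads = 0
        with _open_maybe_gzip(entry.fastq_path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                n_reads += 1
                seq = str(rec.seq)
                hit = _assign(seq, anchor5, anchor3, index, fwd_barcodes)
                if hit is None and scan_reverse_complement:
                    hit = _assign(
                        _reverse_complement(seq), anchor5, anchor3, index, fwd_barcodes
                    )
                if hit is None:
                    unassigned[row] += 1
                else:
                    counts[row, col_of[hit]] += 1
        if n_reads == 0:
            warnings.warn(f"empty FASTQ for sample {entry.sample_id}", stacklevel=2)

    samples = pd.DataFrame(
        {
            "condition": [e.condition for e in manifest],
            "replicate": [e.replicate for e in manifest],
        },
        index=pd.Index([e.sample_id for e in manifest], name="sample_id"),
    )
    return CountTable(
        counts=pd.DataFrame(
            counts, index=samples.index, columns=variant_ids
        ),
        samples=samples,
        unassigned=pd.Series(unassigned, index=samples.index),
    )


def _assign(seq, anchor5, anchor3, index, fwd_barcodes):
    i5 = seq.find(anchor5)
    if i5 < 0:
        return None
    start = i5 + len(anchor5)
    i3 = seq.find(anchor3, start)
    if i3 < 0:
        return None
    region = seq[start:i3]
    candidates = index.get(region)
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0].variant_id
    prefix = seq[:i5]
    matched = [v for v in candidates if prefix.endswith(fwd_barcodes[v.variant_id])]
    if len(matched) == 1:
        return matched[0].variant_id
    return None
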