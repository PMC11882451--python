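"""Sort-seq enrichment scoring.

Counts are converted to reads per million (over assigned reads only),
a pseudocount of 1 is added, and values are log2-transformed.  A
variant's enrichment in a sorted population is its log2 value in that
sample minus the log2 value in the matched unsorted sample of the same
replicate; per-replicate enrichments are then averaged, and finally
normalized to the wild-type reference (whose normalized value is 0 by
construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from loopdms.library import VariantLibrary
from loopdms.seqio import CountTable, SampleManifest

SORTED_CONDITIONS = ("gfp_neg", "gfp_pos")


class EnrichmentError(ValueError):
    pass


def normalize_log2_rpm(counts: CountTable) -> pd.DataFrame:
    """log2(count / assigned_total * 1e6 + 1), per sample (rows) and variant.

    The RPM denominator is the sample's *assigned* read total: the
    library defines the universe being quantified, so unassigned reads
    do not dilute it.
    """
    totals = counts.assigned_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise EnrichmentError(
            f"sample(s) with zero assigned reads: {', '.join(zero.index)}"
        )
    rpm = counts.counts.div(totals, axis=0) * 1e6
    return np.log2(rpm + 1.0)


@dataclass
class EnrichmentTable:
    """Per-variant enrichment scores.

    ``data`` is indexed by variant_id with columns:

    * ``category``
    * ``log2_rpm_<sample_id>`` for every sample,
    * ``enrichment_<cond>_r<rep>`` per sorted condition and replicate,
    * ``enrichment_<cond>_mean`` replicate means,
    * ``enrichment_<cond>_wtnorm`` wild-type-normalized means.
    """

    data: pd.DataFrame
    wt_reference: str

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, condition: str, replicate: int | None = None, wtnorm: bool = False) -> pd.Series:
        if wtnorm:
            return self.data[f"enrichment_{condition}_wtnorm"]
        if replicate is None:
            return self.data[f"enrichment_{condition}_mean"]
        return self.data[f"enrichment_{condition}_r{replicate}"]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="variant_id")

    @classmethod
    def from_tsv(cls, path, wt_reference: str = "wild_type") -> "EnrichmentTable":
        return cls(pd.read_csv(path, sep="\t", index_col="variant_id"), wt_reference)


def compute_enrichment(
    norm: pd.DataFrame,
    manifest: SampleManifest,
    wt_reference: str = "wild_type",
    library: VariantLibrary | None = None,
) -> EnrichmentTable:
    """Per-replicate sorted-minus-unsorted enrichment, averaged, WT-normalized.

    Every sorted sample must have an unsorted sample of the same
    replicate; ``wt_reference`` must be a variant in the table.
    """
    if wt_reference not in norm.columns:
        raise EnrichmentError(f"wild-type reference {wt_reference!r} not in table")
    data = pd.DataFrame(index=pd.Index(norm.columns, name="variant_id"))
    if library is not None:
        cat = {v.variant_id: v.category for v in library}
        data["category"] = [cat.get(vid, "unknown") for vid in data.index]
    for entry in manifest:
        data[f"log2_rpm_{entry.sample_id}"] = norm.loc[entry.sample_id].values

    for cond in SORTED_CONDITIONS:
        rep_cols = []
        for entry in manifest:
            if entry.condition != cond:
                continue
            unsorted = manifest.sample("unsorted", entry.replicate)
            if unsorted is None:
                raise EnrichmentError(
                    f"no unsorted sample matches replicate {entry.replicate} "
                    f"of sorted sample {entry.sample_id}"
                )
            col = f"enrichment_{cond}_r{entry.replicate}"
            data[col] = (norm.loc[entry.sample_id] - norm.loc[unsorted.sample_id]).values
            rep_cols.append(col)
        if rep_cols:
            data[f"enrichment_{cond}_mean"] = data[rep_cols].mean(axis=1)
            wt_mean = data.loc[wt_reference, f"enrichment_{cond}_mean"]
            data[f"enrichment_{cond}_wtnorm"] = data[f"enrichment_{cond}_mean"] - wt_mean
    return EnrichmentTable(data=data, wt_reference=wt_reference)


def summarize_categories(
    enr: EnrichmentTable,
    condition: str = "gfp_neg",
    categories: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category statistics and the ranked waterfall ordering.

    Returns ``(summary, waterfall)``: summary has one row per category
    with n / mean / sd of the WT-normalized enrichment (empty categories
    keep n=0 with NaN mean rather than being dropped); waterfall is the
    full table sorted by descending WT-normalized enrichment with a
    1-based ``rank`` column.
    """
    if enr.data.empty:
        raise EnrichmentError("empty enrichment table")
    col = f"enrichment_{condition}_wtnorm"
    if col not in enr.data.columns:
        raise EnrichmentError(f"no enrichment column for condition {condition!r}")
    if "category" not in enr.data.columns:
        raise EnrichmentError("enrichment table lacks category annotations")
    grouped = enr.data.groupby("category", dropna=False)[col]
    summary = grouped.agg(n="size", mean="mean", sd=lambda s: s.std(ddof=0))
    if categories is not None:
        # expected-but-empty categories are reported with n=0, not dropped
        summary = summary.reindex(categories)
        summary["n"] = summary["n"].fillna(0).astype(int)
    summary.index.name = "category"
    summary = summary.reset_index()

    waterfall = enr.data[["category", col]].copy()
    waterfall = waterfall.sort_values(col, ascending=False, kind="mergesort")
    waterfall["rank"] = np.arange(1, len(waterfall) + 1)
    return summary, waterfall
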