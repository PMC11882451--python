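"""Motif analytics: position probability matrices, KL information-content
logos, heatmap matrices and the single-vs-double adjacency correlation.

Each mutational category has a common mutant-window length (7 for
substitutions, 8 for single insertions, 9 for double insertions on a
7-residue window), so positions align without gaps and the category's
read-weighted variant sequences define a position probability matrix
(PPM).  Per-letter information content against a background PPM is the
Kullback-Leibler term IC = P * log2(P / B); per-position sums are the
relative-entropy logo heights.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from loopdms.enrichment import EnrichmentTable
from loopdms.library import AMINO_ACIDS, Variant, VariantLibrary
from loopdms.seqio import CountTable

logger = logging.getLogger(__name__)

PPM_CATEGORIES = (
    "single_substitution",
    "double_substitution",
    "single_insertion",
    "double_insertion",
)
POPULATIONS = ("gfp_neg", "gfp_pos", "unsorted")

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_INS_RE = re.compile(r"^ins(\d+)([A-Z]+)$")


class MotifError(ValueError):
    pass


class InsufficientDataError(MotifError):
    pass


def _parse_sub(edit: str) -> tuple[int, str]:
    m = _SUB_RE.match(edit)
    if not m:
        raise MotifError(f"not a substitution edit: {edit!r}")
    return int(m.group(2)), m.group(3)


def _parse_ins(edit: str) -> tuple[int, str]:
    m = _INS_RE.match(edit)
    if not m:
        raise MotifError(f"not an insertion edit: {edit!r}")
    return int(m.group(1)), m.group(2)


@dataclass
class PositionProbabilityMatrix:
    """Read-weighted per-position amino-acid probabilities for one category."""

    category: str
    population: str
    probs: pd.DataFrame  # index 1..frame_length, columns the 20 amino acids
    total_counts: float  # raw category reads summed over replicates

    @property
    def frame_length(self) -> int:
        return len(self.probs)

    def to_tsv(self, path) -> None:
        self.probs.to_csv(path, sep="\t", index_label="position")


@dataclass
class ICMatrix:
    """Per-letter KL information content, positions x amino acids."""

    category: str
    values: pd.DataFrame

    @property
    def position_sums(self) -> pd.Series:
        return self.values.sum(axis=1)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out["position_sum"] = self.position_sums
        out.to_csv(path, sep="\t", index_label="position")


def build_ppm(
    counts: CountTable,
    library: VariantLibrary,
    category: str,
    population: str,
) -> PositionProbabilityMatrix:
    """PPM of one category in one population.

    Per replicate, each variant's frequency is its count divided by the
    category's total in that sample; frequencies are averaged across
    replicates and tallied into per-position amino-acid probabilities.
    """
    if category not in PPM_CATEGORIES:
        raise MotifError(f"category must be one of {PPM_CATEGORIES}, got {category!r}")
    if population not in POPULATIONS:
        raise MotifError(f"population must be one of {POPULATIONS}, got {population!r}")
    variants = library.variants_in(category)
    if not variants:
        raise MotifError(f"library has no variants in category {category!r}")
    lengths = {len(v.mutant_window) for v in variants}
    if len(lengths) != 1:
        raise MotifError(f"category {category!r} mixes frame lengths {sorted(lengths)}")
    frame = lengths.pop()
    vids = [v.variant_id for v in variants]

    sample_ids = [
        sid for sid, cond in counts.samples["condition"].items() if cond == population
    ]
    if not sample_ids:
        raise MotifError(f"no samples with condition {population!r}")
    freqs = np.zeros(len(vids))
    total_counts = 0.0
    for sid in sample_ids:
        sub = counts.counts.loc[sid, vids].to_numpy(dtype=float)
        tot = sub.sum()
        if tot == 0:
            rep = counts.samples.loc[sid, "replicate"]
            raise MotifError(
                f"zero {category} reads in sample {sid} (replicate {rep})"
            )
        freqs += sub / tot
        total_counts += tot
    freqs /= len(sample_ids)

    probs = np.zeros((frame, len(AMINO_ACIDS)))
    aa_col = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for f, v in zip(freqs, variants):
        for pos, aa in enumerate(v.mutant_window):
            probs[pos, aa_col[aa]] += f
    df = pd.DataFrame(
        probs, index=pd.RangeIndex(1, frame + 1, name="position"), columns=list(AMINO_ACIDS)
    )
    return PositionProbabilityMatrix(
        category=category, population=population, probs=df, total_counts=total_counts
    )


def information_content(
    fg: PositionProbabilityMatrix, bg: PositionProbabilityMatrix
) -> ICMatrix:
    """Per-letter IC = P * log2(P / B) of foreground vs background.

    P = 0 terms are 0 by continuity.  Background zeros under positive
    foreground mass are floored at epsilon = 1 / (10 x background
    category reads) so the IC stays finite; the floor is logged.
    """
    if fg.category != bg.category:
        raise MotifError(
            f"category mismatch: {fg.category!r} vs {bg.category!r}"
        )
    if fg.frame_length != bg.frame_length:
        raise MotifError("frame length mismatch between foreground and background")
    P = fg.probs.to_numpy(dtype=float)
    B = bg.probs.to_numpy(dtype=float)
    floored = (B == 0) & (P > 0)
    if floored.any():
        eps = 1.0 / (10.0 * bg.total_counts) if bg.total_counts > 0 else 1e-9
        logger.warning(
            "information_content: %d background zeros under positive foreground "
            "floored at epsilon=%.3g", int(floored.sum()), eps,
        )
        B = np.where(floored, eps, B)
    vals = np.zeros_like(P)
    mask = P > 0  # B > 0 wherever P > 0, thanks to the floor above
    vals[mask] = P[mask] * np.log2(P[mask] / B[mask])
    df = pd.DataFrame(vals, index=fg.probs.index.copy(), columns=fg.probs.columns)
    return ICMatrix(category=fg.category, values=df)


@dataclass
class HeatmapMatrix:
    """Mean WT-normalized GFP- enrichment arranged for heatmap display."""

    mutation_type: str
    values: pd.DataFrame  # NaN = masked cell (no library variant)

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.isna()

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def _enrichment_lookup(enr: EnrichmentTable, condition: str = "gfp_neg") -> pd.Series:
    col = f"enrichment_{condition}_wtnorm"
    if col not in enr.data.columns:
        raise MotifError(f"enrichment table lacks column {col!r}")
    return enr.data[col]


def heatmap_matrix(
    enr: EnrichmentTable,
    library: VariantLibrary,
    mutation_type: str,
    site_filter: list[int] | None = None,
    condition: str = "gfp_neg",
) -> HeatmapMatrix:
    """Heatmap of enrichment by position/site (columns) and residue(s) (rows).

    Singles give a 20 x L matrix (wild-type identity cells masked for
    substitutions); doubles give a 400-row matrix over ordered residue
    pairs, with columns the adjacent position pairs (double
    substitutions) or insertion sites (double insertions).  Merged
    (deduplicated) variants are broadcast to every source cell.
    """
    if mutation_type not in PPM_CATEGORIES:
        raise MotifError(f"unsupported mutation_type {mutation_type!r}")
    L = len(library.window)
    values = _enrichment_lookup(enr, condition)
    variants = library.variants_in(mutation_type)

    if mutation_type in ("single_substitution", "single_insertion"):
        cols = list(range(1, L + 1))
        _check_sites(site_filter, cols, mutation_type)
        if site_filter is not None:
            cols = [c for c in cols if c in site_filter]
        mat = pd.DataFrame(np.nan, index=list(AMINO_ACIDS), columns=cols)
        for v in variants:
            val = values.get(v.variant_id, np.nan)
            for edit in v.merged_edits:
                pos, aa = (
                    _parse_sub(edit)
                    if mutation_type == "single_substitution"
                    else _parse_ins(edit)
                )
                if pos in mat.columns:
                    mat.loc[aa, pos] = val
    else:
        pair_index = pd.MultiIndex.from_product(
            [list(AMINO_ACIDS), list(AMINO_ACIDS)], names=["res1", "res2"]
        )
        if mutation_type == "double_substitution":
            all_cols = list(range(1, L))  # pair (i, i+1) keyed by i
            _check_sites(site_filter, all_cols, mutation_type)
            cols = [c for c in all_cols if site_filter is None or c in site_filter]
            mat = pd.DataFrame(np.nan, index=pair_index, columns=cols)
            for v in variants:
                val = values.get(v.variant_id, np.nan)
                for edit in v.merged_edits:
                    first, second = edit.split("+")
                    p1, r1 = _parse_sub(first)
                    _, r2 = _parse_sub(second)
                    if p1 in mat.columns:
                        mat.loc[(r1, r2), p1] = val
        else:
            all_cols = list(range(1, L + 1))
            _check_sites(site_filter, all_cols, mutation_type)
            cols = [c for c in all_cols if site_filter is None or c in site_filter]
            mat = pd.DataFrame(np.nan, index=pair_index, columns=cols)
            for v in variants:
                val = values.get(v.variant_id, np.nan)
                for edit in v.merged_edits:
                    site, ins = _parse_ins(edit)
                    if site in mat.columns:
                        mat.loc[(ins[0], ins[1]), site] = val
    return HeatmapMatrix(mutation_type=mutation_type, values=mat)


def _check_sites(site_filter, valid, mutation_type) -> None:
    if site_filter is None:
        return
    bad = [s for s in site_filter if s not in valid]
    if bad:
        raise MotifError(
            f"site_filter {bad} outside the valid range {valid[0]}..{valid[-1]} "
            f"for {mutation_type}"
        )


@dataclass
class CorrelationResult:
    mutation_type: str
    pairs: pd.DataFrame  # single_id, single_value, double_mean, n_doubles
    r: float
    p_value: float
    slope: float
    intercept: float


def single_double_correlation(
    enr: EnrichmentTable,
    library: VariantLibrary,
    mutation_type: str,
    condition: str = "gfp_neg",
) -> CorrelationResult:
    """Correlate each single mutant with its adjacent double mutants.

    For a single substitution (position n, residue X), the matching
    doubles are the adjacent-pair double substitutions carrying exactly
    X at n plus one substitution at n-1 or n+1.  For a single insertion
    (site s, residue X), the matching doubles are the ordered-pair
    insertions at site s containing X as either member.  Each single is
    paired with the mean enrichment of its doubles, and Pearson r, the
    two-sided p-value and the least-squares line are returned.
    """
    if mutation_type not in ("substitution", "insertion"):
        raise MotifError("mutation_type must be 'substitution' or 'insertion'")
    values = _enrichment_lookup(enr, condition)
    single_cat = f"single_{mutation_type}"
    double_cat = f"double_{mutation_type}"
    singles = library.variants_in(single_cat)
    doubles = library.variants_in(double_cat)
    if not doubles:
        raise InsufficientDataError(f"no {double_cat} variants present")

    # index doubles by the single changes they contain
    contains: dict[tuple[int, str], list[Variant]] = {}
    for d in doubles:
        keys = set()
        for edit in d.merged_edits:
            if mutation_type == "substitution":
                first, second = edit.split("+")
                p1, r1 = _parse_sub(first)
                p2, r2 = _parse_sub(second)
                keys.add((p1, r1))
                keys.add((p2, r2))
            else:
                site, ins = _parse_ins(edit)
                keys.add((site, ins[0]))
                keys.add((site, ins[1]))
        for key in keys:
            contains.setdefault(key, []).append(d)

    rows = []
    for s in singles:
        if s.variant_id not in values.index or not np.isfinite(values[s.variant_id]):
            continue
        matched: dict[str, Variant] = {}
        for edit in s.merged_edits:
            key = _parse_sub(edit) if mutation_type == "substitution" else _parse_ins(edit)
            for d in contains.get(key, []):
                matched[d.variant_id] = d
        dvals = [
            values[d.variant_id]
            for d in matched.values()
            if d.variant_id in values.index and np.isfinite(values[d.variant_id])
        ]
        if not dvals:
            continue
        rows.append(
            {
                "single_id": s.variant_id,
                "single_value": values[s.variant_id],
                "double_mean": float(np.mean(dvals)),
                "n_doubles": len(dvals),
            }
        )
    if len(rows) < 3:
        raise InsufficientDataError(
            f"only {len(rows)} single/double pairs available; need >= 3"
        )
    pairs = pd.DataFrame(rows).set_index("single_id")
    r, p = stats.pearsonr(pairs["single_value"], pairs["double_mean"])
    fit = stats.linregress(pairs["single_value"], pairs["double_mean"])
    return CorrelationResult(
        mutation_type=mutation_type,
        pairs=pairs,
        r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def select_by_pattern(
    enr: EnrichmentTable,
    library: VariantLibrary,
    pattern: str,
    wildcard: str = "?",
) -> pd.DataFrame:
    """All variants whose mutant window matches an exact-length pattern.

    The wildcard symbol matches any residue; the pattern length must
    equal the frame length of at least one library category.
    """
    lengths = {len(v.mutant_window) for v in library}
    if len(pattern) not in lengths:
        raise MotifError(
            f"pattern length {len(pattern)} matches no category frame "
            f"length (present: {sorted(lengths)})"
        )
    regex = re.compile(
        "^" + "".join("." if c == wildcard else re.escape(c) for c in pattern) + "$"
    )
    hits = [
        v for v in library
        if len(v.mutant_window) == len(pattern) and regex.match(v.mutant_window)
    ]
    out = pd.DataFrame(
        {
            "category": [v.category for v in hits],
            "mutant_window": [v.mutant_window for v in hits],
        },
        index=pd.Index([v.variant_id for v in hits], name="variant_id"),
    )
    enr_cols = [c for c in enr.data.columns if c.startswith("enrichment_")]
    return out.join(enr.data[enr_cols], how="left")
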