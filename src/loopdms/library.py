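"""Variant library enumeration and oligo design for a short mutational window.

All enumeration is exhaustive and deduplicated at the protein level
*within* each mutational category: two edits of the same category that
produce the same mutant protein collapse into one library member whose
``merged_edits`` records every originating edit.  Categories are never
deduplicated against each other because each category is amplified from
its own barcoded subpool and remains distinguishable at the DNA level.

Window coordinates are 1-based throughout the public API; residue numbers
in delins nomenclature use full-protein numbering mapped into the window
via ``MutationWindow.first_residue_number``.
"""

from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: One fixed codon per amino acid (most-used human codon), used to encode
#: edited / inserted residues.  Unchanged window positions keep the codons
#: of the reference ``codon_sequence``.
CODON_TABLE: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

CATEGORIES = (
    "deletion",
    "single_substitution",
    "double_substitution",
    "single_insertion",
    "double_insertion",
    "triple_gs_insertion",
    "scramble_control",
    "named_indel",
    "wild_type",
)

# Default homology arms flanking the mutated region in every oligo.
DEFAULT_FLANK5 = "CACCGGCTCCAGATCTTCGT"
DEFAULT_FLANK3 = "GTACTGAGTCCGGACTTAAC"

# Fixed subpool barcode pairs (forward, reverse), one per category.
DEFAULT_SUBPOOL_BARCODES: dict[str, tuple[str, str]] = {
    "deletion": ("ACTGAGTC", "TGACTCAG"),
    "single_substitution": ("AGCTTGCA", "TCGAACGT"),
    "double_substitution": ("ATCGGATC", "TAGCCTAG"),
    "single_insertion": ("CAGTACTG", "GTCATGAC"),
    "double_insertion": ("CTGACAGT", "GACTGTCA"),
    "triple_gs_insertion": ("TGCAGTAC", "ACGTCATG"),
    "scramble_control": ("GATCCGAT", "CTAGGCTA"),
    "named_indel": ("GTACTGCA", "CATGACGT"),
    "wild_type": ("TCAGCTGA", "AGTCGACT"),
}


class LibraryError(ValueError):
    """Invalid window, configuration or nomenclature."""


def encode_protein(protein: str) -> str:
    """Encode a protein string with the fixed one-codon-per-residue table."""
    try:
        return "".join(CODON_TABLE[aa] for aa in protein)
    except KeyError as exc:  # non-canonical residue
        raise LibraryError(f"non-canonical amino acid {exc.args[0]!r}") from None


@dataclass(frozen=True)
class MutationWindow:
    """The wild-type protein window targeted by the scan.

    Parameters
    ----------
    protein_sequence:
        Wild-type amino-acid sequence of the window (default the KBTBD4
        2b-2c loop, GISIPRR).
    first_residue_number:
        Full-protein residue number of the first window position
        (default 307, isoform-2 numbering), so window position ``i``
        corresponds to residue ``first_residue_number + i - 1``.
    codon_sequence:
        Reference nucleotide sequence (length ``3 L``) encoding the
        window; defaults to the fixed codon table's encoding.
    flank5, flank3:
        Homology-arm nucleotide strings placed 5' and 3' of the mutated
        region in every oligo.
    """

    protein_sequence: str = "GISIPRR"
    first_residue_number: int = 307
    codon_sequence: str | None = None
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        seq = self.protein_sequence
        if len(seq) < 1:
            raise LibraryError("window must contain at least one residue")
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise LibraryError(f"non-canonical residues in window: {sorted(bad)}")
        if self.codon_sequence is None:
            object.__setattr__(self, "codon_sequence", encode_protein(seq))
        if len(self.codon_sequence) != 3 * len(seq):
            raise LibraryError("codon_sequence length must be 3 x window length")
        translated = str(Seq(self.codon_sequence).translate())
        if translated != seq:
            raise LibraryError(
                f"codon_sequence translates to {translated!r}, expected {seq!r}"
            )

    def __len__(self) -> int:
        return len(self.protein_sequence)

    @property
    def codons(self) -> tuple[str, ...]:
        """Reference codons, one per window position."""
        cs = self.codon_sequence
        return tuple(cs[3 * i : 3 * i + 3] for i in range(len(self)))

    def residue_number(self, window_pos: int) -> int:
        """Full-protein residue number of a 1-based window position."""
        return self.first_residue_number + window_pos - 1

    def window_position(self, residue_number: int) -> int:
        """1-based window position of a full-protein residue number."""
        return residue_number - self.first_residue_number + 1


@dataclass(frozen=True)
class Variant:
    """One library member (possibly the merge of several identical edits)."""

    variant_id: str
    category: str
    edit: str
    mutant_window: str
    nt_design: str
    subpool: str
    merged_edits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LibraryError(f"unknown category {self.category!r}")
        if not self.merged_edits:
            object.__setattr__(self, "merged_edits", (self.edit,))
        translated = str(Seq(self.nt_design).translate()) if self.nt_design else ""
        if translated != self.mutant_window:
            raise LibraryError(
                f"{self.variant_id}: nt_design translates to {translated!r}, "
                f"expected {self.mutant_window!r}"
            )


def _merge(
    category: str,
    candidates: list[tuple[str, str, str]],
) -> list[Variant]:
    """Collapse (edit, mutant_window, nt_design) candidates by protein.

    The first candidate for each protein (in the given enumeration order)
    is canonical: it names the variant and supplies the nucleotide design;
    the rest are recorded in ``merged_edits``.
    """
    by_protein: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    for edit, prot, nt in candidates:
        if prot not in by_protein:
            by_protein[prot] = []
            order.append(prot)
        by_protein[prot].append((edit, nt))
    out = []
    for prot in order:
        entries = by_protein[prot]
        edit, nt = entries[0]
        out.append(
            Variant(
                variant_id=f"{category}:{edit}",
                category=category,
                edit=edit,
                mutant_window=prot,
                nt_design=nt,
                subpool=category,
                merged_edits=tuple(e for e, _ in entries),
            )
        )
    return out


def enumerate_deletions(
    window: MutationWindow, min_len: int = 1, max_len: int = 6
) -> list[Variant]:
    """All contiguous deletions of ``min_len``..``max_len`` residues.

    Deletions yielding identical proteins are merged; output is ordered by
    (deletion length, start position) of the canonical (first) span.  The
    full-window deletion is outside the design, hence ``max_len <= L - 1``.
    """
    L = len(window)
    if not (1 <= min_len <= max_len <= L - 1):
        raise LibraryError(
            f"deletion lengths must satisfy 1 <= min <= max <= {L - 1}, "
            f"got ({min_len}, {max_len})"
        )
    seq, codons = window.protein_sequence, window.codons
    candidates = []
    for k in range(min_len, max_len + 1):
        for i in range(L - k + 1):
            prot = seq[:i] + seq[i + k :]
            nt = "".join(codons[:i] + codons[i + k :])
            start, end = i + 1, i + k
            edit = f"del{start}" if k == 1 else f"del{start}-{end}"
            candidates.append((edit, prot, nt))
    return _merge("deletion", candidates)


def enumerate_substitutions(window: MutationWindow, order: int = 1) -> list[Variant]:
    """Single (order=1) or adjacent-pair double (order=2) substitutions.

    Every substituted residue differs from the wild type at its position
    (19 choices per position), so no two edits collide at the protein
    level; deduplication is still applied for uniformity.
    """
    if order not in (1, 2):
        raise LibraryError(f"substitution order must be 1 or 2, got {order}")
    L = len(window)
    if L < order:
        raise LibraryError(f"window of length {L} cannot host order-{order} substitutions")
    seq, codons = window.protein_sequence, window.codons
    candidates = []
    if order == 1:
        category = "single_substitution"
        for i in range(L):
            for aa in AMINO_ACIDS:
                if aa == seq[i]:
                    continue
                prot = seq[:i] + aa + seq[i + 1 :]
                nt = "".join(codons[:i] + (CODON_TABLE[aa],) + codons[i + 1 :])
                candidates.append((f"{seq[i]}{i + 1}{aa}", prot, nt))
    else:
        category = "double_substitution"
        for i in range(L - 1):
            for a, b in itertools.product(AMINO_ACIDS, AMINO_ACIDS):
                if a == seq[i] or b == seq[i + 1]:
                    continue
                prot = seq[:i] + a + b + seq[i + 2 :]
                nt = "".join(
                    codons[:i] + (CODON_TABLE[a], CODON_TABLE[b]) + codons[i + 2 :]
                )
                edit = f"{seq[i]}{i + 1}{a}+{seq[i + 1]}{i + 2}{b}"
                candidates.append((edit, prot, nt))
    return _merge(category, candidates)


def enumerate_insertions(window: MutationWindow, order: int = 1) -> list[Variant]:
    """Single-residue (order=1) or ordered-pair (order=2) insertions.

    Insertion sites are "after window position s" for s = 1..L; the
    before-position-1 site is not part of the design.  Insertions of the
    same string at neighbouring sites can produce identical proteins
    (e.g. inserting R anywhere inside a run of Rs); these are merged with
    all originating (site, residues) edits recorded.
    """
    if order not in (1, 2):
        raise LibraryError(f"insertion order must be 1 or 2, got {order}")
    L = len(window)
    seq, codons = window.protein_sequence, window.codons
    inserted = (
        list(AMINO_ACIDS)
        if order == 1
        else ["".join(p) for p in itertools.product(AMINO_ACIDS, AMINO_ACIDS)]
    )
    category = "single_insertion" if order == 1 else "double_insertion"
    candidates = []
    for s in range(1, L + 1):
        for ins in inserted:
            prot = seq[:s] + ins + seq[s:]
            nt = "".join(codons[:s]) + encode_protein(ins) + "".join(codons[s:])
            candidates.append((f"ins{s}{ins}", prot, nt))
    return _merge(category, candidates)


def _distinct_permutations(seq: str, limit: int | None = None):
    """Distinct residue-order permutations of ``seq`` in lexicographic order."""
    seen = set()
    for perm in itertools.permutations(sorted(seq)):
        s = "".join(perm)
        if s not in seen:
            seen.add(s)
            yield s
            if limit is not None and len(seen) >= limit:
                return


def generate_scramble_controls(
    window: MutationWindow, n: int = 100, seed: int = 0
) -> list[Variant]:
    """``n`` seeded random residue-order permutations of the window, plus WT.

    The permutations are distinct and never equal to the wild-type order.
    The wild-type entry (the enrichment normalization reference) is always
    emitted last, even for ``n = 0``.
    """
    if n < 0:
        raise LibraryError("n must be >= 0")
    seq = window.protein_sequence
    codons = window.codons
    if n > 0:
        # capacity: distinct permutations excluding the WT order itself
        cap = sum(1 for _ in _distinct_permutations(seq, limit=n + 1))
        if cap - 1 < n:
            raise LibraryError(
                f"window admits only {cap - 1} non-wild-type permutations, "
                f"cannot generate {n} scramble controls"
            )
    rng = np.random.default_rng(seed)
    chosen: list[tuple[int, ...]] = []
    seen: set[str] = set()
    idx = np.arange(len(seq))
    while len(chosen) < n:
        perm = tuple(rng.permutation(idx))
        s = "".join(seq[i] for i in perm)
        if s == seq or s in seen:
            continue
        seen.add(s)
        chosen.append(perm)
    out = []
    for perm in chosen:
        prot = "".join(seq[i] for i in perm)
        nt = "".join(codons[i] for i in perm)
        out.append(
            Variant(
                variant_id=f"scramble_control:{prot}",
                category="scramble_control",
                edit=f"scr{prot}",
                mutant_window=prot,
                nt_design=nt,
                subpool="scramble_control",
            )
        )
    out.append(
        Variant(
            variant_id="wild_type",
            category="wild_type",
            edit="wt",
            mutant_window=seq,
            nt_design=window.codon_sequence,
            subpool="wild_type",
        )
    )
    return out


_DELINS_RE = re.compile(r"^([A-Z]+)(\d+)delins([A-Z]+)$")


def parse_delins(nomenclature: str, window: MutationWindow) -> Variant:
    """Parse ``<ref><pos>delins<new>`` nomenclature into a named-indel variant.

    The reference residues starting at full-protein position ``pos`` are
    deleted and replaced by the new residues (e.g. R313delinsPRR turns
    ...PRR into ...PRPRR).  The referenced span must lie inside the window
    and match the wild-type sequence.
    """
    m = _DELINS_RE.match(nomenclature)
    if not m:
        raise LibraryError(f"malformed delins nomenclature {nomenclature!r}")
    ref, pos, new = m.group(1), int(m.group(2)), m.group(3)
    bad = (set(ref) | set(new)) - set(AMINO_ACIDS)
    if bad:
        raise LibraryError(f"{nomenclature}: non-canonical residues {sorted(bad)}")
    start = window.window_position(pos)  # 1-based window coordinate
    end = start + len(ref) - 1
    if start < 1 or end > len(window):
        raise LibraryError(
            f"{nomenclature}: residues {pos}..{pos + len(ref) - 1} fall outside "
            f"window residues {window.first_residue_number}.."
            f"{window.residue_number(len(window))}"
        )
    seq = window.protein_sequence
    found = seq[start - 1 : end]
    if found != ref:
        raise LibraryError(
            f"{nomenclature}: reference {ref!r} does not match window "
            f"residues {found!r} at positions {start}..{end}"
        )
    codons = window.codons
    prot = seq[: start - 1] + new + seq[end:]
    nt = "".join(codons[: start - 1]) + encode_protein(new) + "".join(codons[end:])
    return Variant(
        variant_id=f"named_indel:{nomenclature}",
        category="named_indel",
        edit=nomenclature,
        mutant_window=prot,
        nt_design=nt,
        subpool="named_indel",
    )


DEFAULT_NAMED_INDELS = ("PR311delinsPPHV", "IPR310delinsTTYML")


@dataclass(frozen=True)
class LibraryConfig:
    """Category toggles and options for :func:`build_library`."""

    include_deletions: bool = True
    include_single_substitutions: bool = True
    include_double_substitutions: bool = True
    include_single_insertions: bool = True
    include_double_insertions: bool = True
    deletion_min_len: int = 1
    deletion_max_len: int = 6
    n_scrambles: int = 100
    scramble_seed: int = 0
    named_indels: tuple[str, ...] = DEFAULT_NAMED_INDELS
    # optional extra category (GGG / GSG triple insertions), excluded from
    # the default library total
    include_triple_gs_insertions: bool = False
    subpool_barcodes: dict[str, tuple[str, str]] | None = None


@dataclass
class VariantLibrary:
    """Deduplicated, indexed variant collection plus assembly parameters."""

    window: MutationWindow
    variants: list[Variant]
    subpool_barcodes: dict[str, tuple[str, str]]
    absorbed_named_indels: tuple[str, ...] = ()
    _by_key: dict[tuple[str, str], Variant] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_key = {}
        for v in self.variants:
            key = (v.category, v.mutant_window)
            if key in self._by_key:
                raise LibraryError(
                    f"duplicate protein {v.mutant_window!r} within category "
                    f"{v.category!r}"
                )
            self._by_key[key] = v
            if v.subpool not in self.subpool_barcodes:
                raise LibraryError(f"no barcodes for subpool {v.subpool!r}")
        pairs = list(self.subpool_barcodes.values())
        if len(set(pairs)) != len(pairs):
            raise LibraryError("barcode collision between subpools")
        oligos = [self.oligo(v) for v in self.variants]
        if len(set(oligos)) != len(oligos):
            raise LibraryError("oligo collision: library not unique at the nt level")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def get(self, category: str, mutant_window: str) -> Variant | None:
        return self._by_key.get((category, mutant_window))

    def __getitem__(self, variant_id: str) -> Variant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    @property
    def by_id(self) -> dict[str, Variant]:
        return {v.variant_id: v for v in self.variants}

    @property
    def wild_type(self) -> Variant:
        return self._by_key[("wild_type", self.window.protein_sequence)]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.variants:
            counts[v.category] = counts.get(v.category, 0) + 1
        return counts

    @property
    def n_variants(self) -> int:
        """Number of mutant library members (the wild-type reference excluded)."""
        return sum(1 for v in self.variants if v.category != "wild_type")

    def oligo(self, variant: Variant) -> str:
        """Full oligo: fwd barcode + 5' arm + design + 3' arm + rev barcode."""
        fwd, rev = self.subpool_barcodes[variant.subpool]
        w = self.window
        return fwd + w.flank5 + variant.nt_design + w.flank3 + rev

    def variants_in(self, category: str) -> list[Variant]:
        return [v for v in self.variants if v.category == category]

    # ---- persistence -------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for v in self.variants:
                fh.write(f">{v.variant_id}\n{self.oligo(v)}\n")

    def to_tsv(self, path: str | Path) -> None:
        cols = "variant_id\tcategory\twindow_edit\tmutant_window\tnt_design\tsubpool\tmerged_edits\n"
        with open(path, "w") as fh:
            fh.write(cols)
            for v in self.variants:
                fh.write(
                    f"{v.variant_id}\t{v.category}\t{v.edit}\t{v.mutant_window}"
                    f"\t{v.nt_design}\t{v.subpool}\t{','.join(v.merged_edits)}\n"
                )

    def write(self, outdir: str | Path) -> None:
        """Emit library.fasta, variants.tsv and library.json under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_fasta(outdir / "library.fasta")
        self.to_tsv(outdir / "variants.tsv")
        meta = {
            "protein_sequence": self.window.protein_sequence,
            "first_residue_number": self.window.first_residue_number,
            "codon_sequence": self.window.codon_sequence,
            "flank5": self.window.flank5,
            "flank3": self.window.flank3,
            "subpool_barcodes": {k: list(v) for k, v in self.subpool_barcodes.items()},
            "absorbed_named_indels": list(self.absorbed_named_indels),
            "category_counts": self.category_counts(),
            "n_variants": self.n_variants,
        }
        (outdir / "library.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, libdir: str | Path) -> "VariantLibrary":
        libdir = Path(libdir)
        meta = json.loads((libdir / "library.json").read_text())
        window = MutationWindow(
            protein_sequence=meta["protein_sequence"],
            first_residue_number=meta["first_residue_number"],
            codon_sequence=meta["codon_sequence"],
            flank5=meta["flank5"],
            flank3=meta["flank3"],
        )
        variants = []
        with open(libdir / "variants.tsv") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = [
                "variant_id", "category", "window_edit", "mutant_window",
                "nt_design", "subpool", "merged_edits",
            ]
            if header != expected:
                raise LibraryError(f"unexpected variants.tsv header: {header}")
            for line in fh:
                vid, cat, edit, prot, nt, subpool, merged = line.rstrip("\n").split("\t")
                variants.append(
                    Variant(
                        variant_id=vid, category=cat, edit=edit,
                        mutant_window=prot, nt_design=nt, subpool=subpool,
                        merged_edits=tuple(merged.split(",")),
                    )
                )
        return cls(
            window=window,
            variants=variants,
            subpool_barcodes={
                k: tuple(v) for k, v in meta["subpool_barcodes"].items()
            },
            absorbed_named_indels=tuple(meta.get("absorbed_named_indels", ())),
        )


def _triple_gs_insertions(window: MutationWindow) -> list[Variant]:
    seq, codons, L = window.protein_sequence, window.codons, len(window)
    candidates = []
    for s in range(1, L + 1):
        for ins in ("GGG", "GSG"):
            prot = seq[:s] + ins + seq[s:]
            nt = "".join(codons[:s]) + encode_protein(ins) + "".join(codons[s:])
            candidates.append((f"ins{s}{ins}", prot, nt))
    return _merge("triple_gs_insertion", candidates)


def build_library(
    window: MutationWindow, config: LibraryConfig | None = None
) -> VariantLibrary:
    """Assemble the full variant library for ``window``.

    The default configuration on the GISIPRR window yields the complete
    scan: 25 deletions, 133 single substitutions, 2,166 adjacent double
    substitutions, 134 single insertions, 2,680 double insertions, 100
    scrambled controls and 2 named indels — 5,240 mutant members — plus
    the wild-type normalization reference.

    Named indels whose mutant protein is already produced by an enabled
    category are absorbed (skipped and recorded), since they are not
    "new" library members.
    """
    config = config or LibraryConfig()
    variants: list[Variant] = []
    if config.include_deletions:
        variants += enumerate_deletions(
            window, config.deletion_min_len, config.deletion_max_len
        )
    if config.include_single_substitutions:
        variants += enumerate_substitutions(window, order=1)
    if config.include_double_substitutions:
        variants += enumerate_substitutions(window, order=2)
    if config.include_single_insertions:
        variants += enumerate_insertions(window, order=1)
    if config.include_double_insertions:
        variants += enumerate_insertions(window, order=2)
    if config.include_triple_gs_insertions:
        variants += _triple_gs_insertions(window)
    variants += generate_scramble_controls(
        window, n=config.n_scrambles, seed=config.scramble_seed
    )

    existing_proteins = {v.mutant_window for v in variants}
    absorbed = []
    for nom in config.named_indels:
        v = parse_delins(nom, window)
        if v.mutant_window in existing_proteins or v.mutant_window == window.protein_sequence:
            logger.warning(
                "named indel %s absorbed: its protein %r is already in the library",
                nom, v.mutant_window,
            )
            absorbed.append(nom)
            continue
        variants.append(v)

    barcodes = dict(config.subpool_barcodes or DEFAULT_SUBPOOL_BARCODES)
    used_subpools = {v.subpool for v in variants}
    missing = used_subpools - set(barcodes)
    if missing:
        raise LibraryError(f"missing barcodes for subpools {sorted(missing)}")
    return VariantLibrary(
        window=window,
        variants=variants,
        subpool_barcodes={k: barcodes[k] for k in sorted(used_subpools)},
        absorbed_named_indels=tuple(absorbed),
    )
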