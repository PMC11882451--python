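"""End-to-end orchestration: design -> (simulate) -> count -> enrich -> motifs.

One YAML configuration and one seed drive the whole run.  Each
stochastic stage draws its own sub-seed from a stable hash of the master
seed and the stage name, so adding or re-ordering stages never perturbs
the randomness of earlier ones, and re-running the same configuration
reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from loopdms import enrichment as enr_mod
from loopdms import motifs as motif_mod
from loopdms.library import LibraryConfig, MutationWindow, VariantLibrary, build_library
from loopdms.seqio import CountTable, SampleManifest, count_reads
from loopdms.simulate import EffectModel, SimConfig, evaluate_recovery, simulate_screen

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


_WINDOW_KEYS = {"protein_sequence", "first_residue_number", "codon_sequence", "flank5", "flank3"}
_LIBRARY_KEYS = {
    "include_deletions", "include_single_substitutions", "include_double_substitutions",
    "include_single_insertions", "include_double_insertions", "deletion_min_len",
    "deletion_max_len", "n_scrambles", "named_indels", "include_triple_gs_insertions",
}
_SIM_KEYS = {
    "n_cells", "reads_per_sample", "n_replicates", "gate_fraction",
    "frequency_concentration", "intensity_noise_sd", "sequencing_dispersion",
    "read_error_rate", "coverage_floor",
}
_PRODUCT_KEYS = {"waterfall", "class_summary", "heatmaps", "logos", "correlation"}
_TOP_KEYS = {"seed", "output_dir", "window", "library", "simulation", "manifest", "products"}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    window: dict = field(default_factory=dict)
    library: dict = field(default_factory=dict)
    simulation: dict | None = None
    manifest: str | None = None
    products: dict = field(default_factory=lambda: {k: True for k in _PRODUCT_KEYS})

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.manifest is None):
            raise ConfigError("exactly one of 'manifest' and 'simulation' must be given")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "window": dict(self.window),
            "library": dict(self.library),
            "products": dict(self.products),
        }
        if self.simulation is not None:
            d["simulation"] = dict(self.simulation)
        if self.manifest is not None:
            d["manifest"] = self.manifest
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline YAML configuration.

    Unknown keys are rejected; ``seed`` and ``output_dir`` are required;
    exactly one of ``manifest`` / ``simulation`` must be present.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")
    for key in ("seed", "output_dir", "window"):
        if key not in raw:
            raise ConfigError(f"missing required key {key!r}")
    _reject_unknown(raw.get("window") or {}, _WINDOW_KEYS, "window")
    _reject_unknown(raw.get("library") or {}, _LIBRARY_KEYS, "library")
    if raw.get("simulation") is not None:
        _reject_unknown(raw["simulation"], _SIM_KEYS, "simulation")
    _reject_unknown(raw.get("products") or {}, _PRODUCT_KEYS, "products")
    products = {k: True for k in _PRODUCT_KEYS}
    products.update(raw.get("products") or {})
    return PipelineConfig(
        seed=int(raw["seed"]),
        output_dir=str(raw["output_dir"]),
        window=raw.get("window") or {},
        library=raw.get("library") or {},
        simulation=raw.get("simulation"),
        manifest=raw.get("manifest"),
        products=products,
    )


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2**31) from the master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; write artifacts and a machine-readable summary.

    Returns the summary dict (also written as ``summary.json``).  A stage
    failure aborts with the stage name and cause, after dropping an
    ``INCOMPLETE`` marker so partial outputs are recognizable.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    summary: dict = {"seed": config.seed, "notices": [], "checksums": {}}
    stage = "init"

    def checkpoint(paths: list[Path]) -> None:
        for p in paths:
            summary["checksums"][str(p.relative_to(out))] = _sha256(p)

    try:
        marker.write_text("run in progress\n")

        stage = "design"
        window = MutationWindow(**config.window)
        lib_opts = dict(config.library)
        if "named_indels" in lib_opts:
            lib_opts["named_indels"] = tuple(lib_opts["named_indels"])
        lib_config = LibraryConfig(
            scramble_seed=stage_seed(config.seed, "design"), **lib_opts
        )
        library = build_library(window, lib_config)
        libdir = out / "library"
        library.write(libdir)
        logger.info("design: %d mutant variants", library.n_variants)
        checkpoint([libdir / "library.fasta", libdir / "variants.tsv", libdir / "library.json"])
        summary["category_counts"] = library.category_counts()
        summary["n_variants"] = library.n_variants
        summary["absorbed_named_indels"] = list(library.absorbed_named_indels)

        truth = None
        if config.simulation is not None:
            stage = "simulate"
            sim_config = SimConfig(
                seed=stage_seed(config.seed, "simulate"),
                effect_model=EffectModel(),
                **config.simulation,
            )
            simdir = out / "sim"
            manifest, truth = simulate_screen(library, sim_config, out_dir=simdir)
            # manifest.tsv holds run-specific absolute paths; not checksummed
            checkpoint(sorted(simdir.glob("*.fastq.gz")))
        else:
            stage = "manifest"
            manifest = SampleManifest.from_tsv(config.manifest)

        stage = "count"
        counts = count_reads(manifest, library)
        counts.to_tsv(out / "counts.tsv")
        checkpoint([out / "counts.tsv"])

        stage = "enrich"
        norm = enr_mod.normalize_log2_rpm(counts)
        enr = enr_mod.compute_enrichment(norm, manifest, library=library)
        enr.to_tsv(out / "enrichment.tsv")
        checkpoint([out / "enrichment.tsv"])
        wt_row = enr.data.loc["wild_type"]
        summary["wt_enrichment"] = {
            "gfp_neg_mean": float(wt_row["enrichment_gfp_neg_mean"]),
            "gfp_pos_mean": float(wt_row["enrichment_gfp_pos_mean"]),
        }
        ranked = enr.data["enrichment_gfp_neg_wtnorm"].sort_values(ascending=False)
        summary["top_variants"] = {k: float(v) for k, v in ranked.head(5).items()}
        summary["bottom_variants"] = {k: float(v) for k, v in ranked.tail(5).items()}

        stage = "analyze"
        _run_products(config, library, counts, enr, out, summary)

        if truth is not None:
            stage = "recovery"
            report = evaluate_recovery(truth, enr)
            summary["recovery"] = {
                "spearman_rho": report.spearman_rho,
                "neg_pos_pearson": report.neg_pos_pearson,
                "strong_effect_sign_fraction": report.strong_effect_sign_fraction,
            }

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        marker.unlink()
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return summary


def _run_products(config, library, counts, enr, out: Path, summary: dict) -> None:
    products = config.products
    if products.get("class_summary") or products.get("waterfall"):
        try:
            cat_summary, waterfall = enr_mod.summarize_categories(
                enr, categories=sorted(library.category_counts())
            )
            if products.get("class_summary"):
                cat_summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
            if products.get("waterfall"):
                waterfall.to_csv(out / "waterfall.tsv", sep="\t", index_label="variant_id")
        except enr_mod.EnrichmentError as exc:
            summary["notices"].append(f"class summary skipped: {exc}")
    present = set(library.category_counts())
    if products.get("heatmaps"):
        for cat in motif_mod.PPM_CATEGORIES:
            if cat not in present:
                summary["notices"].append(f"heatmap skipped: no {cat} variants")
                continue
            hm = motif_mod.heatmap_matrix(enr, library, cat)
            hm.to_tsv(out / f"heatmap_{cat}.tsv")
    if products.get("logos"):
        for cat in motif_mod.PPM_CATEGORIES:
            if cat not in present:
                summary["notices"].append(f"logo skipped: no {cat} variants")
                continue
            bg = motif_mod.build_ppm(counts, library, cat, "unsorted")
            for population in ("gfp_neg", "gfp_pos"):
                fg = motif_mod.build_ppm(counts, library, cat, population)
                ic = motif_mod.information_content(fg, bg)
                fg.to_tsv(out / f"ppm_{cat}_{population}.tsv")
                ic.to_tsv(out / f"ic_{cat}_{population}.tsv")
    if products.get("correlation"):
        corr_out = {}
        for mtype in ("substitution", "insertion"):
            try:
                res = motif_mod.single_double_correlation(enr, library, mtype)
                corr_out[mtype] = {
                    "r": res.r, "p_value": res.p_value,
                    "slope": res.slope, "intercept": res.intercept,
                    "n_pairs": int(len(res.pairs)),
                }
            except motif_mod.InsufficientDataError as exc:
                summary["notices"].append(f"correlation ({mtype}) skipped: {exc}")
        (out / "correlation.json").write_text(json.dumps(corr_out, indent=2, sort_keys=True) + "\n")
        summary["correlation"] = corr_out
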