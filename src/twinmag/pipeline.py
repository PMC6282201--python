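"""End-to-end orchestration with seeded determinism and a run manifest.

A single master seed fans out to per-stage seeds through
``numpy.random.SeedSequence(master).spawn()`` in a fixed stage order
(simulate, binning), so any stage can be replayed in isolation from the
manifest. All numeric outputs are TSV with headers; the manifest records
package version, parameters, seeds, and a SHA-256 checksum per output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance_profiles import bin_abundance, contig_tpm, standardize
from .cohort_stats import enrichment_contexts, kde_mode, shannon_entropy
from .cooccurrence_network import build_network
from .function_potential import mcr_matrix, parse_module_definition, pbfp
from .kmer_binning import BinningConfig, run_binning, write_bin_tsv
from .synthetic_data import (
    FragmentLaw,
    GenomeSpec,
    TwinDesign,
    default_module_library,
    fragment_genomes,
    generate_genomes,
    read_fasta,
    simulate_annotations,
    simulate_coverage,
    write_fasta,
)
from .twin_ace import ace_table

logger = logging.getLogger("twinmag")

__all__ = ["PipelineConfig", "cohort_summary", "run_pipeline", "default_config"]

_STAGES = ("simulate", "bin", "abundance", "function", "stats", "network", "ace")


@dataclass
class PipelineConfig:
    outdir: str = "twinmag_out"
    seed: int = 0
    # input paths (filled by the simulate stage when it is enabled)
    contigs_fasta: str | None = None
    coverage_tsv: str | None = None
    metadata_tsv: str | None = None
    modules_txt: str | None = None
    ko_table_tsv: str | None = None
    stages: tuple = _STAGES
    # simulate stage
    n_genomes: int = 3
    genome_length: int = 200_000
    gc_targets: tuple = (0.30, 0.50, 0.70)
    n_mz_pairs: int = 5
    n_dz_pairs: int = 5
    ace: tuple = (0.5, 0.2, 0.3)
    caries_effect: dict = field(default_factory=dict)
    depth: float = 50.0
    # tunables
    k: int = 5
    clr_pseudocount: float = 1.0
    log_pseudocount: float = 1e-4
    top_n: int = 500
    r_min: float = 0.5
    min_cluster_size: int = 10
    alpha: float = 0.05
    beta: float = 1.0
    damping: float = 0.85

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls(**data)
        return cfg

    def validate(self) -> None:
        if "simulate" in self.stages:
            return  # simulate generates its own inputs
        for name in ("contigs_fasta", "coverage_tsv", "metadata_tsv"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"config input {name} missing or absent: {p}")


def cohort_summary(metadata: pd.DataFrame) -> dict:
    """Counts and percentages of caries status, zygosity, and depth classes
    (percentages reported to one decimal)."""
    if len(metadata) == 0:
        raise ValueError("empty metadata table")
    caries = metadata["caries"].astype(str)
    n = len(metadata)
    positive = int(caries.isin(["enamel", "dentin"]).sum())
    out = {
        "n_subjects": n,
        "caries_positive": positive,
        "caries_positive_pct": round(100.0 * positive / n, 1),
        "caries_classes": caries.value_counts().to_dict(),
    }
    if "zygosity" in metadata:
        out["zygosity"] = metadata["zygosity"].value_counts().to_dict()
    denom = max(positive, 1)
    out["dentin_pct_of_positive"] = round(
        100.0 * int((caries == "dentin").sum()) / denom, 1
    )
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")
    manifest["outputs"][path.name] = _sha256(path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages and return the output directory.

    Identical config + seed gives byte-identical numeric outputs; the
    manifest records the checksums so a rerun can be verified.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(("simulate", "binning"), ss.spawn(2))
    }
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "parameters": asdict(config),
        "outputs": {},
        "stages_completed": [],
    }

    contigs = coverage = metadata = None
    modules = None
    ko_table = None
    truth_mcr = None

    try:
        if "simulate" in config.stages:
            logger.info("stage: simulate")
            specs = [
                GenomeSpec(
                    genome_id=f"genome_{i + 1}",
                    length=config.genome_length,
                    gc_target=gc,
                    ko_set=frozenset(
                        f"K{j:05d}" for j in range(1 + 4 * i, 1 + 4 * i + 8)
                    ),
                )
                for i, gc in enumerate(config.gc_targets[: config.n_genomes])
            ]
            genomes = generate_genomes(specs, seed=stage_seeds["simulate"])
            contigs = fragment_genomes(
                genomes, FragmentLaw(), seed=stage_seeds["simulate"]
            )
            design = TwinDesign(
                n_mz_pairs=config.n_mz_pairs,
                n_dz_pairs=config.n_dz_pairs,
                ace=tuple(config.ace),
                caries_effect=dict(config.caries_effect),
                seed=stage_seeds["simulate"],
            )
            coverage, metadata, latent = simulate_coverage(
                contigs, design, depth=config.depth
            )
            module_defs = default_module_library()
            ko_table, truth_mcr = simulate_annotations(specs, module_defs)
            modules = {
                mid: parse_module_definition(text, module_id=mid)
                for mid, text in module_defs.items()
            }
            write_fasta(contigs, outdir / "contigs.fasta")
            manifest["outputs"]["contigs.fasta"] = _sha256(outdir / "contigs.fasta")
            _write(coverage, outdir / "coverage.tsv", manifest)
            _write(metadata, outdir / "metadata.tsv", manifest)
            _write(ko_table, outdir / "ko_table.tsv", manifest)
            _write(latent, outdir / "latent_abundance.tsv", manifest)
            _write(truth_mcr, outdir / "truth_mcr.tsv", manifest)
            with open(outdir / "modules.txt", "w") as fh:
                for mid, text in module_defs.items():
                    fh.write(f"{mid}\t{text}\n")
            manifest["outputs"]["modules.txt"] = _sha256(outdir / "modules.txt")
            manifest["stages_completed"].append("simulate")
        else:
            contigs = read_fasta(config.contigs_fasta)
            coverage = pd.read_csv(config.coverage_tsv, sep="\t", index_col=0)
            metadata = pd.read_csv(config.metadata_tsv, sep="\t", index_col=0)
            if config.modules_txt:
                modules = {}
                for line in Path(config.modules_txt).read_text().splitlines():
                    if not line.strip():
                        continue
                    mid, text = line.split("\t", 1)
                    modules[mid] = parse_module_definition(text, module_id=mid)
            if config.ko_table_tsv:
                ko_table = pd.read_csv(config.ko_table_tsv, sep="\t", index_col=0)

        lengths = pd.Series(
            {c.contig_id: c.length for c in contigs}, name="length"
        )

        if "bin" in config.stages:
            logger.info("stage: bin")
            bin_cfg = BinningConfig(
                k=config.k,
                pseudocount=config.clr_pseudocount,
                min_cluster_size=config.min_cluster_size,
                top_n=config.top_n,
                r_min=config.r_min,
                random_state=stage_seeds["binning"],
            )
            assignment = run_binning(contigs, coverage, bin_cfg)
            write_bin_tsv(assignment, outdir / "bin_membership.tsv")
            manifest["outputs"]["bin_membership.tsv"] = _sha256(
                outdir / "bin_membership.tsv"
            )
            manifest["stages_completed"].append("bin")
        else:
            assignment = None

        if "abundance" in config.stages and assignment is not None:
            logger.info("stage: abundance")
            tpm = contig_tpm(coverage, lengths)
            abundance = bin_abundance(tpm, assignment)
            zmat = standardize(abundance, pseudocount=config.log_pseudocount)
            _write(abundance, outdir / "bin_abundance.tsv", manifest)
            _write(zmat, outdir / "standardized_abundance.tsv", manifest)
            manifest["stages_completed"].append("abundance")
        else:
            abundance = zmat = None

        mcr_df = None
        if "function" in config.stages and abundance is not None and modules:
            logger.info("stage: function")
            # map truth KO sets onto recovered bins by majority truth label
            bin_kos = _bin_ko_sets(assignment, contigs, ko_table)
            mcr_df = mcr_matrix(bin_kos, modules)
            bins = [b for b in abundance.columns if b in mcr_df.index]
            A = pbfp(abundance[bins], mcr_df.loc[bins])
            _write(mcr_df, outdir / "mcr.tsv", manifest)
            _write(A, outdir / "pbfp.tsv", manifest)
            manifest["stages_completed"].append("function")

        if "stats" in config.stages and abundance is not None:
            logger.info("stage: stats")
            summary = cohort_summary(metadata)
            entropy = abundance.apply(shannon_entropy, axis=1)
            caries_pos = metadata["caries"].isin(["enamel", "dentin"])
            diversity = {
                "mode_caries": kde_mode(entropy[caries_pos.reindex(entropy.index)])
                if caries_pos.sum() >= 2
                else None,
                "mode_healthy": kde_mode(entropy[~caries_pos.reindex(entropy.index)])
                if (~caries_pos).sum() >= 2
                else None,
            }
            stats_out = {"cohort": summary, "diversity_modes": diversity}
            if mcr_df is not None:
                enr = enrichment_contexts(
                    abundance, mcr_df, metadata, alpha=config.alpha,
                    pseudocount=config.log_pseudocount,
                )
                _write(enr.context1, outdir / "enrichment_context1.tsv", manifest)
                _write(enr.context2, outdir / "enrichment_context2_anchored.tsv", manifest)
                _write(enr.context3, outdir / "enrichment_context3_unanchored.tsv", manifest)
                stats_out["venn"] = enr.venn
            (outdir / "stats_summary.json").write_text(
                json.dumps(stats_out, indent=2, default=float)
            )
            manifest["outputs"]["stats_summary.json"] = _sha256(
                outdir / "stats_summary.json"
            )
            manifest["stages_completed"].append("stats")

        if "network" in config.stages and zmat is not None and zmat.shape[1] >= 2:
            logger.info("stage: network")
            net = build_network(
                zmat,
                prevalence_source=abundance,
                beta=config.beta,
                damping=config.damping,
            )
            _write(net["rho"], outdir / "spearman.tsv", manifest)
            _write(net["tom"], outdir / "tom.tsv", manifest)
            _write(net["pagerank"].to_frame(), outdir / "pagerank.tsv", manifest)
            _write(net["clusters"].to_frame(), outdir / "network_clusters.tsv", manifest)
            manifest["stages_completed"].append("network")

        if "ace" in config.stages and zmat is not None:
            logger.info("stage: ace")
            ace = ace_table(zmat, metadata)
            _write(ace, outdir / "ace_estimates.tsv", manifest)
            manifest["stages_completed"].append("ace")
    except Exception as exc:  # record partial progress before propagating
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _bin_ko_sets(assignment, contigs, ko_table) -> dict:
    """KO set per recovered bin: the KO row of the truth genome contributing
    most contigs to the bin (synthetic fixtures label contigs by genome id
    prefix). Bins without resolvable truth get an empty KO set."""
    if ko_table is None:
        return {}
    truth = {c.contig_id: (c.truth_genome or c.contig_id.rsplit("_c", 1)[0]) for c in contigs}
    out = {}
    for bid, members in assignment.bins().items():
        votes = pd.Series([truth.get(m) for m in members]).value_counts()
        top = votes.index[0] if len(votes) else None
        if top in ko_table.index:
            row = ko_table.loc[top]
            out[bid] = set(ko_table.columns[row > 0])
        else:
            out[bid] = set()
    return out


def default_config(outdir, seed: int = 0) -> PipelineConfig:
    """Small bundled synthetic fixture: 3 genomes, 20 subjects."""
    return PipelineConfig(
        outdir=str(outdir),
        seed=seed,
        caries_effect={"genome_1": 1.5},
    )
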