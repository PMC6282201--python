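"""Synthetic inputs for the plaque-metagenome pipeline.

Generates everything the downstream stages consume — genomes with distinct
oligonucleotide composition, fragmented contigs with a wide length
distribution, twin-structured per-subject coverage tables, subject metadata,
and per-genome KO annotations with known module completion — so the whole
pipeline can be exercised and validated without any sequencing data.

The abundance model follows the classical twin decomposition: each genome's
latent log-abundance for a subject is

    z = sqrt(a2) * G + sqrt(c2) * C + sqrt(e2) * E

where G (additive genetic) is shared within monozygotic pairs and correlated
0.5 within dizygotic pairs, C (common environment) is shared within every
pair, and E (unique environment) is independent. Mapped-read counts per
contig are Poisson around genome relative abundance x contig length x depth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "TwinDesign",
    "ContigRecord",
    "FragmentLaw",
    "generate_genomes",
    "fragment_genomes",
    "simulate_coverage",
    "simulate_annotations",
    "default_module_library",
]

_BASES = np.array(list("ACGT"))
# A<->T, C<->G complement pairing in the 0..3 encoding
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters for one synthetic source genome.

    ``order2_bias`` is an optional 4x4 positive matrix of dinucleotide
    transition weights; when omitted, a genome-specific random stochastic
    matrix is drawn so that distinct genomes have separable k-mer
    signatures even at equal GC content.
    """

    genome_id: str
    length: int = 1_000_000
    gc_target: float = 0.5
    order2_bias: tuple | None = None
    ko_set: frozenset = frozenset()
    exclusion_flag: bool = False

    def __post_init__(self):
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError(
                f"gc_target must lie strictly in (0, 1); got {self.gc_target}"
            )
        if self.length < 10_000:
            raise ValueError(f"genome length must be >= 10,000 nt; got {self.length}")


@dataclass(frozen=True)
class TwinDesign:
    """Twin-cohort layout plus the per-genome variance decomposition.

    ``ace`` maps genome_id -> (a2, c2, e2); a single triple is broadcast to
    every genome. ``caries_effect`` maps genome_id -> log2 abundance shift
    applied to caries-positive subjects (the planted disease signal).
    """

    n_mz_pairs: int
    n_dz_pairs: int
    ace: Mapping[str, tuple] | tuple = (0.0, 0.0, 1.0)
    caries_effect: Mapping[str, float] = field(default_factory=dict)
    caries_prevalence: float = 0.568
    dentin_fraction: float = 0.5
    seed: int = 0

    def ace_for(self, genome_id: str) -> tuple:
        triple = (
            self.ace.get(genome_id, (0.0, 0.0, 1.0))
            if isinstance(self.ace, Mapping)
            else self.ace
        )
        a2, c2, e2 = (float(v) for v in triple)
        if min(a2, c2, e2) < 0 or abs(a2 + c2 + e2 - 1.0) > 1e-8:
            raise ValueError(
                f"ACE fractions for {genome_id} must be nonnegative and sum to 1; "
                f"got ({a2}, {c2}, {e2})"
            )
        return a2, c2, e2


@dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    sequence: str
    truth_genome: str | None = None
    exclusion_flag: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentLaw:
    """Contig-length law: log-normal with a hard minimum, or fixed tiling."""

    min_length: int = 300
    mean_log: float = math.log(1500.0)
    sigma_log: float = 0.8
    fixed_length: int | None = None

    def __post_init__(self):
        if self.min_length < 300:
            raise ValueError("minimum contig length must be >= 300 nt")


def _stationary(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _transition_matrix(spec: GenomeSpec, rng: np.random.Generator) -> np.ndarray:
    """First-order Markov transition matrix whose stationary base composition
    hits the GC target, built by iterative proportional fitting of a
    genome-specific bias matrix."""
    target = np.array(
        [
            (1 - spec.gc_target) / 2,
            spec.gc_target / 2,
            spec.gc_target / 2,
            (1 - spec.gc_target) / 2,
        ]
    )
    if spec.order2_bias is not None:
        P = np.asarray(spec.order2_bias, dtype=float)
        if P.shape != (4, 4) or (P <= 0).any():
            raise ValueError("order2_bias must be a positive 4x4 matrix")
    else:
        P = rng.dirichlet(np.full(4, 2.0), size=4)
    P = P / P.sum(axis=1, keepdims=True)
    for _ in range(500):
        pi = _stationary(P)
        if np.abs(pi - target).max() < 1e-6:
            break
        P = P * (target / pi)[None, :]
        P = P / P.sum(axis=1, keepdims=True)
    return P


def _sample_chain(P: np.ndarray, length: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(length)
    # pre-resolve the transition for every possible current state, then walk
    draws = np.empty((4, length), dtype=np.int8)
    for s in range(4):
        draws[s] = np.searchsorted(cum[s], u, side="right").astype(np.int8)
    np.clip(draws, 0, 3, out=draws)
    states = np.empty(length, dtype=np.int8)
    s = int(rng.integers(4))
    for i in range(length):
        s = draws[s, i]
        states[i] = s
    return states


def generate_genomes(
    specs: Sequence[GenomeSpec], seed: int
) -> list[tuple[str, str]]:
    """Emit (genome_id, sequence) pairs, deterministic in (specs, seed).

    Observed GC content lands within +-0.01 of each spec's target.
    """
    if not specs:
        raise ValueError("at least one GenomeSpec is required")
    ss = np.random.SeedSequence(seed)
    out = []
    for spec, child in zip(specs, ss.spawn(len(specs))):
        rng = np.random.default_rng(child)
        P = _transition_matrix(spec, rng)
        states = _sample_chain(P, spec.length, rng)
        out.append((spec.genome_id, "".join(_BASES[states])))
    return out


def fragment_genomes(
    genomes: Sequence[tuple[str, str]],
    length_law: FragmentLaw = FragmentLaw(),
    seed: int = 0,
    excluded_genomes: Iterable[str] = (),
) -> list[ContigRecord]:
    """Cut genomes into non-overlapping contigs under ``length_law``.

    Every contig carries its source genome as truth label; a trailing
    fragment shorter than the minimum is discarded, so the concatenated
    contig length per genome never exceeds the genome length.
    """
    excluded = set(excluded_genomes)
    rng = np.random.default_rng(seed)
    contigs: list[ContigRecord] = []
    for genome_id, seq in genomes:
        pos, i = 0, 0
        n = len(seq)
        while n - pos >= length_law.min_length:
            if length_law.fixed_length is not None:
                size = length_law.fixed_length
                if n - pos < size:
                    break
            else:
                size = int(rng.lognormal(length_law.mean_log, length_law.sigma_log))
                size = max(size, length_law.min_length)
                size = min(size, n - pos)
            contigs.append(
                ContigRecord(
                    contig_id=f"{genome_id}_c{i:05d}",
                    sequence=seq[pos : pos + size],
                    truth_genome=genome_id,
                    exclusion_flag=genome_id in excluded,
                )
            )
            pos += size
            i += 1
    return contigs


def _latent_abundance(
    design: TwinDesign, genome_ids: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """Subjects x genomes latent log-abundance with the A/C/E covariance
    structure (unit marginal variance per genome)."""
    n_pairs = design.n_mz_pairs + design.n_dz_pairs
    n_sub = 2 * n_pairs
    if n_sub == 0:
        raise ValueError("twin design has zero subjects")
    Z = np.empty((n_sub, len(genome_ids)))
    for g, gid in enumerate(genome_ids):
        a2, c2, e2 = design.ace_for(gid)
        g1 = rng.standard_normal(n_pairs)
        g_extra = rng.standard_normal(n_pairs)
        c = rng.standard_normal(n_pairs)
        e = rng.standard_normal((n_pairs, 2))
        is_mz = np.arange(n_pairs) < design.n_mz_pairs
        # co-twin genetic value: identical for MZ, correlation 0.5 for DZ
        g2 = np.where(is_mz, g1, 0.5 * g1 + math.sqrt(0.75) * g_extra)
        twin1 = math.sqrt(a2) * g1 + math.sqrt(c2) * c + math.sqrt(e2) * e[:, 0]
        twin2 = math.sqrt(a2) * g2 + math.sqrt(c2) * c + math.sqrt(e2) * e[:, 1]
        Z[0::2, g] = twin1
        Z[1::2, g] = twin2
    return Z


def simulate_coverage(
    contigs: Sequence[ContigRecord],
    design: TwinDesign,
    depth: float = 50.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate mapped-read counts for every subject x contig.

    Returns ``(counts, metadata, latent)`` where ``counts`` is subjects x
    contigs, ``metadata`` has columns subject_id, pair_id, zygosity, sex,
    age, caries, and ``latent`` holds the ground-truth subjects x genomes
    log-abundances (before the caries shift).
    """
    if not contigs:
        raise ValueError("contig list is empty")
    if any(c.truth_genome is None for c in contigs):
        raise ValueError("all contigs must carry a truth_genome label")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genome_ids = sorted({c.truth_genome for c in contigs})
    n_pairs = design.n_mz_pairs + design.n_dz_pairs
    n_sub = 2 * n_pairs
    if n_sub == 0:
        raise ValueError("twin design has zero subjects")

    Z = _latent_abundance(design, genome_ids, rng)

    subject_ids = [f"S{i + 1:04d}" for i in range(n_sub)]
    pair_ids = [f"P{i // 2 + 1:04d}" for i in range(n_sub)]
    zygosity = [
        "MZ" if i // 2 < design.n_mz_pairs else "DZ" for i in range(n_sub)
    ]
    sex_pair = rng.choice(["F", "M"], size=n_pairs)  # co-twins share sex
    sex = np.repeat(sex_pair, 2)
    age_pair = rng.integers(5, 12, size=n_pairs)  # juvenile cohort, years
    age = np.repeat(age_pair, 2)
    caries_pos = rng.random(n_sub) < design.caries_prevalence
    dentin = rng.random(n_sub) < design.dentin_fraction
    caries = np.where(
        caries_pos, np.where(dentin, "dentin", "enamel"), "negative"
    )
    metadata = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "pair_id": pair_ids,
            "zygosity": zygosity,
            "sex": sex,
            "age": age,
            "caries": caries,
        }
    ).set_index("subject_id")

    latent = pd.DataFrame(Z, index=subject_ids, columns=genome_ids)

    shifted = latent.copy()
    for gid, log2_shift in design.caries_effect.items():
        if gid in shifted.columns:
            shifted.loc[caries_pos, gid] += float(log2_shift) * math.log(2.0)

    rel = np.exp(shifted.to_numpy())
    rel = rel / rel.sum(axis=1, keepdims=True)

    lengths = np.array([c.length for c in contigs], dtype=float)
    gidx = np.array([genome_ids.index(c.truth_genome) for c in contigs])
    lam = depth * (lengths / 1000.0)[None, :] * rel[:, gidx] * len(genome_ids)
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(
        counts, index=subject_ids, columns=[c.contig_id for c in contigs]
    )
    return counts_df, metadata, latent


def default_module_library() -> dict[str, str]:
    """A small library of KEGG-style module definitions used by the bundled
    fixtures: plain AND chains, OR alternatives, complexes (+), and an
    optional (-) component."""
    return {
        "M90001": "K00001 K00002 K00003 K00004",
        "M90002": "(K00005,K00006) K00007",
        "M90003": "K00008+K00009",
        "M90004": "K00010 (K00011,K00012) K00013",
        "M90005": "K00014+K00015-K00016",
        "M90006": "(K00017 K00018),K00019",
        "M90007": "K00020",
        "M90008": "K00021 K00022",
    }


def simulate_annotations(
    specs: Sequence[GenomeSpec],
    module_definitions: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome KO presence table plus ground-truth module completion.

    Truth MCRs are computed with the same module-definition evaluator the
    analysis stage uses, applied to each genome's KO set.
    """
    from .function_potential import mcr, parse_module_definition

    modules = {
        mid: parse_module_definition(text, module_id=mid)
        for mid, text in module_definitions.items()
    }
    all_kos = sorted({ko for spec in specs for ko in spec.ko_set})
    for ko in all_kos:
        if not (ko.startswith("K") and ko[1:].isdigit()):
            raise ValueError(f"malformed KO identifier in ko_set: {ko!r}")
    ko_table = pd.DataFrame(
        {
            spec.genome_id: [int(ko in spec.ko_set) for ko in all_kos]
            for spec in specs
        },
        index=all_kos,
    ).T
    ko_table.index.name = "genome_id"
    truth = pd.DataFrame(
        {
            mid: [mcr(spec.ko_set, mod) for spec in specs]
            for mid, mod in modules.items()
        },
        index=[spec.genome_id for spec in specs],
    )
    truth.index.name = "genome_id"
    return ko_table, truth


def write_fasta(contigs: Sequence[ContigRecord], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
        for c in contigs
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> list[ContigRecord]:
    from Bio import SeqIO

    return [
        ContigRecord(contig_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
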