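"""Semisupervised iterative k-mer/coverage genome binning.

The strategy, designed for coassemblies too large for embedding-based
visual binning in one shot:

1. seed bins by clustering a 2-D embedding of CLR-transformed canonical
   5-mer profiles of the large contigs (>= 2,500 nt by default);
2. summarize each bin by the first principal component (PC1) of its
   contigs' coverage profiles and of their k-mer profiles;
3. score every small candidate contig (300-2,500 nt) by the mean Pearson
   correlation of its two profiles against each bin's PC1 pair;
4. recruit the top-scoring candidates (capped per bin per iteration);
5. merge, recompute signatures, and iterate until assignments stabilize.

Contigs flagged for exclusion (e.g. a promiscuous-k-mer lineage set aside
by the analyst) never enter clustering or recruitment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import ContigRecord

__all__ = [
    "UNASSIGNED",
    "BinningConfig",
    "BinSignature",
    "BinAssignment",
    "canonical_kmers",
    "kmer_profile",
    "clr",
    "seed_bins",
    "bin_pc1",
    "recruit",
    "run_binning",
]

UNASSIGNED = "UNASSIGNED"

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def canonical_kmers(k: int = 5) -> list[str]:
    """Lexicographically sorted canonical k-mers (min of k-mer and its
    reverse complement); 512 of them for k = 5."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    seen = set()
    for tup in itertools.product("ACGT", repeat=k):
        kmer = "".join(tup)
        rc = "".join(comp[b] for b in reversed(kmer))
        seen.add(min(kmer, rc))
    return sorted(seen)


def _canonical_index(k: int) -> tuple[np.ndarray, int]:
    """Map each of the 4**k integer-encoded k-mers to a canonical column."""
    n = 4**k
    codes = np.arange(n)
    digits = np.empty((k, n), dtype=np.int64)
    tmp = codes.copy()
    for j in range(k - 1, -1, -1):
        digits[j] = tmp % 4
        tmp //= 4
    # reverse complement: complement each digit (3 - d), reverse the order
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        rc = rc * 4 + (3 - digits[k - 1 - j])
    canon = np.minimum(codes, rc)
    uniq, inv = np.unique(canon, return_inverse=True)
    return inv, len(uniq)


def kmer_profile(
    contigs: Sequence[ContigRecord], k: int = 5
) -> pd.DataFrame:
    """Raw canonical k-mer counts, one row per contig.

    Windows containing any non-ACGT character are skipped, so each row sums
    to (length - k + 1) minus the skipped windows.
    """
    inv, n_canon = _canonical_index(k)
    cols = canonical_kmers(k)
    rows = np.zeros((len(contigs), n_canon), dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1)
    for i, contig in enumerate(contigs):
        seq = contig.sequence.upper()
        if len(seq) < k:
            raise ValueError(
                f"contig {contig.contig_id!r} is shorter than k={k}"
            )
        codes = np.fromiter(
            (_BASE_CODE.get(b, -1) for b in seq), dtype=np.int64, count=len(seq)
        )
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (win >= 0).all(axis=1)
        if valid.any():
            enc = win[valid] @ weights
            rows[i] = np.bincount(inv[enc], minlength=n_canon)
    return pd.DataFrame(rows, index=[c.contig_id for c in contigs], columns=cols)


def clr(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform: log(x + pc) minus its row mean.

    Rows of the result sum to zero; in the pc -> 0 limit the transform is
    invariant to row scaling.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log(counts.to_numpy(dtype=float) + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=counts.index, columns=counts.columns)


@dataclass
class BinSignature:
    """Per-bin PC1 summaries in coverage space and k-mer space."""

    bin_id: str
    pc1_coverage: np.ndarray
    pc1_kmer: np.ndarray
    evf_coverage: float
    evf_kmer: float
    degenerate: bool = False


@dataclass
class BinAssignment:
    """contig_id -> bin_id (or UNASSIGNED) with bookkeeping."""

    assignment: dict[str, str]
    iteration_count: int = 0
    converged: bool = False
    scores: dict[str, float] = field(default_factory=dict)
    iteration_recruited: dict[str, int] = field(default_factory=dict)

    def bins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, bid in self.assignment.items():
            if bid != UNASSIGNED:
                out.setdefault(bid, []).append(cid)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": list(self.assignment),
                "bin_id": list(self.assignment.values()),
                "score": [self.scores.get(c, np.nan) for c in self.assignment],
                "iteration_recruited": [
                    self.iteration_recruited.get(c, 0) for c in self.assignment
                ],
            }
        )


@dataclass(frozen=True)
class BinningConfig:
    k: int = 5
    pseudocount: float = 1.0
    large_min: int = 2500  # inclusive lower bound for seed contigs
    candidate_min: int = 300  # candidates live in [candidate_min, large_min)
    min_cluster_size: int = 10
    top_n: int = 500
    r_min: float = 0.5
    max_iter: int = 10
    change_tol: float = 0.01
    random_state: int = 0


def _pca_embedding(random_state: int) -> Callable[[np.ndarray], np.ndarray]:
    from sklearn.decomposition import PCA

    def embed(X: np.ndarray) -> np.ndarray:
        return PCA(n_components=2, random_state=random_state).fit_transform(X)

    return embed


def _dbscan_labels(emb: np.ndarray, min_cluster_size: int) -> np.ndarray:
    """Density-based clustering with a data-driven radius: three times the
    median distance to the min_cluster_size-th neighbor."""
    from sklearn.cluster import DBSCAN
    from sklearn.neighbors import NearestNeighbors

    kk = min(min_cluster_size, len(emb) - 1)
    if kk < 1:
        return np.zeros(len(emb), dtype=int)
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(emb)
    dists, _ = nn.kneighbors(emb)
    eps = 3.0 * float(np.median(dists[:, -1]))
    if eps <= 0:
        eps = 1e-12
    return DBSCAN(eps=eps, min_samples=min_cluster_size).fit_predict(emb)


def seed_bins(
    kmer_clr: pd.DataFrame,
    min_cluster_size: int = 10,
    embedding_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    random_state: int = 0,
) -> BinAssignment:
    """Cluster large contigs into initial bins on a 2-D embedding of their
    CLR k-mer profiles; small clusters and density outliers stay
    UNASSIGNED. Raises if no contigs are available to bin."""
    if len(kmer_clr) == 0:
        raise ValueError("no binnable contigs")
    if len(kmer_clr) < min_cluster_size:
        raise ValueError(
            f"need at least min_cluster_size={min_cluster_size} large contigs, "
            f"got {len(kmer_clr)}"
        )
    embed = embedding_fn or _pca_embedding(random_state)
    emb = np.asarray(embed(kmer_clr.to_numpy()))
    labels = _dbscan_labels(emb, min_cluster_size)

    assignment: dict[str, str] = {}
    sizes = pd.Series(labels[labels >= 0]).value_counts()
    keep = [lab for lab, n in sizes.items() if n >= min_cluster_size]
    # stable bin naming: largest cluster first, ties by raw label
    keep.sort(key=lambda lab: (-sizes[lab], lab))
    rename = {lab: f"bin_{i + 1}" for i, lab in enumerate(keep)}
    for cid, lab in zip(kmer_clr.index, labels):
        assignment[cid] = rename.get(lab, UNASSIGNED)
    return BinAssignment(assignment=assignment)


def _pc1(X: np.ndarray, center: bool = False) -> tuple[np.ndarray, float, bool]:
    """Leading right singular vector of the bin's profile matrix.

    With ``center=False`` (the default used for recruitment) this is the
    eigendecomposition of the uncentered second-moment matrix, whose
    leading axis approximates the bin's normalized mean profile — a
    representative vector candidates can be correlated against. With
    ``center=True`` it is the leading eigenvector of the sample covariance
    (the within-bin direction of greatest variance). Degenerate inputs
    (single row, or zero spread) fall back to the normalized mean profile,
    flagged.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        v = X.mean(axis=0)
        norm = np.linalg.norm(v)
        v = v / norm if norm > 0 else v
        return _fix_sign(v), float("nan"), True
    M = X - X.mean(axis=0) if center else X
    total = float((M**2).sum())
    if total <= 1e-300:
        v = X.mean(axis=0)
        norm = np.linalg.norm(v)
        v = v / norm if norm > 0 else v
        return _fix_sign(v), float("nan"), True
    _, s, vt = np.linalg.svd(M, full_matrices=False)
    evf = float(s[0] ** 2 / (s**2).sum())
    return _fix_sign(vt[0]), evf, False


def _fix_sign(v: np.ndarray) -> np.ndarray:
    if len(v) and v[np.argmax(np.abs(v))] < 0:
        return -v
    return v


def bin_pc1(
    bin_id: str,
    contig_ids: Sequence[str],
    coverage: pd.DataFrame,
    kmer_clr: pd.DataFrame,
    center: bool = False,
) -> BinSignature:
    """PC1 signature of one bin in coverage space (subjects axis) and k-mer
    space. ``coverage`` is subjects x contigs; rows of the bin submatrix are
    contigs. Degenerate bins (one contig, or zero variance) are flagged and
    summarized by their normalized mean profile. See ``_pc1`` for the
    centered-vs-uncentered choice; the uncentered representative vector is
    what recruitment correlates candidates against."""
    cov_rows = coverage[list(contig_ids)].to_numpy().T  # contigs x subjects
    kmer_rows = kmer_clr.loc[list(contig_ids)].to_numpy()
    pc_cov, evf_cov, deg_cov = _pc1(cov_rows, center=center)
    pc_kmer, evf_kmer, deg_kmer = _pc1(kmer_rows, center=center)
    return BinSignature(
        bin_id=bin_id,
        pc1_coverage=pc_cov,
        pc1_kmer=pc_kmer,
        evf_coverage=evf_cov,
        evf_kmer=evf_kmer,
        degenerate=deg_cov or deg_kmer,
    )


def _pearson_to_vector(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r between each row and vector v; rows or v with zero
    variance correlate 0."""
    rows = np.asarray(rows, dtype=float)
    v = np.asarray(v, dtype=float)
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    rn = np.linalg.norm(rc, axis=1)
    vn = np.linalg.norm(vc)
    denom = rn * vn
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ vc) / denom
    r[~np.isfinite(r)] = 0.0
    return r


def recruit(
    signatures: Mapping[str, BinSignature],
    candidate_ids: Sequence[str],
    coverage: pd.DataFrame,
    kmer_clr: pd.DataFrame,
    top_n: int = 500,
    r_min: float = 0.5,
) -> dict[str, tuple[str, float]]:
    """Assign candidates to bins by combined PC1 correlation.

    Each candidate's score against a bin is the unweighted mean of the
    Pearson correlations of its coverage profile with pc1_coverage and of
    its CLR k-mer profile with pc1_kmer. A candidate goes to its argmax bin
    when the score reaches ``r_min``; each bin accepts at most ``top_n``
    recruits per call, highest scores first, ties broken by contig id.
    """
    if not candidate_ids:
        return {}
    bin_ids = sorted(signatures)
    cov_rows = coverage[list(candidate_ids)].to_numpy().T
    kmer_rows = kmer_clr.loc[list(candidate_ids)].to_numpy()
    score = np.empty((len(candidate_ids), len(bin_ids)))
    for j, bid in enumerate(bin_ids):
        sig = signatures[bid]
        r_cov = _pearson_to_vector(cov_rows, sig.pc1_coverage)
        r_kmer = _pearson_to_vector(kmer_rows, sig.pc1_kmer)
        score[:, j] = 0.5 * (r_cov + r_kmer)
    best = score.argmax(axis=1)
    best_score = score[np.arange(len(candidate_ids)), best]

    per_bin: dict[str, list[tuple[float, str]]] = {b: [] for b in bin_ids}
    for cid, j, s in zip(candidate_ids, best, best_score):
        if s >= r_min:
            per_bin[bin_ids[j]].append((float(s), cid))
    out: dict[str, tuple[str, float]] = {}
    for bid, entries in per_bin.items():
        entries.sort(key=lambda t: (-t[0], t[1]))
        for s, cid in entries[:top_n]:
            out[cid] = (bid, s)
    return out


def run_binning(
    contigs: Sequence[ContigRecord],
    coverage: pd.DataFrame,
    config: BinningConfig = BinningConfig(),
    embedding_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> BinAssignment:
    """Full iterative binning: seed on large contigs, then alternately
    recompute bin PC1 signatures and re-recruit small candidates until
    fewer than ``change_tol`` of assignments move (or ``max_iter``)."""
    usable = [c for c in contigs if not c.exclusion_flag and c.length >= config.k]
    if not usable:
        raise ValueError("no binnable contigs")
    profile = kmer_profile(usable, k=config.k)
    kmer_clr = clr(profile, pseudocount=config.pseudocount)

    large = [c.contig_id for c in usable if c.length >= config.large_min]
    cands = [
        c.contig_id
        for c in usable
        if config.candidate_min <= c.length < config.large_min
    ]
    if not large:
        raise ValueError("no large contigs available for seed binning")

    seed = seed_bins(
        kmer_clr.loc[large],
        min_cluster_size=config.min_cluster_size,
        embedding_fn=embedding_fn,
        random_state=config.random_state,
    )
    assignment = dict(seed.assignment)
    for cid in cands:
        assignment[cid] = UNASSIGNED
    result = BinAssignment(assignment=assignment)
    if config.max_iter == 0:
        return result

    for it in range(1, config.max_iter + 1):
        bins = result.bins()
        signatures = {
            bid: bin_pc1(bid, members, coverage, kmer_clr)
            for bid, members in bins.items()
        }
        recruited = recruit(
            signatures,
            cands,
            coverage,
            kmer_clr,
            top_n=config.top_n,
            r_min=config.r_min,
        )
        new_assignment = dict(seed.assignment)
        for cid in cands:
            new_assignment[cid] = UNASSIGNED
        for cid, (bid, s) in recruited.items():
            new_assignment[cid] = bid
            result.scores[cid] = s
            result.iteration_recruited.setdefault(cid, it)
        changed = sum(
            1 for cid in new_assignment if new_assignment[cid] != result.assignment[cid]
        )
        frac = changed / max(len(new_assignment), 1)
        result.assignment = new_assignment
        result.iteration_count = it
        if frac < config.change_tol:
            result.converged = True
            break
    return result


def write_bin_tsv(result: BinAssignment, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def write_bin_fastas(
    result: BinAssignment, contigs: Sequence[ContigRecord], outdir
) -> None:
    from pathlib import Path

    from .synthetic_data import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {c.contig_id: c for c in contigs}
    for bid, members in result.bins().items():
        write_fasta([by_id[m] for m in members if m in by_id], outdir / f"{bid}.fasta")
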