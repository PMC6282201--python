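"""Contig TPM normalization, bin-level abundance, and standardization.

TPM is adapted from transcript-per-million with contigs playing the role
of transcripts: per-kilobase read rates renormalized to a million per
subject. This makes subjects comparable despite the wide contig-length
distribution of a metagenome coassembly. Bin abundances are sums of member
contigs' TPM; the standardization chain used by the network and
variance-decomposition stages is proportion -> log -> per-feature z-score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .kmer_binning import UNASSIGNED, BinAssignment

__all__ = ["contig_tpm", "bin_abundance", "standardize", "UNBINNED"]

UNBINNED = "unbinned"


def contig_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Subjects x contigs TPM matrix.

    rate_ij = count_ij / (length_j / 1000); TPM rescales each subject's
    rates to sum to 1e6. Subjects with no mapped reads get a zero row (with
    a warning), not an error.
    """
    lengths = lengths.reindex(counts.columns)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise KeyError(f"missing contig lengths for: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    rate = counts.to_numpy(dtype=float) / (lengths.to_numpy(dtype=float) / 1000.0)
    totals = rate.sum(axis=1, keepdims=True)
    zero_rows = totals[:, 0] == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} subject(s) have zero total counts; "
            "their TPM rows are all zero"
        )
        totals[zero_rows] = 1.0
    tpm = rate / totals * 1e6
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def bin_abundance(
    tpm: pd.DataFrame,
    assignment: BinAssignment,
    unbinned_label: str = UNBINNED,
) -> pd.DataFrame:
    """Sum member-contig TPM columns per bin; contigs that are UNASSIGNED
    (or absent from the assignment) pool into an ``unbinned`` column so the
    per-subject total is conserved."""
    groups: dict[str, list[str]] = {}
    for cid in tpm.columns:
        bid = assignment.assignment.get(cid, UNASSIGNED)
        groups.setdefault(unbinned_label if bid == UNASSIGNED else bid, []).append(cid)
    cols = {}
    for bid in sorted(groups):
        members = groups[bid]
        if not members:
            warnings.warn(f"bin {bid} has no contigs; dropped")
            continue
        cols[bid] = tpm[members].sum(axis=1)
    return pd.DataFrame(cols, index=tpm.index)


def standardize(
    abundance: pd.DataFrame, pseudocount: float = 1e-4, ddof: int = 1
) -> pd.DataFrame:
    """Proportion -> log -> z-score per feature.

    A pseudocount guards the log when zeros are present. Zero-variance
    features cannot be z-scored and are dropped with a warning. The z-score
    uses the sample (ddof=1) standard deviation by default.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = abundance.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("cannot standardize subjects with zero total abundance")
    props = values / totals
    if (props == 0).any():
        if pseudocount == 0:
            raise ValueError("zeros present; a positive pseudocount is required")
        props = props + pseudocount
    logged = np.log(props)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        dropped = abundance.columns[~keep].tolist()
        warnings.warn(f"dropping zero-variance feature(s): {dropped[:5]}")
    z = (logged[:, keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=abundance.index, columns=abundance.columns[keep])
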