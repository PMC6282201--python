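"""Phenotype enrichment statistics and alpha-diversity summaries.

Effect sizes are mean pairwise log2 fold changes across all cross-cohort
pairs; significance comes from the (two-sided) Mann-Whitney U test at an
inclusive alpha of 0.05 with no multiplicity correction by default.
Functional enrichment is run in three contexts: taxa via abundance
(context 1), modules via the full PBFP profile ("anchored", context 2),
and modules via PBFP restricted to the context-1-significant taxa
("unanchored", context 3); the anchored/unanchored overlap is reported as
Venn counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .function_potential import pbfp

__all__ = [
    "pairwise_mean_log2fc",
    "mwu_test",
    "shannon_entropy",
    "kde_mode",
    "EnrichmentResult",
    "enrichment_contexts",
]


def pairwise_mean_log2fc(values_a, values_b, pseudocount: float = 0.0) -> float:
    """Mean of log2((a + pc)/(b + pc)) over all |A| x |B| cross pairs.

    Antisymmetric in its arguments; positive values mean enrichment in A.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    return float(np.subtract.outer(la, lb).mean())


def mwu_test(
    values_a, values_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U with tie-corrected normal approximation; exact null
    distribution when both groups have <= 8 observations and no ties span
    the pooled sample. Fully tied data yield p = 1 with a warning."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p set to 1")
        return float(a.size * b.size / 2), 1.0
    method = "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def shannon_entropy(abundance_row, base: float = 2.0) -> float:
    """Shannon entropy of a (nonnegative, not all-zero) abundance vector
    after normalization to proportions; zero proportions contribute 0."""
    x = np.asarray(abundance_row, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance row")
    p = x / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def kde_mode(sample, bw_method="scott", grid_size: int = 512) -> float:
    """Mode of a Gaussian kernel density estimate, located on a grid of
    ``grid_size`` points spanning the data +- 3 bandwidths. A constant
    sample returns that constant."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]):
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method=bw_method)
    h = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class EnrichmentResult:
    context1: pd.DataFrame  # taxa via abundance
    context2: pd.DataFrame  # modules via full PBFP (anchored)
    context3: pd.DataFrame  # modules via PBFP on significant taxa (unanchored)
    venn: dict = field(default_factory=dict)


def _split_groups(metadata: pd.DataFrame, group_col: str, contrast: str):
    caries = metadata[group_col].astype(str)
    if contrast == "caries":
        mask_a = caries.isin(["enamel", "dentin"])
        mask_b = caries == "negative"
        labels = ("caries", "healthy")
    elif contrast == "depth":
        mask_a = caries == "dentin"
        mask_b = caries == "enamel"
        labels = ("dentin", "enamel")
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return metadata.index[mask_a], metadata.index[mask_b], labels


def _enrichment_table(
    values: pd.DataFrame,
    idx_a,
    idx_b,
    labels: tuple[str, str],
    alpha: float,
    pseudocount: float,
) -> pd.DataFrame:
    rows = []
    for feat in values.columns:
        a = values.loc[idx_a, feat].to_numpy()
        b = values.loc[idx_b, feat].to_numpy()
        lfc = pairwise_mean_log2fc(a, b, pseudocount=pseudocount)
        u, p = mwu_test(a, b)
        rows.append(
            {
                "feature_id": feat,
                "mean_pairwise_log2fc": lfc,
                "u_statistic": u,
                "p_value": p,
                "direction": labels[0] if lfc >= 0 else labels[1],
                "significant": p <= alpha,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def enrichment_contexts(
    abundance: pd.DataFrame,
    mcr: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    contrast: str = "caries",
    pseudocount: float = 1e-4,
) -> EnrichmentResult:
    """Run the three enrichment contexts and the anchored/unanchored Venn.

    ``abundance`` is subjects x bins (TPM-summed), ``mcr`` is bins x
    modules. Context 1 tests bins on abundance; context 2 (anchored) tests
    modules on PBFP = abundance . MCR; context 3 (unanchored) tests modules
    on the PBFP restricted to the context-1-significant bins.
    """
    common = abundance.index.intersection(metadata.index)
    if len(common) < len(abundance.index):
        raise ValueError("metadata does not cover all subjects")
    idx_a, idx_b, labels = _split_groups(metadata.loc[abundance.index], "caries", contrast)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each cohort needs at least 2 subjects")

    bins = [b for b in abundance.columns if b in mcr.index]
    ctx1 = _enrichment_table(abundance, idx_a, idx_b, labels, alpha, pseudocount)

    A_full = pbfp(abundance[bins], mcr.loc[bins])
    ctx2 = _enrichment_table(A_full, idx_a, idx_b, labels, alpha, pseudocount)

    sig_bins = [b for b in bins if ctx1.loc[b, "significant"]]
    if sig_bins:
        A_sig = pbfp(abundance[sig_bins], mcr.loc[sig_bins])
        ctx3 = _enrichment_table(A_sig, idx_a, idx_b, labels, alpha, pseudocount)
    else:
        ctx3 = ctx2.iloc[0:0].copy()

    anchored = set(ctx2.index[ctx2["significant"]])
    unanchored = set(ctx3.index[ctx3["significant"]]) if len(ctx3) else set()
    venn = {
        "anchored_only": len(anchored - unanchored),
        "unanchored_only": len(unanchored - anchored),
        "overlap": len(anchored & unanchored),
        "overlap_modules": sorted(anchored & unanchored),
    }
    return EnrichmentResult(context1=ctx1, context2=ctx2, context3=ctx3, venn=venn)
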