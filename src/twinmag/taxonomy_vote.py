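"""Bin taxonomy by a running-sum vote over per-ORF best-hit identities.

Each ORF contributes its percent amino-acid identity to the species-level
ancestor of its hit taxon; the species with the maximum summed identity
labels the bin. Ties are reported as ``ambiguous`` with the candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["Taxonomy", "VoteResult", "weighted_taxon_vote"]

AMBIGUOUS = "ambiguous"


class Taxonomy:
    """Parent-pointer taxonomy from a table with columns
    taxon_id, parent_id, rank, name. A root points to itself."""

    def __init__(self, table: pd.DataFrame):
        required = {"taxon_id", "parent_id", "rank", "name"}
        if not required.issubset(table.columns):
            raise ValueError(f"taxonomy table needs columns {sorted(required)}")
        self.parent = dict(zip(table["taxon_id"], table["parent_id"]))
        self.rank = dict(zip(table["taxon_id"], table["rank"]))
        self.name = dict(zip(table["taxon_id"], table["name"]))

    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        return cls(pd.read_csv(path, sep="\t"))

    def species_ancestor(self, taxon_id) -> str | None:
        """Walk parent pointers until a species-rank node; None if the
        lineage never passes through one."""
        seen = set()
        tid = taxon_id
        while tid in self.parent and tid not in seen:
            seen.add(tid)
            if self.rank.get(tid) == "species":
                return tid
            parent = self.parent[tid]
            if parent == tid:
                break
            tid = parent
        return None


@dataclass
class VoteResult:
    label: str
    scores: pd.Series  # summed identity per species taxon_id
    candidates: tuple = ()


def weighted_taxon_vote(
    hits: pd.DataFrame, taxonomy: Taxonomy, best_hit_only: bool = True
) -> VoteResult:
    """Species label for one bin's ORF hit table.

    ``hits`` has columns orf_id, contig_id, taxon_id, identity (percent
    amino-acid identity in [0, 100]). With ``best_hit_only`` each ORF
    contributes only its highest-identity hit. Hits whose taxon cannot be
    resolved to a species are skipped with a warning; if none resolve, an
    error is raised.
    """
    required = {"orf_id", "taxon_id", "identity"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hit table needs columns {sorted(required)}")
    if hits.empty:
        raise ValueError("no hits for this bin")
    ident = hits["identity"]
    if ((ident < 0) | (ident > 100)).any():
        raise ValueError("identities must lie in [0, 100]")
    if best_hit_only:
        hits = hits.loc[hits.groupby("orf_id")["identity"].idxmax()]

    scores: dict = {}
    skipped = 0
    for _, row in hits.iterrows():
        sp = taxonomy.species_ancestor(row["taxon_id"])
        if sp is None:
            skipped += 1
            continue
        scores[sp] = scores.get(sp, 0.0) + float(row["identity"])
    if skipped:
        warnings.warn(f"skipped {skipped} hit(s) with unresolvable taxa")
    if not scores:
        raise ValueError("no hits resolved to a species-level taxon")

    series = pd.Series(scores).sort_values(ascending=False)
    top = series.iloc[0]
    winners = tuple(sorted(series.index[series == top]))
    if len(winners) > 1:
        return VoteResult(label=AMBIGUOUS, scores=series, candidates=winners)
    name = taxonomy.name.get(winners[0], str(winners[0]))
    return VoteResult(label=name, scores=series, candidates=winners)
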