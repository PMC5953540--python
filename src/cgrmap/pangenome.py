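"""Ortholog clustering, presence/absence matrices and conservation ranking.

Protein-coding genes from a strain collection are grouped into orthologous
clusters by single-linkage over pairs passing a global amino-acid identity
threshold (default 60%) with bidirectional coverage (the aligned span must
cover at least 80% of *both* sequences). Clusters are classified core
(present in every genome), singleton (one genome) or accessory (the rest),
and each non-singleton cluster gets a conservation score: the mean pairwise
global identity over its members. A cluster of interest can then be ranked
as a conservation percentile within the pan, core or accessory genome.

All-vs-all alignment is pruned with an amino-acid 8-mer inverted index
(two shared 8-mers propose a candidate pair) and union-find short-circuiting;
on gene families separated by more than the identity threshold this is exact
with respect to plain single linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .alignment import (AA_SCORING, ScoringScheme, SequenceRecord,
                        global_align, global_identity)


@dataclass
class GeneRecord:
    """An annotated protein-coding gene within one genome."""

    genome_id: str
    gene_id: str
    protein: SequenceRecord
    cds: SequenceRecord | None = None
    contig: str = ""
    start: int = 0          # 1-based inclusive
    end: int = 0
    strand: str = "+"

    def __post_init__(self):
        if self.protein.alphabet != "aa":
            raise ValueError(f"{self.gene_id}: protein record must be amino acid")
        if self.end and self.start and self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    def check_translation(self) -> bool:
        """Whether the CDS translates (standard code, trailing stop stripped)
        to the stored protein."""
        if self.cds is None:
            return True
        prot = str(Seq(self.cds.residues).translate())
        return prot.rstrip("*") == self.protein.residues


@dataclass
class OrthologCluster:
    cluster_id: str
    members: list[GeneRecord]
    mean_conservation: float | None = None

    @property
    def representative(self) -> GeneRecord:
        """Longest member; ties broken by gene id."""
        return min(self.members, key=lambda g: (-len(g.protein), g.gene_id))

    @property
    def genome_ids(self) -> set[str]:
        return {g.genome_id for g in self.members}


@dataclass
class PangenomeMatrix:
    """Genomes x ortholog-cluster boolean presence/absence."""

    presence: pd.DataFrame          # bool, index=genome ids, columns=cluster ids
    class_per_cluster: pd.Series    # 'core' | 'accessory' | 'singleton'

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.presence.columns)

    def class_counts(self) -> dict[str, int]:
        c = self.class_per_cluster.value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("core", "accessory", "singleton")}


# ---------------------------------------------------------------------------
# Ortholog clustering

_KMER = 8


def _kmers(seq: str, k: int = _KMER) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _candidate_pairs(genes: Sequence[GeneRecord]) -> Iterable[tuple[int, int]]:
    """Pairs sharing >=2 distinct protein 8-mers (>=1 for short proteins)."""
    index: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        for km in _kmers(g.protein.residues):
            index.setdefault(km, []).append(i)
    shared: dict[tuple[int, int], int] = {}
    for hits in index.values():
        if len(hits) < 2 or len(hits) > 200:   # skip low-complexity mega-buckets
            continue
        for a in range(len(hits)):
            for b in range(a + 1, len(hits)):
                pair = (hits[a], hits[b])
                shared[pair] = shared.get(pair, 0) + 1
    for (i, j), count in sorted(shared.items()):
        need = 2 if min(len(genes[i].protein), len(genes[j].protein)) >= 2 * _KMER else 1
        if count >= need:
            yield i, j


def _homolog_linked(a: GeneRecord, b: GeneRecord, min_identity: float,
                    min_coverage: float, scoring: ScoringScheme) -> bool:
    aln = global_align(a.protein, b.protein, scoring)
    if global_identity(aln) < min_identity:
        return False
    cov_a = 100.0 * aln.aligned_cols / len(a.protein)
    cov_b = 100.0 * aln.aligned_cols / len(b.protein)
    return cov_a >= min_coverage and cov_b >= min_coverage


def cluster_orthologs(genes: Sequence[GeneRecord], min_identity: float = 60.0,
                      min_coverage: float = 80.0,
                      scoring: ScoringScheme = AA_SCORING) -> list[OrthologCluster]:
    """Single-linkage ortholog clusters over the homolog-pair graph.

    Two genes are linked when their global amino-acid identity is at least
    ``min_identity`` percent and the aligned span covers at least
    ``min_coverage`` percent of both sequences. Clusters are the connected
    components; ids ``OC00001, ...`` are assigned in sorted order of each
    cluster's lexicographically smallest gene id, so output is deterministic.
    """
    if not genes:
        raise ValueError("at least one gene required")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("gene ids must be unique")

    parent = list(range(len(genes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in _candidate_pairs(genes):
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if _homolog_linked(genes[i], genes[j], min_identity, min_coverage, scoring):
            parent[rj] = ri

    comps: dict[int, list[GeneRecord]] = {}
    for i, g in enumerate(genes):
        comps.setdefault(find(i), []).append(g)
    ordered = sorted(comps.values(), key=lambda ms: min(g.gene_id for g in ms))
    return [OrthologCluster(cluster_id=f"OC{k + 1:05d}",
                            members=sorted(ms, key=lambda g: g.gene_id))
            for k, ms in enumerate(ordered)]


def build_matrix(clusters: Sequence[OrthologCluster],
                 genome_ids: Sequence[str]) -> PangenomeMatrix:
    """Boolean presence/absence matrix with core/accessory/singleton classes.

    A cell is true when the genome contributes at least one gene to the
    cluster (paralogs do not change presence). Raises on member genomes
    absent from ``genome_ids``.
    """
    genome_ids = list(genome_ids)
    known = set(genome_ids)
    data = {}
    for cl in clusters:
        unknown = cl.genome_ids - known
        if unknown:
            raise ValueError(f"cluster {cl.cluster_id} references unknown "
                             f"genome(s): {sorted(unknown)}")
        data[cl.cluster_id] = [g in cl.genome_ids for g in genome_ids]
    presence = pd.DataFrame(data, index=genome_ids, dtype=bool)
    n = len(genome_ids)
    counts = presence.sum(axis=0)
    cls = pd.Series(
        np.where(counts == n, "core",
                 np.where(counts == 1, "singleton", "accessory")),
        index=presence.columns, name="class")
    return PangenomeMatrix(presence=presence, class_per_cluster=cls)


def cluster_conservation(cluster: OrthologCluster,
                         scoring: ScoringScheme = AA_SCORING) -> float | None:
    """Mean pairwise global amino-acid identity over all member pairs.

    Undefined (None) for singletons; these are excluded from conservation
    distributions.
    """
    ms = cluster.members
    if len(ms) < 2:
        return None
    vals = []
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            vals.append(global_identity(global_align(ms[i].protein,
                                                     ms[j].protein, scoring)))
    cons = float(np.mean(vals))
    cluster.mean_conservation = cons
    return cons


def conservation_table(clusters: Sequence[OrthologCluster],
                       matrix: PangenomeMatrix,
                       scoring: ScoringScheme = AA_SCORING) -> pd.DataFrame:
    """Per-cluster class and conservation (non-singleton clusters only)."""
    rows = []
    for cl in clusters:
        klass = matrix.class_per_cluster.get(cl.cluster_id)
        if klass == "singleton":
            continue
        cons = (cl.mean_conservation if cl.mean_conservation is not None
                else cluster_conservation(cl, scoring))
        rows.append((cl.cluster_id, klass, cons))
    return pd.DataFrame(rows, columns=["cluster_id", "class", "conservation"])


def conservation_percentile(query_conservation: float,
                            table: pd.DataFrame,
                            scope: str = "pan") -> float:
    """Percentile rank of a conservation value within a scope distribution.

    ``scope`` is 'pan' (all non-singleton clusters), 'core' or 'accessory'.
    Percentile = 100 * (# clusters with conservation <= query) / n; the query
    need not belong to the scope.
    """
    if scope == "pan":
        dist = table["conservation"]
    elif scope in ("core", "accessory"):
        dist = table.loc[table["class"] == scope, "conservation"]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    dist = dist.dropna()
    if dist.empty:
        raise ValueError(f"scope {scope!r} has no clusters with conservation")
    return 100.0 * float((dist <= query_conservation).sum()) / len(dist)
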