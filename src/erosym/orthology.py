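"""Orthogroup clustering and core-genome selection.

Desk-scale orthology: proteins are nodes, an edge joins two proteins from
different (or the same) genome when a global alignment reaches the identity
and coverage floors, and orthogroups are the connected components. This is a
deliberate simplification of tree-reconciled hierarchical orthogroup
inference, adequate at simulated divergences and fully deterministic.

Core-set selection keeps single-copy orthogroups whose prevalence is
strictly greater than the threshold ("present in more than X% of genomes"),
after excluding orthogroups touched by pseudogenes or putative-HGT genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.sparse import csr_matrix
from scipy.spatial.distance import pdist

_AA = "ACDEFGHIKLMNPQRSTVWYX"  # 20 residues plus X for unknown/stop-read-through


@dataclass
class OrthogroupTable:
    """og_id → {genome_id → [gene_ids]} plus derived per-og flags."""

    members: dict[str, dict[str, list[str]]]
    n_genomes: int
    genome_ids: list[str] = field(default_factory=list)

    def prevalence(self, og_id: str) -> float:
        return len(self.members[og_id]) / self.n_genomes

    def single_copy(self, og_id: str) -> bool:
        return all(len(v) == 1 for v in self.members[og_id].values())

    def genes_of(self, og_id: str) -> set[str]:
        return {g for genes in self.members[og_id].values() for g in genes}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"og_id": og, "genome_id": gid, "gene_id": gene}
            for og, by_genome in sorted(self.members.items())
            for gid, genes in sorted(by_genome.items())
            for gene in genes
        ]
        return pd.DataFrame(rows, columns=["og_id", "genome_id", "gene_id"])


def _kmer_candidates(names, seqs, kmer: int = 4, min_shared: int = 2):
    """Sparse k-mer cosharing prefilter: pairs sharing >= min_shared k-mers.

    Proteins that cannot reach ~50% identity share essentially no 4-mers, so
    skipping un-cosharing pairs changes nothing at desk-scale divergences
    while making clustering near-linear.
    """
    n = len(seqs)
    rows, cols = [], []
    vocab: dict[str, int] = {}
    for i, s in enumerate(seqs):
        kms = {s[j : j + kmer] for j in range(len(s) - kmer + 1)}
        for km in kms:
            idx = vocab.setdefault(km, len(vocab))
            rows.append(i)
            cols.append(idx)
    M = csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)), shape=(n, len(vocab))
    )
    S = (M @ M.T).tocoo()
    for i, j, v in zip(S.row, S.col, S.data):
        if i < j and v >= min_shared:
            yield int(i), int(j)


def protein_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage) from a global alignment.

    Identity is (longer_len − edit_distance)/longer_len — a conservative
    global identity — and coverage is shorter/longer (a global alignment
    spans both sequences fully).
    """
    la, lb = len(a), len(b)
    longer = max(la, lb)
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return (longer - d) / longer, min(la, lb) / longer


def cluster_orthogroups(
    proteomes: dict[str, dict[str, str]],
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
    prefilter: bool = True,
) -> OrthogroupTable:
    """Cluster proteins across genomes into orthogroups (connected components).

    ``proteomes`` maps genome_id → {gene_id → protein sequence}. Orthogroup
    ids are assigned by the lexicographically smallest (genome_id, gene_id)
    member, so the result is independent of input order.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    for gid, prot in proteomes.items():
        if not prot:
            raise ValueError(f"empty proteome for genome {gid!r}")
        for gene, seq in prot.items():
            bad = set(seq) - set(_AA)
            if bad:
                raise ValueError(
                    f"protein {gene!r} in {gid!r}: non-standard residues {sorted(bad)}"
                )

    nodes = sorted(
        (gid, gene, seq)
        for gid, prot in proteomes.items()
        for gene, seq in prot.items()
    )
    names = [(gid, gene) for gid, gene, _ in nodes]
    seqs = [seq for _, _, seq in nodes]

    G = nx.Graph()
    G.add_nodes_from(range(len(nodes)))
    if prefilter:
        pairs = _kmer_candidates(names, seqs)
    else:
        n = len(seqs)
        pairs = ((i, j) for i in range(n) for j in range(i + 1, n))
    for i, j in pairs:
        ident, cov = protein_identity(seqs[i], seqs[j])
        if ident >= min_identity and cov >= min_coverage:
            G.add_edge(i, j)

    comps = sorted(
        (sorted(c, key=lambda i: names[i]) for c in nx.connected_components(G)),
        key=lambda c: names[c[0]],
    )
    members: dict[str, dict[str, list[str]]] = {}
    for idx, comp in enumerate(comps):
        og = f"OG{idx:06d}"
        by_genome: dict[str, list[str]] = {}
        for i in comp:
            gid, gene = names[i]
            by_genome.setdefault(gid, []).append(gene)
        members[og] = by_genome
    return OrthogroupTable(
        members=members, n_genomes=len(proteomes), genome_ids=sorted(proteomes)
    )


def select_core(
    table: OrthogroupTable,
    prevalence_threshold: float,
    single_copy_only: bool = True,
    exclude_gene_ids: set[str] | None = None,
) -> set[str]:
    """Single-copy core orthogroups above a strict prevalence threshold.

    Any orthogroup containing an excluded gene (pseudogene or putative-HGT
    gene) is removed whole.
    """
    if not table.members:
        raise ValueError("empty orthogroup table")
    if not (0.0 < prevalence_threshold < 1.0):
        raise ValueError("prevalence_threshold must be in (0, 1)")
    exclude = exclude_gene_ids or set()
    out = set()
    for og in table.members:
        if table.prevalence(og) <= prevalence_threshold:
            continue
        if single_copy_only and not table.single_copy(og):
            continue
        if table.genes_of(og) & exclude:
            continue
        out.add(og)
    return out


def shared_matrix(
    table: OrthogroupTable, genome_order: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Binary genomes × orthogroups presence matrix, columns ordered by
    average-linkage hierarchical clustering on Jaccard distance.

    Row order follows ``genome_order`` (e.g. a tree's tip order) when given.
    """
    if not table.members:
        raise ValueError("empty orthogroup table")
    genomes = genome_order or table.genome_ids
    ogs = sorted(table.members)
    mat = np.zeros((len(genomes), len(ogs)), dtype=int)
    for j, og in enumerate(ogs):
        for i, gid in enumerate(genomes):
            if gid in table.members[og]:
                mat[i, j] = 1
    if len(ogs) > 2:
        cols = mat.T.astype(bool)
        d = pdist(cols, metric="jaccard")
        d = np.nan_to_num(d, nan=0.0)  # identical all-zero columns
        order = leaves_list(linkage(d, method="average"))
    else:
        order = np.arange(len(ogs))
    ordered = [ogs[i] for i in order]
    df = pd.DataFrame(mat[:, order], index=genomes, columns=ordered)
    return df, ordered
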