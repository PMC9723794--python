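"""Reciprocal-best-match orthology, OG clustering and pangenome partitioning.

The pipeline mirrors classic comparative-genomics practice: predicted
proteomes are compared all-versus-all; a pair of genes from two genomes is
a reciprocal best match (RBM) when each is the other's best hit and the
pair passes the 50/50 rule — at least 50% sequence similarity over at
least 50% of the query length, applied to the query side of each
direction independently; orthologous groups (OGs) are Markov clusters of
the RBM graph; and OGs partition into core (present in all genomes),
variable (in two or more but not all) and genome-specific (exactly one).

Downstream, the variable-gene presence/absence matrix clusters genomes by
Euclidean distance, and concatenated core-OG alignments give a
p-distance Neighbor-Joining tree.

"Similarity" is percent identity over the aligned region; both the 50%
similarity and 50% coverage thresholds are inclusive (>=).  Markov
clustering uses inflation 1.5 by default with a connected-components
fallback; on graphs whose components are cliques the two agree exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .aligners import ProteinAligner

Proteomes = Mapping[str, Mapping[str, str]]  # genome -> gene -> sequence
GeneKey = tuple[str, str]  # (genome, gene)


@dataclass(frozen=True)
class SearchHit:
    """One alignment of a query gene against a subject-genome gene."""

    query_genome: str
    query_gene: str
    subject_genome: str
    subject_gene: str
    similarity: float  # percent identity over the aligned region
    query_coverage: float  # aligned fraction of the query, (0, 1]
    score: float  # bitscore-like rank key


@dataclass(frozen=True)
class RbmEdge:
    """A reciprocal best match passing the 50/50 rule in both orientations."""

    genome_a: str
    gene_a: str
    genome_b: str
    gene_b: str
    similarity: float  # mean of the two directions' identities
    similarity_ab: float
    similarity_ba: float


@dataclass(frozen=True)
class OrthologGroup:
    og_id: str
    members: frozenset[GeneKey]


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all(
    proteomes: Proteomes,
    aligner: Optional[ProteinAligner] = None,
    prefilter_k: int = 5,
) -> list[SearchHit]:
    """All-versus-all protein search between every ordered genome pair.

    Self-comparisons are excluded.  A k-mer prefilter skips subject genes
    sharing no ``prefilter_k``-mer with the query — such pairs cannot
    approach the 50/50 homology rule — and the survivors are aligned with
    the local protein aligner.  Output order is deterministic: by query
    genome/gene, then descending score, then subject gene id.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    aligner = aligner or ProteinAligner()
    genome_ids = sorted(proteomes)
    for gid in genome_ids:
        if not proteomes[gid]:
            warnings.warn(f"proteome {gid} is empty; skipped")
    index: dict[str, dict[str, set[str]]] = {}
    for gid in genome_ids:
        idx: dict[str, set[str]] = {}
        for gene, seq in proteomes[gid].items():
            for km in _kmers(seq, prefilter_k):
                idx.setdefault(km, set()).add(gene)
        index[gid] = idx

    hits: list[SearchHit] = []
    for qg in genome_ids:
        for sg in genome_ids:
            if qg == sg:
                continue
            sidx = index[sg]
            for qgene in sorted(proteomes[qg]):
                qseq = proteomes[qg][qgene]
                candidates: set[str] = set()
                for km in _kmers(qseq, prefilter_k):
                    candidates |= sidx.get(km, set())
                pair_hits = []
                for sgene in sorted(candidates):
                    res = aligner.align(qseq, proteomes[sg][sgene])
                    if res is None:
                        continue
                    ident, qcov, score = res
                    pair_hits.append(
                        SearchHit(qg, qgene, sg, sgene, ident, qcov, score)
                    )
                pair_hits.sort(key=lambda h: (-h.score, h.subject_gene))
                hits.extend(pair_hits)
    return hits


def find_rbms(
    hits: Sequence[SearchHit],
    min_similarity: float = 50.0,
    min_coverage: float = 0.5,
) -> list[RbmEdge]:
    """Reciprocal best matches under the 50/50 rule (inclusive thresholds).

    A gene's best hit in a subject genome is the highest-scoring hit, ties
    broken by lexicographically smallest subject gene id.  An edge is
    emitted when best-hit reciprocity holds and each direction passes the
    similarity/coverage filter on its own query side.
    """
    best: dict[tuple[str, str, str], SearchHit] = {}
    for h in hits:
        key = (h.query_genome, h.query_gene, h.subject_genome)
        cur = best.get(key)
        if cur is None or h.score > cur.score or (
            h.score == cur.score and h.subject_gene < cur.subject_gene
        ):
            best[key] = h

    edges: list[RbmEdge] = []
    for (qg, qgene, sg), h in best.items():
        if qg >= sg:
            continue  # emit each unordered pair once, from the a<b side
        back = best.get((sg, h.subject_gene, qg))
        if back is None or back.subject_gene != qgene:
            continue
        ok_fwd = h.similarity >= min_similarity and h.query_coverage >= min_coverage
        ok_rev = back.similarity >= min_similarity and back.query_coverage >= min_coverage
        if not (ok_fwd and ok_rev):
            continue
        edges.append(
            RbmEdge(
                genome_a=qg,
                gene_a=qgene,
                genome_b=sg,
                gene_b=h.subject_gene,
                similarity=(h.similarity + back.similarity) / 2.0,
                similarity_ab=h.similarity,
                similarity_ba=back.similarity,
            )
        )
    edges.sort(key=lambda e: (e.genome_a, e.gene_a, e.genome_b, e.gene_b))
    return edges


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _mcl_components(adj: np.ndarray, inflation: float, max_iter: int = 100,
                    tol: float = 1e-6, prune: float = 1e-8) -> list[list[int]]:
    """Markov clustering on a dense adjacency; returns index clusters.

    Expansion power 2; inflation as given; self-loops of weight 1 added
    before normalisation.  Clusters are the connected components of the
    converged (near block-diagonal) flow matrix, which for disjoint-clique
    inputs equal the graph's connected components.
    """
    n = adj.shape[0]
    m = adj.astype(float).copy()
    np.fill_diagonal(m, 1.0)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        last = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - last).max() < tol:
            break
    link = (m + m.T) > 1e-6
    seen = np.zeros(n, dtype=bool)
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        comp = []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.flatnonzero(link[v]):
                if not seen[w]:
                    seen[w] = True
                    stack.append(int(w))
        clusters.append(sorted(comp))
    return clusters


def cluster_ogs(
    edges: Sequence[RbmEdge],
    all_genes: Optional[Sequence[GeneKey]] = None,
    inflation: float = 1.5,
    method: str = "mcl",
) -> list[OrthologGroup]:
    """Cluster the similarity-weighted RBM graph into orthologous groups.

    ``method="mcl"`` runs Markov clustering (default inflation 1.5);
    ``"components"`` takes plain connected components.  Genes listed in
    ``all_genes`` but touched by no edge become singleton OGs.  Each gene
    belongs to exactly one OG; OG ids are assigned in deterministic order.
    """
    if method not in ("mcl", "components"):
        raise ValueError(f"unknown clustering method {method!r}")
    nodes: list[GeneKey] = sorted(
        {(e.genome_a, e.gene_a) for e in edges} | {(e.genome_b, e.gene_b) for e in edges}
    )
    pos = {k: i for i, k in enumerate(nodes)}
    groups: list[frozenset[GeneKey]] = []
    if nodes:
        if method == "mcl":
            adj = np.zeros((len(nodes), len(nodes)))
            for e in edges:
                i, j = pos[(e.genome_a, e.gene_a)], pos[(e.genome_b, e.gene_b)]
                w = e.similarity / 100.0
                adj[i, j] = max(adj[i, j], w)
                adj[j, i] = max(adj[j, i], w)
            idx_clusters = _mcl_components(adj, inflation)
        else:
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(range(len(nodes)))
            for e in edges:
                g.add_edge(pos[(e.genome_a, e.gene_a)], pos[(e.genome_b, e.gene_b)])
            idx_clusters = [sorted(c) for c in nx.connected_components(g)]
        groups.extend(frozenset(nodes[i] for i in c) for c in idx_clusters)
    if all_genes is not None:
        in_graph = set(nodes)
        for key in sorted(set(all_genes) - in_graph):
            groups.append(frozenset({key}))
    groups.sort(key=lambda m: sorted(m)[0])
    return [OrthologGroup(og_id=f"OG{i:05d}", members=m) for i, m in enumerate(groups)]


# ---------------------------------------------------------------------------
# Pangenome partition
# ---------------------------------------------------------------------------

@dataclass
class PangenomePartition:
    """Core / variable / genome-specific OG counts with the presence matrix."""

    n_total_ogs: int
    n_core: int
    n_variable: int
    n_genome_specific: int
    n_singleton_ogs: int  # OGs with a single gene (subset of genome-specific)
    presence: pd.DataFrame  # genomes x OGs, 0/1
    included_genomes: list[str]

    def __post_init__(self):
        assert self.n_core + self.n_variable + self.n_genome_specific == self.n_total_ogs


def partition_pangenome(
    ogs: Sequence[OrthologGroup],
    genome_ids: Sequence[str],
    completeness: Optional[Mapping[str, float]] = None,
    min_completeness: float = 95.0,
) -> PangenomePartition:
    """Partition OGs by genome presence over sufficiently complete genomes.

    When completeness metadata is provided, genomes below the threshold
    (default 95%) are dropped before counting; OGs whose members all come
    from dropped genomes are removed entirely.  Presence counts genomes,
    not genes, so co-clustered paralogs do not inflate it.
    """
    if not ogs:
        raise ValueError("empty OG set")
    included = [
        g
        for g in genome_ids
        if completeness is None or completeness.get(g, 100.0) >= min_completeness
    ]
    if not included:
        raise ValueError("no genome passes the completeness threshold")
    inc = set(included)
    rows = {}
    singleton = 0
    kept_ogs = []
    for og in ogs:
        genomes_present = sorted({g for g, _ in og.members if g in inc})
        if not genomes_present:
            continue
        kept_ogs.append(og.og_id)
        rows[og.og_id] = genomes_present
        if len([m for m in og.members if m[0] in inc]) == 1:
            singleton += 1
    presence = pd.DataFrame(0, index=included, columns=kept_ogs, dtype=int)
    for og_id, genomes_present in rows.items():
        presence.loc[genomes_present, og_id] = 1
    per_og = presence.sum(axis=0)
    n_core = int((per_og == len(included)).sum()) if len(included) > 1 else int((per_og == 1).sum())
    n_specific = int((per_og == 1).sum()) if len(included) > 1 else 0
    n_variable = len(kept_ogs) - n_core - n_specific
    presence.index.name = "genome_id"
    return PangenomePartition(
        n_total_ogs=len(kept_ogs),
        n_core=n_core,
        n_variable=n_variable,
        n_genome_specific=n_specific,
        n_singleton_ogs=singleton,
        presence=presence,
        included_genomes=included,
    )


def variable_presence(partition: PangenomePartition) -> pd.DataFrame:
    """Presence matrix restricted to variable OGs."""
    per_og = partition.presence.sum(axis=0)
    n = len(partition.included_genomes)
    keep = per_og[(per_og > 1) & (per_og < n)].index
    return partition.presence[keep]


def cluster_genomes_by_variable_genes(presence: pd.DataFrame) -> TreeNode:
    """Average-linkage hierarchy on Euclidean distances between 0/1 rows.

    All-identical rows (zero distances) are joined in deterministic input
    order.  Returns a Newick-serialisable tree.
    """
    if presence.shape[0] < 2:
        raise ValueError("need at least two genomes to cluster")
    dist = pdist(presence.to_numpy(dtype=float), metric="euclidean")
    link = hierarchy.linkage(dist, method="average")
    return TreeNode.from_linkage_matrix(link, list(presence.index))


# ---------------------------------------------------------------------------
# Core-gene concatenation and Neighbor-Joining
# ---------------------------------------------------------------------------

def center_star_align(seqs: Mapping[str, str]) -> dict[str, str]:
    """Center-star multiple alignment (adequate for near-identical members).

    The longest sequence is the center; every other member is globally
    aligned to it and the pairwise alignments are merged on center
    coordinates (per-position maximum gap runs).  Not a general-purpose
    MSA — OG members produced by this package's generators are
    substitution-only relatives, for which center-star is effectively
    exact.  A different aligner can be slotted in wherever an aligned
    block mapping is accepted.
    """
    from Bio import Align

    names = sorted(seqs)
    if len(names) == 1:
        return {names[0]: seqs[names[0]]}
    center = max(names, key=lambda n: (len(seqs[n]), n))
    cseq = seqs[center]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0

    others = [n for n in names if n != center]
    # per-alignment gap runs before each center position (and after the last)
    gap_runs: dict[str, list[int]] = {}
    aligned_pairs: dict[str, tuple[str, str]] = {}
    for name in others:
        aln = aligner.align(cseq, seqs[name])[0]
        a, b = str(aln[0]), str(aln[1])
        runs = [0] * (len(cseq) + 1)
        cpos = 0
        for ca in a:
            if ca == "-":
                runs[cpos] += 1
            else:
                cpos += 1
        gap_runs[name] = runs
        aligned_pairs[name] = (a, b)
    master = [0] * (len(cseq) + 1)
    for runs in gap_runs.values():
        for p, r in enumerate(runs):
            master[p] = max(master[p], r)

    out: dict[str, str] = {}
    out[center] = "".join(
        "-" * master[p] + (cseq[p] if p < len(cseq) else "") for p in range(len(cseq) + 1)
    )
    for name in others:
        a, b = aligned_pairs[name]
        runs = gap_runs[name]
        pieces = []
        i = 0  # cursor in the pairwise alignment
        for p in range(len(cseq) + 1):
            r = runs[p]
            pieces.append("-" * (master[p] - r))
            pieces.append(b[i : i + r])
            i += r
            if p < len(cseq):
                pieces.append(b[i])
                i += 1
        out[name] = "".join(pieces)
    width = len(out[center])
    assert all(len(s) == width for s in out.values())
    return out


def core_og_alignments(
    ogs: Sequence[OrthologGroup],
    proteomes: Proteomes,
    partition: PangenomePartition,
) -> dict[str, dict[str, str]]:
    """Center-star-align each core OG, one representative gene per genome."""
    per_og = partition.presence.sum(axis=0)
    n = len(partition.included_genomes)
    core_ids = set(per_og[per_og == n].index)
    blocks: dict[str, dict[str, str]] = {}
    for og in ogs:
        if og.og_id not in core_ids:
            continue
        rep: dict[str, str] = {}
        for genome, gene in sorted(og.members):
            if genome in partition.included_genomes and genome not in rep:
                rep[genome] = proteomes[genome][gene]
        blocks[og.og_id] = center_star_align(rep)
    return blocks


def p_distance_matrix(concat: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise p-distance (differing fraction of gap-free columns)."""
    names = sorted(concat)
    arrs = {n: np.frombuffer(concat[n].encode(), dtype="S1") for n in names}
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[names[i]], arrs[names[j]]
            ok = (a != b"-") & (b != b"-")
            total = int(ok.sum())
            diff = int(((a != b) & ok).sum())
            dist[i, j] = dist[j, i] = diff / total if total else 0.0
    return DistanceMatrix(dist, ids=names)


def core_concat_nj(alignments: Mapping[str, dict[str, str]]) -> TreeNode:
    """Concatenate core-OG blocks in stable OG-id order and run NJ.

    Blocks missing any genome are dropped with a warning.  Negative NJ
    branch lengths are clamped to zero.
    """
    og_ids = sorted(alignments)
    if not og_ids:
        raise ValueError("no alignment blocks")
    genomes = sorted(set.union(*(set(alignments[o]) for o in og_ids)))
    concat = {g: [] for g in genomes}
    kept = 0
    for og_id in og_ids:
        block = alignments[og_id]
        if set(block) != set(genomes):
            warnings.warn(f"core block {og_id} missing genomes; dropped")
            continue
        for g in genomes:
            concat[g].append(block[g])
        kept += 1
    if kept == 0:
        raise ValueError("no complete core block to concatenate")
    joined = {g: "".join(parts) for g, parts in concat.items()}
    dm = p_distance_matrix(joined)
    if len(genomes) == 2:
        d = dm[genomes[0], genomes[1]]
        return TreeNode.read([f"({genomes[0]}:{d / 2},{genomes[1]}:{d / 2});"])
    return nj(dm, neg_as_zero=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_proteomes_dir(directory) -> dict[str, dict[str, str]]:
    """Load every .faa/.fasta in a directory; the stem is the genome id."""
    from pathlib import Path

    from Bio import SeqIO

    out: dict[str, dict[str, str]] = {}
    for path in sorted(Path(directory).glob("*")):
        if path.suffix.lower() not in (".faa", ".fasta", ".fa"):
            continue
        out[path.stem] = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return out


def write_og_tsv(ogs: Sequence[OrthologGroup], path) -> None:
    rows = [
        {"og_id": og.og_id, "genome_id": g, "gene_id": gene}
        for og in ogs
        for g, gene in sorted(og.members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_presence_tsv(presence: pd.DataFrame, path) -> None:
    presence.to_csv(path, sep="\t")
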