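"""Average nucleotide / amino-acid identity and species delineation.

ANI follows the fragment protocol of genome-aggregate identity measures:
the query genome is cut into consecutive non-overlapping fragments
(default 1020 bp, terminal remainder discarded), each fragment is searched
against the whole subject genome, and the best hit is retained when it
reaches >= 30% identity over >= 70% of the fragment length.  One-way ANI
is the mean identity of retained hits; two-way (reciprocal) ANI is the
mean of the two one-way values.  Pairs with no retained fragment are
*undefined* — reported as missing, never as 0, so they cannot corrupt
downstream dendrograms.

AAI averages percent identity over reciprocal best matches (RBMs) between
two proteomes, optionally restricted to core-genome OGs.  "Identity" here
is exact-match identity over aligned columns, not substitution-matrix
positives; see the methods note for why this reading was chosen.

Species are delineated as single-linkage components over genome pairs
with two-way ANI at or above a threshold (default 95%, the conventional
prokaryotic species boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .aligners import EdlibFragmentAligner, FragmentAligner


@dataclass(frozen=True)
class AniParameters:
    """Fragment-protocol constants (overridable; defaults are the published ones)."""

    fragment_length: int = 1020
    min_hit_identity: float = 30.0  # percent
    min_hit_coverage: float = 0.70  # fraction of fragment length

    def __post_init__(self):
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100")
        if not (0 <= self.min_hit_identity <= 100):
            raise ValueError("min_hit_identity must be a percent")
        if not (0 < self.min_hit_coverage <= 1):
            raise ValueError("min_hit_coverage must be a fraction in (0, 1]")


@dataclass(frozen=True)
class PairwiseIdentityResult:
    """An ANI or AAI value with fragment/RBM bookkeeping.

    ``value`` is None when the comparison is undefined (no retained units);
    undefined is distinct from 0 and signals non-comparable genomes.
    """

    query_id: str
    subject_id: str
    metric: str  # "ANI" | "AAI"
    value: Optional[float]  # percent, [0, 100]
    n_units_total: int
    n_units_used: int
    two_way: bool

    @property
    def defined(self) -> bool:
        return self.value is not None


Genome = Sequence[tuple[str, str]]  # [(contig_id, sequence), ...]


def _fragments(genome: Genome, length: int) -> list[str]:
    frags = []
    for _cid, seq in genome:
        for start in range(0, len(seq) - length + 1, length):
            frags.append(seq[start : start + length])
    return frags


def compute_one_way_ani(
    query: Genome,
    subject: Genome,
    params: AniParameters = AniParameters(),
    aligner: Optional[FragmentAligner] = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairwiseIdentityResult:
    """One direction of the fragment protocol: query fragments vs subject."""
    if not query or all(not s for _, s in query):
        raise ValueError("query genome is empty")
    if not subject or all(not s for _, s in subject):
        raise ValueError("subject genome is empty")
    aligner = aligner or EdlibFragmentAligner()
    frags = _fragments(query, params.fragment_length)
    identities = []
    for frag in frags:
        hit = aligner.best_hit(frag, subject)
        if hit is None:
            continue
        if hit.identity >= params.min_hit_identity and hit.aligned_fraction >= params.min_hit_coverage:
            identities.append(hit.identity)
    value = float(np.mean(identities)) if identities else None
    return PairwiseIdentityResult(
        query_id=query_id,
        subject_id=subject_id,
        metric="ANI",
        value=value,
        n_units_total=len(frags),
        n_units_used=len(identities),
        two_way=False,
    )


def compute_ani(
    query: Genome,
    subject: Genome,
    params: AniParameters = AniParameters(),
    aligner: Optional[FragmentAligner] = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairwiseIdentityResult:
    """Two-way (reciprocal) ANI: the mean of the two one-way values.

    Undefined when either direction retains no fragment.
    """
    fwd = compute_one_way_ani(query, subject, params, aligner, query_id, subject_id)
    rev = compute_one_way_ani(subject, query, params, aligner, subject_id, query_id)
    if fwd.defined and rev.defined:
        value = (fwd.value + rev.value) / 2.0
    else:
        value = None
    return PairwiseIdentityResult(
        query_id=query_id,
        subject_id=subject_id,
        metric="ANI",
        value=value,
        n_units_total=fwd.n_units_total + rev.n_units_total,
        n_units_used=fwd.n_units_used + rev.n_units_used,
        two_way=True,
    )


def ani_matrix(
    genomes: Mapping[str, Genome],
    params: AniParameters = AniParameters(),
    aligner: Optional[FragmentAligner] = None,
) -> pd.DataFrame:
    """Symmetric two-way ANI matrix; NaN marks undefined pairs, diagonal 100."""
    ids = list(genomes)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for gid in ids:
        mat.loc[gid, gid] = 100.0
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            res = compute_ani(genomes[a], genomes[b], params, aligner, a, b)
            if res.defined:
                mat.loc[a, b] = mat.loc[b, a] = res.value
    return mat


def compute_aai(
    rbm_edges,
    core_og_members: Optional[set] = None,
    query_id: str = "A",
    subject_id: str = "B",
) -> PairwiseIdentityResult:
    """AAI = mean percent identity over RBM pairs between two proteomes.

    ``rbm_edges`` come from the orthology module (each edge carries the
    identity of its pair).  When ``core_og_members`` — a set of
    (genome, gene) tuples belonging to core OGs — is supplied, the average
    is restricted to RBMs whose both members are core (the core-genome AAI
    variant).  Zero usable RBMs gives an undefined result.
    """
    edges = list(rbm_edges)
    used = []
    for e in edges:
        if core_og_members is not None:
            if (e.genome_a, e.gene_a) not in core_og_members:
                continue
            if (e.genome_b, e.gene_b) not in core_og_members:
                continue
        used.append(e.similarity)
    value = float(np.mean(used)) if used else None
    return PairwiseIdentityResult(
        query_id=query_id,
        subject_id=subject_id,
        metric="AAI",
        value=value,
        n_units_total=len(edges),
        n_units_used=len(used),
        two_way=True,
    )


@dataclass
class SpeciesClustering:
    """Single-linkage species clusters at an ANI threshold."""

    genome_ids: list[str]
    labels: list[int]
    threshold: float = 95.0

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def clusters(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for gid, lab in zip(self.genome_ids, self.labels):
            out.setdefault(lab, set()).add(gid)
        return [out[k] for k in sorted(out)]


def delineate_species(ani: pd.DataFrame, threshold: float = 95.0) -> SpeciesClustering:
    """Transitive closure of pairs with two-way ANI >= threshold.

    Undefined (NaN) pairs contribute no edge; every genome receives
    exactly one cluster label.
    """
    if ani.empty:
        raise ValueError("empty ANI matrix")
    ids = list(ani.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            v = ani.loc[a, b]
            if pd.notna(v) and v >= threshold:
                g.add_edge(a, b)
    labels = {}
    for k, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        for gid in comp:
            labels[gid] = k
    return SpeciesClustering(
        genome_ids=ids, labels=[labels[g] for g in ids], threshold=threshold
    )


def identity_distance_dendrogram(identity: pd.DataFrame) -> TreeNode:
    """Average-linkage tree on 100 - identity distances (heatmap ordering).

    Input must be a square symmetric identity matrix; NaNs are not allowed
    here (drop undefined genomes first).  The returned tree serialises to
    Newick; its leaf order is the heatmap row order.
    """
    if identity.shape[0] != identity.shape[1]:
        raise ValueError("identity matrix must be square")
    if list(identity.index) != list(identity.columns):
        raise ValueError("identity matrix index/columns must agree")
    if identity.isna().any().any():
        raise ValueError("undefined identities present; remove those genomes first")
    dist = 100.0 - identity.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    tree = TreeNode.from_linkage_matrix(link, list(identity.index))
    return tree


def leaf_order(tree: TreeNode) -> list[str]:
    return [tip.name for tip in tree.tips()]


def write_identity_matrix(mat: pd.DataFrame, path) -> None:
    """TSV matrix; undefined pairs serialise as empty cells."""
    mat.to_csv(path, sep="\t", na_rep="")


def read_identity_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_pairwise_details(results: Sequence[PairwiseIdentityResult], path) -> None:
    """Per-pair detail TSV: one row per comparison with unit bookkeeping."""
    rows = [
        {
            "query_id": r.query_id,
            "subject_id": r.subject_id,
            "metric": r.metric,
            "value": "" if r.value is None else f"{r.value:.4f}",
            "n_units_total": r.n_units_total,
            "n_units_used": r.n_units_used,
            "two_way": r.two_way,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
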