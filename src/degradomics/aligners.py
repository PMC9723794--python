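"""Pairwise alignment backends shared by the comparison modules.

Two contracts are defined here:

``FragmentAligner``
    Given a nucleotide query fragment and a set of subject contigs, return
    the best local hit (percent identity over the aligned region and the
    aligned fraction of the query), or ``None`` when nothing aligns.  Used
    by the ANI protocol and the read recruiter.

``ProteinAligner``
    Given two protein sequences, return (percent identity, query coverage,
    score).  Used by the all-vs-all search behind RBM/OG detection and AAI.

The default nucleotide backend is bit-parallel semi-global edit-distance
alignment (edlib): the whole query is aligned against the best-matching
infix of the subject, which is the natural shape for fragment-vs-genome
and read-vs-genome searches.  An affine-gap local aligner (match +1,
mismatch -1, gap open -5, gap extend -2) built on Bio.Align is provided as
an alternative backend with identical hit semantics; it is the reference
for small inputs where an O(nm) sweep is affordable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocalHit:
    """Best local hit of a query against a subject sequence set."""

    identity: float  # percent identity over aligned columns, 0-100
    aligned_fraction: float  # fraction of the query covered, (0, 1]
    score: float  # rank key: higher is better
    contig: Optional[str] = None
    strand: str = "+"


class FragmentAligner(Protocol):
    def best_hit(self, query: str, subject: Sequence[tuple[str, str]]) -> Optional[LocalHit]:
        """Best hit of ``query`` against ``subject`` [(contig_id, seq), ...]."""
        ...


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """Return (matched columns, total columns) from an edlib extended cigar."""
    match = 0
    total = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        total += n
        if op == "=":
            match += n
    return match, total


class EdlibFragmentAligner:
    """Semi-global (query-infix-of-subject) aligner via edlib.

    Searches both strands of every contig; the hit with the smallest edit
    distance wins.  Because the whole query participates in a semi-global
    alignment, the aligned fraction is 1 by construction; identity is the
    fraction of exactly matching columns.
    """

    def __init__(self, search_reverse: bool = True, max_divergence: Optional[float] = 0.5):
        self.search_reverse = search_reverse
        #: hits beyond this edit-distance fraction are treated as no hit;
        #: also bounds the DP band, which is what makes genome-scale sweeps fast
        self.max_divergence = max_divergence

    def best_hit(self, query: str, subject: Sequence[tuple[str, str]]) -> Optional[LocalHit]:
        if not query:
            return None
        best = None  # (distance, contig, strand, cigar)
        k = -1 if self.max_divergence is None else max(1, int(self.max_divergence * len(query)))
        strands = [("+", query)]
        if self.search_reverse:
            strands.append(("-", revcomp(query)))
        for contig_id, seq in subject:
            if not seq:
                continue
            for strand, q in strands:
                res = edlib.align(q, seq, mode="HW", task="path", k=k)
                d = res["editDistance"]
                if d < 0:
                    continue
                if best is None or d < best[0]:
                    best = (d, contig_id, strand, res["cigar"])
                    k = d  # only better hits matter from here on
        if best is None:
            return None
        _, contig_id, strand, cigar = best
        match, total = _cigar_stats(cigar)
        if total == 0:
            return None
        identity = 100.0 * match / total
        return LocalHit(
            identity=identity,
            aligned_fraction=1.0,
            score=float(match),
            contig=contig_id,
            strand=strand,
        )


class AffineLocalAligner:
    """Exact affine-gap local aligner (Bio.Align.PairwiseAligner backend).

    Scoring: match +1, mismatch -1, gap open -5, gap extend -2.  Suitable
    for fragment-scale subjects; quadratic in subject length.
    """

    def __init__(self, search_reverse: bool = True):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
        self._aligner = aligner
        self.search_reverse = search_reverse

    def best_hit(self, query: str, subject: Sequence[tuple[str, str]]) -> Optional[LocalHit]:
        if not query:
            return None
        best = None  # (score, contig, strand, alignment)
        strands = [("+", query)]
        if self.search_reverse:
            strands.append(("-", revcomp(query)))
        for contig_id, seq in subject:
            if not seq:
                continue
            for strand, q in strands:
                try:
                    aln = self._aligner.align(q, seq)[0]
                except (IndexError, ValueError):
                    continue
                if best is None or aln.score > best[0]:
                    best = (aln.score, contig_id, strand, aln, len(q))
        if best is None or best[0] <= 0:
            return None
        score, contig_id, strand, aln, qlen = best
        identity, columns, qspan = _alignment_identity(aln)
        if columns == 0:
            return None
        return LocalHit(
            identity=identity,
            aligned_fraction=qspan / qlen,
            score=score,
            contig=contig_id,
            strand=strand,
        )


def _alignment_identity(aln) -> tuple[float, int, int]:
    """Percent identity, aligned columns and query-span of a Bio.Align alignment."""
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    qspan = int(aln.aligned[0][-1][1] - aln.aligned[0][0][0]) if len(aln.aligned[0]) else 0
    if columns == 0:
        return 0.0, 0, 0
    return 100.0 * counts.identities / columns, columns, qspan


class ProteinAligner:
    """Local protein aligner (BLOSUM62, gap open -11 / extend -1).

    Returns BLAST-like triples: percent identity over the aligned region,
    fraction of the query covered by the alignment, and the raw score used
    as the rank key for best-hit decisions.
    """

    def __init__(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        self._aligner = aligner

    def align(self, query: str, subject: str) -> Optional[tuple[float, float, float]]:
        """Align two proteins; return (identity %, query coverage, score) or None."""
        if not query or not subject:
            return None
        try:
            aln = self._aligner.align(query, subject)[0]
        except (IndexError, ValueError):
            return None
        if aln.score <= 0:
            return None
        identity, columns, qspan = _alignment_identity(aln)
        if columns == 0:
            return None
        return identity, qspan / len(query), float(aln.score)
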