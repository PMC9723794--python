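"""Competitive read recruitment for reference-genome abundance estimation.

Each metagenomic read is aligned against every reference genome and
recruited to the single best reference iff its identity reaches
``min_identity`` (default 95%) over at least ``min_aligned_fraction``
(default 0.8) of the read; reads tied between references are ambiguous
and discarded by default (``split_ties`` divides them equally instead).
A genome's abundance is its recruited reads as a percent of ALL reads in
the sample — not of mapped reads — and percentages below the detection
limit (default 0.001%) are displayed as "<limit" rather than as numbers.

This is a deliberately simple competitive best-hit recruiter with
explicit thresholds: it trades the bells and whistles of full coverage-
based abundance pipelines (depth truncation, coverage evenness) for exact
read-conservation accounting (recruited + ambiguous + unrecruited =
total, always).

The built-in mapper is seed-and-extend: 15-mer seeds locate candidate
loci on either strand, and the read is aligned to each candidate window
by bit-parallel edit distance.  Pre-mapped SAM is accepted as an
alternative input; identity is then recomputed from the alignment records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import edlib

from .aligners import revcomp, _cigar_stats

Genome = Sequence[tuple[str, str]]


@dataclass(frozen=True)
class RecruitmentParams:
    min_identity: float = 95.0  # percent
    min_aligned_fraction: float = 0.8
    detection_limit: float = 0.001  # percent of total reads
    seed_k: int = 15
    window_pad: int = 16
    split_ties: bool = False


class ReferenceIndex:
    """k-mer position index over one reference genome (forward strand)."""

    def __init__(self, genome_id: str, contigs: Genome, k: int = 15):
        self.genome_id = genome_id
        self.contigs = [(cid, seq.upper()) for cid, seq in contigs]
        self.k = k
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        for ci, (_cid, seq) in enumerate(self.contigs):
            for pos in range(0, len(seq) - k + 1):
                self.kmers.setdefault(seq[pos : pos + k], []).append((ci, pos))

    def candidate_starts(self, read: str) -> set[tuple[int, int]]:
        """Approximate (contig, start) placements for a read via sampled seeds."""
        L, k = len(read), self.k
        if L < k:
            return set()
        offsets = sorted({0, L // 2, L - k})
        out: set[tuple[int, int]] = set()
        for off in offsets:
            for ci, pos in self.kmers.get(read[off : off + k], ()):
                out.add((ci, pos - off))
        return out

    def best_identity(self, read: str, pad: int) -> Optional[float]:
        """Best percent identity of the read (either strand) on this reference."""
        best: Optional[float] = None
        for seq in (read, revcomp(read)):
            for ci, start in self.candidate_starts(seq):
                contig = self.contigs[ci][1]
                lo = max(0, start - pad)
                hi = min(len(contig), start + len(seq) + pad)
                window = contig[lo:hi]
                if len(window) < len(seq):
                    continue
                res = edlib.align(seq, window, mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                match, total = _cigar_stats(res["cigar"])
                if total == 0:
                    continue
                ident = 100.0 * match / total
                if best is None or ident > best:
                    best = ident
        return best


@dataclass
class RecruitmentProfile:
    """Per-sample recruitment outcome with exact read accounting."""

    sample_id: str
    total_reads: int
    counts: dict[str, float]  # genome -> recruited reads (float when ties split)
    n_unrecruited: int
    n_ambiguous: int
    params: RecruitmentParams = field(default_factory=RecruitmentParams)

    def percent(self, genome_id: str) -> float:
        if self.total_reads == 0:
            return 0.0
        return 100.0 * self.counts.get(genome_id, 0.0) / self.total_reads

    def percent_display(self, genome_id: str) -> str:
        """Percent as printed: below the detection limit becomes '<limit'."""
        p = self.percent(genome_id)
        if p < self.params.detection_limit:
            return f"<{self.params.detection_limit:g}"
        return f"{p:.4g}"

    @property
    def conservation_ok(self) -> bool:
        recruited = sum(self.counts.values())
        if self.params.split_ties:
            return abs(recruited + self.n_unrecruited - self.total_reads) < 1e-9
        return (
            int(round(recruited)) + self.n_unrecruited + self.n_ambiguous
            == self.total_reads
        )


def recruit(
    reads: Iterable[tuple[str, str]],
    references: Mapping[str, Genome],
    params: RecruitmentParams = RecruitmentParams(),
    sample_id: str = "sample",
    indexes: Optional[Mapping[str, ReferenceIndex]] = None,
) -> RecruitmentProfile:
    """Competitively assign reads to references at the identity threshold.

    Pre-built ``indexes`` may be passed to amortise indexing across
    samples; otherwise they are built here.
    """
    if not references:
        raise ValueError("empty reference set")
    if indexes is None:
        indexes = {
            gid: ReferenceIndex(gid, contigs, k=params.seed_k)
            for gid, contigs in references.items()
        }
    genome_ids = sorted(references)
    counts: dict[str, float] = {g: 0.0 for g in genome_ids}
    n_unrecruited = 0
    n_ambiguous = 0
    total = 0
    for _rid, seq in reads:
        total += 1
        per_ref: list[tuple[str, float]] = []
        for gid in genome_ids:
            ident = indexes[gid].best_identity(seq, params.window_pad)
            if ident is None:
                continue
            # semi-global alignment consumes the whole read
            if ident >= params.min_identity and 1.0 >= params.min_aligned_fraction:
                per_ref.append((gid, ident))
        if not per_ref:
            n_unrecruited += 1
            continue
        best_ident = max(i for _, i in per_ref)
        winners = [g for g, i in per_ref if i == best_ident]
        if len(winners) == 1:
            counts[winners[0]] += 1.0
        elif params.split_ties:
            for g in winners:
                counts[g] += 1.0 / len(winners)
        else:
            n_ambiguous += 1
    return RecruitmentProfile(
        sample_id=sample_id,
        total_reads=total,
        counts=counts,
        n_unrecruited=n_unrecruited,
        n_ambiguous=n_ambiguous,
        params=params,
    )


def recruit_from_sam(
    sam_path,
    params: RecruitmentParams = RecruitmentParams(),
    sample_id: str = "sample",
    reference_of: Optional[Mapping[str, str]] = None,
    total_reads: Optional[int] = None,
) -> RecruitmentProfile:
    """Recruit from pre-mapped alignments (SAM, all hits per read retained).

    Identity is recomputed from each record's cigar and NM tag;
    ``reference_of`` maps SAM reference names to genome ids (identity map
    by default).  ``total_reads`` overrides the denominator when the SAM
    omits unmapped reads.
    """
    import pysam

    best_per_read: dict[str, list[tuple[str, float, float]]] = {}
    seen_reads: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.query_name is None:
                continue
            seen_reads.add(rec.query_name)
            if rec.is_unmapped:
                continue
            ref = rec.reference_name
            gid = reference_of.get(ref, ref) if reference_of else ref
            stats = rec.get_cigar_stats()[0]
            m = stats[0] + stats[7] + stats[8]  # M + = + X columns
            columns = m + stats[1] + stats[2]  # + I + D
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            if columns == 0:
                continue
            ident = 100.0 * (columns - nm) / columns
            qlen = rec.infer_read_length() or rec.query_length or 0
            qaln = stats[0] + stats[1] + stats[7] + stats[8]
            frac = qaln / qlen if qlen else 0.0
            best_per_read.setdefault(rec.query_name, []).append((gid, ident, frac))

    genome_ids = sorted(
        {g for hits in best_per_read.values() for g, _, _ in hits}
        | (set(reference_of.values()) if reference_of else set())
    )
    counts: dict[str, float] = {g: 0.0 for g in genome_ids}
    n_unrecruited = 0
    n_ambiguous = 0
    for read in sorted(seen_reads):
        hits = best_per_read.get(read, [])
        qualified: dict[str, float] = {}
        for gid, ident, frac in hits:
            if ident >= params.min_identity and frac >= params.min_aligned_fraction:
                if gid not in qualified or ident > qualified[gid]:
                    qualified[gid] = ident
        if not qualified:
            n_unrecruited += 1
            continue
        best_ident = max(qualified.values())
        winners = [g for g, i in qualified.items() if i == best_ident]
        if len(winners) == 1:
            counts[winners[0]] += 1.0
        elif params.split_ties:
            for g in winners:
                counts[g] += 1.0 / len(winners)
        else:
            n_ambiguous += 1
    total = total_reads if total_reads is not None else len(seen_reads)
    return RecruitmentProfile(
        sample_id=sample_id,
        total_reads=total,
        counts=counts,
        n_unrecruited=n_unrecruited,
        n_ambiguous=n_ambiguous,
        params=params,
    )


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def timeseries(
    profiles: Sequence[RecruitmentProfile],
    dates: Mapping[str, str],
) -> pd.DataFrame:
    """Long-format abundance table over dated samples.

    One row per (sample, genome): date, Julian day, year, numeric percent
    and the display string with the detection limit applied.  Profiles
    must share a reference set; duplicate (sample, genome) pairs are
    rejected.
    """
    if not profiles:
        return pd.DataFrame(
            columns=["sample_id", "date", "julian_day", "year", "genome_id",
                     "percent", "percent_display"]
        )
    ref_sets = {frozenset(p.counts) for p in profiles}
    if len(ref_sets) != 1:
        raise ValueError("profiles do not share a reference set")
    seen: set[tuple[str, str]] = set()
    rows = []
    for p in profiles:
        when = pd.to_datetime(dates[p.sample_id])
        for gid in sorted(p.counts):
            key = (p.sample_id, gid)
            if key in seen:
                raise ValueError(f"duplicate (sample, genome) pair {key}")
            seen.add(key)
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "date": when,
                    "julian_day": int(when.dayofyear),
                    "year": int(when.year),
                    "genome_id": gid,
                    "percent": p.percent(gid),
                    "percent_display": p.percent_display(gid),
                }
            )
    df = pd.DataFrame(rows).sort_values(["date", "genome_id"], kind="stable")
    return df.reset_index(drop=True)


def max_per_year(table: pd.DataFrame, genome_id: str) -> pd.Series:
    """Maximum percent per year for one genome (bloom-peak summary)."""
    sub = table[table["genome_id"] == genome_id]
    return sub.groupby("year")["percent"].max()


def write_timeseries_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)
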