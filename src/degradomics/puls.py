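"""Polysaccharide utilization locus (PUL) detection and substrate classification.

PULs are co-located gene clusters that couple polysaccharide binding and
uptake (TonB-dependent / susC-like transporters with their susD-like
partners) to degradation (CAZymes) and often desulfation (sulfatases); they
are the hallmark of selfish glycan foraging in marine *Bacteroidetes*.

Detection operates on a role-annotated gene table (one row per predicted
gene, ordinal position along its contig, role flags, CAZy families) with a
sliding-window rule: any degradative CAZyme (i.e. any CAZyme apart from
glycosyl transferases), TonB-dependent transporter / susC-like gene,
sulfatase or susD-like gene is chained to any other such "seed" gene lying
within ``window`` genes up- or downstream, and clusters are the transitive
closure of that chaining.  The default window of 7 genes sits between the
strict 5-gene and permissive 10-gene conventions in the PUL literature.

Substrate classification matches the CAZy-family composition of each
cluster against an ordered signature table (editable YAML shipped with the
package); signatures are curated data, not code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

#: Controlled vocabulary for the ``roles`` column of a gene table.
ROLE_VOCAB = frozenset(
    {
        "degradative_cazyme",
        "glycosyl_transferase",
        "susC_like",
        "tonB_transporter",
        "susD_like",
        "sulfatase",
        "peptidase",
        "other",
    }
)

#: Roles that seed a PUL.  Glycosyl transferases are deliberately absent:
#: a gene that is a glycosyl transferase and nothing else never seeds.
SEED_ROLES = frozenset(
    {"degradative_cazyme", "susC_like", "tonB_transporter", "susD_like", "sulfatase"}
)

SUSC_ROLES = frozenset({"susC_like", "tonB_transporter"})

GENE_TABLE_COLUMNS = [
    "genome_id",
    "contig",
    "gene_index",
    "locus_tag",
    "strand",
    "roles",
    "cazy_families",
    "peptidase_family",
]


@dataclass(frozen=True)
class PulCall:
    """A detected gene cluster with composition and substrate label."""

    genome: str
    contig: str
    member_indices: tuple[int, ...]  # full span [min seed, max seed]
    seed_indices: tuple[int, ...]
    composition: tuple[str, ...]  # multiset of CAZy families, sorted
    has_susC: bool
    has_susD: bool
    roles_present: frozenset[str]
    substrate_label: str = "unclassified"
    window_used: int = 7


@dataclass(frozen=True)
class SubstrateSignature:
    """One row of the substrate-classification table.

    A signature assigns its label to a PUL when every required CAZy family
    occurs in the PUL composition, no forbidden family does, and every
    required role (e.g. ``sulfatase``) is present among member genes.
    Signatures are tried in increasing ``priority`` order; the first match
    wins.
    """

    label: str
    required_families: frozenset[str]
    forbidden_families: frozenset[str] = frozenset()
    required_roles: frozenset[str] = frozenset()
    priority: int = 100


# ---------------------------------------------------------------------------
# Gene-table I/O and validation
# ---------------------------------------------------------------------------

def parse_roles(cell) -> frozenset[str]:
    if isinstance(cell, (set, frozenset)):
        return frozenset(cell)
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(t for t in str(cell).split(";") if t)


def parse_families(cell) -> tuple[str, ...]:
    if isinstance(cell, (list, tuple)):
        return tuple(cell)
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(t for t in str(cell).split(",") if t)


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene table TSV into the in-memory representation.

    ``roles`` becomes a frozenset, ``cazy_families`` a tuple; rows are kept
    in file order (the caller validates sortedness).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    df = df[GENE_TABLE_COLUMNS].copy()
    df["gene_index"] = df["gene_index"].astype(int)
    df["roles"] = df["roles"].map(parse_roles)
    df["cazy_families"] = df["cazy_families"].map(parse_families)
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["roles"] = out["roles"].map(lambda s: ";".join(sorted(s)))
    out["cazy_families"] = out["cazy_families"].map(",".join)
    out.to_csv(path, sep="\t", index=False)


def read_gene_table_gff3(path, genome_id: str = "genome") -> pd.DataFrame:
    """Read a GFF3 file whose column-9 attributes carry role annotations.

    Recognised attribute keys: ``role`` (semicolon-free, comma-separated
    role tokens), ``cazy`` (comma-separated CAZy families), ``merops``
    (peptidase family).  Gene ordinals are assigned per contig in file
    order of ``gene``/``CDS`` features.
    """
    rows = []
    counters: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("gene", "CDS"):
                continue
            contig, strand, attrs = parts[0], parts[6], parts[8]
            kv = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k.strip()] = v.strip()
            idx = counters.get(contig, 0)
            counters[contig] = idx + 1
            roles = frozenset(t for t in kv.get("role", "other").split(",") if t)
            rows.append(
                {
                    "genome_id": genome_id,
                    "contig": contig,
                    "gene_index": idx,
                    "locus_tag": kv.get("ID", f"{contig}_{idx:05d}"),
                    "strand": strand if strand in "+-" else "+",
                    "roles": roles or frozenset({"other"}),
                    "cazy_families": parse_families(kv.get("cazy", "")),
                    "peptidase_family": kv.get("merops", ""),
                }
            )
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def validate_gene_table(df: pd.DataFrame) -> None:
    """Reject unknown role tokens (with row number) and unsorted tables."""
    for i, roles in enumerate(df["roles"]):
        unknown = set(roles) - ROLE_VOCAB
        if unknown:
            raise ValueError(f"unknown role token(s) {sorted(unknown)} at table row {i}")
    for (genome, contig), sub in df.groupby(["genome_id", "contig"], sort=False):
        idx = sub["gene_index"].to_numpy()
        if len(idx) != len(set(idx)):
            raise ValueError(f"duplicate gene_index on {genome}/{contig}")
        if len(idx) > 1 and not (idx[:-1] <= idx[1:]).all():
            raise ValueError(f"gene table not sorted by gene_index on {genome}/{contig}")


# ---------------------------------------------------------------------------
# PUL calling
# ---------------------------------------------------------------------------

def is_seed(roles: frozenset[str]) -> bool:
    """Seed genes: degradative CAZymes, susC/TonB transporters, susD, sulfatases.

    Glycosyl transferases with no other qualifying role are never seeds.
    """
    return bool(roles & SEED_ROLES)


def _gt_only(roles: frozenset[str]) -> bool:
    return "glycosyl_transferase" in roles and "degradative_cazyme" not in roles


def call_puls(
    table: pd.DataFrame,
    window: int = 7,
    distance_mode: str = "index",
    require_suscd: bool = False,
) -> list[PulCall]:
    """Detect PULs with the sliding-window chaining rule.

    Two seed genes on the same contig chain when their ordinal distance is
    within ``window``; ``distance_mode="index"`` reads "within N genes" as
    gene-index difference <= N (the default), ``"intervening"`` as at most
    N intervening genes (index difference <= N+1).  Clusters are the
    transitive closure of chaining and never span contigs.  A cluster is
    emitted when it has at least two seed genes of which at least one is a
    degradative CAZyme; ``require_suscd`` additionally demands the classic
    susC+susD transporter tandem.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if distance_mode not in ("index", "intervening"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    validate_gene_table(table)
    max_gap = window if distance_mode == "index" else window + 1

    calls: list[PulCall] = []
    for (genome, contig), sub in table.groupby(["genome_id", "contig"], sort=False):
        sub = sub.sort_values("gene_index")
        seeds = sub[sub["roles"].map(is_seed)]
        if seeds.empty:
            continue
        seed_idx = seeds["gene_index"].to_numpy()
        seed_roles = list(seeds["roles"])
        # consecutive seeds chain iff the ordinal gap is within the window;
        # transitive closure over sorted seeds is exactly run-splitting
        runs: list[list[int]] = [[0]]
        for i in range(1, len(seed_idx)):
            if seed_idx[i] - seed_idx[i - 1] <= max_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        by_index = {int(r.gene_index): r for r in sub.itertuples()}
        for run in runs:
            run_roles = [seed_roles[i] for i in run]
            if len(run) < 2:
                continue
            if not any("degradative_cazyme" in r for r in run_roles):
                continue
            lo, hi = int(seed_idx[run[0]]), int(seed_idx[run[-1]])
            members = [i for i in sorted(by_index) if lo <= i <= hi]
            comp: Counter[str] = Counter()
            roles_present: set[str] = set()
            for i in members:
                row = by_index[i]
                roles_present |= set(row.roles)
                if row.cazy_families and not _gt_only(row.roles):
                    comp.update(row.cazy_families)
            has_susC = any(r & SUSC_ROLES for r in run_roles)
            has_susD = any("susD_like" in r for r in run_roles)
            if require_suscd and not (has_susC and has_susD):
                continue
            calls.append(
                PulCall(
                    genome=genome,
                    contig=contig,
                    member_indices=tuple(members),
                    seed_indices=tuple(int(seed_idx[i]) for i in run),
                    composition=tuple(sorted(comp.elements())),
                    has_susC=has_susC,
                    has_susD=has_susD,
                    roles_present=frozenset(roles_present),
                    window_used=window,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Substrate classification
# ---------------------------------------------------------------------------

def default_signatures() -> list[SubstrateSignature]:
    """The substrate-signature table shipped with the package."""
    text = resources.files("degradomics").joinpath("data/signatures.yaml").read_text()
    return load_signatures_from_text(text)


def load_signatures(path) -> list[SubstrateSignature]:
    with open(path) as fh:
        return load_signatures_from_text(fh.read())


def load_signatures_from_text(text: str) -> list[SubstrateSignature]:
    raw = yaml.safe_load(text) or []
    sigs = [
        SubstrateSignature(
            label=entry["label"],
            required_families=frozenset(entry.get("required_families", [])),
            forbidden_families=frozenset(entry.get("forbidden_families", [])),
            required_roles=frozenset(entry.get("required_roles", [])),
            priority=int(entry.get("priority", 100)),
        )
        for entry in raw
    ]
    labels = [s.label for s in sigs]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate signature labels")
    return sigs


def classify_pul(pul: PulCall, signatures: Sequence[SubstrateSignature]) -> PulCall:
    """Assign the first matching substrate label (lowest priority number wins)."""
    labels = [s.label for s in signatures]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate signature labels")
    families = set(pul.composition)
    for sig in sorted(signatures, key=lambda s: (s.priority, s.label)):
        if not sig.required_families <= families:
            continue
        if sig.forbidden_families & families:
            continue
        if not sig.required_roles <= pul.roles_present:
            continue
        return replace(pul, substrate_label=sig.label)
    return replace(pul, substrate_label="unclassified")


def classify_all(
    puls: Iterable[PulCall], signatures: Optional[Sequence[SubstrateSignature]] = None
) -> list[PulCall]:
    sigs = default_signatures() if signatures is None else signatures
    return [classify_pul(p, sigs) for p in puls]


def pul_matrix(puls: Iterable[PulCall], genomes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Genome x substrate integer count matrix (a cell of 2 is Fig.-style 'green')."""
    puls = list(puls)
    counts: Counter[tuple[str, str]] = Counter(
        (p.genome, p.substrate_label) for p in puls
    )
    row_ids = list(genomes) if genomes is not None else sorted({p.genome for p in puls})
    col_ids = sorted({label for _, label in counts})
    mat = pd.DataFrame(0, index=row_ids, columns=col_ids, dtype=int)
    for (g, label), n in counts.items():
        if g in mat.index:
            mat.loc[g, label] = n
    mat.index.name = "genome_id"
    return mat


def write_pul_tsv(puls: Iterable[PulCall], path) -> None:
    rows = [
        {
            "genome_id": p.genome,
            "contig": p.contig,
            "span_start": p.member_indices[0],
            "span_end": p.member_indices[-1],
            "n_members": len(p.member_indices),
            "seed_indices": ",".join(map(str, p.seed_indices)),
            "composition": ",".join(p.composition),
            "has_susC": p.has_susC,
            "has_susD": p.has_susD,
            "substrate": p.substrate_label,
            "window": p.window_used,
        }
        for p in puls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
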