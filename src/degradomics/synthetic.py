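"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the data classes the comparative pipeline consumes — genome pairs
at controlled nucleotide divergence (ANI benchmarks), proteome sets with
planted core/accessory orthologous groups (pangenome recovery), gene
tables with planted PUL layouts plus background role noise (caller
equivalence), and read mixtures with known per-genome proportions
(abundance recovery).  All generators are seeded and byte-deterministic.

Deliberately unrealistic simplifications: substitutions are uniform over
the three alternative bases/nineteen alternative residues (no
transition/transversion or exchangeability bias), indels default off, read
errors are substitutions only.  These keep closed-form oracles exact; see
the methods note for what this does and does not demonstrate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .puls import GENE_TABLE_COLUMNS, SEED_ROLES, is_seed

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"

#: CAZy families used when the generators invent annotations.
_GH_FAMILIES = [
    "GH2", "GH3", "GH13", "GH16", "GH17", "GH20", "GH29", "GH30", "GH76",
    "GH78", "GH88", "GH92", "GH95", "GH117", "GH136", "PL6", "PL7", "PL17",
    "CE1", "CE4",
]
_GT_FAMILIES = ["GT2", "GT4"]
_PEPTIDASE_FAMILIES = ["S8", "S9", "M1", "M16", "M23", "C25"]


def _seq_to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(_NT):
        codes[arr == b] = i
    if (codes < 0).any():
        raise ValueError("non-ACGT character in sequence")
    return codes


def _codes_to_seq(codes: np.ndarray) -> str:
    return _NT[codes].tobytes().decode()


def random_genome(
    length: int, seed: int, n_contigs: int = 1, prefix: str = "contig"
) -> list[tuple[str, str]]:
    """An i.i.d.-uniform ACGT genome split into equal contigs."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    bounds = np.linspace(0, length, n_contigs + 1).astype(int)
    return [
        (f"{prefix}_{i}", _codes_to_seq(codes[bounds[i] : bounds[i + 1]]))
        for i in range(n_contigs)
    ]


# ---------------------------------------------------------------------------
# Diverged genome pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergencePairTruth:
    """Parameters of a planted ancestor/derived genome pair."""

    ancestor_length: int
    per_site_divergence: float
    indel_rate: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DivergencePairTruth":
        return cls(**d)


def mutate_genome(
    ancestor: Sequence[tuple[str, str]], truth: DivergencePairTruth
) -> list[tuple[str, str]]:
    """Derive a genome by i.i.d. per-site substitution at the stated rate.

    A substituted site never keeps its original base (the realised Hamming
    fraction is therefore binomial at exactly ``per_site_divergence``).
    Optional indels are applied after substitutions with geometric(0.5)
    lengths.
    """
    d = truth.per_site_divergence
    if not (0.0 <= d < 0.5):
        raise ValueError("per_site_divergence must be in [0, 0.5)")
    if not ancestor or all(len(s) == 0 for _, s in ancestor):
        raise ValueError("ancestor genome is empty")
    rng = np.random.default_rng(truth.seed)
    derived = []
    for contig_id, seq in ancestor:
        codes = _seq_to_codes(seq)
        if d > 0 and len(codes):
            mask = rng.random(len(codes)) < d
            shift = rng.integers(1, 4, size=int(mask.sum()))
            codes = codes.copy()
            codes[mask] = (codes[mask] + shift) % 4
        if truth.indel_rate > 0 and len(codes):
            codes = _apply_indels(codes, truth.indel_rate, rng)
        derived.append((contig_id, _codes_to_seq(codes)))
    return derived


def _apply_indels(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    n_events = rng.binomial(len(codes), rate)
    if n_events == 0:
        return codes
    positions = np.sort(rng.integers(0, len(codes), size=n_events))[::-1]
    out = codes.copy()
    for pos in positions:
        length = rng.geometric(0.5)
        if rng.random() < 0.5:  # deletion
            out = np.delete(out, slice(pos, pos + length))
        else:  # insertion
            ins = rng.integers(0, 4, size=length)
            out = np.insert(out, pos, ins)
    return out


def diverged_pair(
    truth: DivergencePairTruth, n_contigs: int = 1
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Convenience: generate the ancestor and its derived partner."""
    ancestor = random_genome(truth.ancestor_length, truth.seed, n_contigs=n_contigs)
    return ancestor, mutate_genome(ancestor, truth)


# ---------------------------------------------------------------------------
# Planted pangenomes
# ---------------------------------------------------------------------------

@dataclass
class PangenomeTruth:
    """A planted pangenome: core + accessory OGs with a presence pattern."""

    n_genomes: int
    core_ogs: int
    accessory_ogs: int
    per_gene_mutation_rate: float = 0.10
    seed: int = 0
    presence: Optional[np.ndarray] = None  # genomes x OGs, bool

    def __post_init__(self):
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if self.core_ogs < 1:
            raise ValueError("need at least 1 core OG")
        if self.presence is None:
            self.presence = self._draw_presence()
        self.presence = np.asarray(self.presence, dtype=bool)
        self._check()

    def _draw_presence(self) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        n, total = self.n_genomes, self.core_ogs + self.accessory_ogs
        mat = np.zeros((n, total), dtype=bool)
        mat[:, : self.core_ogs] = True
        for j in range(self.core_ogs, total):
            while True:
                col = rng.random(n) < 0.5
                if col.any() and not col.all():
                    break
            mat[:, j] = col
        return mat

    def _check(self):
        n, total = self.n_genomes, self.core_ogs + self.accessory_ogs
        if self.presence.shape != (n, total):
            raise ValueError("presence matrix shape mismatch")
        if not self.presence[:, : self.core_ogs].all():
            raise ValueError("core OGs must be present in all genomes")
        acc = self.presence[:, self.core_ogs :]
        if acc.size and (~acc.any(axis=0)).any():
            raise ValueError("accessory OGs must be present in >=1 genome")
        if acc.size and acc.all(axis=0).any():
            raise ValueError("accessory OGs must be absent from >=1 genome")

    @property
    def og_ids(self) -> list[str]:
        return [f"OG{j:05d}" for j in range(self.core_ogs + self.accessory_ogs)]

    @property
    def genome_ids(self) -> list[str]:
        return [f"G{i:03d}" for i in range(self.n_genomes)]

    def presence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.genome_ids, columns=self.og_ids)

    def partition_counts(self) -> tuple[int, int, int]:
        """True (core, variable, genome-specific) OG counts."""
        per_og = self.presence.sum(axis=0)
        core = int((per_og == self.n_genomes).sum())
        specific = int((per_og == 1).sum())
        variable = int(((per_og > 1) & (per_og < self.n_genomes)).sum())
        return core, variable, specific

    def to_dict(self) -> dict:
        return {
            "n_genomes": self.n_genomes,
            "core_ogs": self.core_ogs,
            "accessory_ogs": self.accessory_ogs,
            "per_gene_mutation_rate": self.per_gene_mutation_rate,
            "seed": self.seed,
            "presence": self.presence.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PangenomeTruth":
        d = dict(d)
        d["presence"] = np.asarray(d["presence"], dtype=bool)
        return cls(**d)


def random_protein(rng: np.random.Generator, min_len: int = 100, max_len: int = 400) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    return "".join(_AA[i] for i in rng.integers(0, 20, size=length))


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    mask = rng.random(len(chars)) < rate
    for i in np.flatnonzero(mask):
        alternatives = _AA.replace(chars[i], "")
        chars[i] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(chars)


@dataclass
class SimulatedPangenome:
    truth: PangenomeTruth
    proteomes: dict[str, dict[str, str]]  # genome -> gene_id -> sequence
    gene_to_og: dict[tuple[str, str], str]  # (genome, gene_id) -> og_id


def simulate_pangenome(truth: PangenomeTruth) -> SimulatedPangenome:
    """Emit per-genome proteomes realising the planted presence pattern.

    Members of one OG are independently mutated copies of a family
    ancestor; distinct families have independently drawn ancestors, so
    inter-family identity stays far below any homology threshold.

    ``per_gene_mutation_rate`` is calibrated as the expected *pairwise*
    divergence between two members of an OG: each copy is mutated at half
    that rate from the ancestor, so a rate of 0.10 yields members at
    roughly 90% mutual identity.
    """
    rng = np.random.default_rng(truth.seed)
    half_rate = truth.per_gene_mutation_rate / 2.0
    ancestors = [random_protein(rng) for _ in truth.og_ids]
    proteomes: dict[str, dict[str, str]] = {g: {} for g in truth.genome_ids}
    gene_to_og: dict[tuple[str, str], str] = {}
    counters = {g: 0 for g in truth.genome_ids}
    for j, og in enumerate(truth.og_ids):
        for i, genome in enumerate(truth.genome_ids):
            if not truth.presence[i, j]:
                continue
            gene_id = f"{genome}_g{counters[genome]:05d}"
            counters[genome] += 1
            proteomes[genome][gene_id] = mutate_protein(ancestors[j], half_rate, rng)
            gene_to_og[(genome, gene_id)] = og
    return SimulatedPangenome(truth=truth, proteomes=proteomes, gene_to_og=gene_to_og)


# ---------------------------------------------------------------------------
# Gene tables with planted PUL layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulLayout:
    """A planted PUL: seed genes at stated ordinals with stated roles."""

    contig: str
    seed_positions: tuple[int, ...]
    roles: tuple[frozenset[str], ...]
    cazy_families: tuple[tuple[str, ...], ...] = ()
    flanking_filler: int = 10

    def __post_init__(self):
        if list(self.seed_positions) != sorted(set(self.seed_positions)):
            raise ValueError("seed positions must be strictly increasing")
        if len(self.roles) != len(self.seed_positions):
            raise ValueError("one role set per seed position required")
        vocab_ok = all(r <= (SEED_ROLES | {"glycosyl_transferase", "peptidase", "other"})
                       for r in self.roles)
        if not vocab_ok:
            raise ValueError("layout roles outside the controlled vocabulary")

    @property
    def span(self) -> tuple[int, int]:
        return self.seed_positions[0], self.seed_positions[-1]

    def to_dict(self) -> dict:
        return {
            "contig": self.contig,
            "seed_positions": list(self.seed_positions),
            "roles": [sorted(r) for r in self.roles],
            "cazy_families": [list(f) for f in self.cazy_families],
            "flanking_filler": self.flanking_filler,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PulLayout":
        return cls(
            contig=d["contig"],
            seed_positions=tuple(d["seed_positions"]),
            roles=tuple(frozenset(r) for r in d["roles"]),
            cazy_families=tuple(tuple(f) for f in d.get("cazy_families", [])),
            flanking_filler=d.get("flanking_filler", 10),
        )


def _background_gene(rng: np.random.Generator, role_rate: float) -> tuple[frozenset, tuple]:
    if rng.random() >= role_rate:
        return frozenset({"other"}), ()
    pick = rng.choice(
        ["degradative_cazyme", "susC_like", "susD_like", "sulfatase",
         "glycosyl_transferase", "peptidase"]
    )
    if pick == "degradative_cazyme":
        fam = str(rng.choice(_GH_FAMILIES))
        return frozenset({pick}), (fam,)
    if pick == "glycosyl_transferase":
        return frozenset({pick}), (str(rng.choice(_GT_FAMILIES)),)
    return frozenset({pick}), ()


def simulate_gene_table(
    layouts: Sequence[PulLayout],
    n_background_genes: int = 0,
    background_role_rate: float = 0.0,
    seed: int = 0,
    genome_id: str = "G000",
    window: int = 7,
) -> tuple[pd.DataFrame, list[tuple[str, tuple[int, ...]]]]:
    """Build a gene table realising the layouts plus background role noise.

    Background genes (mostly ``other``; seed-roled at ``background_role_rate``)
    are appended after each layout's flanking filler and on a dedicated
    background contig.  Returns the table and the true cluster list: the
    seed-index groups a transitive-closure reading of the window rule
    yields, computed by the O(n^2) oracle so the truth is independent of
    the production caller.
    """
    rng = np.random.default_rng(seed)
    spans: dict[str, list[tuple[int, int]]] = {}
    for layout in layouts:
        lo, hi = layout.span
        for other_lo, other_hi in spans.get(layout.contig, []):
            if lo <= other_hi and other_lo <= hi:
                raise ValueError(f"overlapping layouts on contig {layout.contig}")
        spans.setdefault(layout.contig, []).append((lo, hi))

    by_contig: dict[str, dict[int, tuple[frozenset, tuple, str]]] = {}
    for layout in layouts:
        genes = by_contig.setdefault(layout.contig, {})
        lo, hi = layout.span
        lo_f = max(0, lo - layout.flanking_filler)
        hi_f = hi + layout.flanking_filler
        fams = layout.cazy_families or tuple(() for _ in layout.seed_positions)
        seed_map = dict(zip(layout.seed_positions, zip(layout.roles, fams)))
        for pos in range(lo_f, hi_f + 1):
            if pos in seed_map:
                roles, f = seed_map[pos]
                if not f and "degradative_cazyme" in roles:
                    f = (str(rng.choice(_GH_FAMILIES)),)
                elif not f and "glycosyl_transferase" in roles:
                    f = (str(rng.choice(_GT_FAMILIES)),)
                genes[pos] = (roles, tuple(f), "layout")
            elif pos not in genes:
                genes[pos] = (frozenset({"other"}), (), "filler")
    # background genes: appended beyond every layout on a dedicated contig
    bg = by_contig.setdefault("bg_contig", {})
    start = (max(bg) + 1) if bg else 0
    for k in range(n_background_genes):
        roles, fams = _background_gene(rng, background_role_rate)
        bg[start + k] = (roles, fams, "background")
    if not bg:
        del by_contig["bg_contig"]

    rows = []
    for contig in sorted(by_contig):
        for pos in sorted(by_contig[contig]):
            roles, fams, _src = by_contig[contig][pos]
            rows.append(
                {
                    "genome_id": genome_id,
                    "contig": contig,
                    "gene_index": pos,
                    "locus_tag": f"{genome_id}_{contig}_{pos:05d}",
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "roles": roles,
                    "cazy_families": fams,
                    "peptidase_family": (
                        str(rng.choice(_PEPTIDASE_FAMILIES)) if "peptidase" in roles else ""
                    ),
                }
            )
    table = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    return table, oracle_clusters(table, window=window)


def random_gene_table(
    n_genes: int,
    seed: int,
    role_rate: float = 0.25,
    n_contigs: int = 3,
    genome_id: str = "G000",
) -> pd.DataFrame:
    """A fully random role-annotated gene table (caller stress-test input)."""
    rng = np.random.default_rng(seed)
    rows = []
    contig_of = rng.integers(0, n_contigs, size=n_genes)
    counters = {c: 0 for c in range(n_contigs)}
    for g in range(n_genes):
        c = int(contig_of[g])
        idx = counters[c]
        counters[c] += 1
        roles, fams = _background_gene(rng, role_rate)
        rows.append(
            {
                "genome_id": genome_id,
                "contig": f"ctg_{c}",
                "gene_index": idx,
                "locus_tag": f"{genome_id}_c{c}_{idx:05d}",
                "strand": "+" if rng.random() < 0.5 else "-",
                "roles": roles,
                "cazy_families": fams,
                "peptidase_family": (
                    str(rng.choice(_PEPTIDASE_FAMILIES)) if "peptidase" in roles else ""
                ),
            }
        )
    df = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    return df.sort_values(["contig", "gene_index"], kind="stable").reset_index(drop=True)


def oracle_clusters(
    table: pd.DataFrame, window: int = 7, distance_mode: str = "index"
) -> list[tuple[str, tuple[int, ...]]]:
    """Brute-force O(n^2) transitive closure of the PUL window rule.

    Considers every pair of seed genes on each contig, links the pair when
    their ordinal distance is within the window, takes connected components
    by repeated sweeps, and keeps components with >=2 seeds including >=1
    degradative CAZyme.  Independent of the production caller; used as the
    generator's truth and as the equivalence oracle in tests.
    """
    max_gap = window if distance_mode == "index" else window + 1
    out: list[tuple[str, tuple[int, ...]]] = []
    for (_genome, contig), sub in table.groupby(["genome_id", "contig"], sort=False):
        seeds = [
            (int(r.gene_index), r.roles) for r in sub.itertuples() if is_seed(r.roles)
        ]
        if not seeds:
            continue
        # naive union-find by label propagation over all pairs
        labels = list(range(len(seeds)))
        changed = True
        while changed:
            changed = False
            for i in range(len(seeds)):
                for j in range(len(seeds)):
                    if abs(seeds[i][0] - seeds[j][0]) <= max_gap:
                        lo = min(labels[i], labels[j])
                        if labels[i] != lo or labels[j] != lo:
                            labels[i] = labels[j] = lo
                            changed = True
        comps: dict[int, list[int]] = {}
        for k, lab in enumerate(labels):
            comps.setdefault(lab, []).append(k)
        for members in comps.values():
            if len(members) < 2:
                continue
            if not any("degradative_cazyme" in seeds[k][1] for k in members):
                continue
            out.append((contig, tuple(sorted(seeds[k][0] for k in members))))
    return sorted(out)


# ---------------------------------------------------------------------------
# Read mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureTruth:
    """A planted metagenome: per-genome proportions of a read pool."""

    genome_ids: tuple[str, ...]
    proportions: tuple[float, ...]
    n_reads: int
    read_length: int = 150
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if len(self.genome_ids) != len(self.proportions):
            raise ValueError("one proportion per genome required")

    def to_dict(self) -> dict:
        return {
            "genome_ids": list(self.genome_ids),
            "proportions": list(self.proportions),
            "n_reads": self.n_reads,
            "read_length": self.read_length,
            "error_rate": self.error_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MixtureTruth":
        d = dict(d)
        d["genome_ids"] = tuple(d["genome_ids"])
        d["proportions"] = tuple(d["proportions"])
        return cls(**d)


@dataclass
class SimulatedMetagenome:
    truth: MixtureTruth
    reads: list[tuple[str, str]]  # (read_id, sequence)
    provenance: dict[str, str]  # read_id -> genome_id
    counts: dict[str, int]  # genome_id -> reads drawn


def simulate_metagenome(
    truth: MixtureTruth, genomes: Mapping[str, Sequence[tuple[str, str]]]
) -> SimulatedMetagenome:
    """Draw reads from the genomes at the planted proportions.

    Read counts per genome are multinomial; positions are uniform over
    valid windows, strands equiprobable, and errors are uniform
    substitutions at ``error_rate``.
    """
    missing = set(truth.genome_ids) - set(genomes)
    if missing:
        raise ValueError(f"genomes absent from the reference map: {sorted(missing)}")
    rng = np.random.default_rng(truth.seed)
    counts = rng.multinomial(truth.n_reads, truth.proportions)
    reads: list[tuple[str, str]] = []
    provenance: dict[str, str] = {}
    read_no = 0
    L = truth.read_length
    for genome_id, n in zip(truth.genome_ids, counts):
        contigs = [(cid, s) for cid, s in genomes[genome_id] if len(s) >= L]
        if n > 0 and not contigs:
            raise ValueError(f"no contig of {genome_id} is >= read_length")
        lens = np.array([len(s) - L + 1 for _, s in contigs], dtype=float)
        probs = lens / lens.sum() if n > 0 else lens
        for _ in range(int(n)):
            ci = int(rng.choice(len(contigs), p=probs))
            seq = contigs[ci][1]
            pos = int(rng.integers(0, len(seq) - L + 1))
            read = seq[pos : pos + L]
            if truth.error_rate > 0:
                codes = _seq_to_codes(read)
                mask = rng.random(L) < truth.error_rate
                if mask.any():
                    shift = rng.integers(1, 4, size=int(mask.sum()))
                    codes[mask] = (codes[mask] + shift) % 4
                    read = _codes_to_seq(codes)
            if rng.random() < 0.5:
                from .aligners import revcomp

                read = revcomp(read)
            read_id = f"r{read_no:07d}"
            read_no += 1
            reads.append((read_id, read))
            provenance[read_id] = genome_id
    return SimulatedMetagenome(
        truth=truth,
        reads=reads,
        provenance=provenance,
        counts={g: int(n) for g, n in zip(truth.genome_ids, counts)},
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(records: Iterable[tuple[str, str]], path) -> None:
    """FASTQ with a constant quality of 'I' (errors are planted, not scored)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth_json(cls, path):
    with open(path) as fh:
        return cls.from_dict(json.load(fh))
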