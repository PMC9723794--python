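"""Degradome profiling: CAZyme/peptidase counts, ratios and scaling fits.

A genome's "degradome" here is its complement of carbohydrate-active
enzymes (CAZymes; degradative families GH/PL/CE/CBM versus biosynthetic
glycosyl transferases), peptidases and sulfatases.  Across related
genomes, CAZyme counts tend to rise super-linearly (well described by an
exponential in genome size) while peptidase counts rise roughly linearly,
so the CAZyme:peptidase ratio separates large-genome polysaccharide
specialists from streamlined protein-leaning genomes.

Counting conventions: *total* CAZymes include glycosyl transferases;
*degradative* CAZymes exclude GT-only genes.  The ratio defaults to
degradative CAZymes over peptidases; a flag switches to total CAZymes
because published summaries alternate between the two.  The exponential
model is fitted as a linear regression on log counts (deterministic,
closed form); zero counts are offset by +1 before the log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .puls import validate_gene_table


@dataclass(frozen=True)
class DegradomeProfile:
    """Per-genome degradome counts; genome size in Mb."""

    genome_id: str
    genome_size_mb: float
    n_cazymes_total: int
    n_cazymes_degradative: int
    n_peptidases: int
    n_sulfatases: int
    phylogroup: Optional[str] = None
    is_mag: bool = False

    @property
    def ratio(self) -> Optional[float]:
        """Degradative CAZymes per peptidase; None when no peptidase."""
        if self.n_peptidases == 0:
            return None
        return self.n_cazymes_degradative / self.n_peptidases

    @property
    def ratio_total(self) -> Optional[float]:
        if self.n_peptidases == 0:
            return None
        return self.n_cazymes_total / self.n_peptidases


def count_degradome(
    table: pd.DataFrame,
    genome_size_mb: float = float("nan"),
    phylogroup: Optional[str] = None,
    is_mag: bool = False,
) -> DegradomeProfile:
    """Count CAZymes / peptidases / sulfatases on one genome's gene table.

    Degradative CAZymes are rows with the ``degradative_cazyme`` role;
    total CAZymes additionally include glycosyl-transferase-only rows.
    Idempotent and additive over contigs.
    """
    validate_gene_table(table)
    genomes = table["genome_id"].unique().tolist() if len(table) else ["genome"]
    if len(genomes) > 1:
        raise ValueError("gene table spans multiple genomes; count one at a time")
    roles = table["roles"] if len(table) else pd.Series([], dtype=object)
    n_deg = int(roles.map(lambda r: "degradative_cazyme" in r).sum())
    n_gt_only = int(
        roles.map(
            lambda r: "glycosyl_transferase" in r and "degradative_cazyme" not in r
        ).sum()
    )
    n_pep = int(roles.map(lambda r: "peptidase" in r).sum())
    n_sulf = int(roles.map(lambda r: "sulfatase" in r).sum())
    return DegradomeProfile(
        genome_id=genomes[0],
        genome_size_mb=genome_size_mb,
        n_cazymes_total=n_deg + n_gt_only,
        n_cazymes_degradative=n_deg,
        n_peptidases=n_pep,
        n_sulfatases=n_sulf,
        phylogroup=phylogroup,
        is_mag=is_mag,
    )


@dataclass(frozen=True)
class ScalingFit:
    """A count-versus-genome-size fit.

    ``linear``: count = intercept + slope * size.
    ``exponential``: count = a * exp(b * size), fitted on the log scale;
    ``r_squared`` is then the coefficient of determination of the
    log-linear regression.
    """

    model: str
    parameters: dict[str, float]
    r_squared: float
    n_points: int

    def predict(self, size_mb: np.ndarray) -> np.ndarray:
        size_mb = np.asarray(size_mb, dtype=float)
        p = self.parameters
        if self.model == "linear":
            return p["intercept"] + p["slope"] * size_mb
        return p["a"] * np.exp(p["b"] * size_mb)


def fit_scaling(
    profiles: Sequence[DegradomeProfile],
    response: str = "cazymes",
    model: str = "exponential",
    degradative_only: bool = False,
) -> ScalingFit:
    """Least-squares fit of a count against genome size.

    ``response`` is ``cazymes`` or ``peptidases``; ``model`` is ``linear``
    or ``exponential`` (log-linear least squares; zero counts offset +1).
    """
    if response not in ("cazymes", "peptidases"):
        raise ValueError(f"unknown response {response!r}")
    if model not in ("linear", "exponential"):
        raise ValueError(f"unknown model {model!r}")
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to fit")
    x = np.array([p.genome_size_mb for p in profiles], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all genome sizes equal: degenerate design")
    if response == "cazymes":
        y = np.array(
            [
                p.n_cazymes_degradative if degradative_only else p.n_cazymes_total
                for p in profiles
            ],
            dtype=float,
        )
    else:
        y = np.array([p.n_peptidases for p in profiles], dtype=float)
    if model == "linear":
        res = stats.linregress(x, y)
        return ScalingFit(
            model="linear",
            parameters={"intercept": float(res.intercept), "slope": float(res.slope)},
            r_squared=float(res.rvalue**2),
            n_points=len(x),
        )
    offset = 1.0 if (y == 0).any() else 0.0
    logy = np.log(y + offset)
    res = stats.linregress(x, logy)
    return ScalingFit(
        model="exponential",
        parameters={"a": float(np.exp(res.intercept)), "b": float(res.slope)},
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


@dataclass(frozen=True)
class PhylogroupSummary:
    """Mean +/- sample SD of genome size within one phylogroup."""

    group: str
    n: int
    mean_mb: float
    sd_mb: float

    def formatted(self) -> str:
        return f"{self.mean_mb:.2f} ± {self.sd_mb:.2f} Mb"


def phylogroup_size_summary(
    profiles: Iterable[DegradomeProfile],
) -> list[PhylogroupSummary]:
    """Per-phylogroup genome-size mean and sample (n-1) standard deviation.

    Singleton groups report SD 0.00; unlabelled genomes are pooled under
    ``unaffiliated``.  Values are rounded to 2 decimals in ``formatted``.
    """
    groups: dict[str, list[float]] = {}
    for p in profiles:
        groups.setdefault(p.phylogroup or "unaffiliated", []).append(p.genome_size_mb)
    out = []
    for group in sorted(groups):
        sizes = np.array(groups[group], dtype=float)
        if np.isnan(sizes).any():
            warnings.warn(f"phylogroup {group} has genomes without size; skipped")
            continue
        sd = float(np.std(sizes, ddof=1)) if len(sizes) > 1 else 0.0
        out.append(
            PhylogroupSummary(
                group=group, n=len(sizes), mean_mb=float(np.mean(sizes)), sd_mb=sd
            )
        )
    return out


def ratio_scatter(
    profiles: Sequence[DegradomeProfile], degradative_only: bool = True
) -> pd.DataFrame:
    """Tidy table for size-versus-ratio scatter plots (genomes vs MAGs).

    One row per genome: size, CAZyme:peptidase ratio, phylogroup tag and
    the genome-vs-MAG marker.  Profiles without a defined ratio are
    dropped with a warning.
    """
    rows = []
    for p in profiles:
        r = p.ratio if degradative_only else p.ratio_total
        if r is None:
            warnings.warn(f"{p.genome_id}: no peptidases, ratio undefined; dropped")
            continue
        rows.append(
            {
                "genome_id": p.genome_id,
                "genome_size_mb": p.genome_size_mb,
                "cazyme_peptidase_ratio": r,
                "phylogroup": p.phylogroup or "unaffiliated",
                "is_mag": p.is_mag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "genome_size_mb",
            "cazyme_peptidase_ratio",
            "phylogroup",
            "is_mag",
        ],
    )


def profiles_table(profiles: Sequence[DegradomeProfile]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": p.genome_id,
            "genome_size_mb": p.genome_size_mb,
            "n_cazymes_total": p.n_cazymes_total,
            "n_cazymes_degradative": p.n_cazymes_degradative,
            "n_peptidases": p.n_peptidases,
            "n_sulfatases": p.n_sulfatases,
            "ratio": p.ratio,
            "phylogroup": p.phylogroup or "",
            "is_mag": p.is_mag,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)
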