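"""Formula-level microbial community metrics over OTU count tables.

Alpha diversity (observed OTUs, bias-corrected Chao1, Shannon H, the
Gini–Simpson index D = 1 − Σp², Good's coverage), seeded rarefaction by
exact hypergeometric subsampling, three-way OTU sharing (Venn regions),
Archaea:Bacteria-style domain ratios, and rank-level relative-abundance
tables with minor taxa pooled into "others".

An OTU table is taxa × samples of non-negative integer read counts with an
optional semicolon-separated taxonomy lineage per taxon
(``domain;phylum;class;order;family;genus``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "DiversityReport",
    "alpha_diversity",
    "rarefy",
    "venn3",
    "domain_ratio",
    "abundance_table",
    "TAXONOMIC_RANKS",
]

TAXONOMIC_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class OtuTable:
    """Taxa × samples integer counts, with optional taxonomy lineages."""

    counts: pd.DataFrame  # index = taxa, columns = samples
    taxonomy: pd.Series | None = None  # taxon -> "domain;phylum;...;genus"

    def __post_init__(self) -> None:
        c = self.counts
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("OTU counts must be integers")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    def sample_counts(self, sample: str) -> np.ndarray:
        return self.counts[sample].to_numpy()

    def observed_taxa(self, sample: str) -> set[str]:
        col = self.counts[sample]
        return set(col.index[col > 0])

    def lineage_at_rank(self, rank: str) -> pd.Series:
        """Taxonomy label of every taxon at *rank*; 'unclassified' if short."""
        if self.taxonomy is None:
            raise ValueError("OTU table carries no taxonomy")
        try:
            level = TAXONOMIC_RANKS.index(rank)
        except ValueError:
            raise ValueError(
                f"unknown rank {rank!r}; choose from {TAXONOMIC_RANKS}"
            ) from None

        def pick(lineage: object) -> str:
            if not isinstance(lineage, str):
                return "unclassified"
            parts = [p.strip() for p in lineage.split(";")]
            return parts[level] if level < len(parts) and parts[level] else "unclassified"

        return self.taxonomy.map(pick)


@dataclass(frozen=True)
class DiversityReport:
    """Per-sample alpha-diversity indices (rows = samples)."""

    frame: pd.DataFrame  # columns: observed_otus, chao1, shannon, simpson, goods_coverage

    def __post_init__(self) -> None:
        f = self.frame
        assert (f["chao1"] + 1e-9 >= f["observed_otus"]).all()
        assert f["simpson"].between(-1e-12, 1.0 + 1e-12).all()
        assert (f["shannon"] >= -1e-12).all()
        assert f["goods_coverage"].between(-1e-9, 100.0 + 1e-9).all()


def _alpha_one(counts: np.ndarray, shannon_base: float, chao1_bias_corrected: bool):
    counts = counts[counts > 0]
    n = int(counts.sum())
    if n < 1:
        raise ValueError("empty sample: no reads")
    s_obs = counts.size
    p = counts / n
    shannon = float(-(p * np.log(p)).sum() / math.log(shannon_base))
    simpson = float(1.0 - (p * p).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if chao1_bias_corrected:
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        chao1 = s_obs + (f1 * f1 / (2.0 * f2) if f2 > 0 else 0.0)
    coverage = 100.0 * (1.0 - f1 / n)
    return s_obs, chao1, shannon, simpson, coverage


def alpha_diversity(
    table: OtuTable,
    shannon_base: float = 2,
    chao1_bias_corrected: bool = True,
) -> DiversityReport:
    """All five alpha indices for every sample of the table.

    observed = taxa with >0 reads; H = −Σ p·log_b(p); D = 1 − Σp²
    (Gini–Simpson); Chao1 = S_obs + F₁(F₁−1)/(2(F₂+1)) (bias-corrected; the
    classic F₁²/(2F₂) form via ``chao1_bias_corrected=False``); Good's
    coverage = 100·(1 − F₁/N) with F₁, F₂ the singleton and doubleton
    counts and N the sample total.
    """
    rows = {}
    for sample in table.samples:
        rows[sample] = _alpha_one(
            table.sample_counts(sample), shannon_base, chao1_bias_corrected
        )
    frame = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["observed_otus", "chao1", "shannon", "simpson", "goods_coverage"],
    )
    frame.index.name = "sample"
    return DiversityReport(frame)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly *depth* reads without replacement.

    Uses exact multivariate hypergeometric draws, seeded and reproducible.
    Samples shallower than *depth* are dropped with a warning rather than
    padded — matching the usual even-depth normalisation workflow.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    kept: dict[str, np.ndarray] = {}
    for sample in table.samples:
        counts = table.sample_counts(sample)
        total = int(counts.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} < depth {depth}; dropped",
                stacklevel=2,
            )
            continue
        if total == depth:
            kept[sample] = counts.copy()
        else:
            kept[sample] = rng.multivariate_hypergeometric(counts, depth)
    if not kept:
        raise ValueError("no sample is deep enough for the requested depth")
    out = pd.DataFrame(kept, index=table.counts.index)
    return OtuTable(counts=out, taxonomy=table.taxonomy)


def venn3(
    a: set[str], b: set[str], c: set[str]
) -> tuple[dict[str, int], dict[str, float]]:
    """Seven-region counts for three OTU sets, plus percent of the union.

    Region keys: ``"A" "B" "C"`` (unique), ``"AB" "AC" "BC"`` (pairwise
    only) and ``"ABC"`` (core).  Percentages are of the union, one decimal.
    """
    if not (a and b and c):
        raise ValueError("all three sets must be non-empty")
    union = a | b | c
    core = a & b & c
    regions = {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "ABC": len(core),
    }
    n_union = len(union)
    percents = {k: round(100.0 * v / n_union, 1) for k, v in regions.items()}
    return regions, percents


def domain_ratio(
    table: OtuTable, numerator: str = "Archaea", denominator: str = "Bacteria"
) -> pd.Series:
    """Per-sample read-count ratio of two domains (e.g. Archaea:Bacteria).

    A zero denominator is reported as ``inf``; a numerator or denominator
    label absent from the taxonomy altogether raises, signalling a label
    mismatch rather than a genuine zero.
    """
    domains = table.lineage_at_rank("domain")
    present = set(domains.dropna())
    if numerator not in present and denominator not in present:
        raise ValueError(
            f"neither {numerator!r} nor {denominator!r} appears in the taxonomy"
        )
    num_mask = (domains == numerator).to_numpy()
    den_mask = (domains == denominator).to_numpy()
    out = {}
    for sample in table.samples:
        counts = table.sample_counts(sample)
        num = counts[num_mask].sum()
        den = counts[den_mask].sum()
        out[sample] = float(num) / den if den > 0 else float("inf")
    return pd.Series(out, name=f"{numerator}:{denominator}")


def abundance_table(
    table: OtuTable, rank: str, threshold_percent: float = 1.0
) -> pd.DataFrame:
    """Relative abundance (%) per sample at a taxonomic rank.

    Taxa aggregate by their label at *rank*; any label whose abundance is
    below *threshold_percent* in every sample pools into ``"others"``.
    Rows sort lexicographically ("others" last); columns sum to 100.
    """
    labels = table.lineage_at_rank(rank)
    grouped = table.counts.groupby(labels).sum()
    rel = 100.0 * grouped / grouped.sum(axis=0)
    minor = (rel < threshold_percent).all(axis=1)
    major = rel.loc[~minor].sort_index()
    if minor.any():
        others = rel.loc[minor].sum(axis=0).to_frame("others").T
        major = pd.concat([major, others])
    major.index.name = rank
    return major
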