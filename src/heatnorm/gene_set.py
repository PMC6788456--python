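"""SNP-to-gene assignment, candidate flagging, and gene-set enrichment.

The gene-set stage of the genome scan proceeds in three steps: SNPs are
assigned to annotated genes when they fall inside the gene body or within a
symmetric flank (15 kb by default); genes hit by at least one "relevant"
SNP — those in the top tail of the absolute SNP-effect distribution — in a
minimum number of parities become thermotolerance candidates; and each
functional gene set is tested for overrepresentation of candidates with
Fisher's exact test (upper-tail hypergeometric probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval; coordinates 1-based inclusive, strand informational."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.start <= 0:
            raise ValueError(f"{self.gene}: coordinates must be positive")


@dataclass
class GeneSetCollection:
    """Named gene sets over a gene universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    n_candidates: int
    universe_size: int
    p_value: float
    fdr: float = field(default=float("nan"), compare=False)


def read_gene_annotation(path, dialect: str = "native") -> list[GeneAnnotation]:
    """Read gene intervals from TSV.

    ``dialect="native"`` expects 1-based inclusive columns
    (gene, chrom, start, end[, strand]); ``dialect="bed"`` expects 0-based
    half-open BED columns (chrom, start, end, gene[, score, strand]) and
    converts on ingest.
    """
    if dialect == "native":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        strand = df["strand"] if "strand" in df else ["+"] * len(df)
        return [
            GeneAnnotation(str(g), str(c), int(s), int(e), str(st))
            for g, c, s, e, st in zip(df["gene"], df["chrom"], df["start"], df["end"], strand)
        ]
    if dialect == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "gene", "score", "strand"][
                : len(pd.read_csv(path, sep="\t", header=None, nrows=1).columns)
            ],
            dtype={"chrom": str},
        )
        strand = df["strand"] if "strand" in df else ["+"] * len(df)
        return [
            GeneAnnotation(str(g), str(c), int(s) + 1, int(e), str(st))
            for g, c, s, e, st in zip(df["chrom"], df["start"], df["end"], df["gene"], strand)
        ]
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (set name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def assign_snps_to_genes(
    snp_map: pd.DataFrame,
    annotation: list[GeneAnnotation],
    flank: int = 15_000,
) -> dict[str, set[str]]:
    """Map SNP ids to the genes whose flanked interval contains them.

    A SNP at position ``x`` on the gene's chromosome is assigned when
    ``start - flank <= x <= end + flank`` (boundaries inclusive); a SNP may
    map to several overlapping genes.  Returns ``{snp_id: {gene, ...}}``
    with unassigned SNPs mapped to an empty set.
    """
    assigned: dict[str, set[str]] = {str(s): set() for s in snp_map["snp"]}
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, grp in snp_map.groupby(snp_map["chrom"].astype(str)):
        genes = by_chrom.get(chrom, [])
        if not genes:
            continue
        pos = grp["pos"].to_numpy()
        ids = grp["snp"].to_numpy()
        lo = np.array([g.start - flank for g in genes])
        hi = np.array([g.end + flank for g in genes])
        for p, s in zip(pos, ids):
            hits = np.flatnonzero((lo <= p) & (p <= hi))
            if hits.size:
                assigned[str(s)].update(genes[k].gene for k in hits)
    return assigned


def relevant_snps(effects: np.ndarray, snp_ids, top_fraction: float = 0.05) -> set[str]:
    """SNPs whose |effect| reaches the top ``top_fraction`` of the
    distribution (ties at the cutoff are kept, so ties can yield more than
    the nominal fraction)."""
    effects = np.abs(np.asarray(effects, dtype=float))
    if effects.size == 0:
        raise ValueError("empty effect track")
    cutoff = np.quantile(effects, 1.0 - top_fraction)
    keep = effects >= cutoff
    return {str(s) for s, k in zip(snp_ids, keep) if k}


def flag_candidate_genes(
    tracks: dict[int, np.ndarray],
    snp_ids,
    mapping: dict[str, set[str]],
    top_fraction: float = 0.05,
    min_parities: int = 2,
) -> set[str]:
    """Candidate genes: hit by >= 1 relevant SNP in >= ``min_parities`` parities.

    ``tracks`` maps parity to the per-SNP effect vector (the thermotolerance
    slope track, by default framing); all tracks share ``snp_ids`` order.
    """
    gene_parities: dict[str, set[int]] = {}
    for parity, effects in tracks.items():
        rel = relevant_snps(effects, snp_ids, top_fraction)
        for snp in rel:
            for gene in mapping.get(snp, ()):
                gene_parities.setdefault(gene, set()).add(parity)
    return {g for g, ps in gene_parities.items() if len(ps) >= min_parities}


def fisher_enrichment(
    candidates: set[str],
    collection: GeneSetCollection,
    compute_fdr: bool = True,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment P(X >= k) per gene set.

    With universe size N, set size K, and n candidate genes, the p-value for
    an overlap of k is the cumulative hypergeometric tail — Fisher's exact
    test of proportions.  Results are sorted by p-value; an auxiliary
    Benjamini-Hochberg FDR column is attached for reference.
    """
    stray = candidates - collection.universe
    if stray:
        raise ValueError(f"candidates outside universe: {sorted(stray)[:5]}")
    N = len(collection.universe)
    n = len(candidates)
    results = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(candidates & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append((name, k, K, p))
    results.sort(key=lambda t: (t[3], t[0]))
    ps = np.array([t[3] for t in results])
    if compute_fdr and len(ps):
        m = len(ps)
        ranked = ps * m / (np.arange(m) + 1)
        fdr = np.minimum.accumulate(ranked[::-1])[::-1]
        fdr = np.minimum(fdr, 1.0)
    else:
        fdr = np.full(len(ps), np.nan)
    return [
        EnrichmentResult(name, k, K, n, N, p, float(q))
        for (name, k, K, p), q in zip(results, fdr)
    ]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_name, r.overlap, r.set_size, r.n_candidates, r.universe_size,
             r.p_value, r.fdr)
            for r in results
        ],
        columns=["set", "overlap", "set_size", "n_candidates", "universe", "p", "fdr"],
    )
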