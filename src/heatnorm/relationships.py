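"""Pedigree and genomic relationship machinery for single-step GBLUP.

Builds the sparse inverse numerator relationship matrix A⁻¹ (Henderson's
rules with inbreeding from the Meuwissen–Luo recursion), the pedigree
relationship block A₂₂ among genotyped animals, the genomic relationship
matrix G (centred cross-product scaled by 2Σp(1−p), blended with A₂₂), and
the combined single-step inverse

    H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹]

in which the genotyped block of A⁻¹ is corrected by the difference between
genomic and pedigree information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

UNKNOWN = "0"


@dataclass
class Pedigree:
    """A renumbered, topologically ordered pedigree.

    ``sire[i]`` / ``dam[i]`` are integer codes of animal *i*'s parents, or
    -1 when unknown; parents always precede offspring.  ``ids`` maps codes
    back to the original identifiers.
    """

    ids: list[str]
    sire: np.ndarray  # int32, -1 = unknown
    dam: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def code(self, animal: str) -> int:
        return self._index[animal]

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, str]]
    ) -> "Pedigree":
        """Build from (animal, sire, dam) triples; ``"0"`` = unknown parent.

        Parents that never appear as animals are added as founders.  Raises
        ``ValueError`` naming the members of any parent-offspring cycle.
        """
        parents: dict[str, tuple[str, str]] = {}
        for animal, sire, dam in records:
            animal, sire, dam = str(animal), str(sire), str(dam)
            if animal == UNKNOWN:
                raise ValueError("animal id '0' is reserved for unknown parents")
            parents[animal] = (sire, dam)
        for animal in list(parents):
            for p in parents[animal]:
                if p != UNKNOWN and p not in parents:
                    parents[p] = (UNKNOWN, UNKNOWN)

        # Kahn toposort: parents before offspring.
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unvisited, 1 in-stack, 2 done

        def visit(a: str) -> None:
            stack = [(a, iter([p for p in parents[a] if p != UNKNOWN]))]
            state[a] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    st = state.get(p, 0)
                    if st == 1:
                        cycle = [n for n, _ in stack] + [p]
                        raise ValueError(
                            "pedigree cycle detected: " + " -> ".join(cycle)
                        )
                    if st == 0:
                        state[p] = 1
                        stack.append(
                            (p, iter([q for q in parents[p] if q != UNKNOWN]))
                        )
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    order.append(node)
                    stack.pop()

        for a in parents:
            if state.get(a, 0) == 0:
                visit(a)

        index = {a: i for i, a in enumerate(order)}
        sire = np.full(len(order), -1, dtype=np.int32)
        dam = np.full(len(order), -1, dtype=np.int32)
        for a, (s, d) in parents.items():
            i = index[a]
            if s != UNKNOWN:
                sire[i] = index[s]
            if d != UNKNOWN:
                dam[i] = index[d]
        return cls(ids=order, sire=sire, dam=dam)


def read_pedigree(path) -> Pedigree:
    """Read a 3-column delimited pedigree (animal, sire, dam; 0 = unknown)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = list(df.columns[:3])
    return Pedigree.from_records(list(df[cols].itertuples(index=False, name=None)))


def write_pedigree(ped: Pedigree, path) -> None:
    rows = {
        "animal": ped.ids,
        "sire": [ped.ids[s] if s >= 0 else UNKNOWN for s in ped.sire],
        "dam": [ped.ids[d] if d >= 0 else UNKNOWN for d in ped.dam],
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen–Luo recursion.

    Traces, for each animal, the row of the Cholesky factor of A over its
    ancestors so that ``F_i = sum_j L_ij^2 D_j - 1`` where ``D_j`` is the
    Mendelian-sampling variance share of ancestor *j*.  Unknown parents are
    treated as unrelated non-inbred founders (the convention F = -1 for an
    unknown parent makes one formula cover all parent configurations).
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (Fs + Fd)
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        L: dict[int, float] = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            lij = L.pop(j, 0.0)
            if lij == 0.0:
                continue
            aii += lij * lij * D[j]
            if sire[j] >= 0:
                L[sire[j]] = L.get(sire[j], 0.0) + 0.5 * lij
            if dam[j] >= 0:
                L[dam[j]] = L.get(dam[j], 0.0) + 0.5 * lij
        F[i] = aii - 1.0
    return F


def mendelian_sampling_variance(ped: Pedigree) -> np.ndarray:
    """Within-family (Mendelian sampling) variance share per animal."""
    n = len(ped)
    F = inbreeding_coefficients(ped)
    Fs = np.where(ped.sire >= 0, F[np.maximum(ped.sire, 0)], -1.0)
    Fd = np.where(ped.dam >= 0, F[np.maximum(ped.dam, 0)], -1.0)
    return 0.5 - 0.25 * (Fs + Fd)


def tabular_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular recursion.

    Quadratic in pedigree size; intended for moderate pedigrees (the
    synthetic-data scale) and for A₂₂ extraction.
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
    return A


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix (or its inverse) over an ordered id list."""

    values: np.ndarray | sp.spmatrix
    ids: list[str]
    kind: str  # A, A_inverse, A22, A22_inverse, G, G_inverse, H_inverse

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def save(self, path) -> None:
        """Persist to an .npz container together with the ordered id list."""
        np.savez_compressed(
            path, values=self.dense(), ids=np.array(self.ids), kind=self.kind
        )

    @classmethod
    def load(cls, path) -> "RelationshipMatrix":
        z = np.load(path, allow_pickle=False)
        return cls(values=z["values"], ids=list(z["ids"]), kind=str(z["kind"]))


def build_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A⁻¹ by Henderson's rules, accounting for inbreeding.

    Each animal contributes ``alpha = 1/D_i`` (the inverse Mendelian-sampling
    variance share) to its own diagonal, ``-alpha/2`` to animal-parent pairs
    and ``alpha/4`` to parent-parent pairs, for its known parents.
    """
    n = len(ped)
    D = mendelian_sampling_variance(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / D[i]
        par = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        add(i, i, alpha)
        for p in par:
            add(i, p, -alpha / 2.0)
            add(p, i, -alpha / 2.0)
        for p in par:
            for q in par:
                add(p, q, alpha / 4.0)
    Ainv = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n, n), dtype=float
    )
    Ainv.sum_duplicates()
    return RelationshipMatrix(values=Ainv, ids=list(ped.ids), kind="A_inverse")


def extract_A22(ped: Pedigree, genotyped_ids: Sequence[str]) -> RelationshipMatrix:
    """Pedigree relationship block among the genotyped animals."""
    unknown = [g for g in genotyped_ids if g not in ped._index]
    if unknown:
        raise KeyError(f"genotyped ids not in pedigree: {unknown}")
    idx = np.array([ped.code(g) for g in genotyped_ids], dtype=int)
    A = tabular_A(ped)
    return RelationshipMatrix(
        values=A[np.ix_(idx, idx)], ids=[str(g) for g in genotyped_ids], kind="A22"
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Allele-count genotypes (0/1/2) with a physical SNP map.

    ``codes[i, j]`` counts copies of the designated counted allele of SNP
    *j* in individual *i*.  ``snp_map`` has columns (snp, chrom, pos,
    counted_allele), positions sorted within chromosome.  Missing calls are
    rejected on construction.
    """

    codes: np.ndarray
    ids: list[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if not np.isin(codes, (0, 1, 2)).all():
            raise ValueError(
                "genotype codes must be 0/1/2 with no missing values"
            )
        if codes.shape[0] != len(self.ids):
            raise ValueError("row count must match number of individual ids")
        if codes.shape[1] != len(self.snp_map):
            raise ValueError("column count must match SNP map length")
        pos = self.snp_map["pos"].to_numpy()
        if (pos < 0).any():
            raise ValueError("map positions must be non-negative")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) >= 0):
                raise ValueError("map positions must be sorted within chromosome")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed counted-allele frequencies per SNP."""
        return self.codes.mean(axis=0) / 2.0


def read_genotypes(matrix_path, map_path) -> GenotypeMatrix:
    """Read a 0/1/2 genotype matrix (header = SNP ids, first column = id)
    and its SNP map TSV (snp, chrom, pos, counted_allele)."""
    gm = pd.read_csv(matrix_path, sep="\t", index_col=0)
    smap = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    if list(gm.columns) != list(smap["snp"]):
        raise ValueError("genotype matrix columns do not match SNP map order")
    return GenotypeMatrix(
        codes=gm.to_numpy(dtype=np.int8),
        ids=[str(i) for i in gm.index],
        snp_map=smap,
    )


def write_genotypes(geno: GenotypeMatrix, matrix_path, map_path) -> None:
    pd.DataFrame(
        geno.codes, index=pd.Index(geno.ids, name="id"), columns=geno.snp_map["snp"]
    ).to_csv(matrix_path, sep="\t")
    geno.snp_map.to_csv(map_path, sep="\t", index=False)


def qc_snps(
    geno: GenotypeMatrix,
    sex_chromosomes: set[str] = frozenset({"X", "Y"}),
    maf_min: float = 0.01,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop SNPs on sex chromosomes, monomorphic SNPs, and SNPs with minor
    allele frequency strictly below ``maf_min``.

    Filters are applied in that order and each removed SNP is counted under
    the first filter it fails.  Returns the retained subset and a report
    ``{"sex": n, "mono": n, "maf": n, "retained": n}``.
    """
    chrom = geno.snp_map["chrom"].astype(str).to_numpy()
    p = geno.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    on_sex = np.isin(chrom, list(sex_chromosomes))
    mono = (~on_sex) & ((p == 0.0) | (p == 1.0))
    low_maf = (~on_sex) & (~mono) & (maf < maf_min)
    keep = ~(on_sex | mono | low_maf)
    report = {
        "sex": int(on_sex.sum()),
        "mono": int(mono.sum()),
        "maf": int(low_maf.sum()),
        "retained": int(keep.sum()),
    }
    out = GenotypeMatrix(
        codes=geno.codes[:, keep],
        ids=list(geno.ids),
        snp_map=geno.snp_map.loc[keep].reset_index(drop=True),
    )
    return out, report


def build_G(
    geno: GenotypeMatrix,
    A22: RelationshipMatrix,
    blend: float = 0.05,
) -> RelationshipMatrix:
    """Genomic relationship matrix, blended with the pedigree block.

    ``G_raw = ZZ' / (2 Σ p_j (1 - p_j))`` with ``Z`` the genotype matrix
    centred by twice the observed allele frequencies; the returned matrix is
    ``(1 - blend)·G_raw + blend·A22``, which keeps G invertible when the
    marker matrix is rank deficient.
    """
    if geno.n_individuals < 2:
        raise ValueError("G requires at least two individuals")
    if list(A22.ids) != list(geno.ids):
        raise ValueError("A22 ids must match genotype ids in order")
    p = geno.allele_frequencies()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all SNPs are monomorphic; G denominator is zero")
    Z = geno.codes.astype(float) - 2.0 * p
    G_raw = (Z @ Z.T) / denom
    G = (1.0 - blend) * G_raw + blend * A22.dense()
    return RelationshipMatrix(values=G, ids=list(geno.ids), kind="G")


def build_H_inverse(
    A_inv: RelationshipMatrix,
    G_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix,
    genotyped_index: np.ndarray,
) -> RelationshipMatrix:
    """Single-step H⁻¹: A⁻¹ with (G⁻¹ − A₂₂⁻¹) added into the genotyped block."""
    n = A_inv.values.shape[0]
    genotyped_index = np.asarray(genotyped_index, dtype=int)
    if genotyped_index.size and (
        genotyped_index.min() < 0 or genotyped_index.max() >= n
    ):
        raise IndexError("genotyped_index out of range of A ordering")
    if G_inv.values.shape[0] != genotyped_index.size:
        raise ValueError("G_inv dimension must match number of genotyped animals")
    if A22_inv.values.shape != G_inv.values.shape:
        raise ValueError("A22_inv and G_inv dimensions differ")
    delta = np.asarray(G_inv.dense() - A22_inv.dense())
    ng = genotyped_index.size
    rows = np.repeat(genotyped_index, ng)
    cols = np.tile(genotyped_index, ng)
    correction = sp.csr_matrix(
        (delta.ravel(), (rows, cols)), shape=(n, n), dtype=float
    )
    H_inv = sp.csr_matrix(A_inv.values, dtype=float) + correction
    return RelationshipMatrix(values=H_inv, ids=list(A_inv.ids), kind="H_inverse")


def invert(rel: RelationshipMatrix, kind: str | None = None) -> RelationshipMatrix:
    """Dense inverse of a relationship matrix (for G⁻¹ and A₂₂⁻¹)."""
    inv = np.linalg.inv(rel.dense())
    inv = 0.5 * (inv + inv.T)
    return RelationshipMatrix(
        values=inv, ids=list(rel.ids), kind=kind or (rel.kind + "_inverse")
    )
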