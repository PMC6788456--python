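"""SNP-effect backsolving and moving-window variance decomposition.

Given genomic breeding values (GEBVs) of genotyped animals from a
single-step evaluation, per-SNP effects are recovered as

    s_hat = D Z' (Z D Z')⁻ a_hat

with Z the centred genotype matrix, D per-SNP weights (identity here: all
SNPs equally weighted) and (·)⁻ a spectral pseudo-inverse — with more SNPs
than animals Z D Z' is singular by construction, and the pseudo-inverse
yields the minimum-norm preimage.  Windows of adjacent SNPs spanning at
most 2.0 Mb, anchored at every SNP, are then scored by the percentage of
total genomic variance their summed SNP effects explain across the
genotyped individuals.  The scan is run separately on the general
(intercept) and thermotolerance (slope) GEBV components, per parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heatnorm.relationships import GenotypeMatrix


@dataclass
class SnpEffectTrack:
    """Backsolved per-SNP effects for one GEBV component and parity."""

    effects: np.ndarray
    snp_map: pd.DataFrame
    component: str  # "general" or "thermotolerance"
    parity: int
    allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.effects) != len(self.snp_map):
            raise ValueError("effects length must match SNP map")
        if not np.isfinite(self.effects).all():
            raise ValueError("SNP effects must be finite")


@dataclass
class WindowVarianceTrack:
    """Per-window share of genomic variance for one component/parity."""

    windows: pd.DataFrame  # chrom, start, end, first_snp, last_snp, n_snps, pct_variance
    denominator: float
    component: str = ""
    parity: int = 0


def centred_genotypes(
    geno: GenotypeMatrix, allele_freqs: np.ndarray | None = None
) -> np.ndarray:
    """Genotype codes centred by twice the allele frequencies (the same
    frequencies used to build G, when supplied)."""
    p = geno.allele_frequencies() if allele_freqs is None else np.asarray(allele_freqs)
    return geno.codes.astype(float) - 2.0 * p


def backsolve_snp_effects(
    gebv: np.ndarray,
    geno: GenotypeMatrix,
    component: str = "thermotolerance",
    parity: int = 1,
    weights: np.ndarray | None = None,
    allele_freqs: np.ndarray | None = None,
    eig_cutoff: float = 1e-10,
) -> SnpEffectTrack:
    """Backsolve SNP effects from GEBVs of the genotyped animals.

    ``weights`` are the diagonal of D (all ones by default).  The
    pseudo-inverse drops eigenvalues below ``eig_cutoff`` times the largest,
    so the result is the minimum-norm least-squares preimage of the GEBV
    vector under Z D Z'.
    """
    gebv = np.asarray(gebv, dtype=float)
    if gebv.shape[0] != geno.n_individuals:
        raise ValueError(
            f"GEBV length {gebv.shape[0]} != genotyped individuals {geno.n_individuals}"
        )
    if weights is None:
        weights = np.ones(geno.n_snps)
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any():
        raise ValueError("SNP weights must be positive")
    Z = centred_genotypes(geno, allele_freqs)
    ZD = Z * weights
    M = ZD @ Z.T  # n_geno x n_geno
    M = 0.5 * (M + M.T)
    evals, evecs = np.linalg.eigh(M)
    keep = evals > eig_cutoff * evals.max()
    Minv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    s_hat = ZD.T @ (Minv @ gebv)
    return SnpEffectTrack(
        effects=s_hat,
        snp_map=geno.snp_map,
        component=component,
        parity=parity,
        allele_freqs=(
            np.asarray(allele_freqs)
            if allele_freqs is not None
            else geno.allele_frequencies()
        ),
    )


def window_variance(
    track: SnpEffectTrack,
    geno: GenotypeMatrix,
    window_bp: int = 2_000_000,
    sigma_u2: float | None = None,
) -> WindowVarianceTrack:
    """Percent of genomic variance explained by each 2.0-Mb moving window.

    Windows are anchored at every SNP and cover positions
    ``[anchor, anchor + window_bp)`` on the same chromosome.  For window w,
    ``pct = 100 * var_i(sum_{j in w} Z_ij s_j) / sigma_u^2`` where the
    variance is over genotyped individuals.  By default ``sigma_u^2`` is the
    variance of the total genomic value ``Z s``; an externally computed
    denominator (e.g. the GEBV variance) may be supplied instead.
    """
    if len(track.effects) != geno.n_snps:
        raise ValueError("track and genotype matrix are not aligned")
    Z = centred_genotypes(geno, track.allele_freqs)
    total = Z @ track.effects
    if sigma_u2 is None:
        sigma_u2 = float(np.var(total))
    if sigma_u2 == 0:
        raise ValueError("total genomic variance is zero; nothing to decompose")

    rows = []
    chroms = track.snp_map["chrom"].astype(str).to_numpy()
    pos = track.snp_map["pos"].to_numpy()
    # Prefix sums of per-SNP genomic contributions give each window's
    # genomic value in O(1): cum[:, j1] - cum[:, j0].
    contrib = Z * track.effects
    cum = np.concatenate(
        [np.zeros((Z.shape[0], 1)), np.cumsum(contrib, axis=1)], axis=1
    )
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if idx.size == 0:  # pragma: no cover
            continue
        cpos = pos[idx]
        for a in range(idx.size):
            j1 = a + int(np.searchsorted(cpos[a:], cpos[a] + window_bp, side="left"))
            g = cum[:, idx[j1 - 1] + 1] - cum[:, idx[a]]
            rows.append(
                (
                    chrom,
                    int(cpos[a]),
                    int(cpos[a] + window_bp),
                    int(idx[a]),
                    int(idx[j1 - 1]),
                    j1 - a,
                    100.0 * float(np.var(g)) / sigma_u2,
                )
            )
    windows = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "first_snp", "last_snp", "n_snps", "pct_variance"],
    )
    return WindowVarianceTrack(
        windows=windows,
        denominator=sigma_u2,
        component=track.component,
        parity=track.parity,
    )


def manhattan_table(tracks: list[WindowVarianceTrack], top_k: int | None = None) -> pd.DataFrame:
    """Ranked window report across components and parities.

    Windows are ranked by percent variance within each component/parity
    (rank 1 = largest); ``top_k`` truncates each group after ranking.
    """
    if not tracks:
        raise ValueError("at least one window track is required")
    frames = []
    for t in tracks:
        df = t.windows.copy()
        df["component"] = t.component
        df["parity"] = t.parity
        df = df.sort_values("pct_variance", ascending=False, kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        if top_k is not None:
            df = df.head(top_k)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_track(track: SnpEffectTrack | WindowVarianceTrack, path) -> None:
    if isinstance(track, SnpEffectTrack):
        out = track.snp_map.copy()
        out["effect"] = track.effects
        out["component"] = track.component
        out["parity"] = track.parity
    else:
        out = track.windows.copy()
        out["component"] = track.component
        out["parity"] = track.parity
    out.to_csv(path, sep="\t", index=False)


def manhattan_plot(tracks: list[WindowVarianceTrack], path) -> None:
    """Simple per-parity Manhattan panels of window variance percentages."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    parities = sorted({t.parity for t in tracks})
    components = sorted({t.component for t in tracks})
    fig, axes = plt.subplots(
        len(parities), len(components),
        figsize=(5 * len(components), 2.5 * len(parities)),
        squeeze=False,
    )
    for i, parity in enumerate(parities):
        for j, comp in enumerate(components):
            ax = axes[i][j]
            for t in tracks:
                if t.parity == parity and t.component == comp:
                    for k, (chrom, grp) in enumerate(t.windows.groupby("chrom")):
                        ax.scatter(
                            grp["start"], grp["pct_variance"], s=4,
                            color=f"C{k % 10}",
                        )
            ax.set_title(f"{comp}, parity {parity}", fontsize=9)
            ax.set_ylabel("% genetic variance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
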