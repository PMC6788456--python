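"""Gibbs sampling of variance components for the reaction-norm model.

The sampler alternates between (i) a blockwise sweep of all location
effects from their conditional normals — scalars for fixed effects and
(intercept, slope) pairs for additive and permanent-environment effects —
and (ii) conjugate draws of the (co)variance matrices: Φ from an
inverse-Wishart whose scale accumulates the K⁻¹-quadratic cross-product of
the additive coefficient vectors, Ψ analogously over cows, and each
parity's residual variance from a scaled inverse chi-square of that
parity's residuals.  The sparsity pattern of the mixed-model coefficient
matrix is built once; only its data array is refreshed per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import invwishart

from heatnorm.mixed_model._kernels import csr_position_map, sweep_blocks
from heatnorm.mixed_model.design import DesignSystem
from heatnorm.mixed_model.mme import VarianceComponents
from heatnorm.relationships import RelationshipMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainSpec:
    """MCMC run lengths.

    The desk-scale default (20 000 total, 5 000 burn-in, thin 10) targets
    routine synthetic analyses; ``ChainSpec.reference_protocol()`` gives the
    long production protocol (500 000 / 100 000 / 100).
    """

    total: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.total:
            raise ValueError("burn_in must be smaller than total")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.total - self.burn_in) // self.thin

    @classmethod
    def reference_protocol(cls, seed: int = 0) -> "ChainSpec":
        return cls(total=500_000, burn_in=100_000, thin=100, seed=seed)


@dataclass
class GibbsPriors:
    """Proper priors: inverse-Wishart for Φ and Ψ, scaled inverse chi-square
    for residual variances, flat for fixed effects.

    ``Phi_mean``/``Psi_mean`` are prior expectations (typically literature
    starting values); with ``nu = dim + 2`` the inverse-Wishart scale
    ``mean * (nu - dim - 1)`` equals the mean itself, making the prior
    weakly informative.
    """

    Phi_mean: np.ndarray
    Psi_mean: np.ndarray
    se2_mean: np.ndarray
    nu_phi: float | None = None
    nu_psi: float | None = None
    nu_e: float = 5.0

    def __post_init__(self) -> None:
        self.Phi_mean = np.asarray(self.Phi_mean, dtype=float)
        self.Psi_mean = np.asarray(self.Psi_mean, dtype=float)
        self.se2_mean = np.atleast_1d(np.asarray(self.se2_mean, dtype=float))
        d = self.Phi_mean.shape[0]
        if self.nu_phi is None:
            self.nu_phi = d + 2
        if self.nu_psi is None:
            self.nu_psi = d + 2

    def phi_scale(self) -> np.ndarray:
        d = self.Phi_mean.shape[0]
        return self.Phi_mean * (self.nu_phi - d - 1)

    def psi_scale(self) -> np.ndarray:
        d = self.Psi_mean.shape[0]
        return self.Psi_mean * (self.nu_psi - d - 1)


@dataclass
class PosteriorChain:
    """Retained draws of the variance components with run metadata."""

    samples: pd.DataFrame
    parities: tuple[int, ...]
    meta: dict = field(default_factory=dict)

    def posterior_mean_vc(self) -> VarianceComponents:
        labels = _coef_labels(self.parities)
        d = len(labels)
        Phi = np.empty((d, d))
        Psi = np.empty((d, d))
        m = self.samples.mean()
        for i in range(d):
            for j in range(i, d):
                Phi[i, j] = Phi[j, i] = m[f"phi_{labels[i]}_{labels[j]}"]
                Psi[i, j] = Psi[j, i] = m[f"psi_{labels[i]}_{labels[j]}"]
        Rdiag = np.array([m[f"r_e{l}"] for l in self.parities])
        return VarianceComponents(Phi=Phi, Psi=Psi, Rdiag=Rdiag, parities=self.parities)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            self.samples.to_csv(fh, sep="\t", index=False)


def _coef_labels(parities: tuple[int, ...]) -> list[str]:
    return [f"{t}{l}" for l in parities for t in ("a", "v")]


def _tri_columns(prefix: str, labels: list[str]) -> list[tuple[str, int, int]]:
    d = len(labels)
    return [
        (f"{prefix}_{labels[i]}_{labels[j]}", i, j)
        for i in range(d)
        for j in range(i, d)
    ]


class _AlignedSystem:
    """Fixed-pattern CSR machinery for per-iteration coefficient updates."""

    def __init__(self, design: DesignSystem, K_inv: sp.csr_matrix):
        np_par = design.n_parities
        d = 2 * np_par
        n_coef = design.n_coef
        n_fixed = design.n_fixed
        W = design.W

        # Per-parity normal-equation pieces T_l = W_l' W_l, r_l = W_l' y_l.
        self.T = []
        self.r = []
        for parity in design.parities:
            mask = design.record_parity == parity
            Wl = W[mask]
            Tl = (Wl.T @ Wl).tocsr()
            Tl.sum_duplicates()
            Tl.sort_indices()
            self.T.append(Tl)
            self.r.append(Wl.T @ design.y[mask])
        self.n_records_per_parity = np.array(
            [(design.record_parity == p).sum() for p in design.parities]
        )

        # Additive precision pattern: K⁻¹ (x) full d×d blocks.
        K = K_inv.tocoo()
        K.sum_duplicates()
        self.K_csr = K_inv.tocsr()
        k_rows, k_cols, self.k_data = K.row, K.col, K.data
        blk = np.arange(d)
        add_rows = (
            n_fixed + (k_rows[:, None] * d + blk[None, :]).repeat(d, axis=1)
        ).ravel()
        add_cols = np.broadcast_to(
            n_fixed + k_cols[:, None, None] * d + blk[None, None, :],
            (len(k_cols), d, d),
        ).reshape(len(k_cols), d * d)
        add_cols = add_cols.ravel()
        # row pattern above: for nonzero t, rows are (k_rows[t]*d + i) each
        # repeated d times, cols cycle over j — matches data layout
        # (k_data[t] * Phi_inv[i, j]).

        # Permanent-environment precision pattern: I (x) full d×d blocks.
        pe_off = design.permanent_slice.start
        cow_idx = np.arange(design.n_cows)
        pe_rows = (
            pe_off + (cow_idx[:, None] * d + blk[None, :]).repeat(d, axis=1)
        ).ravel()
        pe_cols = np.broadcast_to(
            pe_off + cow_idx[:, None, None] * d + blk[None, None, :],
            (design.n_cows, d, d),
        ).reshape(-1)

        # Union sparsity pattern.
        parts_r = [add_rows, pe_rows] + [t.tocoo().row for t in self.T]
        parts_c = [add_cols, pe_cols] + [t.tocoo().col for t in self.T]
        rows_all = np.concatenate(parts_r)
        cols_all = np.concatenate(parts_c)
        union = sp.csr_matrix(
            (np.ones(len(rows_all)), (rows_all, cols_all)), shape=(n_coef, n_coef)
        )
        union.sum_duplicates()
        union.sort_indices()
        self.indptr = union.indptr.astype(np.int64)
        self.indices = union.indices.astype(np.int64)
        self.nnz = union.nnz

        self.map_add = csr_position_map(
            self.indptr, self.indices, add_rows.astype(np.int64), add_cols.astype(np.int64)
        )
        self.map_pe = csr_position_map(
            self.indptr, self.indices, pe_rows.astype(np.int64), pe_cols.astype(np.int64)
        )
        # Scatter each T_l onto the union once; per-iteration work is then a
        # weighted sum of dense data arrays.
        self.T_full = []
        for t in self.T:
            coo = t.tocoo()
            pos = csr_position_map(
                self.indptr, self.indices, coo.row.astype(np.int64), coo.col.astype(np.int64)
            )
            full = np.zeros(self.nnz)
            full[pos] = coo.data
            self.T_full.append(full)
        self.d = d

    def coefficient_data(self, weights, Phi_inv, Psi_inv, n_cows) -> np.ndarray:
        data = np.zeros(self.nnz)
        for w, tf in zip(weights, self.T_full):
            data += w * tf
        data[self.map_add] += (
            self.k_data[:, None] * Phi_inv.ravel()[None, :]
        ).ravel()
        data[self.map_pe] += np.tile(Psi_inv.ravel(), n_cows)
        return data

    def rhs(self, weights) -> np.ndarray:
        out = np.zeros_like(self.r[0])
        for w, rl in zip(weights, self.r):
            out += w * rl
        return out


def gibbs_sampler(
    design: DesignSystem,
    K_inv: RelationshipMatrix,
    priors: GibbsPriors,
    chain: ChainSpec,
    start: VarianceComponents | None = None,
) -> PosteriorChain:
    """Run the Gibbs sampler and return retained variance-component draws.

    Runs are exactly reproducible for a given ``chain.seed``; all random
    draws (location-effect normals, inverse-Wisharts, chi-squares) come
    from one seeded generator.
    """
    rng = np.random.default_rng(chain.seed)
    Kinv_sp = sp.csr_matrix(K_inv.values, dtype=float)
    if Kinv_sp.shape[0] != design.n_animals:
        raise ValueError("K_inv dimension does not match pedigree size")
    sys_ = _AlignedSystem(design, Kinv_sp)

    parities = design.parities
    d = 2 * design.n_parities
    labels = _coef_labels(parities)
    phi_cols = _tri_columns("phi", labels)
    psi_cols = _tri_columns("psi", labels)
    col_names = (
        [c[0] for c in phi_cols]
        + [c[0] for c in psi_cols]
        + [f"r_e{l}" for l in parities]
    )

    Phi = np.array(start.Phi if start is not None else priors.Phi_mean, dtype=float)
    Psi = np.array(start.Psi if start is not None else priors.Psi_mean, dtype=float)
    se2 = np.array(
        start.Rdiag if start is not None else priors.se2_mean, dtype=float
    )
    theta = np.zeros(design.n_coef)
    phi_scale0 = priors.phi_scale()
    psi_scale0 = priors.psi_scale()

    n_anim, n_cows = design.n_animals, design.n_cows
    add_sl, pe_sl = design.additive_slice, design.permanent_slice
    W = design.W.tocsr()
    y = design.y
    out = np.empty((chain.n_retained, len(col_names)))
    kept = 0

    for it in range(1, chain.total + 1):
        weights = 1.0 / se2
        Phi_inv = np.linalg.inv(Phi)
        Psi_inv = np.linalg.inv(Psi)
        data = sys_.coefficient_data(weights, Phi_inv, Psi_inv, n_cows)
        rhs = sys_.rhs(weights)
        z = rng.standard_normal(design.n_coef)
        sweep_blocks(
            sys_.indptr,
            sys_.indices,
            data,
            rhs,
            theta,
            design.block_start,
            design.block_size,
            z,
        )

        # Phi | additive effects.
        U = theta[add_sl].reshape(n_anim, d)
        S_a = U.T @ (Kinv_sp @ U)
        S_a = 0.5 * (S_a + S_a.T)
        Phi = _draw_invwishart(rng, priors.nu_phi + n_anim, phi_scale0 + S_a)

        # Psi | permanent effects.
        P = theta[pe_sl].reshape(n_cows, d)
        S_p = P.T @ P
        S_p = 0.5 * (S_p + S_p.T)
        Psi = _draw_invwishart(rng, priors.nu_psi + n_cows, psi_scale0 + S_p)

        # Residuals per parity.
        e = y - W @ theta
        for li, parity in enumerate(parities):
            mask = design.record_parity == parity
            sse = float(e[mask] @ e[mask])
            n_l = sys_.n_records_per_parity[li]
            se2[li] = (priors.nu_e * priors.se2_mean[li] + sse) / rng.chisquare(
                priors.nu_e + n_l
            )

        if it > chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            row = (
                [Phi[i, j] for _, i, j in phi_cols]
                + [Psi[i, j] for _, i, j in psi_cols]
                + list(se2)
            )
            out[kept] = row
            kept += 1

    samples = pd.DataFrame(out[:kept], columns=col_names)
    meta = {
        "total": chain.total,
        "burn_in": chain.burn_in,
        "thin": chain.thin,
        "seed": chain.seed,
        "n_retained": kept,
        "n_animals": n_anim,
        "n_cows": n_cows,
        "n_records": len(y),
    }
    return PosteriorChain(samples=samples, parities=parities, meta=meta)


def _draw_invwishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw with a jittered retry on numerical non-PD scale."""
    for attempt in range(3):
        try:
            draw = invwishart.rvs(df=df, scale=scale, random_state=rng)
            return np.atleast_2d(draw)
        except np.linalg.LinAlgError:  # pragma: no cover - numerical edge
            logger.warning("non-PD inverse-Wishart scale; jittering (attempt %d)", attempt)
            scale = scale + 1e-8 * np.eye(scale.shape[0]) * np.trace(scale)
    raise RuntimeError("inverse-Wishart scale remained non-PD after jitter")
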