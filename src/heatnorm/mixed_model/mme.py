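"""Mixed-model equations: assembly and solution.

The coefficient matrix is

    C = W' R⁻¹ W + blockdiag(0, K⁻¹ (x) Φ⁻¹, I (x) Ψ⁻¹)

with W the full design, R⁻¹ the per-record residual precisions, K⁻¹ the
pedigree (A⁻¹) or single-step (H⁻¹) inverse relationship matrix, and Φ, Ψ
the random-regression covariance matrices.  The right-hand side is
``W' R⁻¹ y``; solutions are BLUE/BLUP at the supplied variance components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from heatnorm.mixed_model.design import DesignSystem
from heatnorm.relationships import RelationshipMatrix


@dataclass
class VarianceComponents:
    """(Co)variance matrices of the random-regression model.

    ``Phi`` and ``Psi`` are 2p×2p over (intercept, slope) pairs in parity
    order (p = number of parities, 6×6 for the standard three-parity run);
    ``Rdiag`` holds one residual variance per parity.
    """

    Phi: np.ndarray
    Psi: np.ndarray
    Rdiag: np.ndarray
    parities: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        self.Phi = np.asarray(self.Phi, dtype=float)
        self.Psi = np.asarray(self.Psi, dtype=float)
        self.Rdiag = np.atleast_1d(np.asarray(self.Rdiag, dtype=float))
        d = 2 * len(self.parities)
        for name, m in (("Phi", self.Phi), ("Psi", self.Psi)):
            if m.shape != (d, d):
                raise ValueError(f"{name} must be {d}x{d} for parities {self.parities}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        if len(self.Rdiag) != len(self.parities):
            raise ValueError("Rdiag must have one entry per parity")
        if (self.Rdiag <= 0).any():
            raise ValueError("residual variances must be positive")

    def component(self, matrix: str, parity: int, which: str) -> float:
        """Extract e.g. ('Phi', 1, 'av') -> sigma_av of parity 1."""
        l = self.parities.index(parity)
        m = self.Phi if matrix == "Phi" else self.Psi
        i0 = 2 * l
        idx = {"aa": (i0, i0), "av": (i0, i0 + 1), "vv": (i0 + 1, i0 + 1)}[which]
        return float(m[idx])


@dataclass
class MMESystem:
    C: sp.csr_matrix
    rhs: np.ndarray
    design: DesignSystem


@dataclass
class EffectSolutions:
    """Solutions of the mixed-model equations."""

    fixed: dict[str, float]
    #: additive (intercept, slope) per (animal, parity)
    additive: dict[tuple[str, int], tuple[float, float]]
    #: permanent-environment (intercept, slope) per (cow, parity)
    permanent: dict[tuple[str, int], tuple[float, float]]
    theta: np.ndarray
    relative_residual: float

    def gebv_arrays(self, ids: list[str], parity: int) -> tuple[np.ndarray, np.ndarray]:
        """(intercept, slope) solution vectors for the given animals."""
        a = np.array([self.additive[(i, parity)][0] for i in ids])
        v = np.array([self.additive[(i, parity)][1] for i in ids])
        return a, v


def random_precision(
    design: DesignSystem, vc: VarianceComponents, K_inv: RelationshipMatrix
) -> sp.csr_matrix:
    """Blockdiag(0_fixed, K⁻¹ (x) Φ⁻¹, I (x) Ψ⁻¹) on the full coefficient order."""
    Kinv = sp.csr_matrix(K_inv.values, dtype=float)
    if Kinv.shape[0] != design.n_animals:
        raise ValueError(
            f"K_inv dimension {Kinv.shape[0]} != number of animals {design.n_animals}"
        )
    Phi_inv = np.linalg.inv(vc.Phi)
    Psi_inv = np.linalg.inv(vc.Psi)
    blocks = [
        sp.csr_matrix((design.n_fixed, design.n_fixed)),
        sp.kron(Kinv, Phi_inv, format="csr"),
        sp.kron(sp.eye(design.n_cows, format="csr"), Psi_inv, format="csr"),
    ]
    return sp.block_diag(blocks, format="csr")


def residual_weights(design: DesignSystem, vc: VarianceComponents) -> np.ndarray:
    """Per-record residual precisions 1/sigma_e^2(parity)."""
    se2 = {p: vc.Rdiag[i] for i, p in enumerate(vc.parities)}
    return np.array([1.0 / se2[int(p)] for p in design.record_parity])


def assemble_mme(
    design: DesignSystem, vc: VarianceComponents, K_inv: RelationshipMatrix
) -> MMESystem:
    """Build the (symmetric) mixed-model equations at given components."""
    if tuple(vc.parities) != tuple(design.parities):
        raise ValueError("variance components and design disagree on parities")
    w = residual_weights(design, vc)
    Rinv = sp.diags(w)
    C = (design.W.T @ Rinv @ design.W) + random_precision(design, vc, K_inv)
    rhs = design.W.T @ (w * design.y)
    return MMESystem(C=sp.csr_matrix(C), rhs=rhs, design=design)


def solve_mme(system: MMESystem, rtol: float = 1e-8) -> EffectSolutions:
    """Solve the mixed-model equations by sparse LU.

    Raises ``RuntimeError`` with the achieved residual if the relative
    residual ``||C theta - rhs|| / ||rhs||`` exceeds ``rtol`` (singular or
    ill-conditioned systems; fixed-effect identifiability is handled at
    design time by dropping one DIM class per parity).
    """
    C, rhs, design = system.C.tocsc(), system.rhs, system.design
    theta = spla.spsolve(C, rhs)
    denom = float(np.linalg.norm(rhs)) or 1.0
    rel = float(np.linalg.norm(C @ theta - rhs)) / denom
    if not np.isfinite(rel) or rel > rtol:
        raise RuntimeError(f"mixed-model solve did not converge: relative residual {rel:.3e}")

    fixed = {lab: float(theta[k]) for k, lab in enumerate(design.fixed_labels)}
    additive = {}
    npar = design.n_parities
    for i, animal in enumerate(design.animal_ids):
        base = design.n_fixed + i * 2 * npar
        for l, parity in enumerate(design.parities):
            additive[(animal, parity)] = (
                float(theta[base + 2 * l]),
                float(theta[base + 2 * l + 1]),
            )
    permanent = {}
    pe_off = design.permanent_slice.start
    for i, cow in enumerate(design.cow_ids):
        base = pe_off + i * 2 * npar
        for l, parity in enumerate(design.parities):
            permanent[(cow, parity)] = (
                float(theta[base + 2 * l]),
                float(theta[base + 2 * l + 1]),
            )
    return EffectSolutions(
        fixed=fixed,
        additive=additive,
        permanent=permanent,
        theta=theta,
        relative_residual=rel,
    )
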