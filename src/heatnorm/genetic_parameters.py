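"""Reaction-norm genetic parameters from variance components.

Under the reaction-norm model an animal's additive genetic merit at heat
load ``f`` is ``a + f·v`` (general intercept plus thermotolerance slope), so
the additive genetic variance at ``f`` is ``σa² + f²σv² + 2fσav`` and the
analogous permanent-environment variance is ``σpe² + f²σq² + 2fσpq``.  The
functions here evaluate heritability along the heat-load gradient, the
correlation between general and thermotolerance effects, across-parity
correlations of intercepts and slopes, and percent changes of variances —
pointwise or per posterior draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Published variance-component estimates for US Holstein test-day yields
#: (multi-trait repeatability reaction-norm model, parities 1-3).  Rows are
#: (trait, parity); columns are the additive intercept variance sigma_a2,
#: the slope variance scaled as 100*sigma_v2, the intercept-slope
#: covariance scaled as 10*sigma_av, and the residual variance sigma_e2.
#: Milk in kg; fat and protein in (kg x 100).  These serve as simulation
#: defaults and as worked-example inputs.
HOLSTEIN_COMPONENTS = pd.DataFrame(
    [
        ("milk", 1, 9.26, 0.94, -1.21, 7.31),
        ("milk", 2, 10.03, 1.56, -1.17, 12.97),
        ("milk", 3, 10.55, 1.62, -2.31, 15.65),
        ("fat", 1, 119.76, 18.19, -11.44, 351.15),
        ("fat", 2, 205.77, 48.61, -37.90, 666.04),
        ("fat", 3, 252.33, 33.78, -63.03, 840.74),
        ("protein", 1, 55.65, 8.57, -6.31, 79.92),
        ("protein", 2, 63.80, 9.98, -4.58, 127.98),
        ("protein", 3, 76.01, 13.30, -12.81, 154.51),
    ],
    columns=["trait", "parity", "sigma_a2", "sigma_v2_x100", "sigma_av_x10", "sigma_e2"],
)


def components_for(trait: str, parity: int) -> dict[str, float]:
    """Unscaled components (sigma_a2, sigma_v2, sigma_av, sigma_e2) for a
    trait/parity from the published reference table."""
    row = HOLSTEIN_COMPONENTS.query("trait == @trait and parity == @parity")
    if row.empty:
        raise KeyError(f"no reference components for {trait!r} parity {parity}")
    r = row.iloc[0]
    return {
        "sigma_a2": float(r.sigma_a2),
        "sigma_v2": float(r.sigma_v2_x100) / 100.0,
        "sigma_av": float(r.sigma_av_x10) / 10.0,
        "sigma_e2": float(r.sigma_e2),
    }


@dataclass
class GeneticParameterSet:
    """Point estimates (optionally with HPD bounds) of derived parameters."""

    h2: float
    r_av: float
    h2_hpd: tuple[float, float] | None = None
    r_av_hpd: tuple[float, float] | None = None


def heritability_at(
    sa2: float,
    sv2: float,
    sav: float,
    spe2: float,
    sq2: float,
    spq: float,
    se2: float,
    f: float,
) -> float:
    """Heritability at heat load ``f``.

    ``h² = (σa² + f²σv² + 2fσav) /
    (σa² + f²σv² + 2fσav + σpe² + f²σq² + 2fσpq + σe²)``

    A negative genetic numerator (possible with a strongly negative σav) is
    returned as-is with a warning: the expression is a ratio of quadratic
    forms and per-draw posterior summaries must not censor chain tails.
    """
    num = sa2 + f * f * sv2 + 2.0 * f * sav
    den = num + spe2 + f * f * sq2 + 2.0 * f * spq + se2
    if den <= 0:
        raise ValueError(f"total phenotypic variance must be positive, got {den}")
    if num < 0:
        warnings.warn(
            f"negative genetic variance at f={f}: {num:.4g}", stacklevel=2
        )
    return num / den


def general_thermo_correlation(sa2: float, sv2: float, sav: float, f: float) -> float:
    """Correlation between general merit ``a`` and scaled slope ``f·v``.

    ``corr[a, f·v] = f σav / sqrt(σa² · f² σv²)``, which for any f > 0
    reduces to σav / sqrt(σa² σv²).
    """
    if f == 0:
        raise ValueError("correlation with f*v is undefined at f = 0")
    if sa2 <= 0 or sv2 <= 0:
        raise ValueError("variances must be positive")
    return f * sav / np.sqrt(sa2 * f * f * sv2)


def across_parity_correlations(Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Across-parity correlation matrices of intercepts and slopes.

    ``Phi`` is the 2p×2p additive covariance over (intercept, slope) pairs
    in parity-major order; returns (cor_gen, cor_ht), the p×p correlation
    matrices of general (intercept) and thermotolerance (slope) effects.
    """
    Phi = np.asarray(Phi, dtype=float)
    if Phi.shape[0] != Phi.shape[1] or Phi.shape[0] % 2:
        raise ValueError("Phi must be square with an even dimension")
    p = Phi.shape[0] // 2
    gen = Phi[0::2, 0::2]
    ht = Phi[1::2, 1::2]

    def corr(m: np.ndarray) -> np.ndarray:
        d = np.sqrt(np.diag(m))
        return m / np.outer(d, d)

    return corr(gen), corr(ht)


def variance_increase_pct(v_from: float, v_to: float) -> float:
    """Percent change ``100·(v_to − v_from)/v_from`` (e.g. across parities)."""
    if v_from <= 0:
        raise ValueError(f"baseline variance must be positive, got {v_from}")
    return 100.0 * (v_to - v_from) / v_from


def parameters_per_draw(
    chain_df: pd.DataFrame,
    parity: int,
    f: float,
    level: float = 0.95,
) -> dict[str, GeneticParameterSet]:
    """Posterior summaries of h² and r(a,v) computed per retained draw.

    ``chain_df`` holds one row per retained Gibbs draw with columns named
    ``phi_a{l}_a{l}``, ``phi_a{l}_v{l}``, ``phi_v{l}_v{l}``, the analogous
    ``psi_*`` permanent-environment entries, and ``r_e{l}``.  Functionals
    are evaluated on each draw and then summarised (mean + shortest HPD),
    never on the posterior-mean components.
    """
    from heatnorm.mixed_model.summary import hpd_interval

    l = parity
    sa2 = chain_df[f"phi_a{l}_a{l}"].to_numpy()
    sav = chain_df[f"phi_a{l}_v{l}"].to_numpy()
    sv2 = chain_df[f"phi_v{l}_v{l}"].to_numpy()
    spe2 = chain_df[f"psi_a{l}_a{l}"].to_numpy()
    spq = chain_df[f"psi_a{l}_v{l}"].to_numpy()
    sq2 = chain_df[f"psi_v{l}_v{l}"].to_numpy()
    se2 = chain_df[f"r_e{l}"].to_numpy()

    gnum = sa2 + f * f * sv2 + 2.0 * f * sav
    h2 = gnum / (gnum + spe2 + f * f * sq2 + 2.0 * f * spq + se2)
    r = f * sav / np.sqrt(sa2 * f * f * sv2)
    return {
        "h2": GeneticParameterSet(
            h2=float(h2.mean()), r_av=float(r.mean()), h2_hpd=hpd_interval(h2, level)
        ),
        "r_av": GeneticParameterSet(
            h2=float(h2.mean()), r_av=float(r.mean()), r_av_hpd=hpd_interval(r, level)
        ),
    }


def reference_correlation_table(f: float = 10.0) -> pd.DataFrame:
    """General-by-thermotolerance correlations recomputed from the published
    component table at heat load ``f`` (default 10 THI units above threshold)."""
    rows = []
    for _, r in HOLSTEIN_COMPONENTS.iterrows():
        c = general_thermo_correlation(
            r.sigma_a2, r.sigma_v2_x100 / 100.0, r.sigma_av_x10 / 10.0, f
        )
        rows.append((r.trait, int(r.parity), c, round(c, 2)))
    return pd.DataFrame(rows, columns=["trait", "parity", "r_av", "r_av_2dp"])
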