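"""Synthetic pedigrees, genotypes, weather, and test-day phenotypes.

Generates data with exactly the statistical structure the reaction-norm
analysis assumes: a multi-generation random-mating pedigree; biallelic SNP
genotypes gene-dropped through it; a subtropical seasonal THI series that
spends roughly two thirds of the year above the heat-stress threshold; and
phenotypes built from the model equation — herd-test-day and DIM-class
fixed effects, pedigree-correlated (intercept, slope) breeding-value pairs
with covariance A (x) Phi, independent permanent-environment pairs with
covariance Psi, optional SNP QTL contributions, and parity-specific
residuals.  Default variance components are the published Holstein milk
estimates; the permanent-environment components, which are not published,
default to half the corresponding genetic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from heatnorm.genetic_parameters import HOLSTEIN_COMPONENTS
from heatnorm.relationships import (
    GenotypeMatrix,
    Pedigree,
    mendelian_sampling_variance,
)
from heatnorm.weather import DailyThi


def default_phi(parities: tuple[int, ...] = (1, 2, 3), trait: str = "milk") -> np.ndarray:
    """Additive covariance Phi assembled from the published component table.

    Within-parity blocks use the printed intercept/slope variances and
    covariance.  Across parities the published intercept and slope
    correlations fill the like-with-like covariances; the unprinted
    intercept-by-slope covariances across parities are filled by the path
    rule corr(a_i, v_j) = corr(a_i, a_j) * corr(a_j, v_j), which keeps the
    matrix positive definite at the published values.
    """
    tab = HOLSTEIN_COMPONENTS.query("trait == @trait").set_index("parity")
    sa2 = {p: tab.loc[p, "sigma_a2"] for p in parities}
    sv2 = {p: tab.loc[p, "sigma_v2_x100"] / 100.0 for p in parities}
    sav = {p: tab.loc[p, "sigma_av_x10"] / 10.0 for p in parities}
    # Published across-parity correlations (intercept cor_gen, slope cor_ht).
    cor_gen = {(1, 2): 0.82, (1, 3): 0.85, (2, 3): 0.92}
    cor_ht = {(1, 2): 0.78, (1, 3): 0.65, (2, 3): 0.61}
    if trait == "fat":
        cor_gen = {(1, 2): 0.91, (1, 3): 0.95, (2, 3): 0.95}
        cor_ht = {(1, 2): 0.46, (1, 3): 0.34, (2, 3): 0.38}
    elif trait == "protein":
        cor_gen = {(1, 2): 0.78, (1, 3): 0.76, (2, 3): 0.96}
        cor_ht = {(1, 2): 0.36, (1, 3): 0.55, (2, 3): 0.78}

    p = len(parities)
    Phi = np.zeros((2 * p, 2 * p))
    for i, pi in enumerate(parities):
        Phi[2 * i, 2 * i] = sa2[pi]
        Phi[2 * i + 1, 2 * i + 1] = sv2[pi]
        Phi[2 * i, 2 * i + 1] = Phi[2 * i + 1, 2 * i] = sav[pi]
        for j, pj in enumerate(parities):
            if j <= i:
                continue
            key = (pi, pj) if (pi, pj) in cor_gen else (pj, pi)
            caa = cor_gen[key] * np.sqrt(sa2[pi] * sa2[pj])
            cvv = cor_ht[key] * np.sqrt(sv2[pi] * sv2[pj])
            Phi[2 * i, 2 * j] = Phi[2 * j, 2 * i] = caa
            Phi[2 * i + 1, 2 * j + 1] = Phi[2 * j + 1, 2 * i + 1] = cvv
            # path-rule fill for intercept_i x slope_j
            r_av_j = sav[pj] / np.sqrt(sa2[pj] * sv2[pj])
            r_av_i = sav[pi] / np.sqrt(sa2[pi] * sv2[pi])
            cav = cor_gen[key] * r_av_j * np.sqrt(sa2[pi] * sv2[pj])
            cva = cor_gen[key] * r_av_i * np.sqrt(sa2[pj] * sv2[pi])
            Phi[2 * i, 2 * j + 1] = Phi[2 * j + 1, 2 * i] = cav
            Phi[2 * i + 1, 2 * j] = Phi[2 * j, 2 * i + 1] = cva
    return Phi


def default_psi(Phi: np.ndarray) -> np.ndarray:
    """Permanent-environment covariance fill-in: half the within-parity
    genetic blocks, uncorrelated across parities."""
    d = Phi.shape[0]
    Psi = np.zeros((d, d))
    for i in range(0, d, 2):
        Psi[i : i + 2, i : i + 2] = 0.5 * Phi[i : i + 2, i : i + 2]
    return Psi


def default_rdiag(parities: tuple[int, ...] = (1, 2, 3), trait: str = "milk") -> np.ndarray:
    tab = HOLSTEIN_COMPONENTS.query("trait == @trait").set_index("parity")
    return np.array([tab.loc[p, "sigma_e2"] for p in parities])


@dataclass
class QtlSpec:
    """A planted QTL on a genotyped SNP.

    ``component`` is "intercept" (general merit) or "slope"
    (thermotolerance); the allele-substitution ``effect`` applies to every
    modelled parity.  ``snp_index`` of None means the SNP closest to the
    centre of chromosome 1.
    """

    effect: float
    component: str = "slope"
    snp_index: int | None = None


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator (milk-yield defaults)."""

    seed: int = 0
    trait: str = "milk"
    parities: tuple[int, ...] = (1, 2, 3)
    n_founders: int = 200
    n_generations: int = 2
    n_cows_phenotyped: int = 1500
    n_herds: int = 2
    n_snps: int = 2000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 10_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    Phi: np.ndarray | None = None
    Psi: np.ndarray | None = None
    Rdiag: np.ndarray | None = None
    qtl_spec: list[QtlSpec] = field(default_factory=list)
    #: subtropical seasonality: ~65% of days above the THI-68 threshold
    thi_mean: float = 72.0
    thi_amplitude: float = 9.0
    thi_noise_sd: float = 2.5
    thi_threshold: float = 68.0
    n_days: int | None = None
    start_date: date = date(2015, 1, 1)
    tests_per_lactation: int = 10
    test_interval_days: int = 30
    htd_effect_sd: float = 2.0
    dim_effect_sd: float = 1.5
    genotyped_cow_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.Phi is None:
            self.Phi = default_phi(self.parities, self.trait)
        if self.Psi is None:
            self.Psi = default_psi(self.Phi)
        if self.Rdiag is None:
            self.Rdiag = default_rdiag(self.parities, self.trait)
        if self.n_days is None:
            # cover all lactations (successive calvings one year apart)
            self.n_days = 365 * len(self.parities) + 365
        for name, m in (("Phi", self.Phi), ("Psi", self.Psi)):
            if np.linalg.eigvalsh(np.asarray(m)).min() <= 0:
                raise ValueError(f"{name} must be positive definite")


@dataclass
class SimulatedPedigree:
    pedigree: Pedigree
    sex: np.ndarray  # "M"/"F" per animal in pedigree order
    generation: np.ndarray

    @property
    def cow_ids(self) -> list[str]:
        last = self.generation.max()
        return [
            a
            for a, s, g in zip(self.pedigree.ids, self.sex, self.generation)
            if s == "F" and g == last
        ]


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests."""

    breeding_values: np.ndarray  # n_animals x 2p, pedigree order
    permanent_effects: np.ndarray  # n_cows x 2p
    cow_ids: list[str]
    qtls: list[dict]
    qtl_variance_inflation: np.ndarray  # added genetic variance per coefficient
    htd_effects: dict[str, float]
    dim_effects: dict[tuple[int, int], float]


def simulate_pedigree(cfg: SimulationConfig) -> SimulatedPedigree:
    """Discrete-generation random-mating pedigree.

    Generation 0 holds ``n_founders`` unrelated founders (half of each sex);
    intermediate generations keep that size; the final generation consists
    of ``n_cows_phenotyped`` females whose parents are drawn at random from
    the previous generation.
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least two founders")
    rng = np.random.default_rng(cfg.seed)
    ids: list[str] = []
    sires: list[str] = []
    dams: list[str] = []
    sex: list[str] = []
    gen: list[int] = []

    males: list[str] = []
    females: list[str] = []
    for i in range(cfg.n_founders):
        a = f"G0_{i}"
        ids.append(a)
        sires.append("0")
        dams.append("0")
        s = "M" if i % 2 == 0 else "F"
        sex.append(s)
        gen.append(0)
        (males if s == "M" else females).append(a)

    for g in range(1, cfg.n_generations + 1):
        last = g == cfg.n_generations
        size = cfg.n_cows_phenotyped if last else cfg.n_founders
        new_m: list[str] = []
        new_f: list[str] = []
        for i in range(size):
            a = f"G{g}_{i}"
            ids.append(a)
            sires.append(males[rng.integers(len(males))])
            dams.append(females[rng.integers(len(females))])
            s = "F" if last else ("M" if rng.random() < 0.5 else "F")
            sex.append(s)
            gen.append(g)
            (new_m if s == "M" else new_f).append(a)
        if not last:
            males, females = (new_m or males), (new_f or females)

    ped = Pedigree.from_records(list(zip(ids, sires, dams)))
    order = [ped.code(a) for a in ids]
    sex_arr = np.empty(len(ids), dtype="U1")
    gen_arr = np.empty(len(ids), dtype=int)
    for a, s, g in zip(ids, sex, gen):
        sex_arr[ped.code(a)] = s
        gen_arr[ped.code(a)] = g
    del order
    return SimulatedPedigree(pedigree=ped, sex=sex_arr, generation=gen_arr)


def simulate_genotypes(sim_ped: SimulatedPedigree, cfg: SimulationConfig) -> GenotypeMatrix:
    """Gene-drop biallelic genotypes through the pedigree.

    Founder alleles are Bernoulli draws at per-SNP frequencies uniform on
    ``maf_range``; each descendant inherits one uniformly chosen allele per
    parent per locus (loci unlinked).  Map positions are uniform within
    chromosomes of equal length.
    """
    ped = sim_ped.pedigree
    rng = np.random.default_rng(cfg.seed + 1)
    m = cfg.n_snps
    p = rng.uniform(*cfg.maf_range, size=m)
    n = len(ped)
    hap = np.zeros((n, m, 2), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for k, parent in enumerate((s, d)):
            if parent < 0:
                hap[i, :, k] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                hap[i, :, k] = hap[parent, np.arange(m), pick]
    codes = hap.sum(axis=2).astype(np.int8)

    chrom_of = np.repeat(np.arange(cfg.n_chromosomes), int(np.ceil(m / cfg.n_chromosomes)))[:m]
    pos = rng.integers(1, cfg.chromosome_length_bp, size=m)
    order = np.lexsort((pos, chrom_of))
    snp_map = pd.DataFrame(
        {
            "snp": [f"snp{j}" for j in range(m)],
            "chrom": (chrom_of[order] + 1).astype(str),
            "pos": pos[order],
            "counted_allele": "A",
        }
    )
    return GenotypeMatrix(codes=codes[:, order], ids=list(ped.ids), snp_map=snp_map)


def expected_fraction_above_threshold(cfg: SimulationConfig) -> float:
    """Closed-form fraction of days above threshold for the noiseless
    sinusoid: P(sin > (thr - mean)/amplitude) over a uniform phase."""
    x = (cfg.thi_threshold - cfg.thi_mean) / cfg.thi_amplitude
    if x <= -1:
        return 1.0
    if x >= 1:
        return 0.0
    return 0.5 - float(np.arcsin(x)) / np.pi


def simulate_weather(cfg: SimulationConfig) -> list[DailyThi]:
    """Sinusoidal annual THI cycle plus Gaussian noise."""
    import warnings

    rng = np.random.default_rng(cfg.seed + 2)
    days = np.arange(cfg.n_days)
    thi = (
        cfg.thi_mean
        + cfg.thi_amplitude * np.sin(2 * np.pi * days / 365.25)
        + rng.normal(0.0, cfg.thi_noise_sd, size=cfg.n_days)
    )
    if (thi <= cfg.thi_threshold).all():
        warnings.warn(
            "simulated THI never exceeds the threshold; all heat loads will be zero"
        )
    return [
        DailyThi(date=cfg.start_date + timedelta(days=int(d)), thi=float(t))
        for d, t in zip(days, thi)
    ]


def hourly_from_daily(daily: list[DailyThi]) -> pd.DataFrame:
    """Hourly weather table whose daily-mean THI reproduces ``daily``.

    Holds relative humidity at 0.5 and inverts the THI equation for
    temperature, adding a small diurnal cycle that averages out.
    """
    rows = []
    for d in daily:
        for h in range(24):
            thi_h = d.thi + 2.0 * np.sin(2 * np.pi * (h - 8) / 24)
            temp = (thi_h - 39.15) / 1.305  # rh=0.5 inverse of the THI equation
            rows.append((pd.Timestamp(d.date) + pd.Timedelta(hours=h), temp, 0.5))
    return pd.DataFrame(rows, columns=["timestamp", "temp", "rh"])


def simulate_breeding_values(
    ped: Pedigree, Phi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Pedigree-recursive draw of (intercept, slope) pairs with Var = A (x) Phi.

    child = mean of known parents' vectors + Mendelian deviation with
    covariance ``D_i * Phi``, where ``D_i`` is the Mendelian-sampling share
    from the inbreeding recursion — equivalent to a Cholesky of A (x) Phi
    but linear in pedigree size.
    """
    n = len(ped)
    d = Phi.shape[0]
    L = np.linalg.cholesky(Phi)
    D = mendelian_sampling_variance(ped)
    u = np.zeros((n, d))
    z = rng.standard_normal((n, d))
    for i in range(n):
        mean = np.zeros(d)
        if ped.sire[i] >= 0:
            mean += 0.5 * u[ped.sire[i]]
        if ped.dam[i] >= 0:
            mean += 0.5 * u[ped.dam[i]]
        u[i] = mean + np.sqrt(D[i]) * (L @ z[i])
    return u


def simulate_phenotypes(
    sim_ped: SimulatedPedigree,
    daily_thi: list[DailyThi],
    cfg: SimulationConfig,
    geno: GenotypeMatrix | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate test-day records from the model equation.

    Cows (final-generation females) calve at seed-determined dates through
    the first simulated year, one calving per parity a year apart; records
    fall on herd-wide test days every ``test_interval_days`` with DIM in
    [5, 305], capped at ``tests_per_lactation``; every lactation retains at
    least 6 tests by construction.  Heat loads attach the 3-day-lagged mean
    daily THI through the weather module.  QTL allele effects are added on
    top of the polygenic draw (the resulting inflation of the slope or
    intercept variance is reported in the truth object, not re-normalised).
    """
    ped = sim_ped.pedigree
    rng = np.random.default_rng(cfg.seed + 3)
    parities = cfg.parities
    d = 2 * len(parities)
    Phi = np.asarray(cfg.Phi)
    Psi = np.asarray(cfg.Psi)
    Rdiag = np.asarray(cfg.Rdiag)

    u = simulate_breeding_values(ped, Phi, rng)

    qtls = []
    inflation = np.zeros(d)
    if geno is not None and cfg.qtl_spec:
        p_freq = geno.allele_frequencies()
        for q in cfg.qtl_spec:
            j = q.snp_index
            if j is None:
                # default: a common variant near the middle of chromosome 1,
                # so the planted signal is actually expressed in the sample
                chrom1 = (geno.snp_map["chrom"] == geno.snp_map["chrom"].iloc[0]).to_numpy()
                mid = cfg.chromosome_length_bp // 2
                score = (
                    np.abs(p_freq - 0.4)
                    + np.abs(geno.snp_map["pos"].to_numpy() - mid) / cfg.chromosome_length_bp
                )
                score[~chrom1] = np.inf
                j = int(np.argmin(score))
            zj = geno.codes[:, j].astype(float) - 2.0 * p_freq[j]
            offset = 0 if q.component == "intercept" else 1
            for li in range(len(parities)):
                code_idx = [ped.code(a) for a in geno.ids]
                u[code_idx, 2 * li + offset] += zj * q.effect
                inflation[2 * li + offset] += 2 * p_freq[j] * (1 - p_freq[j]) * q.effect**2
            qtls.append(
                {
                    "snp_index": j,
                    "snp": geno.snp_map["snp"].iloc[j],
                    "chrom": geno.snp_map["chrom"].iloc[j],
                    "pos": int(geno.snp_map["pos"].iloc[j]),
                    "component": q.component,
                    "effect": q.effect,
                }
            )

    cows = sim_ped.cow_ids
    n_cows = len(cows)
    pe = rng.multivariate_normal(np.zeros(d), Psi, size=n_cows)

    thi_by_date = {t.date: t.thi for t in daily_thi}
    first = daily_thi[0].date
    last = daily_thi[-1].date

    # Herd-wide test calendar.
    test_dates = [
        first + timedelta(days=k)
        for k in range(4, cfg.n_days, cfg.test_interval_days)
    ]
    herd_of = {c: f"H{i % cfg.n_herds + 1}" for i, c in enumerate(cows)}
    calving_day = {c: int(rng.integers(0, 360)) for c in cows}

    spec_width = 20
    dim_min = 5

    htd_effects: dict[str, float] = {}
    dim_effects: dict[tuple[int, int], float] = {}

    rows = []
    for ci, cow in enumerate(cows):
        code = ped.code(cow)
        herd = herd_of[cow]
        for li, parity in enumerate(parities):
            calving = first + timedelta(days=calving_day[cow] + 365 * li)
            n_tests = 0
            for td in test_dates:
                dim = (td - calving).days
                if dim < dim_min or dim > 305 or n_tests >= cfg.tests_per_lactation:
                    continue
                if td - timedelta(days=3) < first or td > last:
                    continue
                # 3-day-lagged mean THI (same rule as weather.assign_test_day_thi,
                # inlined for the per-record loop)
                thi = (
                    thi_by_date[td - timedelta(days=1)]
                    + thi_by_date[td - timedelta(days=2)]
                    + thi_by_date[td - timedelta(days=3)]
                ) / 3.0
                f = max(0.0, thi - cfg.thi_threshold)
                htd = f"{herd}|{td.isoformat()}|{parity}"
                if htd not in htd_effects:
                    htd_effects[htd] = float(rng.normal(0.0, cfg.htd_effect_sd))
                dim_class = (dim - dim_min) // spec_width + 1
                key = (parity, dim_class)
                if key not in dim_effects:
                    dim_effects[key] = float(rng.normal(0.0, cfg.dim_effect_sd))
                mu = (
                    htd_effects[htd]
                    + dim_effects[key]
                    + u[code, 2 * li]
                    + pe[ci, 2 * li]
                    + f * (u[code, 2 * li + 1] + pe[ci, 2 * li + 1])
                )
                y = mu + rng.normal(0.0, np.sqrt(Rdiag[li]))
                rows.append(
                    (cow, herd, td.isoformat(), parity, dim, y, f, thi)
                )
                n_tests += 1
    df = pd.DataFrame(
        rows,
        columns=["cow", "herd", "test_date", "parity", "dim", cfg.trait, "heat_load", "thi"],
    )
    truth = SyntheticTruth(
        breeding_values=u,
        permanent_effects=pe,
        cow_ids=cows,
        qtls=qtls,
        qtl_variance_inflation=inflation,
        htd_effects=htd_effects,
        dim_effects=dim_effects,
    )
    return df, truth


def select_genotyped(
    sim_ped: SimulatedPedigree, cfg: SimulationConfig
) -> list[str]:
    """Genotyped subset: every sire with final-generation offspring plus a
    seed-determined fraction of the phenotyped cows."""
    ped = sim_ped.pedigree
    rng = np.random.default_rng(cfg.seed + 4)
    last = sim_ped.generation.max()
    sires = sorted(
        {
            ped.ids[ped.sire[i]]
            for i in range(len(ped))
            if sim_ped.generation[i] == last and ped.sire[i] >= 0
        }
    )
    cows = sim_ped.cow_ids
    n_geno = int(round(cfg.genotyped_cow_fraction * len(cows)))
    chosen = sorted(rng.choice(len(cows), size=n_geno, replace=False))
    genotyped = sires + [cows[i] for i in chosen]
    # preserve pedigree order for downstream block alignment
    return sorted(genotyped, key=ped.code)


def simulate_gene_annotation(
    cfg: SimulationConfig, gene_length: int = 50_000, spacing: int = 200_000
) -> list:
    """Regularly spaced synthetic gene intervals tiling each chromosome."""
    from heatnorm.gene_set import GeneAnnotation

    genes = []
    k = 0
    for c in range(1, cfg.n_chromosomes + 1):
        start = 10_000
        while start + gene_length < cfg.chromosome_length_bp:
            genes.append(
                GeneAnnotation(
                    gene=f"gene{k}", chrom=str(c), start=start, end=start + gene_length
                )
            )
            k += 1
            start += spacing
    return genes


def simulate_gene_sets(
    genes: list[str], n_sets: int = 50, set_sizes=(10, 50, 200), seed: int = 0
):
    """Random gene sets over a universe, GMT-style."""
    from heatnorm.gene_set import GeneSetCollection

    rng = np.random.default_rng(seed)
    universe = set(genes)
    sets = {}
    for i in range(n_sets):
        size = int(set_sizes[i % len(set_sizes)])
        size = min(size, len(genes))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"SET{i:03d}"] = {genes[j] for j in members}
    return GeneSetCollection(sets=sets, universe=universe)
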