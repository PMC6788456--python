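"""Shared fixtures: tiny pedigrees, genotypes, and simulated datasets."""

import numpy as np
import pytest

from heatnorm import synthetic_data as sd
from heatnorm.relationships import GenotypeMatrix, Pedigree


@pytest.fixture
def trio() -> Pedigree:
    """Unrelated sire and dam with one offspring."""
    return Pedigree.from_records([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])


@pytest.fixture
def random_pedigree():
    """Factory for seeded multi-generation pedigrees."""

    def make(n_founders=20, n_generations=3, n_per_gen=50, seed=0) -> Pedigree:
        rng = np.random.default_rng(seed)
        records = [(f"F{i}", "0", "0") for i in range(n_founders)]
        prev = [f"F{i}" for i in range(n_founders)]
        for g in range(1, n_generations + 1):
            cur = []
            for i in range(n_per_gen):
                s, d = rng.choice(len(prev), size=2, replace=False)
                a = f"G{g}_{i}"
                records.append((a, prev[s], prev[d]))
                cur.append(a)
            prev = cur
        return Pedigree.from_records(records)

    return make


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """4 individuals x 5 SNPs with one sex-chromosome, one monomorphic and
    one rare SNP."""
    import pandas as pd

    codes = np.array(
        [
            [0, 2, 1, 0, 2],
            [1, 2, 0, 1, 1],
            [2, 2, 1, 0, 0],
            [1, 2, 2, 0, 1],
        ],
        dtype=np.int8,
    )
    snp_map = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(5)],
            "chrom": ["1", "1", "X", "2", "2"],
            "pos": [100, 200, 50, 10, 400],
            "counted_allele": ["A"] * 5,
        }
    )
    return GenotypeMatrix(codes=codes, ids=["i1", "i2", "i3", "i4"], snp_map=snp_map)


@pytest.fixture(scope="session")
def small_simulation():
    """One modest single-parity dataset reused across slow-ish tests."""
    cfg = sd.SimulationConfig(
        seed=42,
        n_founders=60,
        n_cows_phenotyped=150,
        parities=(1,),
        n_snps=300,
        n_chromosomes=2,
    )
    sim_ped = sd.simulate_pedigree(cfg)
    geno = sd.simulate_genotypes(sim_ped, cfg)
    daily = sd.simulate_weather(cfg)
    pheno, truth = sd.simulate_phenotypes(sim_ped, daily, cfg, geno)
    return {
        "cfg": cfg,
        "ped": sim_ped,
        "geno": geno,
        "weather": daily,
        "pheno": pheno,
        "truth": truth,
    }


def recursive_A(parents: dict[str, tuple[str | None, str | None]]):
    """Independent oracle: additive relationships by direct memoised recursion.

    ``parents`` maps animal -> (sire|None, dam|None).  Returns a nested dict
    a[x][y].  Intentionally distinct from both the package's tabular builder
    and Henderson's inverse rules.
    """
    order = list(parents)
    memo: dict[tuple[str, str], float] = {}

    def a(x: str, y: str) -> float:
        key = (x, y) if order.index(x) <= order.index(y) else (y, x)
        if key in memo:
            return memo[key]
        # ensure x is the later-born of the pair
        if order.index(x) < order.index(y):
            x, y = y, x
        sx, dx = parents[x]
        if x == y:
            val = 1.0 + 0.5 * (a(sx, dx) if (sx and dx) else 0.0)
        else:
            val = 0.5 * ((a(sx, y) if sx else 0.0) + (a(dx, y) if dx else 0.0))
        memo[key] = val
        return val

    return {x: {y: a(x, y) for y in order} for x in order}
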