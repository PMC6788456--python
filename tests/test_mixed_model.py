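"""Design construction, MME assembly/solution, and the Gibbs sampler."""

import numpy as np
import pandas as pd
import pytest

from heatnorm import synthetic_data as sd
from heatnorm.mixed_model import (
    ChainSpec,
    GibbsPriors,
    ModelSpec,
    TestDayRecord,
    VarianceComponents,
    apply_record_edits,
    assemble_mme,
    build_design,
    gibbs_sampler,
    hpd_interval,
    posterior_summary,
    solve_mme,
)
from heatnorm.mixed_model.design import records_from_table
from heatnorm.relationships import (
    Pedigree,
    RelationshipMatrix,
    build_A_inverse,
    tabular_A,
)


def rec(cow="c1", htd="H1|d1|1", parity=1, dim=50, y=30.0, f=0.0):
    return TestDayRecord(
        cow=cow, herd_test_day=htd, parity=parity, dim=dim, yield_value=y, heat_load=f
    )


def founder_ped(names):
    return Pedigree.from_records([(n, "0", "0") for n in names])


def vc_1parity(sa2=2.0, sav=0.0, sv2=1.0, spe2=1.0, spq=0.0, sq2=1.0, se2=1.0):
    return VarianceComponents(
        Phi=np.array([[sa2, sav], [sav, sv2]]),
        Psi=np.array([[spe2, spq], [spq, sq2]]),
        Rdiag=np.array([se2]),
        parities=(1,),
    )


class TestDesign:
    @pytest.mark.parametrize("dim,expected", [(5, 1), (24, 1), (25, 2), (305, 16)])
    def test_dim_class_boundaries(self, dim, expected):
        assert ModelSpec().dim_class(dim) == expected

    def test_zero_heat_load_drops_slope_columns(self):
        ped = founder_ped(["c1"])
        design = build_design([rec(f=0.0)], ped, ModelSpec(parities=(1,)))
        W = design.W.toarray()
        slope_cols = [design.additive_index("c1", 1, slope=True),
                      design.permanent_index("c1", 1, slope=True)]
        assert (W[:, slope_cols] == 0).all()

    def test_fixed_incidence_column_sums_match_tally(self):
        ped = founder_ped(["c1", "c2"])
        rng = np.random.default_rng(0)
        records = [
            rec(
                cow=rng.choice(["c1", "c2"]),
                htd=rng.choice(["H1|d1|1", "H1|d2|1"]),
                dim=int(rng.integers(5, 100)),
                f=float(rng.choice([0.0, 3.0])),
            )
            for _ in range(10)
        ]
        design = build_design(records, ped, ModelSpec(parities=(1,)))
        W = design.W.toarray()
        htd_cols = [i for i, lab in enumerate(design.fixed_labels) if lab.startswith("htd")]
        # one HTD indicator per record
        assert (W[:, htd_cols].sum(axis=1) == 1).all()
        for col in htd_cols:
            lev = design.fixed_labels[col].split(":", 1)[1]
            tally = sum(1 for r in records if r.herd_test_day == lev)
            assert W[:, col].sum() == tally

    def test_missing_cow_listed(self):
        ped = founder_ped(["c1"])
        with pytest.raises(KeyError, match="c2"):
            build_design([rec(cow="c2")], ped, ModelSpec(parities=(1,)))


class TestAssembleSolve:
    def test_zero_records_reduces_to_precisions(self):
        ped = founder_ped(["c1"])
        design = build_design([], ped, ModelSpec(parities=(1,), fixed_factors=()))
        vc = vc_1parity()
        K = build_A_inverse(ped)
        system = assemble_mme(design, vc, K)
        expected = np.linalg.inv(vc.Phi)  # single founder, no PE blocks (no cows)
        assert system.C.toarray() == pytest.approx(expected)
        assert system.rhs == pytest.approx(np.zeros(2))

    def test_scalar_blup_closed_form(self):
        y, sa2, spe2, se2 = 4.0, 2.0, 1.0, 1.0
        ped = founder_ped(["c1"])
        design = build_design(
            [rec(y=y, f=0.0)], ped, ModelSpec(parities=(1,), fixed_factors=())
        )
        vc = vc_1parity(sa2=sa2, spe2=spe2, se2=se2)
        sols = solve_mme(assemble_mme(design, vc, build_A_inverse(ped)))
        expected_a = sa2 / (sa2 + spe2 + se2) * y
        assert sols.additive[("c1", 1)][0] == pytest.approx(expected_a)
        assert sols.additive[("c1", 1)][1] == pytest.approx(0.0)

    def _toy_instance(self, seed=0, n_cows=5, parities=(1, 2)):
        cfg = sd.SimulationConfig(
            seed=seed, n_founders=6, n_cows_phenotyped=n_cows, parities=parities,
            n_snps=10, n_chromosomes=1, tests_per_lactation=6,
        )
        sim = sd.simulate_pedigree(cfg)
        daily = sd.simulate_weather(cfg)
        pheno, _ = sd.simulate_phenotypes(sim, daily, cfg)
        records = records_from_table(pheno, "milk")
        design = build_design(records, sim.pedigree, ModelSpec(parities=parities))
        idx = [2 * (p - 1) + k for p in parities for k in (0, 1)]
        Phi = sd.default_phi()[np.ix_(idx, idx)]
        vc = VarianceComponents(
            Phi=Phi, Psi=sd.default_psi(Phi),
            Rdiag=sd.default_rdiag()[[p - 1 for p in parities]], parities=parities,
        )
        return sim.pedigree, design, vc

    def test_matches_dense_textbook_mme(self):
        """Sparse assembly equals an independently built dense MME (<=30 animals)."""
        ped, design, vc = self._toy_instance()
        assert design.n_animals <= 30
        K = build_A_inverse(ped)
        system = assemble_mme(design, vc, K)

        # independent dense construction
        W = design.W.toarray()
        npar = design.n_parities
        Rinv = np.diag(
            [1.0 / vc.Rdiag[list(vc.parities).index(p)] for p in design.record_parity]
        )
        Ainv_dense = np.linalg.inv(tabular_A(ped))
        prec = np.zeros((design.n_coef, design.n_coef))
        a0 = design.n_fixed
        prec[a0 : a0 + 2 * npar * design.n_animals,
             a0 : a0 + 2 * npar * design.n_animals] = np.kron(
            Ainv_dense, np.linalg.inv(vc.Phi)
        )
        p0 = design.permanent_slice.start
        prec[p0:, p0:] = np.kron(np.eye(design.n_cows), np.linalg.inv(vc.Psi))
        C_dense = W.T @ Rinv @ W + prec
        assert system.C.toarray() == pytest.approx(C_dense, abs=1e-8)
        assert system.rhs == pytest.approx(W.T @ Rinv @ design.y)

    def test_solution_matches_dense_solve(self):
        ped, design, vc = self._toy_instance(seed=1, n_cows=8)
        system = assemble_mme(design, vc, build_A_inverse(ped))
        sols = solve_mme(system)
        dense = np.linalg.solve(system.C.toarray(), system.rhs)
        assert sols.theta == pytest.approx(dense, abs=1e-6)
        assert sols.relative_residual <= 1e-8

    def test_duplicate_records_invariance_fixed_only(self):
        """OLS solutions of the fixed-effect subsystem are unchanged when
        every record is duplicated (estimability invariance)."""
        ped = founder_ped(["c1", "c2"])
        records = [
            rec(cow="c1", htd="H1|d1|1", dim=10, y=30.0),
            rec(cow="c2", htd="H1|d1|1", dim=40, y=34.0),
            rec(cow="c1", htd="H1|d2|1", dim=40, y=31.0),
            rec(cow="c2", htd="H1|d2|1", dim=80, y=29.0),
        ]
        spec = ModelSpec(parities=(1,))

        def fixed_solution(recs):
            design = build_design(recs, ped, spec)
            W = design.W.toarray()[:, : design.n_fixed]
            y = design.y
            return np.linalg.lstsq(W, y, rcond=None)[0]

        once = fixed_solution(records)
        twice = fixed_solution(records + records)
        assert once == pytest.approx(twice, abs=1e-10)

    def test_non_pd_vc_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            vc_1parity(sa2=-1.0)


class TestRecordEdits:
    def test_rules_and_tally(self):
        rows = []
        # 10 lactations; lactation k has k+2 tests
        for k in range(10):
            for t in range(k + 2):
                rows.append((f"c{k}", "H1", f"d{t}", 1, 5 + 30 * t, 30.0))
        df = pd.DataFrame(rows, columns=["cow", "herd", "test_date", "parity", "dim", "milk"])
        df.loc[0, "dim"] = 306  # out-of-range record inside a short lactation
        edited, report = apply_record_edits(df, ModelSpec(parities=(1,)))
        # manual tally: lactations with >= 6 surviving tests are c4..c9
        assert report["dim_range"] == 1
        surviving = {f"c{k}" for k in range(4, 10)}
        assert set(edited["cow"]) == surviving
        assert report["retained"] == sum(k + 2 for k in range(4, 10))

    def test_dim_boundaries(self):
        df = pd.DataFrame(
            {
                "cow": ["c"] * 7, "herd": "H1",
                "test_date": [f"d{i}" for i in range(7)], "parity": 1,
                "dim": [5, 50, 100, 150, 200, 305, 306], "milk": 30.0,
            }
        )
        edited, report = apply_record_edits(df, ModelSpec(parities=(1,)))
        assert report["dim_range"] == 1
        assert len(edited) == 6  # DIM 305 kept, 306 dropped

    def test_high_parities_dropped(self):
        df = pd.DataFrame(
            {
                "cow": ["c"] * 12, "herd": "H1",
                "test_date": [f"d{i}" for i in range(6)] * 2,
                "parity": [1] * 6 + [4] * 6,
                "dim": list(range(5, 185, 30)) * 2, "milk": 30.0,
            }
        )
        edited, report = apply_record_edits(df, ModelSpec())
        assert report["parity"] == 6
        assert set(edited["parity"]) == {1}


class TestChainBookkeeping:
    def test_reference_protocol_retains_4000(self):
        assert ChainSpec.reference_protocol().n_retained == 4000

    def test_small_chain_counts(self, small_simulation):
        pheno = small_simulation["pheno"].iloc[:200]
        ped = small_simulation["ped"].pedigree
        design = build_design(
            records_from_table(pheno, "milk"), ped, ModelSpec(parities=(1,))
        )
        cfg = small_simulation["cfg"]
        priors = GibbsPriors(Phi_mean=cfg.Phi, Psi_mean=cfg.Psi, se2_mean=cfg.Rdiag)
        chain = gibbs_sampler(
            design, build_A_inverse(ped), priors,
            ChainSpec(total=50, burn_in=10, thin=4, seed=0),
        )
        assert len(chain.samples) == chain.meta["n_retained"] == (50 - 10) // 4

    def test_invalid_chain_spec(self):
        with pytest.raises(ValueError):
            ChainSpec(total=100, burn_in=100, thin=1)


class TestGibbs:
    def test_bitwise_reproducible(self, small_simulation):
        pheno = small_simulation["pheno"].iloc[:300]
        ped = small_simulation["ped"].pedigree
        design = build_design(
            records_from_table(pheno, "milk"), ped, ModelSpec(parities=(1,))
        )
        cfg = small_simulation["cfg"]
        priors = GibbsPriors(Phi_mean=cfg.Phi, Psi_mean=cfg.Psi, se2_mean=cfg.Rdiag)
        spec = ChainSpec(total=30, burn_in=0, thin=1, seed=123)
        Ainv = build_A_inverse(ped)
        c1 = gibbs_sampler(design, Ainv, priors, spec)
        c2 = gibbs_sampler(design, Ainv, priors, spec)
        assert c1.samples.equals(c2.samples)

    def test_no_data_recovers_prior_closed_form(self):
        """With zero records the chain's stationary distribution is the
        prior: E[Phi] = Phi_mean and E[se2] = nu*s0/(nu-2), the conjugate
        inverse-gamma closed form."""
        ped = founder_ped(["c1"])
        design = build_design([], ped, ModelSpec(parities=(1,), fixed_factors=()))
        priors = GibbsPriors(
            Phi_mean=np.array([[2.0, 0.3], [0.3, 1.0]]),
            Psi_mean=np.eye(2),
            se2_mean=np.array([3.0]),
            nu_e=6.0,
        )
        chain = gibbs_sampler(
            design, build_A_inverse(ped), priors,
            ChainSpec(total=20_000, burn_in=2_000, thin=1, seed=7),
        )
        m = chain.samples.mean()
        assert m["phi_a1_a1"] == pytest.approx(2.0, rel=0.1)
        assert m["phi_a1_v1"] == pytest.approx(0.3, abs=0.1)
        assert m["phi_v1_v1"] == pytest.approx(1.0, rel=0.1)
        # scaled inverse chi-square mean nu*s0^2/(nu-2) with our parameterisation
        expected_se2 = 6.0 * 3.0 / (6.0 - 2.0)
        assert m["r_e1"] == pytest.approx(expected_se2, rel=0.1)

    def test_zero_heat_load_degenerates_to_repeatability_model(self):
        """With f = 0 everywhere the slope design columns vanish and slope
        variances stay at their prior."""
        ped = founder_ped([f"c{i}" for i in range(20)])
        rng = np.random.default_rng(3)
        records = [
            rec(cow=f"c{i}", htd=f"H1|d{t}|1", dim=5 + 30 * t,
                y=float(30 + rng.normal()), f=0.0)
            for i in range(20)
            for t in range(6)
        ]
        design = build_design(records, ped, ModelSpec(parities=(1,)))
        slope_cols = [design.additive_index(f"c{i}", 1, slope=True) for i in range(20)]
        assert design.W.toarray()[:, slope_cols].sum() == 0


class TestSummaries:
    def test_hpd_constant_chain_is_point(self):
        lo, hi = hpd_interval(np.full(500, 3.14), 0.95)
        assert lo == hi == pytest.approx(3.14)

    def test_hpd_matches_exhaustive_scan(self):
        x = np.arange(1.0, 1001.0)
        lo, hi = hpd_interval(x, 0.95)
        # independent exhaustive window scan
        k = int(np.ceil(0.95 * 1000))
        widths = [(x[i + k - 1] - x[i], x[i], x[i + k - 1]) for i in range(1000 - k + 1)]
        w, elo, ehi = min(widths)
        assert (lo, hi) == (elo, ehi)
        assert hi - lo == pytest.approx(w)

    def test_hpd_standard_normal_quantiles(self):
        rng = np.random.default_rng(0)
        lo, hi = hpd_interval(rng.standard_normal(50_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_summary_requires_enough_draws(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="too short"):
            posterior_summary(df, min_samples=100)


class TestThreeParityRun:
    def test_full_6x6_gibbs_smoke(self):
        """Three-parity run: 6x6 Phi/Psi sampling produces PD posterior
        means and parity-specific residuals."""
        cfg = sd.SimulationConfig(
            seed=9, n_founders=30, n_cows_phenotyped=40, parities=(1, 2, 3),
            n_snps=10, n_chromosomes=1, tests_per_lactation=6,
        )
        sim = sd.simulate_pedigree(cfg)
        daily = sd.simulate_weather(cfg)
        pheno, _ = sd.simulate_phenotypes(sim, daily, cfg)
        from heatnorm.mixed_model import records_from_table
        from heatnorm.relationships import build_A_inverse

        design = build_design(
            records_from_table(pheno, "milk"), sim.pedigree, ModelSpec()
        )
        priors = GibbsPriors(Phi_mean=cfg.Phi, Psi_mean=cfg.Psi, se2_mean=cfg.Rdiag)
        chain = gibbs_sampler(
            design, build_A_inverse(sim.pedigree), priors,
            ChainSpec(total=120, burn_in=20, thin=2, seed=1),
        )
        assert len(chain.samples) == 50
        vc = chain.posterior_mean_vc()
        assert np.linalg.eigvalsh(vc.Phi).min() > 0
        assert np.linalg.eigvalsh(vc.Psi).min() > 0
        assert len(vc.Rdiag) == 3 and (vc.Rdiag > 0).all()
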