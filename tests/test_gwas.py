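"""Longitudinal GWAS: back-solving, trajectories, selection, durations, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from longgblup import BSplineBasis, LegendreBasis
from longgblup.grm import GRMResult
from longgblup.gwas import (
    SnpEffectTrajectories,
    backsolve_snp_effects,
    candidate_windows,
    classify_duration,
    duration_report,
    effects_over_time,
    select_top_snps,
)
from longgblup.residuals import ResidualClassMap
from longgblup.rrm import RRMFit
from tests.conftest import ConstantBasis


def full_rank_grm(rng, n=4, s=6):
    """Uncentered Z so that ZZ' is nonsingular (a full-rank instance)."""
    Z = rng.standard_normal((n, s))
    return GRMResult(
        G=Z @ Z.T, Z_centered=Z, p_freq=np.full(s, 0.5), k_scale=1.0,
        kept_snp_ids=[f"s{j}" for j in range(s)],
        line_ids=[f"L{i}" for i in range(n)],
        chrom=np.array(["1"] * s, dtype=object), pos_bp=(np.arange(s) + 1) * 1000,
    )


def fit_stub(g_hat, basis, line_ids):
    m = g_hat.shape[1]
    return RRMFit(
        G0_hat=np.eye(m), residual_variances=np.array([1.0]),
        residual_map=ResidualClassMap.homogeneous(27, 83),
        b_hat=pd.Series(dtype=float), env_effects=pd.Series(dtype=float),
        g_hat=g_hat, line_ids=line_ids, basis=basis,
        logL_reml=0.0, n_varcomp_params=1, AIC=0.0, converged=True, n_iterations=1,
    )


class TestBacksolve:
    def test_zero_gebv_gives_zero_effects(self):
        rng = np.random.default_rng(0)
        grm = full_rank_grm(rng)
        fit = fit_stub(np.zeros((4, 2)), LegendreBasis(order=1), grm.line_ids)
        traj = backsolve_snp_effects(fit, grm)
        assert np.allclose(traj.u_hat, 0.0)

    def test_projection_identity_on_full_rank_instance(self):
        rng = np.random.default_rng(1)
        grm = full_rank_grm(rng)
        g = rng.standard_normal((4, 3))
        fit = fit_stub(g, LegendreBasis(order=2), grm.line_ids)
        traj = backsolve_snp_effects(fit, grm)
        assert np.max(np.abs(grm.Z_centered @ traj.u_hat - g)) < 1e-8

    def test_matches_dense_brute_force(self):
        rng = np.random.default_rng(2)
        grm = full_rank_grm(rng)
        g = rng.standard_normal((4, 2))
        fit = fit_stub(g, LegendreBasis(order=1), grm.line_ids)
        traj = backsolve_snp_effects(fit, grm)
        Z = grm.Z_centered
        brute = Z.T @ np.linalg.inv(Z @ Z.T) @ g
        assert np.allclose(traj.u_hat, brute, atol=1e-10)

    def test_line_order_mismatch_raises(self):
        rng = np.random.default_rng(3)
        grm = full_rank_grm(rng)
        fit = fit_stub(np.zeros((4, 2)), LegendreBasis(order=1), list(reversed(grm.line_ids)))
        with pytest.raises(ValueError, match="line"):
            backsolve_snp_effects(fit, grm)

    def test_phenotype_scaling_scales_effect_trajectories(self, small_dataset, small_grm):
        """Scaling all phenotypes by c scales every SNP-effect trajectory by c."""
        from longgblup import build_mme
        from longgblup.data import PhenotypeTable

        d = small_dataset
        m = d["basis"].n_coef
        vc = (0.3 * np.eye(m), 1.0)
        c = 3.0
        fit1 = build_mme(d["phen"], d["basis"], small_grm,
                         ResidualClassMap.homogeneous(27, 83), vc)
        scaled = d["phen"].df.copy()
        scaled["value"] *= c
        fit2 = build_mme(PhenotypeTable(scaled), d["basis"], small_grm,
                         ResidualClassMap.homogeneous(27, 83),
                         (c ** 2 * vc[0], c ** 2 * vc[1]))
        t1 = effects_over_time(backsolve_snp_effects(fit1, small_grm), d["basis"], d["grid"])
        t2 = effects_over_time(backsolve_snp_effects(fit2, small_grm), d["basis"], d["grid"])
        assert np.allclose(t2.effects_by_dap, c * t1.effects_by_dap, atol=1e-8)


class TestEffectsOverTime:
    def test_zero_u_gives_zero_trajectory(self):
        traj = SnpEffectTrajectories(
            u_hat=np.zeros((5, 3)), effects_by_dap=None, dap_grid=None,
            snp_ids=[f"s{j}" for j in range(5)],
            chrom=np.array(["1"] * 5, dtype=object), pos_bp=np.arange(1, 6),
        )
        out = effects_over_time(traj, BSplineBasis(degree=1, knots=(55,)))
        assert np.allclose(out.effects_by_dap, 0.0)

    def test_constant_basis_gives_constant_trajectory(self):
        u = np.array([[2.0], [-1.0]])
        traj = SnpEffectTrajectories(
            u_hat=u, effects_by_dap=None, dap_grid=None, snp_ids=["a", "b"],
            chrom=np.array(["1", "1"], dtype=object), pos_bp=np.array([1, 2]),
        )
        out = effects_over_time(traj, ConstantBasis(), np.arange(27, 84, 10))
        assert np.allclose(out.effects_by_dap, u @ np.ones((1, 6)))

    def test_matches_per_snp_loop(self):
        rng = np.random.default_rng(4)
        basis = LegendreBasis(order=3)
        u = rng.standard_normal((7, 4))
        traj = SnpEffectTrajectories(
            u_hat=u, effects_by_dap=None, dap_grid=None,
            snp_ids=[f"s{j}" for j in range(7)],
            chrom=np.array(["1"] * 7, dtype=object), pos_bp=np.arange(1, 8),
        )
        grid = np.arange(27, 84, 3)
        out = effects_over_time(traj, basis, grid)
        T = basis.design_matrix(grid)
        for s in range(7):
            assert np.allclose(out.effects_by_dap[s], T @ u[s])


def make_traj(E, chrom=None, pos=None, grid=None):
    s = E.shape[0]
    grid = grid if grid is not None else np.arange(27, 27 + E.shape[1])
    return SnpEffectTrajectories(
        u_hat=np.zeros((s, 1)), effects_by_dap=E, dap_grid=np.asarray(grid),
        snp_ids=[f"s{j}" for j in range(s)],
        chrom=np.array(chrom if chrom is not None else ["1"] * s, dtype=object),
        pos_bp=np.array(pos if pos is not None else (np.arange(s) + 1) * 100),
    )


class TestTopSnpSelection:
    def test_matches_sort_based_brute_force(self):
        rng = np.random.default_rng(5)
        E = rng.standard_normal((40, 9))
        traj = make_traj(E)
        sel = select_top_snps(traj, k=10)
        for j, dap in enumerate(traj.dap_grid):
            got = sel[sel["dap"] == dap]["snp_id"].tolist()
            brute = sorted(
                range(40),
                key=lambda s: (-abs(E[s, j]), traj.chrom[s], traj.pos_bp[s]),
            )[:10]
            assert got == [f"s{b}" for b in brute]

    def test_tie_broken_by_chrom_then_position(self):
        E = np.array([[1.0], [-1.0]])
        traj = make_traj(E, chrom=["2", "1"], pos=[10, 500])
        sel = select_top_snps(traj, k=1)
        assert sel["snp_id"].tolist() == ["s1"]  # chrom 1 wins over chrom 2

    def test_single_dominant_snp_present_all_days(self):
        E = np.vstack([np.full(6, 9.0), np.ones((3, 6))])
        traj = make_traj(E)
        sel = select_top_snps(traj, k=1)
        assert set(sel["snp_id"]) == {"s0"}
        assert len(sel) == 6

    def test_invalid_k(self):
        with pytest.raises(ValueError, match="k"):
            select_top_snps(make_traj(np.ones((2, 2))), k=0)


class TestDurationClassification:
    @pytest.mark.parametrize(
        "days,expected",
        [
            (range(27, 61), "long"),          # 34 consecutive days
            (range(40, 48), "short"),          # 8 consecutive days
            (list(range(30, 36)) + list(range(70, 76)), "intermittent"),
            (range(27, 37), "mid"),            # exactly 10 days: boundary -> mid
            (range(27, 57), "mid"),            # exactly 30 days: boundary -> mid
            (range(27, 58), "long"),           # 31 days
            ([55], "short"),
        ],
    )
    def test_rules(self, days, expected):
        assert classify_duration(list(days)) == expected

    def test_empty_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            classify_duration([])

    @given(st.sets(st.integers(27, 83), min_size=1, max_size=57))
    def test_total_and_exclusive(self, days):
        cat = classify_duration(sorted(days))
        arr = np.sort(np.array(sorted(days)))
        runs = 1 + int(np.sum(np.diff(arr) > 1))
        span = arr[-1] - arr[0] + 1
        if runs > 1:
            assert cat == "intermittent"
        elif span > 30:
            assert cat == "long"
        elif span >= 10:
            assert cat == "mid"
        else:
            assert cat == "short"

    def test_duration_report_categories(self):
        E = np.zeros((2, 57))
        E[0, :] = 5.0               # always top -> long
        E[1, :] = 1.0
        traj = make_traj(E, grid=np.arange(27, 84))
        sel = select_top_snps(traj, k=1)
        rep = duration_report(sel)
        assert rep.loc[rep["snp_id"] == "s0", "category"].iloc[0] == "long"
        assert rep.loc[rep["snp_id"] == "s0", "n_days"].iloc[0] == 57


@pytest.fixture
def bed_annotation(tmp_path):
    import pyranges as pr

    p = tmp_path / "ann.bed"
    p.write_text(
        "1\t89999\t95000\tgeneA\n"
        "1\t99999\t100001\tgeneB\n"
        "2\t0\t1000\tgeneC\n"
    )
    return pr.read_bed(str(p))


class TestCandidateWindows:
    def _sel(self, chrom, pos):
        return pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(len(pos))], "chrom": chrom,
             "pos_bp": pos, "dap": 30, "effect": 1.0, "rank": 1}
        )

    def test_window_overlap_reported(self, bed_annotation):
        hits = candidate_windows(self._sel(["1"], [100000]), bed_annotation, 25000)
        assert set(hits["feature_name"]) == {"geneA", "geneB"}

    def test_snp_inside_feature_flagged(self, bed_annotation):
        hits = candidate_windows(self._sel(["1"], [100000]), bed_annotation, 25000)
        assert bool(hits.set_index("feature_name").loc["geneB", "within_gene"])
        assert not bool(hits.set_index("feature_name").loc["geneA", "within_gene"])

    def test_closed_interval_boundary_included(self, tmp_path):
        import pyranges as pr

        p = tmp_path / "edge.bed"
        p.write_text("1\t74000\t75000\tedge\n")  # 1-based [74001, 75000]
        hits = candidate_windows(
            self._sel(["1"], [100000]), pr.read_bed(str(p)), 25000
        )
        assert hits["feature_name"].tolist() == ["edge"]

    def test_missing_chromosome_warns_and_empty(self, bed_annotation, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="longgblup.gwas"):
            hits = candidate_windows(self._sel(["9"], [100]), bed_annotation, 25000)
        assert hits.empty
        assert "absent" in caplog.text

    def test_matches_quadratic_scan_oracle(self, tmp_path):
        import pyranges as pr

        rng = np.random.default_rng(6)
        starts = rng.integers(0, 500000, size=60)
        lens = rng.integers(100, 20000, size=60)
        chroms = rng.choice(["1", "2"], size=60)
        bed = "".join(
            f"{c}\t{s}\t{s + l}\tf{i}\n" for i, (c, s, l) in enumerate(zip(chroms, starts, lens))
        )
        p = tmp_path / "rand.bed"
        p.write_text(bed)
        ann = pr.read_bed(str(p))
        snp_chrom = rng.choice(["1", "2"], size=20).tolist()
        snp_pos = rng.integers(1, 500000, size=20).tolist()
        sel = self._sel(snp_chrom, snp_pos)
        w = 10000
        hits = candidate_windows(sel, ann, w)
        got = set(zip(hits["snp_id"], hits["feature_name"]))
        brute = set()
        for i, (c, pos) in enumerate(zip(snp_chrom, snp_pos)):
            lo, hi = pos - w, pos + w  # closed, 1-based
            for jf, (cf, s, l) in enumerate(zip(chroms, starts, lens)):
                f_lo, f_hi = s + 1, s + l  # 1-based closed feature
                if c == cf and not (hi < f_lo or lo > f_hi):
                    brute.add((f"s{i}", f"f{jf}"))
        assert got == brute
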