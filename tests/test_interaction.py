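"""LD pruning, kinship estimation, Model-2 screen, Q-K mixed refits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scdeqtl import SimulationConfig
from scdeqtl.containers import GenotypeMatrix, KinshipMatrix
from scdeqtl.esnp import compute_bonferroni_thresholds
from scdeqtl.interaction import (
    InteractionScan,
    QKMixedModel,
    estimate_kinship,
    finalize_interactions,
    ld_prune,
)
from scdeqtl.simulate import simulate_cohort, simulate_genotypes, simulate_metadata
from scdeqtl._linalg import build_design
from conftest import make_expression


def _geno_from_dosage(d, chrom=None, pos=None):
    n, s = d.shape
    snps = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * s,
        "pos": pos if pos is not None else np.arange(1, s + 1),
        "allele_minor": "B", "allele_major": "A",
    }, index=pd.Index([f"rs{j}" for j in range(s)], name="snp_id"))
    return GenotypeMatrix(sample_ids=[f"s{i}" for i in range(n)], snps=snps,
                         dosage=np.asarray(d, dtype=float))


# ---------------------------------------------------------------------------
# LD pruning


def test_prune_keeps_independent_snps():
    rng = np.random.default_rng(0)
    g = _geno_from_dosage(rng.binomial(2, 0.3, size=(300, 40)))
    kept = ld_prune(g, r2_max=0.3, maf_min=0.1)
    assert len(kept) >= 38  # chance r2 above 0.3 is rare at n = 300


def test_prune_removes_exactly_one_of_a_duplicated_pair():
    rng = np.random.default_rng(1)
    col = rng.binomial(2, 0.4, 200)
    d = np.column_stack([col, col, rng.binomial(2, 0.4, 200)])
    g = _geno_from_dosage(d)
    kept = ld_prune(g)
    assert "rs0" in kept and "rs1" not in kept  # earlier position survives
    assert "rs2" in kept


def test_prune_filters_low_maf_and_missing():
    rng = np.random.default_rng(2)
    good = rng.binomial(2, 0.3, 100).astype(float)
    rare = rng.binomial(2, 0.02, 100).astype(float)
    holey = good.copy()
    holey[0] = np.nan
    g = _geno_from_dosage(np.column_stack([good, rare, holey]))
    kept = ld_prune(g, maf_min=0.1)
    assert kept == ["rs0"]


def test_prune_breaks_up_correlated_blocks():
    """Survivors of an AR-correlated block have pairwise r^2 < 0.3."""
    cfg = SimulationConfig(n_snps=200, n_probes=5, sibling_fraction=0.0,
                           ld_rho=0.85, n_chromosomes=2, seed=3,
                           maf_range=(0.2, 0.5), n_local_esnps=0,
                           n_distal_esnps=0)
    g, _ = simulate_genotypes(cfg)
    kept = ld_prune(g, r2_max=0.3, maf_min=0.1, window=50, step=5)
    assert 0 < len(kept) < g.n_snps
    idx = [g.snp_ids.index(s) for s in kept]
    chroms = g.snps["chrom"].to_numpy()
    viol = total = 0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if chroms[idx[a]] != chroms[idx[b]]:
                continue
            r = np.corrcoef(g.dosage[:, idx[a]], g.dosage[:, idx[b]])[0, 1]
            total += 1
            viol += r * r >= 0.3
    assert viol / total < 0.02  # windowed pruning: distant pairs unchecked


# ---------------------------------------------------------------------------
# kinship


def test_self_relatedness_is_one():
    rng = np.random.default_rng(4)
    g = _geno_from_dosage(rng.binomial(2, 0.3, size=(10, 100)))
    kin = estimate_kinship(g)
    assert np.all(np.diag(kin.pihat) == 1.0)


def test_unrelated_founders_have_near_zero_pihat():
    cfg = SimulationConfig(
        n_patients_E=60, n_patients_FU=0, n_controls=40, sibling_fraction=0.0,
        n_snps=2000, n_probes=5, seed=5, maf_range=(0.1, 0.5),
        n_local_esnps=0, n_distal_esnps=0,
    )
    g, _ = simulate_genotypes(cfg)
    kin = estimate_kinship(g)
    off = kin.pihat[np.triu_indices(g.n_samples, k=1)]
    assert np.nanmean(np.abs(off)) < 0.02


def test_full_sib_pihat_near_half():
    cfg = SimulationConfig(
        n_patients_E=60, n_patients_FU=40, n_controls=60, sibling_fraction=0.8,
        n_snps=2000, n_probes=5, seed=6, maf_range=(0.1, 0.5),
        n_local_esnps=0, n_distal_esnps=0,
    )
    g, truth = simulate_genotypes(cfg)
    kin = estimate_kinship(g)
    true_k = truth.kinship_true.pihat
    iu = np.triu_indices(g.n_samples, k=1)
    sib_mask = true_k[iu] == 0.5
    assert sib_mask.sum() >= 50
    sib_est = kin.pihat[iu][sib_mask]
    assert abs(np.nanmean(sib_est) - 0.5) < 0.05
    # regression of estimate on truth over mixed sibs/unrelateds: slope ~ 1
    slope = np.polyfit(true_k[iu], kin.pihat[iu], 1)[0]
    assert abs(slope - 1.0) < 0.1


def test_pair_with_too_few_snps_flagged_missing():
    rng = np.random.default_rng(7)
    d = rng.binomial(2, 0.3, size=(4, 60)).astype(float)
    d[0, :40] = np.nan  # sample 0 shares <50 complete SNPs with everyone
    g = _geno_from_dosage(d)
    kin = estimate_kinship(g, min_snps=50)
    assert np.isnan(kin.pihat[0, 1])
    assert np.isfinite(kin.pihat[2, 3])


# ---------------------------------------------------------------------------
# Model-2 screen


@pytest.fixture(scope="module")
def interaction_cohort():
    cfg = SimulationConfig(
        n_snps=150, n_probes=30, n_local_esnps=0, n_distal_esnps=0,
        n_interaction_effects=3, interaction_delta=0.5, noise_sd=0.3,
        maf_range=(0.2, 0.5), seed=8,
    )
    return cfg, *simulate_cohort(cfg)


def test_interaction_f_matches_rss_bookkeeping_oracle(interaction_cohort):
    cfg, g, e, meta, truth = interaction_cohort
    res = InteractionScan(e, g, meta).fit(emit_all=True)
    table = res.records.set_index(["probe_id", "snp_id"])
    C = build_design(meta, ["clin_status", "wbc", "rbc", "sex"]).X
    status = meta["clin_status"].to_numpy()
    levels = sorted(pd.unique(status))
    dummies = np.column_stack([(status == lv).astype(float) for lv in levels[1:]])
    rng = np.random.default_rng(9)
    checked = 0
    for _ in range(30):
        pid = e.probe_ids[rng.integers(e.n_probes)]
        sid = g.snp_ids[rng.integers(g.n_snps)]
        if (pid, sid) not in table.index:
            continue
        y = e.values[e.probe_ids.index(pid)]
        gd = g.dosage[:, g.snp_ids.index(sid)]
        X1 = np.column_stack([C, gd])
        X2 = np.column_stack([C, gd, dummies * gd[:, None]])
        rss = []
        for X in (X1, X2):
            b, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            rss.append(r @ r)
        df1 = X2.shape[1] - X1.shape[1]
        df2 = len(y) - X2.shape[1]
        F = ((rss[0] - rss[1]) / df1) / (rss[1] / df2)
        row = table.loc[(pid, sid)]
        assert row["F"] == pytest.approx(F, rel=1e-8)
        assert row["df1"] == df1 and row["df2"] == df2
        checked += 1
    assert checked >= 20


def test_planted_interactions_detected_with_correct_slopes(interaction_cohort):
    cfg, g, e, meta, truth = interaction_cohort
    res = InteractionScan(e, g, meta).fit()
    sig = res.significant.set_index(["probe_id", "snp_id"])
    found = 0
    for pid, sid, slopes in truth.interaction_assignments:
        if (pid, sid) not in sig.index:
            continue
        found += 1
        row = sig.loc[(pid, sid)]
        for lv, true_slope in slopes.items():
            assert row[f"slope_{lv}"] == pytest.approx(true_slope, abs=0.25)
    assert found >= 2


def test_null_interaction_pvalues_are_uniform():
    cfg = SimulationConfig(
        n_snps=150, n_probes=30, n_local_esnps=0, n_distal_esnps=0,
        n_interaction_effects=0, de_fraction=0.0, clinstatus_effect_sd=0.0,
        hb_effect_sd=0.0, seed=10,
    )
    g, e, meta, _ = simulate_cohort(cfg)
    res = InteractionScan(e, g, meta).fit(emit_all=True)
    ks = stats.kstest(res.records["p"], "uniform")
    assert ks.pvalue > 0.01


def test_group_monomorphic_snp_skipped(interaction_cohort):
    cfg, g, e, meta, truth = interaction_cohort
    d = g.dosage.copy()
    ctl = (meta["clin_status"] == "Ctl").to_numpy()
    d[ctl, 0] = 0.0  # SNP 0 monomorphic among controls
    g2 = GenotypeMatrix(sample_ids=list(g.sample_ids), snps=g.snps, dosage=d)
    res = InteractionScan(e, g2, meta).fit(emit_all=True)
    assert g.snp_ids[0] not in set(res.records["snp_id"])
    assert res.n_snps_skipped >= 1


# ---------------------------------------------------------------------------
# Q-K mixed model


def test_identity_kinship_reduces_to_ols():
    rng = np.random.default_rng(11)
    n = 80
    for _ in range(5):
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 4))])
        y = rng.standard_normal(n)
        res = QKMixedModel(y, X, 2.0 * np.eye(n), test_cols=[3, 4]).fit()
        b, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r1 = y - X @ b
        Xr = X[:, :3]
        br, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ br
        F = ((rr @ rr - r1 @ r1) / 2) / ((r1 @ r1) / (n - 5))
        p_ols = stats.f.sf(F, 2, n - 5)
        assert abs(res.test_p - p_ols) <= 1e-6


def test_mixed_model_recovers_polygenic_heritability():
    rng = np.random.default_rng(12)
    cfg = SimulationConfig(sibling_fraction=1.0, n_snps=10, n_probes=5, seed=13,
                           n_local_esnps=0, n_distal_esnps=0)
    _, truth = simulate_genotypes(cfg)
    K2 = 2.0 * truth.kinship_true.pihat
    n = cfg.n_samples
    L = np.linalg.cholesky(K2 + 1e-8 * np.eye(n))
    h2s = []
    for rep in range(20):
        u = L @ rng.standard_normal(n) * np.sqrt(0.6)
        y = u + rng.standard_normal(n) * np.sqrt(0.4)
        res = QKMixedModel(y, np.ones((n, 1)), K2, test_cols=[]).fit()
        h2s.append(res.heritability)
    assert abs(np.mean(h2s) - 0.6) < 0.15


def test_planted_interaction_survives_mixed_refit():
    cfg = SimulationConfig(
        n_snps=100, n_probes=20, n_local_esnps=0, n_distal_esnps=0,
        n_interaction_effects=2, interaction_delta=0.6, noise_sd=0.3,
        maf_range=(0.2, 0.5), sibling_fraction=0.6, seed=14,
    )
    g, e, meta, truth = simulate_cohort(cfg)
    scan = InteractionScan(e, g, meta)
    res = scan.fit()
    refit = res.refit_mixed(truth.kinship_true)
    assert len(refit) >= 1
    final = finalize_interactions(refit, scan.thresholds)
    planted = {(p, s) for p, s, _ in truth.interaction_assignments}
    assert planted & set(map(tuple, final[["probe_id", "snp_id"]].values))


def test_refit_only_covers_screen_passing_pairs():
    """Two-stage subset property: no refit without an OLS pass."""
    cfg = SimulationConfig(
        n_snps=80, n_probes=15, n_local_esnps=0, n_distal_esnps=0,
        n_interaction_effects=1, interaction_delta=0.8, noise_sd=0.3,
        maf_range=(0.2, 0.5), seed=15,
    )
    g, e, meta, truth = simulate_cohort(cfg)
    scan = InteractionScan(e, g, meta)
    res = scan.fit()
    refit = res.refit_mixed(truth.kinship_true)
    screened = set(map(tuple, res.significant[["probe_id", "snp_id"]].values))
    assert set(map(tuple, refit[["probe_id", "snp_id"]].values)) <= screened


def test_finalize_thresholds_and_orders_records():
    thr = compute_bonferroni_thresholds(10, 1000, 200)
    recs = pd.DataFrame({
        "probe_id": ["a", "b", "c", "d"],
        "snp_id": ["s1", "s2", "s3", "s4"],
        "class": ["local", "local", "distal", "local"],
        "p": [1e-9, 1e-9, 1e-9, 1e-9],
        "mixedmodel_p": [1e-7, 1e-4, 1e-9, 2e-8],
        "refit_converged": [True, True, True, False],
    })
    final = finalize_interactions(recs, thr)
    # local threshold 2.5e-5: 'a' passes; 'b' fails; 'c' needs the distal
    # threshold 5e-6 and passes; 'd' failed to converge
    assert list(final["probe_id"]) == ["c", "a"]


def test_finalize_empty_refits():
    thr = compute_bonferroni_thresholds(10, 1000, 200)
    assert finalize_interactions(pd.DataFrame(), thr).empty
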