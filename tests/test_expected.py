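"""Clumping, QC, candidate sets, LD summaries and the expected-RA model.

The greedy operations are checked against exhaustive brute-force oracles on
small random fixtures; the expected-RA bracketing is pinned by an analytic
single-tag/single-causal oracle.
"""

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel, random_panel
from pgiport import expected as exp
from pgiport.gstats import hwe_exact_pvalues
from pgiport.simulate import SimulationConfig
from pgiport.study import study_inputs, analyze


def sumstats_for(panel, pvals, betas=None):
    m = panel.n_variants
    betas = np.ones(m) * 0.1 if betas is None else betas
    return pd.DataFrame({
        "id": panel.variants["id"],
        "effect_allele": panel.variants["a1"],
        "other_allele": panel.variants["a2"],
        "eaf": panel.allele_freq(),
        "beta": betas,
        "se": np.full(m, 0.01),
        "pval": pvals,
        "n": 1000,
    })


def pairwise_r(panel):
    x = panel.imputed_dosages()
    z = (x - x.mean(0))
    sd = x.std(0)
    sd[sd == 0] = 1.0
    z = z / sd
    return (z.T @ z) / x.shape[0]


def brute_force_clump(panel, pvals, window_bp, r2_min, p_max):
    """Exhaustive greedy oracle that rescans all pairs every round."""
    r2 = pairwise_r(panel) ** 2
    pos = panel.variants["pos"].to_numpy()
    ids = panel.variants["id"].to_numpy()
    unassigned = set(range(len(ids)))
    index_ids = []
    while True:
        eligible = [j for j in unassigned if pvals[j] < p_max]
        if not eligible:
            break
        j = min(eligible, key=lambda k: (pvals[k], k))
        unassigned.discard(j)
        index_ids.append(ids[j])
        for k in list(unassigned):
            if (pvals[k] < p_max and abs(pos[k] - pos[j]) <= window_bp
                    and r2[j, k] > r2_min):
                unassigned.discard(k)
    return index_ids


class TestClump:
    def test_uncorrelated_all_index(self, rng):
        panel = random_panel(rng, n=400, m=12, pos=1 + 10_000_000 * np.arange(12))
        pvals = rng.uniform(0.001, 0.4, size=12)
        top = exp.clump(sumstats_for(panel, pvals), panel, window_kb=2000,
                        set_sizes=(5,))
        assert len(top.index_ids) == 12 or len(top.index_ids) >= 5
        assert top.top(5) == list(panel.variants["id"].to_numpy()[np.argsort(pvals)][:5])

    def test_perfectly_correlated_pair(self, rng):
        col = rng.binomial(2, 0.4, size=100).astype(float)
        panel = make_panel(np.column_stack([col, col]), pos=[1000, 2000])
        top = exp.clump(sumstats_for(panel, np.array([0.2, 0.01])), panel)
        assert top.index_ids == ["snp1"]
        assert top.clumps["snp1"] == ["snp0"]

    def test_matches_brute_force_oracle(self, rng):
        cfg = SimulationConfig(seed=17, n_variants=200, n_blocks=10,
                               n_samples_per_pop=150, n_causal=20,
                               spacing_bp=20_000)
        from pgiport.simulate import simulate_reference_panel

        panel = simulate_reference_panel(cfg).by_ancestry("pop1")
        pvals = np.random.default_rng(3).uniform(size=200)
        ss = sumstats_for(panel, pvals)
        got = exp.clump(ss, panel, window_kb=100, r2_min=0.1, p_max=0.5,
                        set_sizes=(200,)).index_ids
        oracle = brute_force_clump(panel, pvals, 100_000, 0.1, 0.5)
        assert got == oracle


class TestQc:
    def test_monomorphic_excluded(self, rng):
        d1 = rng.binomial(2, 0.3, size=(100, 3)).astype(float)
        d2 = d1.copy()
        d2[:, 1] = 0.0  # monomorphic in pop 2
        p1, p2 = make_panel(d1), make_panel(d2)
        kept = exp.qc_common_snps({"a": p1, "b": p2})
        assert "snp1" not in kept and "snp0" in kept

    def test_all_pass_full_intersection(self, rng):
        panel = random_panel(rng, n=200, m=6, maf_low=0.2)
        kept = exp.qc_common_snps({"a": panel, "b": panel})
        assert kept == list(panel.variants["id"])

    def test_matches_per_filter_oracle(self, rng):
        panels = {}
        for pop in ("a", "b"):
            panels[pop] = random_panel(rng, n=150, m=40, maf_low=0.005,
                                       maf_high=0.5, missing=0.03)
        kept = exp.qc_common_snps(panels)
        expected = None
        for panel in panels.values():
            ok_s = panel.sample_missingness() < 0.01
            sub = panel.subset(sample_mask=ok_s)
            ok = (sub.call_rate() > 0.95) & (sub.maf() > 0.01) & \
                 (hwe_exact_pvalues(np.rint(sub.dosages)) > 1e-10)
            ids = set(sub.variants["id"][ok])
            expected = ids if expected is None else expected & ids
        assert set(kept) == expected


class TestCandidates:
    def test_index_is_own_candidate(self, rng):
        panel = random_panel(rng, n=100, m=5)
        cand = exp.select_candidate_causal(["snp2"], panel)
        assert "snp2" in cand.candidates["snp2"]

    def test_window_bound_excludes(self, rng):
        col = rng.binomial(2, 0.4, size=200).astype(float)
        # identical columns 150 kb apart: r² = 1 but outside the 100 kb window
        panel = make_panel(np.column_stack([col, col]), pos=[1, 150_001])
        cand = exp.select_candidate_causal(["snp0"], panel, window_kb=100)
        assert cand.candidates["snp0"] == ["snp0"]

    def test_matches_nested_loop_oracle(self, rng):
        cfg = SimulationConfig(seed=23, n_variants=120, n_blocks=6,
                               n_samples_per_pop=200, n_causal=10)
        from pgiport.simulate import simulate_reference_panel

        panel = simulate_reference_panel(cfg).by_ancestry("pop1")
        indexes = list(panel.variants["id"][::17])
        got = exp.select_candidate_causal(indexes, panel, window_kb=40, r2_min=0.2)
        r2 = pairwise_r(panel) ** 2
        pos = panel.variants["pos"].to_numpy()
        lookup = {v: j for j, v in enumerate(panel.variants["id"])}
        for vid in indexes:
            j = lookup[vid]
            oracle = [panel.variants["id"][k] for k in range(panel.n_variants)
                      if abs(pos[k] - pos[j]) <= 40_000 and r2[j, k] > 0.2]
            assert got.candidates[vid] == oracle


class TestLdSummaries:
    def test_self_candidate_unity(self, rng):
        panel = random_panel(rng, n=150, m=3)
        cand = exp.CandidateCausalSet(candidates={"snp1": ["snp1"]},
                                      r2={"snp1": np.array([1.0])})
        out = exp.ld_summaries(pd.DataFrame({"id": ["snp1"], "beta_hat": [0.2]}),
                               cand, panel, panel)
        row = out.iloc[0]
        assert row["mean_r2_pop1"] == pytest.approx(1.0)
        assert row["mean_r1r2"] == pytest.approx(1.0)

    def test_identical_panels_r1r2_equals_r2(self, rng):
        panel = random_panel(rng, n=100, m=20, pos=1 + 2000 * np.arange(20))
        idx = list(panel.variants["id"][:5])
        cand = exp.select_candidate_causal(idx, panel, window_kb=100, r2_min=0.0)
        out = exp.ld_summaries(pd.DataFrame({"id": idx, "beta_hat": 0.1}),
                               cand, panel, panel)
        np.testing.assert_allclose(out["mean_r1r2"], out["mean_r2_pop1"], atol=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        cfg = SimulationConfig(seed=29, n_variants=50, n_blocks=2,
                               n_samples_per_pop=120, n_causal=5)
        from pgiport.simulate import simulate_reference_panel

        panel = simulate_reference_panel(cfg)
        p1, p2 = panel.by_ancestry("pop1"), panel.by_ancestry("pop2")
        idx = list(p1.variants["id"][::7])
        cand = exp.select_candidate_causal(idx, p1, window_kb=60, r2_min=0.1)
        out = exp.ld_summaries(pd.DataFrame({"id": idx, "beta_hat": 0.1}),
                               cand, p1, p2, window_kb=60).set_index("id")
        r_1, r_2 = pairwise_r(p1), pairwise_r(p2)
        pos = p1.variants["pos"].to_numpy()
        lookup = {v: j for j, v in enumerate(p1.variants["id"])}
        pool = sorted({c for cs in cand.candidates.values() for c in cs},
                      key=lambda v: lookup[v])
        for vid in idx:
            j = lookup[vid]
            cs = [lookup[c] for c in pool if abs(pos[lookup[c]] - pos[j]) <= 60_000]
            if not cs:
                assert vid not in out.index
                continue
            m_r2 = np.mean([r_1[j, k] ** 2 for k in cs])
            m_r1r2 = np.mean([r_1[j, k] * r_2[j, k] for k in cs])
            assert out.loc[vid, "mean_r2_pop1"] == pytest.approx(m_r2, abs=1e-10)
            assert out.loc[vid, "mean_r1r2"] == pytest.approx(m_r1r2, abs=1e-10)


def one_tag_summary(r1, r2, p_tag1, p_tag2, beta=0.37):
    return pd.DataFrame({
        "id": ["tag"], "mean_r2_pop1": [r1 ** 2], "mean_r1r2": [r1 * r2],
        "maf_pop1": [p_tag1], "maf_pop2": [p_tag2], "beta_hat": [beta],
        "n_candidates": [1],
    })


class TestExpectedRA:
    def test_identical_populations_unity(self):
        out = exp.expected_ra(one_tag_summary(0.8, 0.8, 0.3, 0.3),
                              effects_factor=1.0)
        assert out.factor_ld_maf == pytest.approx(1.0)
        assert out.factor_varscale == pytest.approx(1.0)
        assert out.ra_expected == pytest.approx(1.0)

    def test_sole_causal_perfect_ld(self):
        out = exp.expected_ra(one_tag_summary(1.0, 1.0, 0.2, 0.2))
        assert out.ra_expected == pytest.approx(1.0)

    def test_single_tag_analytic_oracle(self):
        """The tag's own frequencies must cancel: for one tag with one causal
        candidate the model equals the exact one-SNP-predictor R² ratio
        r2²/r1² x h2²/h1², whatever the tag MAFs are."""
        for r1, r2, p2 in [(0.3, 0.9, 0.1), (0.6, 0.6, 0.5), (0.9, 0.3, 0.25)]:
            c1, c2 = 0.2, 0.4  # causal freqs -> heritability ratio
            h_ratio = (c2 * (1 - c2)) / (c1 * (1 - c1))
            out = exp.expected_ra(one_tag_summary(r1, r2, 0.3, p2),
                                  effects_factor=h_ratio)
            oracle = (r2 ** 2 / r1 ** 2) * h_ratio
            assert out.ra_expected == pytest.approx(oracle, abs=1e-10)

    def test_symmetric_consistency(self, rng):
        m = 12
        summary = pd.DataFrame({
            "id": [f"s{k}" for k in range(m)],
            "mean_r2_pop1": rng.uniform(0.4, 1.0, m),
            "mean_r1r2": rng.uniform(0.2, 0.8, m),
            "maf_pop1": rng.uniform(0.05, 0.5, m),
            "maf_pop2": rng.uniform(0.05, 0.5, m),
            "beta_hat": rng.normal(size=m),
            "n_candidates": 3,
        })
        fwd = exp.expected_ra(summary)
        swapped = summary.rename(columns={"maf_pop1": "maf_pop2",
                                          "maf_pop2": "maf_pop1"})
        rev = exp.expected_ra(swapped)
        assert rev.factor_varscale == pytest.approx(1 / fwd.factor_varscale, rel=1e-10)
        # with identical panels (symmetric LD, equal frequencies) the full
        # model maps to its reciprocal when the effects factor is inverted
        sym = summary.assign(mean_r1r2=summary["mean_r2_pop1"],
                             maf_pop2=summary["maf_pop1"])
        f = exp.expected_ra(sym, effects_factor=2.0)
        b = exp.expected_ra(sym, effects_factor=0.5)
        assert b.ra_expected == pytest.approx(1 / f.ra_expected, rel=1e-10)

    def test_minor_allele_labelling_invariance(self):
        # p(1-p) terms are invariant to which allele is labelled minor
        a = exp.expected_ra(one_tag_summary(0.7, 0.5, 0.3, 0.2))
        b = exp.expected_ra(one_tag_summary(0.7, 0.5, 0.7, 0.8))
        assert a.ra_expected == pytest.approx(b.ra_expected, rel=1e-12)

    def test_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            exp.expected_ra(one_tag_summary(1, 1, 0.3, 0.3).iloc[:0])


class TestStabilityCurve:
    @pytest.fixture(scope="class")
    def small_run(self):
        cfg = SimulationConfig(seed=31, n_variants=600, n_blocks=12,
                               n_samples_per_pop=400, n_causal=60,
                               n_discovery=50_000)
        panel, causal, y, ss = study_inputs(cfg)
        p1, p2 = panel.by_ancestry("pop1"), panel.by_ancestry("pop2")
        qc_ids = exp.qc_common_snps({"pop1": p1, "pop2": p2})
        return ss[ss["id"].isin(qc_ids)], p1, p2, qc_ids

    def test_single_size_single_row(self, small_run):
        ss, p1, p2, qc_ids = small_run
        curve = exp.stability_curve(ss, p1, p2, set_sizes=(20,), qc_ids=qc_ids)
        assert len(curve) == 1
        assert curve["snp_set_size"].iloc[0] == 20

    def test_deterministic_rerun(self, small_run):
        ss, p1, p2, qc_ids = small_run
        a = exp.stability_curve(ss, p1, p2, set_sizes=(10, 30), qc_ids=qc_ids)
        b = exp.stability_curve(ss, p1, p2, set_sizes=(10, 30), qc_ids=qc_ids)
        pd.testing.assert_frame_equal(a, b)

    def test_flat_for_homogeneous_architecture(self, small_run):
        ss, p1, p2, qc_ids = small_run
        curve = exp.stability_curve(ss, p1, p2, set_sizes=(20, 40, 60),
                                    qc_ids=qc_ids)
        vals = curve["ra_expected"].to_numpy()
        assert vals.max() - vals.min() < 0.25  # stable within Monte-Carlo noise


def test_rho_b_degrades_agreement():
    """With the effects factor held at 1, the gap between observed and
    expected RA grows as the cross-population effect correlation drops."""
    gaps = {}
    for rho in (1.0, 0.5):
        diffs = []
        for seed in (101, 102, 103):
            cfg = SimulationConfig(seed=seed, rho_b=rho, n_variants=1000,
                                   n_blocks=20, n_samples_per_pop=600,
                                   n_causal=50)
            panel, causal, y, ss = study_inputs(cfg)
            r = analyze(panel, y, ss, top_k=30)
            diffs.append(r.ra_expected - r.ra_obs)
        gaps[rho] = np.mean(diffs)
    assert gaps[0.5] > gaps[1.0]
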