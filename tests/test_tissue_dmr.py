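"""Variance decomposition, moderated tests, p combination, motifs, TF calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcode import tissue_dmr as td


def _species_fm(rng, mode, n_frag=200, effect=0.3, sd_noise=0.05):
    samples = [("s1", "heart", "i1"), ("s2", "liver", "i1"),
               ("s3", "heart", "i2"), ("s4", "liver", "i2")]
    base = rng.uniform(0.2, 0.7, n_frag)
    eff = rng.random(n_frag) < 0.5
    rows = []
    for s, t, i in samples:
        v = base.copy()
        if mode == "tissue" and t == "heart":
            v = v + np.where(eff, effect, 0)
        if mode == "individual" and i == "i1":
            v = v + np.where(eff, effect, 0)
        v = np.clip(v + rng.normal(0, sd_noise, n_frag), 0, 1)
        rows += [(s, f"f{k}", v[k]) for k in range(n_frag)]
    fm = pd.DataFrame(rows, columns=["sample", "fragment", "mean_ratio"])
    meta = pd.DataFrame([{"sample": s, "species": "sp", "tissue": t, "individual": i}
                         for s, t, i in samples])
    return fm, meta


class TestVarianceDecomposition:
    def test_duplicated_samples_perfect_r2(self):
        rng = np.random.default_rng(0)
        fm, meta = _species_fm(rng, "none", sd_noise=0.0)
        vd = td.variance_decomposition({"sp": fm}, meta)
        row = vd.per_species.iloc[0]
        assert row["r2_tissue"] == pytest.approx(1.0)
        assert row["r2_individual"] == pytest.approx(1.0)

    def test_tissue_effects_dominate(self):
        rng = np.random.default_rng(1)
        fm, meta = _species_fm(rng, "tissue")
        row = td.variance_decomposition({"sp": fm}, meta).per_species.iloc[0]
        assert row["r2_tissue"] > row["r2_individual"]

    def test_single_individual_species_excluded(self):
        rng = np.random.default_rng(2)
        fm, meta = _species_fm(rng, "tissue")
        meta["individual"] = "i1"
        vd = td.variance_decomposition({"sp": fm}, meta)
        assert "sp" not in vd.per_species.index


class TestModeratedTest:
    def test_type_i_control(self):
        rng = np.random.default_rng(3)
        A = rng.normal(0.5, 0.1, (5000, 20))
        B = rng.normal(0.5, 0.1, (5000, 20))
        res = td.cpg_differential_test(A, B)
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_difference_power(self):
        rng = np.random.default_rng(4)
        A = rng.normal(0.8, 0.05, (20, 20))
        B = rng.normal(0.3, 0.05, (20, 20))
        res = td.cpg_differential_test(A, B)
        assert (res["p"] < 1e-4).all()

    def test_identical_values_maximal_p(self):
        A = np.full((1, 5), 0.4)
        B = np.full((1, 5), 0.4)
        with pytest.warns(UserWarning):
            res = td.cpg_differential_test(A, B)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            td.cpg_differential_test(np.ones((3, 1)), np.ones((3, 1)))


class TestCombineP:
    def test_single_p_passthrough(self):
        assert td.combine_fragment_p([0.3]) == 0.3

    def test_all_ones_stay_one(self):
        assert td.combine_fragment_p([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_fisher_chi_square_tail(self):
        # independent p = (0.05, 0.05): X = -4 ln 0.05 = 11.98, df 4
        p = td.combine_fragment_p([0.05, 0.05], method="fisher")
        expected = stats.chi2.sf(-4 * np.log(0.05), 4)
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(0.0175, abs=5e-4)

    def test_zero_p_clipped(self):
        with pytest.warns(UserWarning):
            p = td.combine_fragment_p([0.0, 0.5], method="fisher")
        assert 0 < p < 1

    def test_brown_controls_correlated_type_i(self):
        # strongly correlated CpGs within fragments: plain Fisher inflates,
        # the Brown correction keeps the type-I rate near nominal
        rng = np.random.default_rng(5)
        n_frag, n_cpg, n = 800, 3, 40
        base = rng.normal(0.5, 0.1, (n_frag, n))
        ratios = np.repeat(base, n_cpg, axis=0) + rng.normal(0, 0.03, (n_frag * n_cpg, n))
        A, B = ratios[:, :20], ratios[:, 20:]
        res = td.cpg_differential_test(A, B)
        tab = pd.DataFrame({"fragment": np.repeat(np.arange(n_frag), n_cpg), "p": res["p"]})
        brown = td.fragment_level_p(tab, A, B, method="brown")
        fisher = td.fragment_level_p(tab, A, B, method="fisher")
        assert (brown["p_combined"] < 0.05).mean() <= 0.07
        assert (fisher["p_combined"] < 0.05).mean() > (brown["p_combined"] < 0.05).mean()


class TestRankDmrs:
    def _stats(self):
        return pd.DataFrame({
            "fragment": ["a", "b", "c", "d"],
            "p_combined": [1e-6, 0.2, 1e-8, 0.01],
            "mean_a": [0.1, 0.1, 0.9, 0.5],
            "mean_b": [0.7, 0.7, 0.2, 0.45],
            "coverage_a": [10, 10, 10, 1],
            "coverage_b": [10, 10, 10, 10],
        })

    def test_p_threshold_excludes(self):
        res = td.rank_dmrs(self._stats())
        assert not res.table.set_index("fragment").loc["b", "selected"]

    def test_low_coverage_excludes(self):
        res = td.rank_dmrs(self._stats())
        assert not res.table.set_index("fragment").loc["d", "selected"]

    def test_planted_dmr_top_rank(self):
        res = td.rank_dmrs(self._stats())
        t = res.table.set_index("fragment")
        assert t.loc["c", "selected"] and t.loc["c", "combined_rank"] == 1

    def test_direction_swap_flips_direction_not_ranks(self):
        df = self._stats()
        res1 = td.rank_dmrs(df)
        swapped = df.rename(columns={"mean_a": "mean_b", "mean_b": "mean_a",
                                     "coverage_a": "coverage_b", "coverage_b": "coverage_a"})
        res2 = td.rank_dmrs(swapped)
        t1 = res1.table.set_index("fragment")
        t2 = res2.table.set_index("fragment")
        assert (t1["direction"] != t2["direction"]).all()
        assert (t1["combined_rank"] == t2["combined_rank"]).all()

    def test_top_k_cap(self):
        rng = np.random.default_rng(6)
        n = 1500
        df = pd.DataFrame({
            "fragment": [f"f{i}" for i in range(n)],
            "p_combined": rng.uniform(0, 0.04, n),
            "mean_a": 0.2, "mean_b": 0.8,
            "coverage_a": 10, "coverage_b": 10,
        })
        res = td.rank_dmrs(df, top_k=500)
        assert res.table["selected"].sum() == 500


@pytest.fixture(scope="module")
def pwms():
    strong = np.full((8, 4), 0.01)
    for i, b in enumerate("ACGTACGT"):
        strong[i, "ACGT".index(b)] = 0.97
    return [td.Pwm("planted", strong), td.Pwm("uniform_null", np.full((8, 4), 0.25))]


class TestMotifEnrichment:
    def test_planted_enrichment(self, pwms):
        rng = np.random.default_rng(7)
        def seq(with_motif):
            s = "".join(rng.choice(list("ACGT"), size=60))
            return ("ACGTACGT" + s) if with_motif else s
        fg = [seq(rng.random() < 0.8) for _ in range(300)]
        bg = [seq(rng.random() < 0.05) for _ in range(300)]
        enr = td.motif_enrichment({"hypo_in_heart": fg, "hypo_in_liver": bg}, pwms)
        t = enr.table.set_index(["motif", "direction"])
        assert t.loc[("planted", "hypo_in_heart"), "significant"]
        assert t.loc[("planted", "hypo_in_heart"), "q"] < 1e-6
        assert not t.loc[("uniform_null", "hypo_in_heart"), "significant"]

    def test_identical_sets_not_significant(self, pwms):
        rng = np.random.default_rng(8)
        seqs = ["ACGTACGT" + "".join(rng.choice(list("ACGT"), size=40)) for _ in range(100)]
        enr = td.motif_enrichment({"d1": seqs, "d2": list(seqs)}, pwms[:1])
        assert not enr.table["significant"].any()

    def test_bh_never_below_raw(self, pwms):
        rng = np.random.default_rng(9)
        fg = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(50)]
        bg = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(50)]
        enr = td.motif_enrichment({"d1": fg, "d2": bg}, pwms)
        assert (enr.table["q"] >= enr.table["p"] - 1e-15).all()

    def test_hit_calling_matches_bruteforce(self, pwms):
        # independent oracle: empirical threshold from scoring every window of
        # a long null sequence, then direct max-window comparison
        rng = np.random.default_rng(10)
        pwm = pwms[0]
        background = np.full(4, 0.25)
        lo = td._log_odds(pwm, background)
        thr = td.pwm_score_threshold(lo, background, hit_p=1e-3)
        # brute force null distribution over all 4^8 windows is large; sample
        null_scores = []
        for _ in range(20000):
            w = rng.integers(0, 4, size=8)
            null_scores.append(sum(lo[j, w[j]] for j in range(8)))
        emp = float(np.mean(np.asarray(null_scores) >= thr))
        assert emp <= 2e-3  # threshold respects the null exceedance bound
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(100)]
        for s in seqs:
            brute = False
            for strand in (s, s.translate(str.maketrans("ACGT", "TGCA"))[::-1]):
                for i in range(len(strand) - 7):
                    sc = sum(lo[j, "ACGT".index(strand[i + j])] for j in range(8))
                    if sc >= thr:
                        brute = True
            assert brute == td._scan_hit(s, lo, thr)

    def test_meme_parser(self, tmp_path):
        text = """MEME version 4

ALPHABET= ACGT

MOTIF TF1
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
0.9 0.03 0.03 0.04
0.1 0.8 0.05 0.05
0.25 0.25 0.25 0.25

MOTIF TF2
letter-probability matrix: alength= 4 w= 2
0.5 0.5 0.0 0.0
0.0 0.0 0.5 0.5
"""
        p = tmp_path / "motifs.meme"
        p.write_text(text)
        pwms = td.read_meme(str(p))
        assert [m.name for m in pwms] == ["TF1", "TF2"]
        assert pwms[0].length == 3 and pwms[1].length == 2
        assert np.allclose(pwms[0].matrix.sum(axis=1), 1.0)


class TestTfActivity:
    def _inputs(self):
        enr = td.MotifEnrichment(pd.DataFrame({
            "motif": ["TF_u", "TF_m", "TF_off"],
            "direction": ["hypo_in_liver", "hypo_in_heart", "hypo_in_liver"],
            "odds_ratio": [3.0, 3.0, 3.0],
            "p": [1e-5, 1e-5, 1e-5],
            "q": [1e-4, 1e-4, 1e-4],
            "significant": [True, True, True],
        }))
        pref = pd.DataFrame({"tf": ["TF_u", "TF_m", "TF_off"],
                             "preference": ["unmethylated", "methylated", "unmethylated"]})
        expr = pd.DataFrame({"tf": ["TF_u", "TF_m", "TF_off"],
                             "heart": [2.0, 5.0, 0.5], "liver": [3.0, 0.2, 0.9]})
        targets = pd.DataFrame({"tf": ["TF_u", "TF_off"], "target": ["GENE1", "GENE2"],
                                "sign": ["activation", "repression"]})
        return enr, pref, expr, targets

    def test_unmethylated_preference_rule(self):
        enr, pref, expr, targets = self._inputs()
        calls, edges = td.tf_activity_and_network(enr, pref, expr, targets)
        c = calls.set_index("tf")
        assert c.loc["TF_u", "activity"] == "liver"

    def test_methylated_preference_rule(self):
        # prefers methylated + enriched among liver-hypermethylated
        # (= heart-hypomethylated) fragments -> active in liver
        enr, pref, expr, targets = self._inputs()
        calls, _ = td.tf_activity_and_network(enr, pref, expr, targets)
        assert calls.set_index("tf").loc["TF_m", "activity"] == "liver"

    def test_low_expression_excluded(self):
        enr, pref, expr, targets = self._inputs()
        calls, edges = td.tf_activity_and_network(enr, pref, expr, targets)
        c = calls.set_index("tf")
        assert c.loc["TF_off", "activity"] == "none"
        assert "GENE2" not in set(edges["target"])
        assert "GENE1" in set(edges["target"])
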