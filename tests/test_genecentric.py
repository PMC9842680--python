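"""Cross-mapping, gene profiles, promoter matrix, embedding, held-out AUC."""

import numpy as np
import pandas as pd
import pytest

from methcode import genecentric as gn


def _random_genome(rng, n=20_000):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCrossmap:
    def test_exact_fragment_maps_with_zero_mismatches(self):
        rng = np.random.default_rng(0)
        g = _random_genome(rng)
        cm = gn.crossmap_fragments({"f": g[3000:3060]}, {"g1": {"c1": g}})
        m = cm.mappings["f"]
        assert (m.chrom, m.start, m.end, m.n_mismatches) == ("c1", 3000, 3060, 0)

    def test_reverse_strand_mapping(self):
        rng = np.random.default_rng(1)
        g = _random_genome(rng)
        frag = gn._revcomp(g[5000:5050])
        cm = gn.crossmap_fragments({"f": frag}, {"g1": {"c1": g}})
        assert cm.mappings["f"].strand == "-"
        assert cm.mappings["f"].start == 5000

    def test_mismatch_rate_bound(self):
        rng = np.random.default_rng(2)
        g = _random_genome(rng)
        frag = list(g[4000:4050])
        # 11 substitutions in 50 bp: rate 0.22 > 0.2 -> rejected
        positions = rng.choice(np.arange(12, 50), size=11, replace=False)
        for p in positions:
            frag[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[p]]
        cm = gn.crossmap_fragments({"f": "".join(frag)}, {"g1": {"c1": g}})
        assert "f" not in cm.mappings

    def test_best_genome_dominance(self):
        rng = np.random.default_rng(3)
        g1 = _random_genome(rng)
        g2 = _random_genome(rng)
        frags = {f"f{i}": g1[1000 * (i + 1):1000 * (i + 1) + 50] for i in range(5)}
        cm = gn.crossmap_fragments(frags, {"right": {"c": g1}, "wrong": {"c": g2}})
        assert cm.best_genome == "right"
        assert cm.mapping_rate["right"] == 1.0

    def test_ambiguous_best_hit_unmapped(self):
        rng = np.random.default_rng(4)
        core = _random_genome(rng, 2000)
        dup = core[500:550]
        genome = core + "TTTT" + core  # two identical copies
        cm = gn.crossmap_fragments({"f": dup}, {"g": {"c": genome}})
        assert "f" not in cm.mappings


class TestGeneProfile:
    def _uniform_calls(self, level=0.8):
        pos = np.arange(1000, 19000, 20)
        return pd.DataFrame({"chrom": "c1", "pos": pos, "ratio": level})

    def _genes(self):
        return pd.DataFrame({"gene": ["gp", "gm"], "chrom": "c1",
                             "start": [8000, 14000], "end": [9000, 15000],
                             "strand": ["+", "-"]})

    def test_constant_field(self):
        gp = gn.gene_profile(self._uniform_calls(0.8), self._genes())
        assert np.allclose(gp.meta.dropna(), 0.8)
        assert gp.dip_statistic == pytest.approx(0.0, abs=1e-12)

    def test_planted_dip_in_promoter(self):
        calls = self._uniform_calls(0.8)
        genes = self._genes()
        for _, g in genes.iterrows():
            if g["strand"] == "+":
                mask = (calls["pos"] >= g["start"] - 1000) & (calls["pos"] < g["start"] + 500)
            else:
                mask = (calls["pos"] >= g["end"] - 500) & (calls["pos"] < g["end"] + 1000)
            calls.loc[mask, "ratio"] = 0.1
        gp = gn.gene_profile(calls, genes)
        n_flank = 50
        prom_idx = set(range(n_flank - 10, n_flank + 3))
        assert int(np.nanargmin(gp.meta.to_numpy())) in prom_idx
        assert gp.dip_statistic > 0.3

    def test_minus_strand_equals_revcomp_construction(self):
        # an asymmetric field around a minus-strand gene must equal the
        # plus-strand profile of the mirrored field
        pos = np.arange(1000, 19000, 10)
        grad = (pos - 1000) / 18000
        calls = pd.DataFrame({"chrom": "c1", "pos": pos, "ratio": grad})
        s, e = 9000, 10000
        minus_gene = pd.DataFrame({"gene": ["g"], "chrom": "c1", "start": [s],
                                   "end": [e], "strand": ["-"]})
        gp_minus = gn.gene_profile(calls, minus_gene)
        A = 19990  # reflection p -> A - p maps the position grid onto itself
        mirrored = calls.copy()
        mirrored["pos"] = A - mirrored["pos"]
        plus_gene = pd.DataFrame({"gene": ["g"], "chrom": "c1", "start": [A - e + 1],
                                  "end": [A - s + 1], "strand": ["+"]})
        gp_plus = gn.gene_profile(mirrored, plus_gene)
        a = gp_minus.meta.to_numpy()
        b = gp_plus.meta.to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        assert ok.sum() > 100
        assert np.allclose(a[ok], b[ok], atol=0.02)

    def test_gene_order_invariance(self):
        calls = self._uniform_calls()
        genes = self._genes()
        a = gn.gene_profile(calls, genes).meta
        b = gn.gene_profile(calls, genes.iloc[::-1]).meta
        assert np.allclose(a.dropna(), b.dropna())


class TestPromoterMatrix:
    def test_constant_promoter_value(self):
        calls = pd.DataFrame({"chrom": "c1", "pos": np.arange(0, 10000, 25), "ratio": 0.3})
        genes = pd.DataFrame({"gene": ["g1"], "chrom": "c1", "start": [6000],
                              "end": [7000], "strand": ["+"]})
        prom = gn.promoter_methylation(calls, genes)
        assert prom["g1"] == pytest.approx(0.3)

    def test_join_semantics_and_averaging(self):
        prom = pd.Series({"g1": 0.2, "g2": 0.6, "g3": 0.9})
        g2n = pd.DataFrame({"gene": ["g1", "g2"], "ncbi": ["n1", "n2"]})
        n2h = pd.DataFrame({"ncbi": ["n1", "n2"], "human": ["H1", "H1"]})
        M = gn.promoter_matrix({"s1": prom}, g2n, n2h)
        assert list(M.columns) == ["H1"]
        assert M.loc["s1", "H1"] == pytest.approx(0.4)  # mean of 0.2, 0.6
        # g3 has no ortholog: no column

    def test_duplicate_rows_warn(self):
        prom = pd.Series({"g1": 0.2})
        g2n = pd.DataFrame({"gene": ["g1", "g1"], "ncbi": ["n1", "n1"]})
        n2h = pd.DataFrame({"ncbi": ["n1"], "human": ["H1"]})
        with pytest.warns(UserWarning):
            M = gn.promoter_matrix({"s1": prom}, g2n, n2h)
        assert M.loc["s1", "H1"] == pytest.approx(0.2)


class TestScramble:
    def test_mask_preserved_values_permuted(self):
        rng = np.random.default_rng(5)
        M = pd.DataFrame(rng.normal(size=(20, 10)))
        M[M > 1] = np.nan
        S = gn.scramble_matrix(M, seed=1)
        assert (S.isna() == M.isna()).all().all()
        assert sorted(S.stack()) == pytest.approx(sorted(M.stack()))


class TestEmbedCluster:
    def test_planted_groups_recovered_and_control_collapses(self):
        rng = np.random.default_rng(6)
        ng = 60
        base = {"a": rng.normal(0.3, 0.05, ng), "b": rng.normal(0.7, 0.05, ng)}
        rows, idx = [], []
        for grp in "ab":
            for i in range(25):
                rows.append(base[grp] + rng.normal(0, 0.05, ng))
                idx.append(f"{grp}{i}")
        X = np.array(rows)
        X[rng.random(X.shape) < 0.1] = np.nan
        mat = pd.DataFrame(X, index=idx, columns=[f"G{j}" for j in range(ng)])
        res = gn.embed_and_cluster(mat, mode="samples", min_col_cover=10,
                                   min_row_cover=10, resolution=0.5, seed=7)
        assert res.clusters.nunique() >= 2
        truth = pd.Series([i[0] for i in res.clusters.index], index=res.clusters.index)
        purity = res.clusters.groupby(truth).agg(lambda s: s.value_counts().iloc[0] / len(s))
        assert (purity >= 0.9).all()
        assert res.scrambled_clusters.nunique() <= res.clusters.nunique()


class TestHeldOutClassification:
    def _matrix(self, signal=0.4, seed=8):
        rng = np.random.default_rng(seed)
        ns, ng = 80, 60
        species = pd.Series([f"sp{i // 2}" for i in range(ns)],
                            index=[f"s{i}" for i in range(ns)])
        labels = pd.Series(["heart", "liver"] * (ns // 2), index=species.index)
        X = rng.normal(0.5, 0.1, (ns, ng))
        X[(labels == "heart").to_numpy(), :20] += signal
        X[rng.random((ns, ng)) < 0.1] = np.nan
        mat = pd.DataFrame(X, index=species.index, columns=[f"G{j}" for j in range(ng)])
        return mat, labels, species

    def test_planted_signal_beats_scrambled_control(self):
        mat, labels, species = self._matrix()
        res = gn.classify_held_out(mat, labels, species, n_train_species=25,
                                   n_reps=8, n_trees=60, seed=9)
        assert res.mean_auc >= 0.85
        assert 0.3 <= res.scrambled_mean_auc <= 0.7
        assert res.mean_auc - res.scrambled_mean_auc >= 0.2
        # predictive genes carry the importance mass
        top = res.importances.sort_values(ascending=False).head(20).index
        assert sum(1 for g in top if int(g[1:]) < 20) >= 12

    def test_labels_independent_of_values_near_half(self):
        mat, labels, species = self._matrix(signal=0.0, seed=10)
        res = gn.classify_held_out(mat, labels, species, n_train_species=25,
                                   n_reps=6, n_trees=40, seed=11)
        assert 0.35 <= res.mean_auc <= 0.65

    def test_seed_determinism(self):
        mat, labels, species = self._matrix()
        r1 = gn.classify_held_out(mat, labels, species, 25, n_reps=3, n_trees=20, seed=12)
        r2 = gn.classify_held_out(mat, labels, species, 25, n_reps=3, n_trees=20, seed=12)
        assert r1.per_rep_auc == r2.per_rep_auc
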