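import numpy as np
import pandas as pd
import pytest

from pegquant.screen import (NoNonTargeting, TooFewNT, TooFewPseudogenes,
                             analyze_screen, apply_count_floor, empirical_fdr,
                             export_for_crisphiermix, gene_scores,
                             make_pseudogenes, pseudogene_scores,
                             sgrna_phenotypes)
from pegquant.simulate import ScreenSimConfig, sim_screen


def _table(rows):
    return pd.DataFrame(rows, columns=["sgrna_id", "gene", "tss",
                                       "non_targeting", "count_pos", "count_neg"])


@pytest.fixture
def small_table():
    rows = [
        ("g1_sg0", "G1", "P1", False, 200, 100),
        ("g1_sg1", "G1", "P1", False, 100, 100),
        ("nt_0", "", "", True, 100, 100),
        ("nt_1", "", "", True, 110, 110),
        ("nt_2", "", "", True, 90, 90),
    ]
    return _table(rows)


class TestCountFloor:
    def test_low_counts_raised_to_floor(self):
        t = _table([("a", "G", "P", False, 3, 120), ("nt", "", "", True, 60, 70)])
        out = apply_count_floor(t, 50)
        assert out.loc[0, "count_pos"] == 50 and out.loc[0, "count_neg"] == 120

    def test_boundary_counts_unchanged(self):
        t = _table([("a", "G", "P", False, 50, 50)])
        out = apply_count_floor(t, 50)
        assert (out[["count_pos", "count_neg"]].to_numpy() == 50).all()

    def test_floor_zero_is_identity(self, small_table):
        out = apply_count_floor(small_table, 0)
        pd.testing.assert_frame_equal(out, small_table)

    def test_filter_mode_drops_rows(self):
        t = _table([("a", "G", "P", False, 3, 120), ("nt", "", "", True, 60, 70)])
        out = apply_count_floor(t, 50, mode="filter")
        assert list(out["sgrna_id"]) == ["nt"]


class TestSgrnaPhenotypes:
    def test_twofold_enrichment_is_one(self, small_table):
        # equal totals are not required: normalization handles them; with NT
        # sgRNAs at ratio 0, a 2x enriched sgRNA has phenotype log2(2) = 1
        phen = sgrna_phenotypes(small_table)
        p = phen.set_index("sgrna_id")["phenotype"]
        assert p["g1_sg0"] == pytest.approx(1.0)

    def test_nt_sgrna_at_median_is_zero(self, small_table):
        phen = sgrna_phenotypes(small_table)
        p = phen.set_index("sgrna_id")["phenotype"]
        assert p["nt_0"] == 0.0

    def test_nt_median_exactly_zero(self, small_table):
        phen = sgrna_phenotypes(small_table)
        nt = phen.loc[phen["non_targeting"], "phenotype"]
        assert np.median(nt) == 0.0

    def test_total_count_normalization_invariance(self, small_table):
        scaled = small_table.copy()
        scaled["count_pos"] = scaled["count_pos"] * 10
        p1 = sgrna_phenotypes(small_table)["phenotype"].to_numpy()
        p2 = sgrna_phenotypes(scaled)["phenotype"].to_numpy()
        assert np.allclose(p1, p2)

    def test_missing_nt_raises(self):
        t = _table([("a", "G", "P", False, 10, 10)])
        with pytest.raises(NoNonTargeting):
            sgrna_phenotypes(apply_count_floor(t))


def _phen_frame(values, gene="G1", tss="P1"):
    rows = [(f"sg{i}", gene, tss, False, v) for i, v in enumerate(values)]
    rows.append(("nt0", "", "", True, 0.0))
    return pd.DataFrame(rows, columns=["sgrna_id", "gene", "tss",
                                       "non_targeting", "phenotype"])


class TestGeneScores:
    def test_top3_by_absolute_value_signed_mean(self):
        out = gene_scores(_phen_frame([2.0, -1.5, 1.0, 0.2, -0.1]))
        assert out.loc[0, "score"] == pytest.approx(0.5)
        assert out.loc[0, "n_sgrnas_used"] == 3

    def test_constant_phenotypes(self):
        out = gene_scores(_phen_frame([1.0] * 5))
        assert out.loc[0, "score"] == pytest.approx(1.0)

    def test_fewer_than_k_uses_all(self):
        out = gene_scores(_phen_frame([3.0, 1.0]))
        assert out.loc[0, "score"] == pytest.approx(2.0)
        assert out.loc[0, "n_sgrnas_used"] == 2

    def test_score_bounded_by_strongest_member(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = rng.normal(0, 2, size=int(rng.integers(1, 8)))
            out = gene_scores(_phen_frame(list(vals)))
            assert abs(out.loc[0, "score"]) <= np.abs(vals).max() + 1e-12

    def test_row_order_permutation_invariance(self):
        f = _phen_frame([2.0, -1.5, 1.0, 0.2, -0.1])
        shuffled = f.sample(frac=1.0, random_state=1).reset_index(drop=True)
        s1 = gene_scores(f).loc[0, "score"]
        s2 = gene_scores(shuffled).loc[0, "score"]
        assert s1 == pytest.approx(s2)

    def test_multi_tss_gene_collapse_takes_largest_magnitude(self):
        rows = ([(f"a{i}", "G1", "P1", False, v) for i, v in enumerate([0.5, 0.4, 0.3])]
                + [(f"b{i}", "G1", "P2", False, v) for i, v in enumerate([-2.0, -1.0, -0.5])])
        rows.append(("nt0", "", "", True, 0.0))
        f = pd.DataFrame(rows, columns=["sgrna_id", "gene", "tss",
                                        "non_targeting", "phenotype"])
        out = gene_scores(f)
        assert set(out["tss"]) == {"P1", "P2"}
        assert np.allclose(out["gene_score"], -3.5 / 3)


class TestPseudogenes:
    def test_auto_mode_cuts_disjoint_groups(self):
        ids = [f"nt{i}" for i in range(1000)]
        ps = make_pseudogenes(ids, group_size=5, seed=3)
        assert len(ps) == 200
        members = [m for g in ps.groups for m in g]
        assert len(members) == len(set(members)) == 1000

    def test_same_seed_reproduces_grouping(self):
        ids = [f"nt{i}" for i in range(57)]
        a = make_pseudogenes(ids, seed=9)
        b = make_pseudogenes(ids, seed=9)
        assert a.groups == b.groups

    def test_too_few_nt_raises(self):
        with pytest.raises(TooFewNT):
            make_pseudogenes(["a", "b", "c", "d"], group_size=5)

    def test_with_replacement_keeps_groups_internally_unique(self):
        ids = [f"nt{i}" for i in range(10)]
        ps = make_pseudogenes(ids, group_size=5, n_pseudogenes=30, seed=1,
                              with_replacement=True)
        assert len(ps) == 30
        assert all(len(set(g)) == 5 for g in ps.groups)


class TestEmpiricalFdr:
    def _genes(self, scores):
        return pd.DataFrame({"gene": [f"g{i}" for i in range(len(scores))],
                             "tss": "P1", "score": scores,
                             "n_sgrnas_used": 3})

    def test_plus_one_rule_for_extreme_gene(self):
        pseudo = np.linspace(-1, 1, 200)
        out = empirical_fdr(self._genes([5.0]), pseudo)
        assert out.loc[0, "empirical_p"] == pytest.approx(1 / 201)

    def test_gene_at_pseudogene_median_magnitude(self):
        pseudo = np.concatenate([np.linspace(0.01, 1, 100),
                                 -np.linspace(0.01, 1, 100)])
        out = empirical_fdr(self._genes([0.5]), pseudo)
        assert out.loc[0, "empirical_p"] == pytest.approx(0.5, abs=0.02)

    def test_too_few_pseudogenes_raises(self):
        with pytest.raises(TooFewPseudogenes):
            empirical_fdr(self._genes([1.0]), np.zeros(10))

    def test_fdr_preserves_p_value_order(self):
        rng = np.random.default_rng(4)
        pseudo = rng.normal(0, 1, 300)
        out = empirical_fdr(self._genes(list(rng.normal(0, 1.5, 40))), pseudo)
        srt = out.sort_values("empirical_p")
        assert (np.diff(srt["fdr"]) >= -1e-12).all()
        assert (out["fdr"] >= out["empirical_p"] - 1e-12).all()


class TestExport:
    def test_round_trip_preserves_phenotypes(self, tmp_path, small_table):
        phen = sgrna_phenotypes(apply_count_floor(small_table))
        path = tmp_path / "mix.tsv"
        export_for_crisphiermix(phen, path)
        back = pd.read_csv(path, sep="\t", float_precision="round_trip")
        assert len(back) == len(phen)
        assert np.array_equal(back["phenotype"].to_numpy(),
                              phen["phenotype"].to_numpy())
        assert (back.loc[back["non_targeting"] == 1, "gene"]
                == "negative_control").all()

    def test_empty_table_writes_header_only(self, tmp_path):
        empty = pd.DataFrame(columns=["sgrna_id", "gene", "tss",
                                      "non_targeting", "phenotype"])
        path = tmp_path / "mix.tsv"
        export_for_crisphiermix(empty, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1


class TestSyntheticScreens:
    def test_null_screen_pseudogenes_match_unplanted_genes(self):
        """Pseudogene scores and true-null gene scores are exchangeable."""
        from scipy.stats import ks_2samp
        ok = 0
        for seed in range(5):
            cfg = ScreenSimConfig(n_genes=400, n_nt=500, depth=500,
                                  dispersion=30.0, seed=seed)
            table, _ = sim_screen(cfg)
            phen, genes, pscores = analyze_screen(table, seed=seed)
            if ks_2samp(genes["score"], pscores).pvalue > 0.01:
                ok += 1
        assert ok >= 4

    def test_planted_gene_dominates_null(self):
        cfg = ScreenSimConfig(n_genes=300, n_nt=400, depth=500,
                              dispersion=30.0, seed=11,
                              planted={"gene00007": 2.0}, active_per_gene=5)
        table, truth = sim_screen(cfg)
        # BH at 0.01 over 300 genes needs empirical p below ~3e-5, hence a
        # large resampled pseudogene null
        phen, genes, _ = analyze_screen(table, seed=11, n_pseudogenes=50_000,
                                        with_replacement=True)
        top = genes.iloc[genes["score"].abs().to_numpy().argmax()]
        assert top["gene"] == "gene00007"
        assert top["hit"]
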