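import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pclstx.de import ExpressionMatrix, log_cpm
from pclstx.design import MEDIUM_ORDER
from pclstx.simulate import SimulationConfig, simulate_study
from pclstx.xspecies import (
    GROUP_ORDER,
    condition_correlations,
    correlation_vs_identity,
    donor_center,
    group_medians,
    pair_correlations,
    resolve_orthologs,
    top_pairs,
    _spearman,
)


def _expr(values: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(values, 0.5, values.sum())


def _balanced_data(n_subjects=3, n_genes=20, donor_shift=0.0, seed=0):
    from pclstx.design import enumerate_design

    rng = np.random.default_rng(seed)
    design = enumerate_design("human", [f"S{i}" for i in range(n_subjects)])
    meta = pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "species": d.species,
                "subject_id": d.subject_id,
                "medium": d.medium,
                "timepoint_h": d.timepoint_h,
                "status": d.status,
            }
            for d in design
        ]
    )
    base = rng.normal(5, 1, n_genes)
    shifts = rng.normal(0, donor_shift, (n_genes, n_subjects)) if donor_shift else None
    cols = {}
    for j, d in enumerate(design):
        x = base + rng.normal(0, 0.1, n_genes)
        if shifts is not None:
            x = x + shifts[:, int(d.subject_id[1:])]
        cols[d.sample_id] = x
    values = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    return _expr(values), meta


class TestDonorCenter:
    def test_no_donor_effect_is_identity(self):
        expr, meta = _balanced_data(donor_shift=0.0)
        out = donor_center(expr, meta)
        # an additive model with zero planted subject effects removes ~nothing
        assert np.abs(out.values - expr.values).to_numpy().max() < 0.2

    def test_removes_planted_donor_shifts(self):
        expr, meta = _balanced_data(donor_shift=2.0, seed=1)
        out = donor_center(expr, meta)

        def donor_var(values):
            subj = meta.set_index("sample_id")["subject_id"]
            means = values.T.groupby(subj).mean()
            return float(means.var(axis=0).mean())

        assert donor_var(out.values) < 0.01 * donor_var(expr.values)

    def test_group_means_preserved_on_balanced_data(self):
        expr, meta = _balanced_data(donor_shift=1.5, seed=2)
        out = donor_center(expr, meta)
        key = meta.set_index("sample_id")
        grp = key["medium"] + "_" + key["timepoint_h"].astype(str) + "h"
        before = expr.values.T.groupby(grp).mean()
        after = out.values.T.groupby(grp).mean()
        assert np.abs(before - after).to_numpy().max() < 1e-8

    def test_fully_excluded_subject_rejected(self):
        expr, meta = _balanced_data()
        meta = meta.copy()
        meta.loc[meta["subject_id"] == "S1", "status"] = "pca_outlier"
        with pytest.raises(ValueError, match="excluded"):
            donor_center(expr, meta)


class TestGroupMedians:
    def test_single_sample_groups_pass_through(self):
        expr, meta = _balanced_data(n_subjects=1)
        gm = group_medians(expr, meta)
        assert list(gm.columns) == list(GROUP_ORDER)
        sid = meta.set_index("sample_id")
        for g in GROUP_ORDER:
            med, tp = g.rsplit("_", 1)
            s = sid[(sid["medium"] == med) & (sid["timepoint_h"] == int(tp[:-1]))].index[0]
            assert np.allclose(gm[g], expr.values[s])

    def test_median_definition(self):
        values = pd.DataFrame(
            {"a": [1.0], "b": [5.0], "c": [100.0]}, index=["g"]
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "species": "human",
                "subject_id": ["S0", "S1", "S2"],
                "medium": "CTR",
                "timepoint_h": 24,
                "status": "included",
            }
        )
        with pytest.warns(UserWarning, match="empty condition group"):
            gm = group_medians(_expr(values), meta)
        assert gm.loc["g", "CTR_24h"] == 5.0

    def test_empty_group_flagged_not_imputed(self):
        expr, meta = _balanced_data(n_subjects=2)
        meta = meta.copy()
        meta.loc[meta["medium"] == "GFIPO", "status"] = "not_prepared"
        with pytest.warns(UserWarning, match="empty condition group"):
            gm = group_medians(expr, meta)
        assert gm["GFIPO_24h"].isna().all() and gm["GFIPO_48h"].isna().all()

    def test_study_exclusions_keep_all_16_groups(self):
        """After the staged human exclusions every condition group survives."""
        from pclstx.design import (
            HUMAN_DONORS,
            PCA_OUTLIERS,
            PRESEQ_FAILURES,
            apply_exclusions,
            enumerate_design,
        )

        design = apply_exclusions(
            apply_exclusions(enumerate_design("human", list(HUMAN_DONORS)), PRESEQ_FAILURES),
            PCA_OUTLIERS,
        )
        included = [d for d in design if d.status == "included"]
        sizes = {}
        for d in included:
            sizes.setdefault((d.medium, d.timepoint_h), 0)
            sizes[(d.medium, d.timepoint_h)] += 1
        assert len(sizes) == 16
        assert min(sizes.values()) == 4


class TestPairCorrelations:
    def _gm(self, arr, genes):
        return pd.DataFrame(arr, index=genes, columns=list(GROUP_ORDER))

    def test_perfect_and_anti_correlation(self):
        x = np.arange(16.0)
        gm_h = self._gm([x, x], ["h1", "h2"])
        gm_m = self._gm([2 * x + 1, -x], ["m1", "m2"])
        pairs = pd.DataFrame({"gene_h": ["h1", "h2"], "gene_m": ["m1", "m2"]})
        pc = pair_correlations(gm_h, gm_m, pairs)
        assert pc["pearson_r"].to_numpy() == pytest.approx([1.0, -1.0])
        assert pc["spearman_rho"].to_numpy() == pytest.approx([1.0, -1.0])

    def test_linear_relation_gives_unit_correlations(self):
        gm_h = self._gm([np.resize([1.0, 2, 3, 4], 16)], ["h"])
        gm_m = self._gm([np.resize([2.0, 4, 6, 8], 16)], ["m"])
        pc = pair_correlations(gm_h, gm_m, pd.DataFrame({"gene_h": ["h"], "gene_m": ["m"]}))
        assert pc.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert pc.loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        gm_h = self._gm([np.ones(16)], ["h"])
        gm_m = self._gm([np.arange(16.0)], ["m"])
        pc = pair_correlations(gm_h, gm_m, pd.DataFrame({"gene_h": ["h"], "gene_m": ["m"]}))
        assert np.isnan(pc.loc[0, "pearson_r"])
        assert pc.loc[0, "reason"] == "zero_variance"

    def test_too_few_groups_flagged(self):
        arr = np.full(16, np.nan)
        arr[:2] = [1.0, 2.0]
        gm_h = self._gm([arr], ["h"])
        gm_m = self._gm([np.arange(16.0)], ["m"])
        pc = pair_correlations(gm_h, gm_m, pd.DataFrame({"gene_h": ["h"], "gene_m": ["m"]}))
        assert pc.loc[0, "reason"] == "too_few_groups"

    def test_species_symmetry(self):
        rng = np.random.default_rng(5)
        gm_h = self._gm(rng.normal(size=(10, 16)), [f"h{i}" for i in range(10)])
        gm_m = self._gm(rng.normal(size=(10, 16)), [f"m{i}" for i in range(10)])
        pairs = pd.DataFrame(
            {"gene_h": gm_h.index, "gene_m": gm_m.index}
        )
        ab = pair_correlations(gm_h, gm_m, pairs)
        ba = pair_correlations(
            gm_m, gm_h, pairs.rename(columns={"gene_h": "gene_m", "gene_m": "gene_h"})
        )
        assert np.allclose(ab["pearson_r"], ba["pearson_r"])
        assert np.allclose(ab["spearman_rho"], ba["spearman_rho"])

    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=3, max_size=16),
        st.integers(0, 2**31 - 1),
    )
    @settings(deadline=None, max_examples=100)
    def test_spearman_matches_rank_then_pearson_oracle(self, x, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(x)
        y = rng.normal(size=len(x))
        if np.ptp(x) == 0:
            return
        ours = _spearman(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert ours == pytest.approx(oracle, abs=1e-12)
        assert ours == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-9)


class TestResolveOrthologs:
    def test_many_to_many_reduced_by_identity(self):
        pairs = pd.DataFrame(
            {
                "gene_h": ["h1", "h1", "h2"],
                "gene_m": ["m1", "m2", "m1"],
                "pct_identity": [90.0, 80.0, 85.0],
            }
        )
        out = resolve_orthologs(pairs)
        assert out["gene_h"].is_unique and out["gene_m"].is_unique
        assert set(map(tuple, out[["gene_h", "gene_m"]].to_numpy())) == {("h1", "m1")}


class TestConditionCorrelations:
    def test_identical_arms_give_unit_correlation(self):
        expr, meta = _balanced_data(n_subjects=2, n_genes=30, seed=3)
        pairs = pd.DataFrame({"gene_h": expr.gene_ids, "gene_m": expr.gene_ids})
        cc = condition_correlations(expr, expr, meta, meta, pairs)
        assert len(cc) == 16
        assert np.allclose(cc["pearson_r"], 1.0)
        assert np.allclose(cc["spearman_rho"], 1.0)

    def test_independent_arms_centered_at_zero(self):
        rs = []
        for seed in range(6):
            e1, meta = _balanced_data(n_subjects=2, n_genes=60, seed=10 + seed)
            e2, _ = _balanced_data(n_subjects=2, n_genes=60, seed=200 + seed)
            pairs = pd.DataFrame({"gene_h": e1.gene_ids, "gene_m": e2.gene_ids})
            cc = condition_correlations(e1, e2, meta, meta, pairs)
            rs.append(cc["pearson_r"].mean())
        assert abs(np.mean(rs)) < 0.1


class TestCorrelationVsIdentity:
    def test_monotone_construction_gives_rho_one(self):
        pc = pd.DataFrame(
            {
                "gene_h": [f"h{i}" for i in range(12)],
                "gene_m": [f"m{i}" for i in range(12)],
                "pct_identity": np.linspace(60, 99, 12),
                "pearson_r": np.linspace(-0.5, 0.9, 12),
            }
        )
        _, rho, p = correlation_vs_identity(pc)
        assert rho == pytest.approx(1.0)

    def test_constant_identity_undefined(self):
        pc = pd.DataFrame(
            {
                "gene_h": [f"h{i}" for i in range(12)],
                "gene_m": [f"m{i}" for i in range(12)],
                "pct_identity": 80.0,
                "pearson_r": np.linspace(0, 1, 12),
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            _, rho, _ = correlation_vs_identity(pc)
        assert np.isnan(rho)

    def test_too_few_pairs(self):
        pc = pd.DataFrame(
            {"gene_h": ["h"], "gene_m": ["m"], "pct_identity": [80.0], "pearson_r": [0.5]}
        )
        with pytest.raises(ValueError, match="pairs"):
            correlation_vs_identity(pc)


class TestTopPairs:
    def _pc(self):
        return pd.DataFrame(
            {
                "gene_h": [f"h{i}" for i in range(20)],
                "gene_m": [f"m{i}" for i in range(20)],
                "pct_identity": np.r_[np.full(10, 90.0), np.full(10, 80.0)],
                "pearson_r": np.r_[np.full(10, 0.9), np.linspace(0, 0.8, 10)],
            }
        )

    def test_exactly_k_rows(self):
        assert len(top_pairs(self._pc(), k=15)) == 15

    def test_k_zero_empty(self):
        assert len(top_pairs(self._pc(), k=0)) == 0

    def test_k_exceeding_defined_warns_and_returns_all(self):
        pc = self._pc().iloc[:5]
        with pytest.warns(UserWarning, match="exceeds"):
            out = top_pairs(pc, k=15)
        assert len(out) == 5

    def test_tie_break_by_identity_then_gene(self):
        out = top_pairs(self._pc(), k=10)
        # ten tied at r=0.9 share identity 90 -> lexicographic gene_h order
        assert list(out["gene_h"]) == sorted(out["gene_h"])


class TestSharedGenesMoreConcordant:
    def test_shared_class_attains_higher_pair_correlation(self, study, ortholog_pairs):
        centered = {}
        gms = {}
        for sp in ("human", "mouse"):
            expr = log_cpm(study.counts[sp])
            centered[sp] = donor_center(expr, study.metadata[sp])
            gms[sp] = group_medians(centered[sp], study.metadata[sp])
        pc = pair_correlations(gms["human"], gms["mouse"], ortholog_pairs)
        cls = study.truth.genes.set_index("gene_h")["gene_class"]
        pc = pc.set_index("gene_h")
        shared = pc.loc[cls == "shared_nutrient", "pearson_r"].dropna()
        null = pc.loc[cls == "null", "pearson_r"].dropna()
        assert shared.mean() > null.mean() + 0.2
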