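"""DNA-vs-mRNA alignment: the k-NN vote rule, match proportions, pooling,
filter-and-refit and eQTL selection."""

import numpy as np
import pytest

from crossalign.core_io import NA
from crossalign.geno_align import (
    EqtlGenotypeClassifier,
    dna_mrna_similarity,
    fit_knn,
    match_proportion,
)


def _vote_training(n_major, n_minor, k=40):
    """Training set whose k nearest neighbors of the origin split
    n_major (BB) / n_minor (BR), all closer than a far-away backdrop."""
    X = np.concatenate(
        [
            np.linspace(0.1, 1.0, n_major),  # BB cluster near origin
            np.linspace(1.01, 1.5, n_minor),  # BR points, still within the k nearest
            np.linspace(50, 60, 30),  # far backdrop (RR), never among neighbors
        ]
    )[:, None]
    y = np.array([0] * n_major + [1] * n_minor + [2] * 30, dtype=np.int8)
    return fit_knn(X, y, k=k, vote=0.8)


class TestVoteRule:
    def test_unanimous_vote(self):
        clf = _vote_training(40, 0)
        assert clf.predict(np.array([[0.0]]))[0] == 0

    def test_exactly_eighty_percent_is_missing(self):
        clf = _vote_training(32, 8)
        assert clf.predict(np.array([[0.0]]))[0] == NA

    def test_just_above_eighty_percent_calls(self):
        clf = _vote_training(33, 7)
        assert clf.predict(np.array([[0.0]]))[0] == 0

    def test_small_training_uses_proportional_vote(self):
        X = np.arange(10, dtype=float)[:, None]
        y = np.array([0] * 9 + [1], dtype=np.int8)
        with pytest.warns(UserWarning, match="proportional"):
            clf = fit_knn(X, y, k=40, vote=0.8)
        assert clf.k_used_ == 10
        assert clf.predict(np.array([[0.0]]))[0] == 0  # 9/10 > 0.8

    def test_missing_expression_predicts_missing(self):
        clf = _vote_training(40, 0)
        assert clf.predict(np.array([[np.nan]]))[0] == NA

    def test_vote_threshold_validated(self):
        with pytest.raises(ValueError):
            EqtlGenotypeClassifier(k=40, vote=0.4)

    def test_get_set_params(self):
        clf = EqtlGenotypeClassifier()
        assert clf.get_params() == {"k": 40, "vote": 0.8}
        clf.set_params(k=10)
        assert clf.k == 10
        with pytest.raises(ValueError):
            clf.set_params(bogus=1)


class TestClassifierOnClusters:
    def test_separated_clusters_recovered_and_boundary_unassigned(self):
        rng = np.random.default_rng(10)
        centers = np.array([-4.0, 0.5, 4.0])
        g = rng.integers(0, 3, size=200)
        X = centers[g] + 0.3 * rng.normal(size=200)
        clf = fit_knn(X[:, None], g.astype(np.int8), k=40, vote=0.8)
        queries = centers[:, None]
        assert list(clf.predict(queries)) == [0, 1, 2]
        boundary = np.array([[(centers[0] + centers[1]) / 2]])
        assert clf.predict(boundary)[0] == NA

    def test_self_exclusion_changes_own_vote(self):
        """A sample's own training record never votes for itself.

        With the query's own (mislabeled) record among the 40 neighbors the BB
        vote is exactly 32/40 and fails; excluding it pulls in a 41st neighbor
        that is BB, giving 33/40 and a call."""
        X = np.concatenate(
            [[0.0], np.linspace(1, 2, 32), np.linspace(2.5, 3, 7), [3.5], np.full(30, 50.0)]
        )[:, None]
        y = np.array([2] + [0] * 32 + [1] * 7 + [0] + [2] * 30, dtype=np.int8)
        clf = fit_knn(X, y, [f"s{i}" for i in range(len(y))], k=40, vote=0.8)
        with_self = clf.predict(np.array([[0.0]]))[0]
        without_self = clf.predict(np.array([[0.0]]), exclude=np.array([0]))[0]
        assert with_self == NA
        assert without_self == 0


class TestMatchProportion:
    def test_worked_example(self):
        obs = np.array([0, 1, 2, NA], dtype=np.int8)
        inf = np.array([0, 1, 0, 2], dtype=np.int8)
        assert match_proportion(obs, inf) == pytest.approx(2 / 3)

    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 1], dtype=np.int8)
        assert match_proportion(v, v) == 1.0

    def test_no_comparable_positions_is_missing(self):
        obs = np.array([NA, 0], dtype=np.int8)
        inf = np.array([1, NA], dtype=np.int8)
        assert np.isnan(match_proportion(obs, inf))


class TestSimilarityPooling:
    def test_pooled_counts_not_mean_of_proportions(self):
        # tissue A: 3/4 matches; tissue B: 1/2 -> combined 4/6
        obs = np.array([[0, 0, 0, 0, 1, 1]], dtype=np.int8)
        inf_a = np.array([[0, 0, 0, 1]], dtype=np.int8)
        inf_b = np.array([[1, 0]], dtype=np.int8)
        per, comb = dna_mrna_similarity(
            obs,
            ["d0"],
            {"A": (inf_a, ["m0"]), "B": (inf_b, ["m0"])},
            {"A": slice(0, 4), "B": slice(4, 6)},
        )
        assert per["A"].values[0, 0] == pytest.approx(3 / 4)
        assert per["B"].values[0, 0] == pytest.approx(1 / 2)
        assert comb.values[0, 0] == pytest.approx(4 / 6)

    def test_single_tissue_combined_equals_per_tissue(self):
        obs = np.array([[0, 1, 2]], dtype=np.int8)
        inf = np.array([[0, 1, 1]], dtype=np.int8)
        per, comb = dna_mrna_similarity(
            obs, ["d0"], {"A": (inf, ["m0"])}, {"A": slice(0, 3)}
        )
        assert comb.values[0, 0] == per["A"].values[0, 0]

    def test_combined_bounded_by_per_tissue(self, default_pipeline):
        res = default_pipeline.geno_result
        per = [m.to_frame() for m in res.per_tissue.values()]
        comb = res.combined.to_frame()
        aligned = [p.reindex(index=comb.index, columns=comb.columns) for p in per]
        import pandas as pd

        stack = np.stack([a.to_numpy() for a in aligned])
        lo = np.nanmin(stack, axis=0)
        hi = np.nanmax(stack, axis=0)
        vals = comb.to_numpy()
        ok = np.isfinite(vals)
        assert np.all(vals[ok] >= lo[ok] - 1e-12)
        assert np.all(vals[ok] <= hi[ok] + 1e-12)


class TestPipelinePieces:
    def test_eqtl_selection_exact_on_clean_data(self, null_study, null_pipeline):
        """With no mislabels, exactly the planted eQTL clear the LOD>100
        screen; the X-linked and unannotated probes are never eligible."""
        cfg = null_study.config
        units = null_pipeline.geno_result.units
        for tissue in cfg.tissues:
            planted = {e["probe"] for e in null_study.ledger.eqtl_truth if e["tissue"] == tissue}
            selected = {p for u in units[tissue] for p in u.probe_ids}
            assert selected == planted
            assert len(units[tissue]) == cfg.n_eqtl_per_tissue
            sizes = sorted(len(u.probe_ids) for u in units[tissue])
            assert sizes.count(2) == cfg.n_paired_eqtl
        xist = f"p{cfg.n_shared_probes + 1:04d}"
        assert all(xist not in {p for u in units[t] for p in u.probe_ids} for t in cfg.tissues)

    def test_eqtl_selection_robust_to_planted_mislabels(self, default_study, default_pipeline):
        """Mislabeled DNAs depress single-position LODs, but most planted eQTL
        still clear the screen and no noise probe ever does."""
        cfg = default_study.config
        units = default_pipeline.geno_result.units
        for tissue in cfg.tissues:
            planted = {e["probe"] for e in default_study.ledger.eqtl_truth if e["tissue"] == tissue}
            selected = {p for u in units[tissue] for p in u.probe_ids}
            assert selected <= planted
            assert len(selected) >= 0.8 * len(planted)

    def test_filter_removes_exactly_planted_dna_errors(self, default_study, default_pipeline):
        """The <0.7 match filter drops the mislabeled DNAs from training."""
        wrong = set(default_study.ledger.dna_source)
        for tissue, removed in default_pipeline.geno_result.filtered_samples.items():
            assert set(removed) == wrong

    def test_unassayed_dna_has_missing_similarity(self, default_study, default_pipeline):
        cfg = default_study.config
        comb = default_pipeline.geno_result.combined
        no_expr = default_study.genotypes.sample_ids[-cfg.n_no_expression :]
        col_set = set(comb.col_ids)
        for s in no_expr:
            assert s not in col_set  # never an mRNA column
            i = comb.row_ids.index(s)
            # row exists (DNA present) and its self cell is unavailable
            d = default_pipeline.geno_result.diagnosis.table
            assert d.loc[d["label"] == s, "status"].item() == "unverifiable"
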