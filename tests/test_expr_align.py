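"""Cross-tissue expression alignment: probe selection, similarity, diagnosis,
duplicates and corrections."""

import numpy as np
import pandas as pd
import pytest

from crossalign.core_io import Diagnosis, ExpressionSet, SimilarityMatrix
from crossalign.expr_align import (
    TissuePairProbes,
    apply_corrections,
    diagnose,
    find_within_tissue_duplicates,
    merge_diagnoses,
    pair_similarity,
    select_corr_probes,
    tissue_similarity,
)


def _es(tissue, values, sample_ids=None, probe_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    probe_ids = probe_ids or [f"p{j}" for j in range(p)]
    return ExpressionSet(
        tissue=tissue,
        sample_ids=sample_ids,
        values=values,
        probe_ids=probe_ids,
        probe_chrom=[None] * p,
        probe_pos=np.full(p, np.nan),
    )


class TestSelectCorrProbes:
    def test_exact_copy_selects_all_varying_probes(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 6))
        vals[:, 5] = 2.0  # constant probe: correlation undefined
        a, b = _es("a", vals), _es("b", vals.copy())
        pp = select_corr_probes(a, b, threshold=0.75)
        assert set(pp.probe_ids) == {f"p{j}" for j in range(5)}
        assert np.allclose(pp.correlations, 1.0)

    def test_too_few_shared_samples(self):
        a = _es("a", np.zeros((2, 4)))
        b = _es("b", np.zeros((2, 4)))
        with pytest.raises(ValueError, match="at least 3"):
            select_corr_probes(a, b)

    def test_shared_signal_recovered_in_simulation(self, default_study):
        """Latent-factor probes pass the 0.75 screen; noise probes do not."""
        cfg = default_study.config
        tissues = list(default_study.clean_expression)
        a = default_study.clean_expression[tissues[0]]
        b = default_study.clean_expression[tissues[1]]
        pp = select_corr_probes(a, b, threshold=0.75)
        shared = {f"p{j + 1:04d}" for j in range(cfg.n_shared_probes)}
        sex = {f"p{cfg.n_shared_probes + 1:04d}", f"p{cfg.n_shared_probes + 2:04d}"}
        selected = set(pp.probe_ids)
        # designed probes: latent-factor correlation 0.9, sex probes 0.8
        assert len(selected & shared) >= 0.9 * len(shared)
        assert selected <= shared | sex


class TestPairSimilarity:
    def test_identical_tissues_have_unit_diagonal(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 30))
        a, b = _es("a", vals), _es("b", vals.copy())
        pp = select_corr_probes(a, b)
        sim = pair_similarity(a, b, pp, min_probes=3)
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_all_missing_sample_gets_missing_row(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 30))
        a, b = _es("a", vals.copy()), _es("b", vals.copy())
        pp = select_corr_probes(a, b)
        a.values[3, :] = np.nan
        sim = pair_similarity(a, b, pp, min_probes=3)
        assert np.all(np.isnan(sim.values[3]))
        assert np.isfinite(sim.values[0]).all()

    def test_too_few_probes_suggests_threshold(self):
        rng = np.random.default_rng(3)
        a = _es("a", rng.normal(size=(5, 4)))
        b = _es("b", rng.normal(size=(5, 4)))
        pp = TissuePairProbes("a", "b", ["p0"], np.array([0.9]), 0.75)
        with pytest.raises(ValueError, match="threshold"):
            pair_similarity(a, b, pp, min_probes=20)


class TestTissueSimilarity:
    def _sm(self, vals):
        vals = np.asarray(vals, dtype=float)
        return SimilarityMatrix(["r0"], [f"c{j}" for j in range(vals.shape[1])], vals, "correlation")

    def test_median_of_three(self):
        mats = [self._sm([[0.2]]), self._sm([[0.8]]), self._sm([[0.9]])]
        assert tissue_similarity(mats).values[0, 0] == pytest.approx(0.8)

    def test_single_pair_passthrough(self):
        m = self._sm([[0.4, 0.6]])
        out = tissue_similarity([m])
        assert np.allclose(out.values, m.values)

    def test_all_missing_stays_missing(self):
        mats = [self._sm([[np.nan]]), self._sm([[np.nan]])]
        assert np.isnan(tissue_similarity(mats).values[0, 0])


class TestDiagnose:
    def _sim(self, values, labels=None):
        values = np.asarray(values, dtype=float)
        labels = labels or [f"s{i}" for i in range(values.shape[0])]
        return SimilarityMatrix(labels, labels, values, "correlation")

    def test_identity_matrix_all_correct(self):
        d = diagnose(self._sim(np.eye(4) * 0.95 + 0.02))
        assert set(d.table["status"]) == {"correct"}

    def test_forced_relabel(self):
        # s0 and s1 swapped: each row's max sits on the other's column
        vals = [
            [0.3, 0.95, 0.5],
            [0.96, 0.5, 0.2],
            [0.1, 0.2, 0.97],
        ]
        d = diagnose(self._sim(vals))
        assert d.table.iloc[0]["status"] == "relabel"
        assert d.table.iloc[0]["inferred_label"] == "s1"
        assert d.table.iloc[1]["status"] == "relabel"
        assert d.table.iloc[1]["inferred_label"] == "s0"

    def test_missing_self_weak_match_is_unverifiable(self):
        vals = np.array([[np.nan, 0.4, 0.2], [0.3, 0.9, 0.1], [0.2, 0.1, 0.92]])
        d = diagnose(self._sim(vals))
        assert d.table.iloc[0]["status"] == "unverifiable"

    def test_relabel_onto_correct_row_is_duplicate(self):
        vals = [
            [0.2, 0.95, 0.1],  # s0 points at s1 ...
            [0.1, 0.97, 0.2],  # ... whose own row is correct
            [0.0, 0.1, 0.96],
        ]
        d = diagnose(self._sim(vals))
        assert d.table.iloc[0]["status"] == "duplicate"
        assert d.table.iloc[0]["inferred_label"] == "s1"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, size=(6, 6))
        np.fill_diagonal(vals, 0.95)
        vals[2, 2] = 0.1
        vals[2, 4] = 0.93
        vals[2, [0, 1, 3, 5]] = 0.2
        sim = self._sim(vals)
        d1 = diagnose(sim)
        perm = rng.permutation(6)
        sim2 = SimilarityMatrix(
            [sim.row_ids[i] for i in perm],
            [sim.col_ids[i] for i in perm],
            vals[np.ix_(perm, perm)],
            "correlation",
        )
        d2 = diagnose(sim2)
        t1 = d1.table.set_index("label").sort_index()
        t2 = d2.table.set_index("label").sort_index()
        pd.testing.assert_frame_equal(t1, t2)


class TestDuplicates:
    def test_planted_duplicate_reported_and_self_never(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(8, 40))
        vals[5] = vals[2] + 0.05 * rng.normal(size=40)
        es = _es("t", vals)
        hits = find_within_tissue_duplicates(es, es.probe_ids, dup_threshold=0.9)
        assert [(a, b) for a, b, _ in hits] == [("s2", "s5")]

    def test_independent_samples_give_empty_list(self):
        rng = np.random.default_rng(7)
        es = _es("t", rng.normal(size=(10, 60)))
        assert find_within_tissue_duplicates(es, es.probe_ids, 0.9) == []


class TestApplyCorrections:
    def _diag(self, rows):
        cols = list(Diagnosis.COLUMNS)
        return Diagnosis(pd.DataFrame(rows, columns=cols))

    def test_swap_is_involution(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(3, 5))
        es = _es("t", vals)
        d = self._diag(
            [
                ("s0", "relabel", "s1", 0.1, 0.9, "s1", 0.2),
                ("s1", "relabel", "s0", 0.1, 0.9, "s0", 0.2),
                ("s2", "correct", None, 0.9, 0.9, "s2", 0.1),
            ]
        )
        out, log = apply_corrections({"t": es}, {"t": d})
        fixed = out["t"]
        assert fixed.sample_ids == ["s1", "s0", "s2"]
        assert np.array_equal(fixed.values, vals)

    def test_three_cycle_rotates(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(3, 5))
        es = _es("t", vals)
        # row s0 holds s1's array, s1 holds s2's, s2 holds s0's
        d = self._diag(
            [
                ("s0", "relabel", "s1", 0.1, 0.9, "s1", 0.2),
                ("s1", "relabel", "s2", 0.1, 0.9, "s2", 0.2),
                ("s2", "relabel", "s0", 0.1, 0.9, "s0", 0.2),
            ]
        )
        out, _ = apply_corrections({"t": es}, {"t": d})
        fixed = out["t"]
        idx = {s: i for i, s in enumerate(fixed.sample_ids)}
        assert np.array_equal(fixed.values[idx["s1"]], vals[0])
        assert np.array_equal(fixed.values[idx["s2"]], vals[1])
        assert np.array_equal(fixed.values[idx["s0"]], vals[2])

    def test_duplicate_combined_by_mean(self):
        vals = np.array([[1.0, 3.0], [9.0, 5.0], [0.0, 0.0]])
        es = _es("t", vals)
        d = self._diag(
            [
                ("s0", "duplicate", "s1", 0.1, 0.9, "s1", 0.2),
                ("s1", "correct", None, 0.9, 0.9, "s1", 0.2),
                ("s2", "correct", None, 0.9, 0.9, "s2", 0.1),
            ]
        )
        out, _ = apply_corrections({"t": es}, {"t": d})
        fixed = out["t"]
        assert fixed.sample_ids == ["s1", "s2"]
        assert np.allclose(fixed.values[0], [5.0, 4.0])

    def test_conflicting_relabels_raise(self):
        es = _es("t", np.zeros((3, 4)))
        d = self._diag(
            [
                ("s0", "relabel", "s2", 0.1, 0.9, "s2", 0.2),
                ("s1", "relabel", "s2", 0.1, 0.9, "s2", 0.2),
                ("s2", "relabel", "s0", 0.1, 0.9, "s0", 0.2),
            ]
        )
        with pytest.raises(ValueError, match="conflict"):
            apply_corrections({"t": es}, {"t": d})

    def test_unfixable_dropped_only_on_request(self):
        es = _es("t", np.zeros((2, 4)))
        d = self._diag(
            [
                ("s0", "unfixable", None, 0.1, 0.4, "s1", 0.2),
                ("s1", "correct", None, 0.9, 0.9, "s1", 0.2),
            ]
        )
        kept, _ = apply_corrections({"t": es}, {"t": d}, drop_unfixable=False)
        assert kept["t"].sample_ids == ["s0", "s1"]
        dropped, _ = apply_corrections({"t": es}, {"t": d}, drop_unfixable=True)
        assert dropped["t"].sample_ids == ["s1"]


class TestMergeDiagnoses:
    def test_unresolved_rows_take_second_pass_verdict(self):
        cols = list(Diagnosis.COLUMNS)
        first = Diagnosis(
            pd.DataFrame(
                [
                    ("a", "relabel", "b", 0.1, 0.9, "b", 0.2),
                    ("c", "unfixable", None, 0.4, 0.5, "d", 0.3),
                ],
                columns=cols,
            )
        )
        second = Diagnosis(
            pd.DataFrame(
                [
                    ("b", "correct", None, 0.95, 0.95, "b", 0.2),
                    ("c", "correct", None, 0.92, 0.92, "c", 0.3),
                ],
                columns=cols,
            )
        )
        merged = merge_diagnoses(first, second)
        by = merged.table.set_index("label")
        assert by.loc["a", "status"] == "relabel"
        assert by.loc["c", "status"] == "correct"
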