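"""The synthetic-study generator: cross genetics, expression structure,
planted-error bookkeeping and exact ledger invertibility."""

import numpy as np
import pytest

from crossalign.core_io import NA
from crossalign.genmap import inverse_map_r
from crossalign.simulate import (
    SimConfig,
    default_planted_errors,
    plant_errors,
    simulate_cross,
    simulate_study,
)


@pytest.fixture(scope="module")
def big_cross():
    """Large error-free panel for checking segregation statistics."""
    cfg = SimConfig(
        n_mice=2000,
        autosome_lengths_cM=(60.0,),
        markers_per_autosome=10,
        error_rate=0.0,
        missing_rate=0.0,
        seed=42,
    )
    gt, gmap, layout, ledger = simulate_cross(cfg)
    return cfg, gt, gmap


class TestCrossGenetics:
    def test_genotype_frequencies_quarter_half_quarter(self, big_cross):
        cfg, gt, gmap = big_cross
        n = cfg.n_mice
        auto = gt.calls[:, :cfg.markers_per_autosome]
        for j in range(auto.shape[1]):
            col = auto[:, j]
            for g, f in ((0, 0.25), (1, 0.5), (2, 0.25)):
                se = np.sqrt(f * (1 - f) / n)
                assert abs((col == g).mean() - f) < 3 * se

    def test_adjacent_recombination_matches_map_function(self, big_cross):
        cfg, gt, gmap = big_cross
        d = 60.0 / 9  # marker spacing
        r_expected = inverse_map_r(d, cfg.map_function)
        # recombination events per meiosis: count via genotype transitions of
        # the two gametes; use homozygote-to-homozygote transitions, whose
        # frequency is r^2 + ... simpler: average gamete switches estimated
        # from genotype changes |g[k+1]-g[k]| summed = switches of both gametes
        auto = gt.calls[:, :cfg.markers_per_autosome].astype(int)
        diffs = np.abs(np.diff(auto, axis=1))
        est_r = diffs.mean() / 2  # two meioses per interval
        se = np.sqrt(r_expected * (1 - r_expected) / (2 * cfg.n_mice * 9))
        assert abs(est_r - r_expected) < 4 * se

    def test_x_chromosome_follows_cross_design(self, big_cross):
        cfg, gt, gmap = big_cross
        x = gt.calls[:, cfg.markers_per_autosome:]
        for i, sex in enumerate(gt.sex):
            if sex == "female":
                assert not np.any(x[i] == 0)  # never homozygous B6
            else:
                assert not np.any(x[i] == 1)  # hemizygous, never heterozygous

    def test_determinism(self):
        cfg = SimConfig(seed=5)
        s1, s2 = simulate_study(cfg), simulate_study(cfg)
        assert np.array_equal(s1.genotypes.calls, s2.genotypes.calls)
        for t in s1.expression:
            assert np.array_equal(s1.expression[t].values, s2.expression[t].values)
        assert s1.ledger.planted == s2.ledger.planted


class TestExpressionStructure:
    def test_eqtl_probe_separates_genotype_groups(self, default_study):
        truth = default_study.ledger.eqtl_truth[0]
        es = default_study.clean_expression[truth["tissue"]]
        gt = default_study.clean_genotypes
        mcol = next(
            j
            for j, m in enumerate(default_study.genetic_map.markers)
            if default_study.genetic_map.chromosomes[j] == truth["chromosome"]
            and default_study.genetic_map.positions[j] == truth["position_cM"]
        )
        y = es.values[:, es.probe_ids.index(truth["probe"])]
        g = gt._true_calls[: len(y), mcol]
        means = [y[g == k].mean() for k in range(3)]
        assert means[0] < means[1] < means[2]
        assert means[2] - means[0] == pytest.approx(2 * truth["additive"], abs=0.5)

    def test_pure_noise_probes_uncorrelated_between_tissues(self, default_study):
        tissues = list(default_study.clean_expression)
        a = default_study.clean_expression[tissues[0]].values[:, -50:]
        b = default_study.clean_expression[tissues[1]].values[:, -50:]
        rs = [np.corrcoef(a[:, j], b[:, j])[0, 1] for j in range(50)]
        assert abs(np.mean(rs)) < 0.05
        assert max(np.abs(rs)) < 0.3


class TestPlantedErrors:
    def test_empty_error_list_is_identity(self, null_study):
        assert np.array_equal(null_study.genotypes.calls, null_study.clean_genotypes.calls)
        for t in null_study.expression:
            assert np.array_equal(
                null_study.expression[t].values, null_study.clean_expression[t].values
            )
        assert null_study.ledger.dna_source == {}

    def test_ledger_restores_clean_data_exactly(self, default_study):
        restored = default_study.ledger.restore_genotypes(default_study.genotypes)
        assert np.array_equal(restored.calls, default_study.clean_genotypes.calls)
        assert restored.sex == default_study.clean_genotypes.sex
        for t, es in default_study.expression.items():
            back = default_study.ledger.restore_expression(es)
            assert np.array_equal(
                back.values, default_study.clean_expression[t].values, equal_nan=True
            )

    def test_plate_shift_displaces_run_in_filling_order(self, default_study):
        shift = next(e for e in default_study.ledger.planted if e["kind"] == "dna_plate_shift")
        fill = default_study.layout.fill_positions()
        run = shift["samples"]
        # each of the last `length` run members holds the previous well's DNA
        src = default_study.ledger.dna_source
        for prev, cur in zip(run[:-1], run[1:]):
            assert src[cur] == prev
            assert fill[cur] == fill[prev] + 1
        assert src[run[0]] == run[-1]  # wrap-back keeps it a permutation

    def test_expr_cycle_applied_three_times_restores(self, default_study):
        cyc = next(e for e in default_study.ledger.planted if e["kind"] == "expr_cycle")
        tissue, samples = cyc["tissue"], cyc["samples"]
        es = default_study.clean_expression[tissue]
        corrupted = default_study.expression[tissue]
        idx = {s: i for i, s in enumerate(es.sample_ids)}
        # one application of the cycle, as a row permutation of the clean data
        cycle_perm = np.arange(es.n_samples)
        for i, label in enumerate(samples):
            cycle_perm[idx[label]] = idx[samples[(i + 1) % len(samples)]]
        values = es.values
        for _ in range(3):
            values = values[cycle_perm]
        assert np.array_equal(values, es.values, equal_nan=True)
        # the corrupted rows of the cycle members hold exactly the ledgered sources
        src = default_study.ledger.expr_source[tissue]
        for label in samples:
            assert np.array_equal(
                corrupted.values[idx[label]], es.values[idx[src[label]]], equal_nan=True
            )

    def test_conflicting_errors_rejected(self):
        cfg = SimConfig(
            seed=3,
            planted_errors=[
                {"kind": "dna_plate_shift", "start_fill": 2, "length": 8, "offset": 1},
                {"kind": "dna_duplicate", "source_fill": 3, "target_fill": 50},
            ],
        )
        with pytest.raises(ValueError, match="twice"):
            simulate_study(cfg)

    def test_sex_swap_pair_is_detectable_by_design(self, default_study):
        a, b = default_study.ledger.sex_swapped
        gt = default_study.genotypes
        x_cols = [j for j, m in enumerate(gt.markers) if m.startswith("cXm")]
        for s in (a, b):
            i = gt.sample_ids.index(s)
            row = gt.calls[i, x_cols]
            recorded = gt.sex[i]
            discordant = (row == 0).sum() if recorded == "female" else (row == 1).sum()
            assert discordant >= 2

    def test_default_scenario_counts(self, default_study):
        led = default_study.ledger
        assert len(led.expected_dna_relabels()) == 9
        assert len(led.expected_dna_duplicates()) == 1
        assert len(led.sex_swapped) == 2
        n_expr_errors = sum(
            len(led.expected_expr_relabels(t)) + len(led.expected_expr_duplicates(t))
            for t in default_study.expression
        )
        assert n_expr_errors == 2 * 3 + 3 + 1  # swaps + 3-cycle + duplicate


class TestConfigValidation:
    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(error_rate=0.7).validate()
        with pytest.raises(ValueError):
            SimConfig(n_probes=10).validate()
        with pytest.raises(ValueError):
            SimConfig(n_no_expression=300).validate()
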