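"""Point-mutation drift model against exhaustive enumeration oracles."""

import itertools

import numpy as np
import pytest

from teaudit import (
    aggregate_by_type,
    binom_cdf,
    conversion_matrix,
    conversion_prob,
    diagnostic_sites,
    site_change_probs,
)
from teaudit.drift import DriftMatrix, _drift_sum
from teaudit.simgen import make_subfamily_library, seq_to_ints, simulate_instances


def enumeration_oracle(n: int, p_a: float) -> float:
    """Sum over all 3^n per-site outcome vectors (stay / flip-to-j /
    other) of the probability that strictly more sites agree with j
    than with i."""
    p_stay = p_a
    p_j = (1 - p_a) / 3
    p_other = 2 * (1 - p_a) / 3
    total = 0.0
    for outcome in itertools.product((0, 1, 2), repeat=n):
        if outcome.count(1) > outcome.count(0):
            prob = 1.0
            for state in outcome:
                prob *= (p_stay, p_j, p_other)[state]
            total += prob
    return total


class TestDiagnosticSites:
    def test_single_substitution(self):
        sites = diagnostic_sites("ACGT", "AGGT")
        assert sites.n == 1
        assert sites.sites == [(1, "C", "G")]

    def test_identical_sequences(self):
        assert diagnostic_sites("ACGTACGT", "ACGTACGT").n == 0

    def test_indel_columns_excluded(self):
        # one deletion plus one substitution: the indel column is not a
        # site, the substitution column is
        consensus = "AACCTTGGAACCTTGGAACC"
        variant = consensus[:5] + consensus[6:]  # drop one base
        variant = variant[:12] + ("G" if variant[12] != "G" else "A") + variant[13:]
        sites = diagnostic_sites(consensus, variant)
        assert sites.n == 1

    def test_unequal_lengths_aligned_globally(self):
        # deleting one base must not spuriously shift every downstream
        # column into a "site"
        consensus = "ACGTACGTACGTACGTACGT"
        deleted = consensus[:10] + consensus[11:]
        assert diagnostic_sites(consensus, deleted).n == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_sites("", "ACGT")


class TestSiteChangeProbs:
    def test_perfect_identity(self):
        params = site_change_probs(1.0)
        assert (params.p_c, params.p_o) == (1.0, 0.0)

    def test_worked_example(self):
        params = site_change_probs(0.7)
        assert params.p_c == pytest.approx(0.875)
        assert params.p_o == pytest.approx(0.2)
        assert params.p_b == pytest.approx(0.1)
        assert params.p_a + params.p_b + params.p_o == pytest.approx(1.0)

    def test_zero_identity(self):
        params = site_change_probs(0.0)
        assert params.p_c == 0.0
        assert params.p_o == pytest.approx(2 / 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            site_change_probs(1.2)


class TestBinomCdf:
    def test_direct_summation(self):
        assert binom_cdf(1, 3, 0.5) == pytest.approx(0.5)  # (1+3)/8

    def test_saturates_at_n(self):
        for p in (0.0, 0.3, 1.0):
            assert binom_cdf(3, 3, p) == 1.0
            assert binom_cdf(10, 3, p) == 1.0

    def test_lower_tail(self):
        assert binom_cdf(0, 2, 0.9) == pytest.approx(0.01)
        assert binom_cdf(-1, 2, 0.9) == 0.0


class TestConversionProb:
    def test_no_mutations_no_conversion(self):
        for n in (1, 3, 10):
            assert conversion_prob(n, 1.0) == 0.0

    def test_zero_sites(self):
        assert conversion_prob(0, 0.5) == 0.0

    def test_worked_examples(self):
        assert conversion_prob(2, 0.7) == pytest.approx(0.05, abs=1e-12)
        assert conversion_prob(1, 0.7) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("p_a", [0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
    def test_matches_exhaustive_enumeration(self, p_a):
        for n in range(7):
            assert conversion_prob(n, p_a) == pytest.approx(
                enumeration_oracle(n, p_a), abs=1e-12
            )

    def test_forcing_no_other_state_leaves_single_term(self):
        # with P(O) forced to 0 the sum collapses to its k=0 term
        for n in (1, 3, 6):
            for p_a in (0.6, 0.9):
                p_c = site_change_probs(p_a).p_c
                assert _drift_sum(n, p_c, 0.0) == pytest.approx(
                    binom_cdf((n - 1) // 2, n, p_c), abs=1e-12
                )

    def test_half_majority_reading_is_at_least_strict(self):
        for n in (2, 4, 6):
            assert conversion_prob(n, 0.8, majority="half") >= conversion_prob(
                n, 0.8, majority="strict"
            )


class TestConversionMatrix:
    def test_compositional_against_elementwise_calls(self, tiny_library):
        identities = {"SF01": 0.9, "SF02": 0.8, "SF03": 0.85}
        matrix = conversion_matrix(tiny_library, identities)
        for i in tiny_library.names:
            for j in tiny_library.names:
                if i == j:
                    assert matrix.pairwise.loc[i, j] == 0.0
                    continue
                n_ij = diagnostic_sites(
                    tiny_library[i].consensus, tiny_library[j].consensus
                ).n
                assert matrix.pairwise.loc[i, j] == pytest.approx(
                    conversion_prob(n_ij, identities[i])
                )

    def test_identical_consensuses_give_zero(self, tiny_library):
        lib = make_subfamily_library(n_subfamilies=1, seed=0)
        matrix = conversion_matrix(lib, {"SF01": 0.9})
        assert matrix.pairwise.values.sum() == 0.0

    def test_asymmetric_when_identities_differ(self, tiny_library):
        identities = {"SF01": 0.95, "SF02": 0.7, "SF03": 0.9}
        matrix = conversion_matrix(tiny_library, identities)
        assert matrix.pairwise.loc["SF01", "SF02"] != matrix.pairwise.loc["SF02", "SF01"]

    def test_missing_identity_rejected(self, tiny_library):
        with pytest.raises(KeyError):
            conversion_matrix(tiny_library, {"SF01": 0.9})


class TestAggregateByType:
    def test_one_subfamily_per_type_passes_through(self, tiny_library):
        identities = {"SF01": 0.9, "SF02": 0.85, "SF03": 0.8}
        matrix = conversion_matrix(tiny_library, identities)
        type_map = {"SF01": "A", "SF02": "B", "SF03": "C"}
        table = aggregate_by_type(
            matrix, {n: 1.0 for n in tiny_library.names}, type_map
        ).set_index("type")
        assert table.loc["A", "B"] == pytest.approx(matrix.pairwise.loc["SF01", "SF02"])
        assert table.loc["B", "C"] == pytest.approx(matrix.pairwise.loc["SF02", "SF03"])

    def test_hand_weighted_average(self):
        import pandas as pd

        names = ["X1", "X2", "Y1"]
        pairwise = pd.DataFrame(0.0, index=names, columns=names)
        # within-type totals 0.1 (X1) and 0.2 (X2) toward type Y
        pairwise.loc["X1", "Y1"] = 0.1
        pairwise.loc["X2", "Y1"] = 0.2
        matrix = DriftMatrix(pairwise=pairwise, site_counts=pairwise * 0)
        table = aggregate_by_type(
            matrix,
            {"X1": 0.25, "X2": 0.75, "Y1": 1.0},
            {"X1": "X", "X2": "X", "Y1": "Y"},
        ).set_index("type")
        assert table.loc["X", "Y"] == pytest.approx(0.175)

    def test_combined_column_equals_row_sum_over_types(self, tiny_library):
        matrix = conversion_matrix(tiny_library, {"SF01": 0.9, "SF02": 0.8, "SF03": 0.85})
        table = aggregate_by_type(
            matrix, {"SF01": 2.0, "SF02": 1.0, "SF03": 3.0}, tiny_library.type_map()
        )
        types = [c for c in table.columns if c not in ("type", "combined_mismatch")]
        for _, row in table.iterrows():
            assert row["combined_mismatch"] == pytest.approx(sum(row[t] for t in types))

    def test_zero_weight_type_rejected(self, tiny_library):
        matrix = conversion_matrix(tiny_library, {"SF01": 0.9, "SF02": 0.8, "SF03": 0.85})
        with pytest.raises(ValueError, match="weight"):
            aggregate_by_type(
                matrix,
                {"SF01": 0.0, "SF02": 0.0, "SF03": 1.0},
                {"SF01": "T1", "SF02": "T1", "SF03": "T2"},
            )


class TestDriftSelfConsistency:
    def test_simulated_flip_rate_matches_model(self):
        """Instances simulated under the generator's mutation model and
        annotated by diagnostic-site strict majority flip at the rate
        the closed-form model predicts (moderate n here; the full-scale
        check lives in the acceptance suite)."""
        n_sites, p_a, n_inst = 6, 0.8, 20_000
        lib = make_subfamily_library(
            ancestral_length=60,
            n_subfamilies=2,
            diagnostic_per_split=n_sites,
            identity=p_a,
            frequency=[1.0, 0.0],
            seed=21,
        )
        cons_i = seq_to_ints(lib["SF01"].consensus)
        cons_j = seq_to_ints(lib["SF02"].consensus)
        sites = np.nonzero(cons_i != cons_j)[0]
        instances, _ = simulate_instances(lib, n_inst, seed=22)
        flips = 0
        for seq, _anno in instances:
            arr = seq_to_ints(seq)[sites]
            flips += int((arr == cons_j[sites]).sum() > (arr == cons_i[sites]).sum())
        expected = conversion_prob(n_sites, p_a)
        se = np.sqrt(expected * (1 - expected) / n_inst)
        assert abs(flips / n_inst - expected) < 3 * se
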