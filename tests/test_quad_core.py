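"""Process-tree structure, closed-form probabilities, likelihood, simulation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadbias.iat_data import CELLS, Pairing, ResponseCountTable, StimulusCategory
from quadbias.quad_core import (
    ActivationMap,
    BiasDirection,
    QuadParameters,
    QuadSpecification,
    cell_probabilities,
    cell_probability_array,
    enumerate_paths,
    export_equations,
    log_likelihood,
    simulate_counts,
)

IP, OP = Pairing.INGROUP_PLEASANT, Pairing.OUTGROUP_PLEASANT
CAT = StimulusCategory

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
params_strategy = st.tuples(unit, unit, unit, unit, unit).map(
    lambda t: QuadParameters(*t)
)


def path_sums(spec, cell, params):
    wiring = spec.wiring(cell)
    gc = params.g if wiring.pleasant_correct else 1 - params.g
    paths = enumerate_paths(spec, cell)
    correct = sum(p.probability(params, gc) for p in paths if p.outcome == "correct")
    total = sum(p.probability(params, gc) for p in paths)
    return correct, total


class TestTreeStructure:
    def test_incongruent_face_cell_has_three_error_paths(self, outgroup_spec):
        """An activated conflicting association yields exactly the three
        incorrect routes AC*D*(1-OB), AC*(1-D), (1-AC)*(1-D)*(1-G)."""
        cell = (CAT.INGROUP_TARGET, IP)  # ingroup-unpleasant AC pushes wrong key
        wiring = outgroup_spec.wiring(cell)
        assert wiring.ac_index == 1 and not wiring.push_correct
        bad = [p for p in enumerate_paths(outgroup_spec, cell)
               if p.outcome == "incorrect"]
        assert sorted(str(p) for p in bad) == sorted(
            [
                "ac_b * d_detect * (1 - ob)",
                "ac_b * (1 - d_detect)",
                "(1 - ac_b) * (1 - d_detect) * (1 - g_cell)",
            ]
        )

    def test_congruent_face_cell_single_error_path(self, outgroup_spec):
        cell = (CAT.INGROUP_TARGET, OP)  # ingroup-unpleasant association congruent
        wiring = outgroup_spec.wiring(cell)
        assert wiring.push_correct
        bad = [p for p in enumerate_paths(outgroup_spec, cell)
               if p.outcome == "incorrect"]
        assert [str(p) for p in bad] == ["(1 - ac_b) * (1 - d_detect) * (1 - g_cell)"]

    def test_word_cell_without_association(self):
        spec = QuadSpecification(BiasDirection.OUTGROUP_BIAS,
                                 ActivationMap.FACES_ONLY)
        cell = (CAT.PLEASANT_WORD, IP)
        paths = enumerate_paths(spec, cell)
        good = [str(p) for p in paths if p.outcome == "correct"]
        assert sorted(good) == sorted(["d_detect", "(1 - d_detect) * g_cell"])

    def test_printed_three_term_error_probability(self, outgroup_spec):
        """AC=.3, D=.5, OB=.6, G=.4 on an incongruent cell whose correct key
        is pleasant-assigned: .3*.5*.4 + .3*.5 + .7*.5*.6 = 0.42."""
        cell = (CAT.INGROUP_TARGET, IP)
        params = QuadParameters(0.0, 0.3, 0.5, 0.6, 0.4)
        probs = {c.cell: c for c in cell_probabilities(params, outgroup_spec)}
        assert probs[cell].p_incorrect == pytest.approx(0.42, abs=1e-12)

    def test_pleasant_word_detection_plus_guessing(self):
        spec = QuadSpecification(BiasDirection.OUTGROUP_BIAS,
                                 ActivationMap.FACES_ONLY)
        params = QuadParameters(0.9, 0.9, 0.5, 0.5, 0.4)  # ACs inert on words
        probs = {c.cell: c for c in cell_probabilities(params, spec)}
        assert probs[(CAT.PLEASANT_WORD, IP)].p_correct == pytest.approx(0.7)


class TestClosedFormAgreement:
    @pytest.mark.parametrize("direction", list(BiasDirection))
    @pytest.mark.parametrize("amap", list(ActivationMap))
    def test_grid_paths_match_closed_form(self, direction, amap):
        """5-D parameter grid with step 0.25, all 8 cells: the path sum
        equals the closed form and probabilities sum to one, to 1e-12."""
        spec = QuadSpecification(direction, amap)
        grid = np.array(
            list(itertools.product(*[np.arange(0.0, 1.01, 0.25)] * 5))
        )
        closed = cell_probability_array(grid, spec)
        for j, cell in enumerate(CELLS):
            for row, expected in zip(grid, closed[:, j]):
                correct, total = path_sums(spec, cell, QuadParameters(*row))
                assert abs(total - 1.0) < 1e-12
                assert abs(correct - expected) < 1e-12

    @given(params=params_strategy)
    @settings(max_examples=50, deadline=None)
    def test_probabilities_complementary(self, params, outgroup_spec):
        for c in cell_probabilities(params, outgroup_spec):
            assert abs(c.p_correct + c.p_incorrect - 1.0) < 1e-12
            assert -1e-12 <= c.p_correct <= 1 + 1e-12


class TestSpecificationSymmetries:
    def test_direction_swap_equals_group_relabel(self):
        """Swapping the bias direction while swapping the group labels
        (ingroup<->outgroup categories and pairings) leaves all cell
        probabilities unchanged."""
        swap_cat = {
            CAT.INGROUP_TARGET: CAT.OUTGROUP_TARGET,
            CAT.OUTGROUP_TARGET: CAT.INGROUP_TARGET,
            CAT.PLEASANT_WORD: CAT.PLEASANT_WORD,
            CAT.UNPLEASANT_WORD: CAT.UNPLEASANT_WORD,
        }
        swap_pair = {IP: OP, OP: IP}
        params = QuadParameters(0.3, 0.15, 0.8, 0.55, 0.45)
        out = {c.cell: c.p_correct for c in cell_probabilities(
            params, QuadSpecification(BiasDirection.OUTGROUP_BIAS))}
        ing = {c.cell: c.p_correct for c in cell_probabilities(
            params, QuadSpecification(BiasDirection.INGROUP_BIAS))}
        for (cat, pairing), p in out.items():
            assert ing[(swap_cat[cat], swap_pair[pairing])] == pytest.approx(
                p, abs=1e-12
            )

    def test_zero_acs_collapse_to_detection_guessing(self):
        params = QuadParameters(0.0, 0.0, 0.7, 0.9, 0.6)
        probs = {c.cell: c.p_correct for c in cell_probabilities(
            params, QuadSpecification(BiasDirection.OUTGROUP_BIAS))}
        for cat in CAT:
            # pairing has no effect without associations
            gc = {CAT.PLEASANT_WORD: 0.6, CAT.UNPLEASANT_WORD: 0.4}
            if cat in gc:
                expected = 0.7 + 0.3 * gc[cat]
                assert probs[(cat, IP)] == pytest.approx(expected, abs=1e-12)
                assert probs[(cat, OP)] == pytest.approx(expected, abs=1e-12)
            else:
                # face cells: g_cell flips with pairing, so compare the pair
                assert probs[(cat, IP)] + probs[(cat, OP)] == pytest.approx(
                    2 * 0.7 + 0.3 * (0.6 + 0.4), abs=1e-12
                )

    @given(
        ac=st.floats(0.01, 0.99), d=st.floats(0.01, 0.99),
        ob=st.floats(0.0, 0.98), g=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity_in_ob_and_ac(self, ac, d, ob, g, outgroup_spec):
        cell_idx = CELLS.index((CAT.INGROUP_TARGET, IP))  # incongruent cell

        def p(ac_b, ob_):
            return cell_probability_array(
                np.array([0.0, ac_b, d, ob_, g]), outgroup_spec
            )[cell_idx]

        assert p(ac, ob + 0.01) >= p(ac, ob) - 1e-12
        assert p(min(ac + 0.01, 1.0), ob) <= p(ac, ob) + 1e-12


class TestLikelihoodSimulation:
    def test_zero_trials_zero_loglik(self, outgroup_spec, reference_params):
        table = ResponseCountTable({c: (0, 0) for c in CELLS})
        assert log_likelihood(reference_params, outgroup_spec, table) == 0.0

    def test_single_cell_hand_value(self, outgroup_spec):
        # with AC=0 and D=0, every cell is pure guessing; a pleasant-word
        # cell with G=0.5 has p_correct = 0.5; counts (1,1):
        # LL = log C(2,1) + 2 log .5
        counts = {c: (0, 0) for c in CELLS}
        counts[(CAT.PLEASANT_WORD, IP)] = (1, 1)
        table = ResponseCountTable(counts)
        params = QuadParameters(0.0, 0.0, 0.0, 0.5, 0.5)
        expected = math.log(2) + 2 * math.log(0.5)
        assert log_likelihood(params, outgroup_spec, table) == pytest.approx(expected)

    def test_impossible_counts_give_neg_inf(self, outgroup_spec):
        counts = {c: (0, 0) for c in CELLS}
        counts[(CAT.PLEASANT_WORD, IP)] = (0, 3)
        table = ResponseCountTable(counts)
        params = QuadParameters(0.0, 0.0, 1.0, 1.0, 1.0)  # p_correct = 1
        assert log_likelihood(params, outgroup_spec, table) == -math.inf

    def test_perfect_detection_no_errors(self, outgroup_spec):
        params = QuadParameters(0.0, 0.0, 1.0, 0.5, 0.5)
        table = simulate_counts(params, outgroup_spec, 100, seed=0)
        assert all(ni == 0 for _, ni in table.counts.values())

    def test_simulation_deterministic_under_seed(self, outgroup_spec,
                                                 reference_params):
        t1 = simulate_counts(reference_params, outgroup_spec, 500, seed=9)
        t2 = simulate_counts(reference_params, outgroup_spec, 500, seed=9)
        assert t1.counts == t2.counts

    def test_large_simulation_matches_probabilities(self, outgroup_spec):
        params = QuadParameters(0.3, 0.2, 0.8, 0.5, 0.55)
        n = 100_000
        table = simulate_counts(params, outgroup_spec, n, seed=4)
        probs = cell_probability_array(params.as_array(), outgroup_spec)
        for j, cell in enumerate(CELLS):
            nc, ni = table.counts[cell]
            assert abs(nc / n - probs[j]) < 0.005


def test_equation_export_lists_all_cells(outgroup_spec):
    text = export_equations(outgroup_spec)
    lines = [l for l in text.splitlines() if l.strip()]
    assert len(lines) == 16
    assert "ac_b * d_detect * (1 - ob)" in text
    assert "g_cell" not in text  # expanded to g / (1 - g)
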