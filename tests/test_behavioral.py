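"""Behavioral scoring: letter accuracy, digit span, deficit typing, coding."""

from collections import deque
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svrlsm.behavioral import (
    DigitSpanRecord,
    SpellingTrial,
    classify_deficits,
    classify_from_pvalues,
    construct_owm_variable,
    damerau_levenshtein,
    digit_span,
    effect_chi_square,
    effect_test,
    letter_accuracy,
    letter_counts,
    load_table3,
    table3_discordances,
    z_normalize,
)
from svrlsm.exceptions import (
    DegenerateCovariateError,
    InvalidCohortError,
    InvalidInputError,
    UndefinedTestError,
)


def bfs_edit_distance(a: str, b: str, alphabet: str) -> int:
    """Breadth-first search over edit scripts (substitution, insertion,
    deletion, adjacent transposition), independent of the DP scorer."""
    if a == b:
        return 0
    seen = {a}
    frontier = deque([a])
    dist = 0
    while frontier:
        dist += 1
        nxt = deque()
        for s in frontier:
            neighbors = set()
            for i in range(len(s)):
                neighbors.add(s[:i] + s[i + 1:])  # deletion
                for ch in alphabet:
                    neighbors.add(s[:i] + ch + s[i + 1:])  # substitution
            for i in range(len(s) + 1):
                for ch in alphabet:
                    neighbors.add(s[:i] + ch + s[i:])  # insertion
            for i in range(len(s) - 1):
                neighbors.add(s[:i] + s[i + 1] + s[i] + s[i + 2:])  # transposition
            for t in neighbors:
                if t == b:
                    return dist
                if t not in seen and len(t) <= max(len(a), len(b)) + 1:
                    seen.add(t)
                    nxt.append(t)
        frontier = nxt
    raise AssertionError("unreachable")


class TestLetterAccuracy:
    @pytest.mark.parametrize(
        ("target", "response", "expected"),
        [
            ("COAT", "COET", 0.75),
            ("COAT", "CUAD", 0.50),
            ("COAT", "COAT", 1.0),
            ("COAT", "", 0.0),
            ("COAT", "OCAT", 0.75),  # one adjacent transposition
        ],
    )
    def test_worked_examples(self, target, response, expected):
        assert letter_accuracy(target, response) == pytest.approx(expected)

    def test_case_and_whitespace_normalized(self):
        assert letter_accuracy("coat", " coet ") == 0.75

    def test_empty_target_rejected(self):
        with pytest.raises(InvalidInputError):
            letter_accuracy("", "COAT")

    @pytest.mark.parametrize("seed", range(4))
    def test_distance_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = "ABC"
        for _ in range(25):
            a = "".join(rng.choice(list(alphabet), rng.integers(1, 5)))
            b = "".join(rng.choice(list(alphabet), rng.integers(0, 5)))
            assert damerau_levenshtein(a, b) == bfs_edit_distance(a, b, alphabet)

    @given(
        st.text(alphabet="ABCDE", min_size=1, max_size=8),
        st.text(alphabet="ABCDE", min_size=0, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_bounded_and_identity(self, target, response):
        acc = letter_accuracy(target, response)
        assert 0.0 <= acc <= 1.0
        assert (acc == 1.0) == (target == response)

    @given(st.text(alphabet="ABCDE", min_size=1, max_size=8))
    @settings(max_examples=80, deadline=None)
    def test_symmetric_for_equal_length(self, target):
        # equal lengths: only substitutions/transpositions apply; the
        # distance, hence the accuracy, is symmetric
        scrambled = target[::-1]
        assert letter_accuracy(target, scrambled) == letter_accuracy(scrambled, target)


class TestDigitSpan:
    def test_printed_example(self):
        rec = DigitSpanRecord({2: (2, 2), 3: (2, 1), 4: (2, 0)})
        assert digit_span(rec) == 2.5

    def test_ceiling(self):
        rec = DigitSpanRecord({length: (2, 2) for length in range(2, 10)})
        assert digit_span(rec) == 9.0

    def test_floor(self):
        assert digit_span(DigitSpanRecord({2: (2, 0)})) == 0.0

    def test_half_credit_below_base(self):
        rec = DigitSpanRecord({2: (2, 1), 3: (2, 0)})
        assert digit_span(rec) == 0.5

    def test_stopping_rule_violation_rejected(self):
        with pytest.raises(InvalidInputError):
            DigitSpanRecord({2: (2, 0), 3: (2, 1)})

    def test_correct_exceeding_administered_rejected(self):
        with pytest.raises(InvalidInputError):
            DigitSpanRecord({2: (1, 2)})

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_list_outcomes(self, seed):
        # upgrading any incorrect list to correct never lowers the span
        rng = np.random.default_rng(seed)
        trials = {}
        for length in range(2, 10):
            correct = int(rng.integers(0, 3))
            trials[length] = (2, correct)
            if correct == 0:
                break
        base = DigitSpanRecord(trials)
        score = digit_span(base)
        for length, (adm, cor) in trials.items():
            if cor < adm:
                upgraded = dict(trials)
                upgraded[length] = (adm, cor + 1)
                if length == max(trials) or trials[length] != (2, 0):
                    # upgrading the stopping length keeps the record valid
                    # only if nothing was administered beyond it
                    beyond = [l for l in trials if l > length and trials[l][0] > 0]
                    if beyond:
                        continue
                assert digit_span(DigitSpanRecord(upgraded)) >= score


def _trials(specs):
    """Build SpellingTrials from (target, n_substitutions, freq) tuples."""
    out = []
    for target, n_sub, freq in specs:
        response = list(target)
        for i in range(n_sub):
            response[i] = "Z" if target[i] != "Z" else "Q"
        out.append(SpellingTrial(target, "".join(response), freq))
    return out


class TestEffectChiSquare:
    def test_identical_error_rates_give_p_one(self):
        trials = _trials([
            ("BADE", 2, 5.0), ("BODE", 2, 5.0),   # low freq: 4/8 correct
            ("DUNE", 2, 100.0), ("DINE", 2, 100.0),  # high freq: 4/8 correct
        ])
        assert effect_chi_square(trials, "frequency") == pytest.approx(1.0)

    def test_matches_independent_chi_square(self):
        # letter table known by construction: low 12 correct / 8 wrong,
        # high 18 correct / 2 wrong
        trials = _trials([
            ("BADEL", 4, 2.0), ("BODEL", 4, 2.0), ("BIDEL", 0, 2.0), ("BUDEL", 0, 2.0),
            ("DUNEL", 1, 99.0), ("DINEL", 1, 99.0), ("DONEL", 0, 99.0), ("DANEL", 0, 99.0),
        ])
        from scipy.stats import chi2_contingency

        expected = chi2_contingency([[12, 8], [18, 2]], correction=False)[1]
        assert effect_chi_square(trials, "frequency") == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_cell_swap(self):
        specs = [("BADE", 1, 3.0), ("LODE", 2, 3.0), ("DUNE", 0, 90.0), ("MINE", 1, 90.0)]
        p = effect_chi_square(_trials(specs), "frequency")
        swapped = [(t, n, 90.0 if f < 15 else 3.0) for t, n, f in specs]
        assert effect_chi_square(_trials(swapped), "frequency") == pytest.approx(p)

    def test_unbinned_words_excluded(self):
        base = _trials([("BADE", 1, 3.0), ("DUNE", 0, 90.0)])
        with_mid = base + [
            SpellingTrial("BADE", "ZZZZ", 30.0),   # mid frequency: no freq bin
            SpellingTrial("LODE", "ZQZQ", 60.0),   # boundary is exclusive (> 60)
        ]
        assert effect_chi_square(with_mid, "frequency") == pytest.approx(
            effect_chi_square(base, "frequency")
        )

    def test_empty_cell_is_undefined(self):
        only_low = _trials([("BADE", 1, 3.0)])
        with pytest.raises(UndefinedTestError):
            effect_chi_square(only_low, "frequency")

    def test_length_split_bins_by_target_length(self):
        trials = _trials([
            ("BADE", 0, 30.0), ("LODE", 0, 30.0),          # short, perfect
            ("BADELUM", 4, 30.0), ("LODEKIN", 4, 30.0),    # long, degraded
        ])
        res = effect_test(trials, "length")
        assert res.accuracy_low == 1.0
        assert res.accuracy_high < 1.0
        assert res.p_value < 0.05

    def test_planted_length_effect_detected(self):
        # strongly imbalanced generator output: length effect planted
        from svrlsm.synthetic import SyntheticConfig, simulate_spelling_trials

        config = SyntheticConfig()
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            trials = simulate_spelling_trials(0.6, 0.0, config, rng)
            hits += effect_chi_square(trials, "length") < 0.05
        assert hits >= 0.95 * n_seeds


class TestClassification:
    def test_no_effects_no_ppe_is_none(self):
        trials = _trials([
            ("BADE", 0, 3.0), ("DUNE", 0, 90.0),
            ("BADELUM", 0, 3.0), ("DUNELET", 0, 90.0),
        ])
        profile = classify_deficits(trials, ppe_present=False)
        assert profile.deficit_type == "none"
        assert profile.freq_effect_p == pytest.approx(1.0)

    def test_ppe_alone_drives_oltm(self):
        # phonologically plausible errors mark OLTM damage even with
        # flat chi-square evidence (p = 1 both ways)
        trials = _trials([
            ("BADE", 0, 3.0), ("DUNE", 0, 90.0),
            ("BADELUM", 0, 3.0), ("DUNELET", 0, 90.0),
        ])
        profile = classify_deficits(trials, ppe_present=True)
        assert profile.deficit_type == "OLTM"

    def test_directionality_guard(self):
        # significant effect in the wrong direction (long words spelled
        # better) must not count as an OWM deficit
        # frequency is crossed with length so the frequency test stays flat
        trials = _trials(
            [(t, 3, f) for t, f in (("BADE", 3.0), ("LODE", 3.0), ("MINE", 3.0),
                                    ("RUNE", 90.0), ("SAGE", 90.0), ("TIDE", 90.0))]
            + [(t, 0, f) for t, f in (("BADELUM", 3.0), ("LODEKIN", 3.0),
                                      ("MINERAL", 3.0), ("RUNELET", 90.0),
                                      ("SAGEORS", 90.0), ("TIDEFUL", 90.0))]
        )
        undirected = classify_from_pvalues(
            1.0, False, effect_chi_square(trials, "length"))
        assert undirected.deficit_type == "OWM"  # p alone would misfire
        assert classify_deficits(trials, ppe_present=False).deficit_type == "none"

    def test_planted_owm_participant_recovered(self):
        from svrlsm.synthetic import SyntheticConfig, simulate_spelling_trials

        config = SyntheticConfig()
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            trials = simulate_spelling_trials(0.6, 0.0, config, rng)
            hits += classify_deficits(trials, ppe_present=False).deficit_type == "OWM"
        assert hits >= 18


class TestOwmVariable:
    def test_cohort_counts_and_values(self):
        df = load_table3()
        codes = construct_owm_variable(
            dict(zip(df["participant_id"], df["deficit_type"]))
        )
        values = np.array(list(codes.values()))
        mean = Fraction(-6 + 20, 26)  # mean of the +/-1 codes
        lo, hi = float(-1 - mean), float(1 - mean)
        assert np.sum(np.isclose(values, lo)) == 6
        assert np.sum(np.isclose(values, hi)) == 20
        assert np.sum(values == 0.0) == 11
        coded = values[values != 0.0]
        assert coded.sum() == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_pair(self):
        codes = construct_owm_variable({"p1": "OWM", "p2": "OLTM"})
        assert codes == {"p1": -1.0, "p2": 1.0}

    def test_demean_scope_all(self):
        codes = construct_owm_variable(
            {"a": "OWM", "b": "OLTM", "c": "OWM+OLTM"}, demean_scope="all"
        )
        assert codes["a"] == pytest.approx(-1.0)
        assert codes["b"] == pytest.approx(1.0)
        assert codes["c"] == 0.0

    def test_rejects_unimpaired_participant(self):
        with pytest.raises(InvalidCohortError):
            construct_owm_variable({"a": "OWM", "b": "none"})

    def test_rejects_cohort_without_selective_deficit(self):
        with pytest.raises(InvalidCohortError):
            construct_owm_variable({"a": "OWM+OLTM", "b": "OWM+OLTM"})


class TestZNormalize:
    def test_hand_computed(self):
        out = z_normalize([1, 2, 3])
        assert out == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    def test_idempotent_and_centered(self, rng):
        x = rng.normal(size=25)
        z = z_normalize(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)
        assert z_normalize(z) == pytest.approx(z)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            z_normalize([2.0, 2.0, 2.0])


class TestTable3Fixture:
    def test_shape_and_counts(self):
        df = load_table3()
        assert len(df) == 37
        assert df["deficit_type"].value_counts().to_dict() == {
            "OLTM": 20, "OWM+OLTM": 11, "OWM": 6,
        }

    def test_mk_row_is_ppe_driven_oltm(self):
        df = load_table3().set_index("participant_id")
        row = df.loc["MK"]
        assert row["freq_p"] == "1.000" and row["ppe"] and row["deficit_type"] == "OLTM"

    def test_concordant_rows_reproduced_discordant_listed(self):
        df = load_table3()
        disc = table3_discordances()
        assert set(disc["participant_id"]) == {"ABS", "KMN", "LHT", "MK", "RFZ", "RHN"}
        concordant = df[~df["participant_id"].isin(disc["participant_id"])]
        for row in concordant.itertuples(index=False):
            rule = classify_from_pvalues(
                row.freq_p_value, row.ppe, row.length_p_value
            ).deficit_type
            assert rule == row.deficit_type
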