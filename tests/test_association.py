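import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from wireworm.association import (
    ContingencyTable2x2,
    chi_square_2x2,
    contingency_from_pairs,
    fisher_exact_2x2,
    phi_coefficient,
    yates_chi2_statistic,
)
from wireworm.data import DataError

from conftest import make_pairs

# published species-level presence/absence tables (both-absent, trap-only,
# soil-only, both-present)
BREVIS = (300, 123, 24, 39)
SORDIDUS = (206, 77, 3, 12)
USTULATUS = (139, 159, 10, 27)


def fisher_enumeration_oracle(t: ContingencyTable2x2) -> float:
    """Exhaustive two-sided Fisher p: sum of all same-margin tables whose
    hypergeometric probability is at most the observed one."""
    r0, r1, c0, c1 = t.margins
    n = t.n
    rv = hypergeom(n, r0, c0)  # distribution of cell a
    p_obs = rv.pmf(t.a)
    ks = np.arange(max(0, r0 + c0 - n), min(r0, c0) + 1)
    probs = rv.pmf(ks)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


tables_strategy = st.tuples(
    st.integers(1, 15), st.integers(1, 15), st.integers(1, 15), st.integers(1, 15)
)


class TestContingencyFromPairs:
    def test_mirrors_classification(self):
        t = contingency_from_pairs(make_pairs([0, 0, 1, 3], [0, 2, 0, 4]))
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_empty_input_errors(self):
        with pytest.raises(DataError):
            contingency_from_pairs([])

    def test_all_trap_positive_soil_zero(self):
        t = contingency_from_pairs(make_pairs([0] * 6, [1, 2, 3, 1, 1, 2]))
        assert (t.a, t.b, t.c, t.d) == (0, 6, 0, 0)


class TestChiSquare:
    def test_uncorrected_p_values_match_published(self):
        for cells, expect in [(BREVIS, 2.516e-7), (SORDIDUS, 1.34e-5), (USTULATUS, 0.02353)]:
            res = chi_square_2x2(ContingencyTable2x2(*cells))
            assert res.p_value == pytest.approx(expect, rel=1e-3)

    def test_yates_statistic_matches_published(self):
        res = chi_square_2x2(ContingencyTable2x2(*USTULATUS), continuity_correction=True)
        assert res.statistic == pytest.approx(4.37, abs=0.005)

    def test_proportional_table_is_independent(self):
        res = chi_square_2x2(ContingencyTable2x2(10, 20, 5, 10))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_errors(self):
        with pytest.raises(DataError):
            chi_square_2x2(ContingencyTable2x2(5, 5, 0, 0))

    @given(tables_strategy)
    @settings(max_examples=100, deadline=None)
    def test_yates_is_conservative(self, cells):
        t = ContingencyTable2x2(*cells)
        p_plain = chi_square_2x2(t, continuity_correction=False).p_value
        p_yates = chi_square_2x2(t, continuity_correction=True).p_value
        assert p_yates >= p_plain - 1e-12

    @given(tables_strategy)
    @settings(max_examples=50, deadline=None)
    def test_vectorized_yates_matches_scalar(self, cells):
        t = ContingencyTable2x2(*cells)
        vec = yates_chi2_statistic(*(np.array([c]) for c in cells))[0]
        assert vec == pytest.approx(
            chi_square_2x2(t, continuity_correction=True).statistic, rel=1e-12
        )


class TestFisherExact:
    def test_published_p_values(self):
        assert fisher_exact_2x2(ContingencyTable2x2(*BREVIS)).p_value == pytest.approx(
            6.534e-7, rel=1e-3
        )
        assert fisher_exact_2x2(ContingencyTable2x2(*USTULATUS)).p_value == pytest.approx(
            0.03416, rel=1e-3
        )

    def test_two_by_two_identity_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 0, 0, 1)).p_value == pytest.approx(1.0)

    @given(tables_strategy)
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle(self, cells):
        t = ContingencyTable2x2(*cells)
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            fisher_enumeration_oracle(t), rel=1e-7
        )

    @given(tables_strategy)
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_transpose_and_label_swap(self, cells):
        a, b, c, d = cells
        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
        p_t = fisher_exact_2x2(ContingencyTable2x2(a, c, b, d)).p_value
        p_swap = fisher_exact_2x2(ContingencyTable2x2(d, c, b, a)).p_value
        assert p == pytest.approx(p_t, rel=1e-9)
        assert p == pytest.approx(p_swap, rel=1e-9)


class TestPhi:
    def test_proportional_table_zero(self):
        assert phi_coefficient(ContingencyTable2x2(10, 20, 5, 10)) == pytest.approx(0.0)

    def test_perfect_association(self):
        assert phi_coefficient(ContingencyTable2x2(7, 0, 0, 7)) == pytest.approx(1.0)

    def test_published_species_value(self):
        t = ContingencyTable2x2(*BREVIS)
        assert phi_coefficient(t) == pytest.approx(np.sqrt(26.5896 / 486), abs=1e-3)

    def test_zero_margin_errors(self):
        with pytest.raises(DataError):
            phi_coefficient(ContingencyTable2x2(3, 4, 0, 0))

    @given(tables_strategy)
    @settings(max_examples=100, deadline=None)
    def test_phi_squared_times_n_is_chi2(self, cells):
        t = ContingencyTable2x2(*cells)
        chi2 = chi_square_2x2(t, continuity_correction=False).statistic
        assert phi_coefficient(t) ** 2 * t.n == pytest.approx(chi2, rel=1e-9, abs=1e-12)
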