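import itertools
import math

import numpy as np
import pytest

from introscan.io import TaxonMap
from introscan.dstats import (
    DFOIL_PATTERNS,
    SIGNATURE_TABLE,
    block_jackknife,
    classify_dfoil_signature,
    count_site_patterns,
    count_site_patterns5,
    d_statistic,
    dfoil,
    dfoil_direction,
    pairwise_d_scan,
    patterson_d,
    site_frequencies,
)
from tests.conftest import make_matrix


@pytest.fixture
def quartet_map():
    return TaxonMap({"p1": "T1", "p2": "T2", "p3": "T3", "o": "TO"})


def quartet_matrix(rows, quartet_map, **kwargs):
    return make_matrix(rows, ["p1", "p2", "p3", "o"], quartet_map, **kwargs)


ROLES = {"P1": "p1", "P2": "p2", "P3": "p3", "O": "o"}


class TestPatternCounts:
    def test_heterozygote_products_hand_checked(self, quartet_map):
        # p = (0, 0.5, 1, 0): ABBA = 1*0.5*1*1 = 0.5, BABA = 0
        gm = quartet_matrix([[0, 1, 2, 0]], quartet_map)
        counts = count_site_patterns(gm, ROLES, n_blocks=2)
        assert counts.abba.sum() == pytest.approx(0.5)
        assert counts.baba.sum() == 0.0

    def test_ancestral_p3_contributes_nothing(self, quartet_map):
        gm = quartet_matrix([[2, 2, 0, 0]], quartet_map)
        counts = count_site_patterns(gm, ROLES, n_blocks=2)
        assert counts.abba.sum() == 0.0 and counts.baba.sum() == 0.0

    def test_missing_role_excludes_site(self, quartet_map):
        gm = quartet_matrix([[0, 1, 2, -1], [0, 2, 2, 0]], quartet_map)
        counts = count_site_patterns(gm, ROLES, n_blocks=2)
        assert counts.n_sites_total == 1
        assert counts.abba.sum() == pytest.approx(1.0)

    def test_bad_roles_rejected(self, quartet_map):
        gm = quartet_matrix([[0, 1, 2, 0]], quartet_map)
        with pytest.raises(ValueError):
            count_site_patterns(gm, {"P1": "p1"}, n_blocks=2)


class TestPattersonD:
    def test_symmetric_counts_give_zero(self, quartet_map):
        gm = quartet_matrix([[0, 2, 2, 0], [2, 0, 2, 0]], quartet_map)
        counts = count_site_patterns(gm, ROLES, n_blocks=2)
        assert patterson_d(counts) == 0.0

    def test_pure_abba_gives_one(self, quartet_map):
        gm = quartet_matrix([[0, 2, 2, 0]] * 10, quartet_map)
        counts = count_site_patterns(gm, ROLES, n_blocks=2)
        assert patterson_d(counts) == 1.0

    def test_single_het_site_gives_one(self, quartet_map):
        gm = quartet_matrix([[0, 1, 2, 0]], quartet_map)
        assert patterson_d(count_site_patterns(gm, ROLES, n_blocks=2)) == 1.0

    def test_no_informative_sites_undefined(self, quartet_map):
        gm = quartet_matrix([[2, 0, 0, 0]], quartet_map)
        assert math.isnan(patterson_d(count_site_patterns(gm, ROLES, n_blocks=2)))

    def test_antisymmetry_under_p1_p2_swap(self, quartet_map):
        rng = np.random.default_rng(3)
        gm = quartet_matrix(rng.integers(0, 3, size=(60, 4)), quartet_map)
        d_fwd = patterson_d(count_site_patterns(gm, ROLES, n_blocks=5))
        swapped = {"P1": "p2", "P2": "p1", "P3": "p3", "O": "o"}
        d_rev = patterson_d(count_site_patterns(gm, swapped, n_blocks=5))
        assert d_fwd == pytest.approx(-d_rev)

    def test_frequency_path_equals_discrete_count_oracle(self, quartet_map):
        # all-homozygous data: weighted products reduce to 0/1 indicators
        rng = np.random.default_rng(7)
        dosage = rng.choice([0, 2], size=(200, 4))
        gm = quartet_matrix(dosage, quartet_map)
        counts = count_site_patterns(gm, ROLES, n_blocks=4)
        n_abba = n_baba = 0
        for row in dosage:
            states = tuple(row // 2)
            if states == (0, 1, 1, 0):
                n_abba += 1
            elif states == (1, 0, 1, 0):
                n_baba += 1
        assert counts.abba.sum() == n_abba
        assert counts.baba.sum() == n_baba
        if n_abba + n_baba:
            assert patterson_d(counts) == pytest.approx(
                (n_abba - n_baba) / (n_abba + n_baba)
            )


class TestBlockJackknife:
    def test_worked_example_exact(self):
        # blocks (ABBA, BABA) = (3,1), (2,2), (3,1)
        abba = np.array([3.0, 2.0, 3.0])
        baba = np.array([1.0, 2.0, 1.0])
        res = block_jackknife(abba - baba, abba + baba)
        assert res.d == pytest.approx(1 / 3)
        assert res.se == pytest.approx(1 / 6)
        assert res.z == pytest.approx(2.0)

    def test_identical_blocks_flagged_degenerate(self):
        abba = np.array([2.0, 2.0, 2.0])
        baba = np.array([1.0, 1.0, 1.0])
        res = block_jackknife(abba - baba, abba + baba)
        assert res.degenerate and res.se == 0.0
        assert math.isnan(res.z)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            block_jackknife(np.array([1.0]), np.array([2.0]))

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        num = rng.normal(size=20)
        den = np.abs(rng.normal(size=20)) + 1.0
        a = block_jackknife(num, den)
        b = block_jackknife(7.5 * num, 7.5 * den)
        assert a.d == pytest.approx(b.d) and a.z == pytest.approx(b.z)

    def test_weighted_variant_close_to_unweighted_on_equal_blocks(self):
        abba = np.array([3.0, 2.0, 3.0, 2.5])
        baba = np.array([1.0, 2.0, 1.0, 1.5])
        sites = np.array([10, 10, 10, 10])
        u = block_jackknife(abba - baba, abba + baba, n_sites=sites)
        w = block_jackknife(abba - baba, abba + baba, n_sites=sites, weighted=True)
        assert w.d == pytest.approx(u.d)
        assert w.se == pytest.approx(u.se, rel=0.3)


class TestJackknifeProperties:
    """Ratio-statistic invariants over arbitrary small block tables."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    counts = st.lists(
        st.tuples(st.integers(0, 20), st.integers(0, 20)),
        min_size=3, max_size=12,
    ).filter(lambda rows: sum(a + b for a, b in rows) > 0
             and sum(1 for a, b in rows if a + b > 0) >= 2)

    @given(counts)
    @settings(max_examples=200, deadline=None)
    def test_d_bounded_and_scale_invariant(self, rows):
        abba = np.array([float(a) for a, _ in rows])
        baba = np.array([float(b) for _, b in rows])
        res = block_jackknife(abba - baba, abba + baba)
        assert -1.0 <= res.d <= 1.0
        scaled = block_jackknife(3.0 * (abba - baba), 3.0 * (abba + baba))
        assert scaled.d == pytest.approx(res.d)
        if not res.degenerate:
            assert scaled.z == pytest.approx(res.z)


class TestPairwiseScan:
    def test_row_count_is_product_of_accessions(self):
        tm = TaxonMap({
            "l1": "L", "l2": "L", "c1": "C", "c2": "C", "c3": "C",
            "v1": "V", "o1": "O",
        })
        rng = np.random.default_rng(11)
        gm = make_matrix(rng.integers(0, 3, size=(120, 7)),
                         ["l1", "l2", "c1", "c2", "c3", "v1", "o1"], tm)
        table = pairwise_d_scan(gm, "L", "C", "v1", "o1", n_blocks=5)
        assert len(table) == 6
        assert set(table.columns) >= {"D", "SE", "z", "p", "q_bh"}
        assert (table["z"].abs().diff().dropna() <= 1e-12).all() or \
               (table["z"].abs().is_monotonic_decreasing)


class TestDfoil:
    def test_pattern_sets_are_balanced(self):
        # each statistic uses 4 plus and 4 minus patterns, all distinct
        for name, (plus, minus) in DFOIL_PATTERNS.items():
            assert len(plus) == len(minus) == 4
            assert not (set(plus) & set(minus))

    def test_equal_counts_give_all_zero(self):
        tm = TaxonMap({s: s.upper() for s in ("p1", "p2", "p3", "p4", "o")})
        # every informative pattern appears exactly once, homozygous
        patterns = sorted({p for pl, mi in DFOIL_PATTERNS.values() for p in pl + mi})
        rows = [[2 if c == "B" else 0 for c in pat] for pat in patterns]
        gm = make_matrix(rows, ["p1", "p2", "p3", "p4", "o"], tm)
        counts = count_site_patterns5(
            gm, {"P1": "p1", "P2": "p2", "P3": "p3", "P4": "p4", "O": "o"},
            n_blocks=2,
        )
        res = dfoil(counts)
        for comp in res.components.values():
            assert comp.d == pytest.approx(0.0)
        assert res.signature == ("0", "0", "0", "0")
        assert res.classification == "none"

    def test_classification_table(self):
        assert classify_dfoil_signature(("0", "0", "0", "0")) == "none"
        assert classify_dfoil_signature(("+", "+", "0", "0")) == "ancestral"
        assert classify_dfoil_signature(("-", "-", "0", "0")) == "ancestral"
        assert classify_dfoil_signature(("+", "-", "0", "0")) == "ambiguous"
        assert classify_dfoil_signature(("0", "+", "-", "-")) == "P2<->P3"
        assert classify_dfoil_signature(("+", "0", "+", "+")) == "P1<->P3"

    def test_direction_reading(self):
        assert dfoil_direction(("+", "0", "+", "+")) == "P3=>P1"
        assert dfoil_direction(("+", "+", "0", "0")) == "anc(P1,P2)<->P3"
        assert dfoil_direction(("0", "0", "0", "0")) is None

    def test_signature_rows_respect_taxon_swap_symmetry(self):
        # swapping P1<->P2 swaps DFO<->DIL and negates DFI, DOL;
        # the table must map mirrored signatures to mirrored events
        flip = {"+": "-", "-": "+", "0": "0"}
        for sig, (label, _) in SIGNATURE_TABLE.items():
            mirrored = (sig[1], sig[0], flip[sig[2]], flip[sig[3]])
            if mirrored in SIGNATURE_TABLE:
                mirror_label = SIGNATURE_TABLE[mirrored][0]
                expected = (label
                            .replace("P1", "Px").replace("P2", "P1")
                            .replace("Px", "P2"))
                assert mirror_label == expected
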