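import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orfanscan import reference
from orfanscan.segments import (AssociationRules, abundance_correlation,
                                binarize_ct, call_association,
                                cooccurrence_score, terminal_conservation)
from oracles import pearson_oracle


class TestTerminalConservation:
    def test_identical_prefixes(self):
        a = "ACGT" * 10
        assert terminal_conservation(a, a).mism5 == 0

    def test_single_constructed_mismatch(self):
        a = "A" * 40
        b = "A" * 10 + "C" + "A" * 29
        td = terminal_conservation(a, b, k=20)
        assert (td.mism5, td.mism3) == (1, 0)

    def test_short_sequence_is_error(self):
        with pytest.raises(ValueError):
            terminal_conservation("ACGT", "ACGT" * 10, k=20)

    def test_random_prefix_mean_matches_monte_carlo(self):
        # independent uniform termini: E[mismatches] = 0.75 * k
        rng = np.random.default_rng(123)
        nt = np.array(list("ACGT"))
        total = 0
        trials = 1000
        for _ in range(trials):
            a = "".join(nt[rng.integers(0, 4, size=20)])
            b = "".join(nt[rng.integers(0, 4, size=20)])
            total += terminal_conservation(a, b, k=20).mism5
        mean = total / trials
        assert abs(mean - 15.0) < 3 * np.sqrt(20 * 0.75 * 0.25 / trials)


class TestBinarize:
    def test_rules(self):
        table = pd.DataFrame({"s1": [24.67, 39.0], "s2": [np.nan, 38.0]},
                             index=["v1", "v2"])
        pres = binarize_ct(table, cutoff=38.0)
        assert pres.at["v1", "s1"]          # Ct 24.67: present
        assert not pres.at["v2", "s1"]      # Ct 39: absent
        assert not pres.at["v1", "s2"]      # blank: absent
        assert pres.at["v2", "s2"]          # Ct == cutoff: present

    @given(st.lists(st.floats(min_value=15, max_value=45), min_size=1,
                    max_size=8),
           st.floats(min_value=20, max_value=40),
           st.floats(min_value=0, max_value=5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_cutoff(self, cts, cutoff, bump):
        table = pd.DataFrame([cts])
        low = binarize_ct(table, cutoff=cutoff)
        high = binarize_ct(table, cutoff=cutoff + bump)
        # raising the cutoff never turns a present cell absent
        assert bool((high | ~low).all().all())


class TestCooccurrence:
    def _pres(self):
        return binarize_ct(reference.load_starmerella_ct())

    def test_sbomv1_segments_cosegregate(self):
        pres = self._pres()
        jac, exact, n = cooccurrence_score(pres.loc["SbOMV1_RNA1"],
                                           pres.loc["SbOMV1_RNA2"])
        assert (jac, exact, n) == (1.0, True, 3)

    def test_sbomv1_vs_mitovirus(self):
        # SbMV1 amplifies in Cz1 (Ct 34.43 <= 38) and Cz12, so it shares one
        # of SbOMV1's three positives: |{Cz12}| / |{Cz1,Cz12,Cz16,Cz25}|
        pres = self._pres()
        jac, exact, _ = cooccurrence_score(pres.loc["SbOMV1_RNA1"],
                                           pres.loc["SbMV1"])
        assert jac == pytest.approx(1 / 4)
        assert not exact

    def test_disjoint_sets(self):
        a = pd.Series([True, False], index=["x", "y"])
        b = pd.Series([False, True], index=["x", "y"])
        assert cooccurrence_score(a, b) == (0.0, False, 0)

    def test_both_empty_warns_zero(self, caplog):
        empty = pd.Series([False, False], index=["x", "y"])
        with caplog.at_level("WARNING"):
            jac, exact, n = cooccurrence_score(empty, empty)
        assert (jac, n) == (0.0, 0)

    def test_mismatched_samples_rejected(self):
        a = pd.Series([True], index=["x"])
        b = pd.Series([True], index=["y"])
        with pytest.raises(ValueError):
            cooccurrence_score(a, b)

    def test_symmetry(self):
        pres = self._pres()
        assert cooccurrence_score(pres.loc["SbTV1"], pres.loc["SbMV1"])[0] == \
               cooccurrence_score(pres.loc["SbMV1"], pres.loc["SbTV1"])[0]


class TestAbundanceCorrelation:
    def test_proportional_vectors(self):
        a = pd.Series([10.0, 100.0, 1000.0])
        r, n = abundance_correlation(a, 2 * a)
        # the +1 inside log10(count+1) breaks exact affine invariance, so
        # proportional vectors give r ~ 1 rather than exactly 1
        assert r == pytest.approx(1.0, abs=1e-3)
        assert n == 3

    def test_reference_counts_match_textbook_pearson(self):
        counts = reference.load_counts_wide()
        libs = ["DMGA", "DMGE", "DMGD", "PMA", "PMGA"]
        a = counts.loc["PvlaOMV3_RNA1", libs]
        b = counts.loc["PvlaOMV3_RNA2", libs]
        r, n = abundance_correlation(a, b)
        expected = pearson_oracle(list(np.log10(a + 1)), list(np.log10(b + 1)))
        assert n == 5
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self, caplog):
        a = pd.Series([5.0, 5.0, 5.0])
        b = pd.Series([1.0, 2.0, 3.0])
        with caplog.at_level("WARNING"):
            r, _ = abundance_correlation(a, b)
        assert r is None

    def test_both_zero_libraries_dropped(self):
        a = pd.Series([10.0, 0.0, 20.0, 40.0])
        b = pd.Series([12.0, 0.0, 22.0, 44.0])
        _, n = abundance_correlation(a, b)
        assert n == 3


class TestAssociationCall:
    def test_terminal_alone_is_strong(self):
        from orfanscan.segments import TerminalDistance
        ev = call_association("rna1", "rna2",
                              terminal=TerminalDistance(20, 1, 0))
        assert ev.call == "associated"
        assert ev.grades == ["STRONG"]

    def test_moderate_plus_weak_associates(self):
        ev = call_association("rna1", "rna2",
                              cooccurrence=(1.0, True, 3),
                              abundance=(0.95, 5))
        assert set(ev.grades) == {"MODERATE", "WEAK"}
        assert ev.call == "associated"

    def test_weak_alone_is_unresolved(self):
        ev = call_association("rna1", "rna2", abundance=(0.95, 5))
        assert ev.grades == ["WEAK"]
        assert ev.call == "unresolved"

    def test_moderate_needs_enough_shared_positives(self):
        ev = call_association("rna1", "rna2", cooccurrence=(1.0, True, 1),
                              abundance=(0.99, 5))
        assert ev.call == "unresolved"

    def test_thresholds_configurable(self):
        from orfanscan.segments import TerminalDistance
        strict = AssociationRules(max_mism5=0)
        ev = call_association("a", "b", terminal=TerminalDistance(20, 1, 0),
                              rules=strict)
        assert ev.call == "unresolved"
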