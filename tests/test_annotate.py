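"""Accurate-mass algebra: formulas, adducts, ppm matching, head groups."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedlip import (DEFAULT_RULES, AdductRule, adduct_mz, classify_headgroup,
                      monoisotopic_mass, parse_formula, ppm_match)
from breedlip.masses import C13_DELTA

# independent constants table for the brute-force oracle (CODATA/AME values
# transcribed separately from the implementation's table)
ORACLE_MASS = {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "P": 30.973761630,
    "S": 31.972071000,
}
ORACLE_ELECTRON = 5.48579909e-4


def oracle_mz(counts: dict, extra: dict, charge: int = 1, n_c13: int = 0) -> float:
    """Naive per-atom summation, one atom at a time."""
    total = 0.0
    merged: dict = {}
    for d in (counts, extra):
        for el, n in d.items():
            merged[el] = merged.get(el, 0) + n
    for el, n in merged.items():
        for _ in range(abs(n)):
            total += np.sign(n) * ORACLE_MASS[el]
    total += n_c13 * 1.0033548
    total -= charge * ORACLE_ELECTRON
    return total / abs(charge)


class TestParseFormula:
    @pytest.mark.parametrize("text,expected", [
        ("H2O", {"H": 2, "O": 1}),
        ("C39H78NO8P", {"C": 39, "H": 78, "N": 1, "O": 8, "P": 1}),
        ("C_39_H_78_NO_8_P", {"C": 39, "H": 78, "N": 1, "O": 8, "P": 1}),
        ("C3H9N", {"C": 3, "H": 9, "N": 1}),
    ])
    def test_parses_counts_with_implicit_ones(self, text, expected):
        assert parse_formula(text).composition == expected

    def test_unknown_element_rejected_with_position(self):
        with pytest.raises(ValueError, match="X"):
            parse_formula("C39X2")

    @pytest.mark.parametrize("bad", ["", "39C", "c3h9"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestMonoisotopicMass:
    def test_single_atom(self):
        assert monoisotopic_mass({"H": 1}) == pytest.approx(1.00782503, abs=1e-7)

    def test_water_hand_sum(self):
        # 2 * 1.00782503207 + 15.9949146196 = 18.0105647
        assert monoisotopic_mass("H2O") == pytest.approx(18.0105646, abs=1e-6)

    def test_lipid_composition_against_oracle(self):
        got = monoisotopic_mass("C39H78NO8P")
        want = sum(n * ORACLE_MASS[el]
                   for el, n in {"C": 39, "H": 78, "N": 1, "O": 8, "P": 1}.items())
        assert got == pytest.approx(want, rel=1e-9)
        assert got == pytest.approx(719.5465051, abs=1e-5)


# Published theoretical m/z values for the positive-mode ions of known
# lipid-range compositions (printed to 6 decimals in the source tables).
GOLDEN = [
    ("C39H78NO8P", "[M+H]1+", 720.553784),
    ("C41H82NO8P", "[M+H]1+", 748.585084),
    ("C41H82NO8P", "[M+H]1+ 13C", 749.588438),
    ("C43H86NO8P", "[M+H]1+", 776.616384),
    ("C18H34", "[M+NH4]1+", 268.299877),
    ("C18H36", "[M+NH4]1+", 270.315527),
    ("C17H34O2", "[M+NH4]1+", 288.289706),
    ("C15H30O", "[M+NH4]1+", 244.263491),
    ("C17H34", "[M+NH4]1+", 256.299877),
    ("C14H28", "[M+NH4]1+", 214.252926),
]


class TestAdductMz:
    @pytest.mark.parametrize("formula,rule,expected", GOLDEN)
    def test_published_theoretical_mz(self, formula, rule, expected):
        assert adduct_mz(formula, DEFAULT_RULES[rule]) == pytest.approx(
            expected, abs=1e-4)

    def test_isotopologue_spacing_exact(self):
        base = adduct_mz("C41H82NO8P", DEFAULT_RULES["[M+H]1+"])
        iso = adduct_mz("C41H82NO8P", DEFAULT_RULES["[M+H]1+ 13C"])
        assert iso - base == pytest.approx(C13_DELTA, abs=1e-12)

    def test_nh4_vs_h_difference_constant(self):
        for f in ("C10H20", "C39H78NO8P", "C5H5N5"):
            d = (adduct_mz(f, DEFAULT_RULES["[M+NH4]1+"])
                 - adduct_mz(f, DEFAULT_RULES["[M+H]1+"]))
            assert d == pytest.approx(17.026549, abs=1e-5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="removes more"):
            adduct_mz("C10H20", AdductRule("[M-N]1+", {"N": -1}, charge=1))

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            AdductRule("bad", {"H": 1}, charge=0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        c=st.integers(0, 60), h=st.integers(0, 120), n=st.integers(0, 3),
        o=st.integers(0, 10), p=st.integers(0, 2), s=st.integers(0, 2),
        rule_name=st.sampled_from(["[M+H]1+", "[M+NH4]1+", "[M+H]1+ 13C"]),
    )
    def test_matches_per_atom_oracle(self, c, h, n, o, p, s, rule_name):
        counts = {k: v for k, v in
                  zip("CHNOPS", (c, h, n, o, p, s)) if v > 0}
        if not counts:
            return
        rule = DEFAULT_RULES[rule_name]
        got = adduct_mz(counts, rule)
        want = oracle_mz(counts, dict(rule.delta), rule.charge, rule.n_c13)
        assert got == pytest.approx(want, rel=1e-6)


class TestPpmMatch:
    CAND = [(parse_formula("C39H78NO8P"), DEFAULT_RULES["[M+H]1+"], "PC(31:0)")]

    def test_observed_within_window(self):
        hits = ppm_match(720.5525, self.CAND, window_ppm=5)
        assert len(hits) == 1
        assert hits[0].ppm_error == pytest.approx(-1.78, abs=0.05)
        assert hits[0].putative_name == "PC(31:0)"

    def test_exact_match_zero_ppm(self):
        theo = adduct_mz("C39H78NO8P", DEFAULT_RULES["[M+H]1+"])
        assert ppm_match(theo, self.CAND)[0].ppm_error == 0.0

    def test_far_outside_window_no_match(self):
        theo = adduct_mz("C39H78NO8P", DEFAULT_RULES["[M+H]1+"])
        assert ppm_match(theo * 1.01, self.CAND) == []

    def test_sorted_by_abs_ppm(self):
        cands = [(parse_formula(f), DEFAULT_RULES["[M+H]1+"])
                 for f in ("C39H78NO8P", "C40H82NO7P")]
        hits = ppm_match(720.5535, cands, window_ppm=200)
        errs = [abs(h.ppm_error) for h in hits]
        assert errs == sorted(errs)


class TestHeadgroup:
    def test_pc_sm_requires_both_fragments(self):
        assert classify_headgroup(720.5538, [184.0733, 661.4803]) == ["PC/SM"]
        assert classify_headgroup(720.5538, [184.0733]) == []  # no neutral loss
        assert classify_headgroup(720.5538, [661.4803]) == []  # no 184 peak

    def test_pe_neutral_loss(self):
        assert classify_headgroup(720.5538, [579.5347]) == ["PE"]

    def test_ps_neutral_loss(self):
        assert classify_headgroup(720.5538, [535.5449]) == ["PS"]

    def test_no_hits_empty_labels(self):
        assert classify_headgroup(720.5538, [100.0, 200.0]) == []

    def test_empty_fragments_rejected(self):
        with pytest.raises(ValueError):
            classify_headgroup(720.5538, [])
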