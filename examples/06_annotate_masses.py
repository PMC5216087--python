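"""Annotate observed accurate masses with adduct rules and head-group logic.

Computes theoretical m/z for candidate lipid compositions under positive-
mode ionisation rules, matches an observed signal within a ppm window, and
calls phospholipid head-group classes from tandem-MS fragment evidence.
"""

from breedlip import (DEFAULT_RULES, adduct_mz, classify_headgroup,
                      parse_formula, ppm_match)
from breedlip.annotate import bundled_formulas

# 1. theoretical m/z from first principles
pc310 = parse_formula("C39H78NO8P")
mh = DEFAULT_RULES["[M+H]1+"]
print(f"{pc310} [M+H]+  -> m/z {adduct_mz(pc310, mh):.6f}")
print(f"{pc310} [M+H]+ 13C -> m/z {adduct_mz(pc310, mh.isotopologue()):.6f}")

# 2. ppm matching of an observed signal against the bundled lipid table
observed = 720.5525
cands = [(f, rule, name) for f, name in bundled_formulas()
         for rule in DEFAULT_RULES.values() if rule.charge > 0]
for hit in ppm_match(observed, cands, window_ppm=5):
    print(f"observed {observed} ~ {hit.formula} {hit.rule.name} "
          f"(theoretical {hit.theoretical_mz:.6f}, "
          f"{hit.ppm_error:+.2f} ppm) {hit.putative_name}")
# a |ppm| <= 5 match is a putative annotation; confirmation needs fragments:

# 3. head-group diagnostics from tandem-MS fragments
frags = [184.0733, 661.4803]  # phosphocholine head + trimethylamine loss
labels = classify_headgroup(720.5538, frags)
print(f"precursor 720.5538 with fragments {frags} -> {labels}")
# both the m/z 184.07 head-group fragment and the -59.07 neutral loss are
# required before a choline phospholipid (PC/SM) call is made.
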