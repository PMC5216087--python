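"""Rule-based accurate-mass annotation of lipidomics signals.

Implements the algebra behind adduct/neutral-loss annotation of
electrospray signals: elemental formulas, monoisotopic masses, adduct and
isotopologue rules, ppm matching of observed m/z against candidate
compositions, and head-group fragment diagnostics for choline/ethanolamine/
serine phospholipids.

All theoretical m/z values are computed from first principles (atomic
masses, electron-mass correction); nothing is looked up from a spectrum
database, so the module works fully offline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .masses import C13_DELTA, ELECTRON_MASS, MONOISOTOPIC_MASS

__all__ = [
    "Formula",
    "AdductRule",
    "Annotation",
    "FragmentRule",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_match",
    "classify_headgroup",
    "DEFAULT_RULES",
    "FRAGMENT_RULES",
    "load_rules",
    "bundled_formulas",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition, e.g. C39H78NO8P.

    ``composition`` maps element symbol to a non-negative count; at least one
    element must be positive.
    """

    composition: Mapping[str, int]

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        for el, n in comp.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")
        if not any(n > 0 for n in comp.values()):
            raise ValueError("empty formula: no element with positive count")
        object.__setattr__(self, "composition", comp)

    def __str__(self) -> str:  # Hill-ish ordering: C, H, then alphabetical
        comp = {e: n for e, n in self.composition.items() if n}
        order = [e for e in ("C", "H") if e in comp]
        order += sorted(e for e in comp if e not in ("C", "H"))
        return "".join(f"{e}{comp[e] if comp[e] != 1 else ''}" for e in order)


def parse_formula(text: str) -> Formula:
    """Parse Hill-like formula notation into a :class:`Formula`.

    Underscores and whitespace (subscript markers in table text) are
    stripped, so ``"C_39_H_78_NO_8_P"`` and ``"C39H78NO8P"`` are equivalent.
    Implicit counts are 1 (the N in C39H78NO8P).
    """
    cleaned = text.replace("_", "").replace(" ", "")
    if not cleaned:
        raise ValueError("empty formula string")
    comp: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if not m or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, count = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(
                f"unknown element symbol {el!r} in {text!r} at position {pos}"
            )
        comp[el] = comp.get(el, 0) + (int(count) if count else 1)
        pos = m.end()
    return Formula(comp)


def _as_formula(formula: Formula | Mapping[str, int] | str) -> Formula:
    if isinstance(formula, Formula):
        return formula
    if isinstance(formula, str):
        return parse_formula(formula)
    return Formula(formula)


def monoisotopic_mass(formula: Formula | Mapping[str, int] | str) -> float:
    """Neutral monoisotopic mass in Da (sum of per-atom monoisotopic masses)."""
    f = _as_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.composition.items())


@dataclass(frozen=True)
class AdductRule:
    """An ionisation rule mapping a neutral composition to an observed ion.

    ``delta`` is the element-count change of the rule (e.g. +1 H for
    [M+H]+), ``charge`` the signed ion charge, and ``n_c13`` the number of
    12C atoms replaced by 13C in the isotopologue variant.
    """

    name: str
    delta: Mapping[str, int] = field(default_factory=dict)
    charge: int = 1
    n_c13: int = 0

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("ionic rules must carry a non-zero charge")
        object.__setattr__(self, "delta", dict(self.delta))

    def isotopologue(self, n_c13: int = 1) -> "AdductRule":
        """Return the same rule shifted by ``n_c13`` 13C substitutions."""
        return replace(self, name=f"{self.name} {n_c13}x13C", n_c13=n_c13)


def adduct_mz(formula: Formula | Mapping[str, int] | str, rule: AdductRule) -> float:
    """Theoretical m/z of ``formula`` ionised under ``rule``.

    m/z = (mono mass of M+delta + n_c13 * (13C-12C) - charge * m_e) / |charge|.
    The electron-mass correction is mandatory: omitting it is a ~0.8 ppm
    error at m/z 700, comparable to the matching window.
    """
    f = _as_formula(formula)
    comp = dict(f.composition)
    for el, dn in rule.delta.items():
        comp[el] = comp.get(el, 0) + dn
        if comp[el] < 0:
            raise ValueError(
                f"rule {rule.name!r} removes more {el} than {f} contains"
            )
    ion_mass = (
        monoisotopic_mass({e: n for e, n in comp.items() if n > 0})
        + rule.n_c13 * C13_DELTA
        - rule.charge * ELECTRON_MASS
    )
    return ion_mass / abs(rule.charge)


#: Positive-mode rules covering the adduct/isotopologue patterns seen in
#: first-pass lipid profiles.
DEFAULT_RULES: dict[str, AdductRule] = {
    r.name: r
    for r in (
        AdductRule("[M+H]1+", {"H": 1}, charge=1),
        AdductRule("[M+H]1+ 13C", {"H": 1}, charge=1, n_c13=1),
        AdductRule("[M+NH4]1+", {"N": 1, "H": 4}, charge=1),
        AdductRule("[M+NH4]1+ 13C", {"N": 1, "H": 4}, charge=1, n_c13=1),
        AdductRule("[M+Na]1+", {"Na": 1}, charge=1),
        AdductRule("[M-H]1-", {"H": -1}, charge=-1),
    )
}


@dataclass(frozen=True)
class Annotation:
    """One candidate annotation of an observed signal."""

    observed_mz: float
    formula: Formula
    rule: AdductRule
    theoretical_mz: float
    ppm_error: float
    putative_name: str = ""
    msi_level: int = 3  # 2 when fragment evidence supports the head group
    feature_name: str = ""


def ppm_match(
    observed_mz: float,
    candidates: Iterable[tuple],
    window_ppm: float = 5.0,
) -> list[Annotation]:
    """Match an observed m/z against candidate (formula, rule[, name]) tuples.

    Returns annotations whose |ppm error| <= ``window_ppm``, sorted by
    absolute ppm error (best first).
    """
    if window_ppm <= 0:
        raise ValueError("window_ppm must be positive")
    hits: list[Annotation] = []
    for cand in candidates:
        formula, rule = cand[0], cand[1]
        name = cand[2] if len(cand) > 2 else ""
        theo = adduct_mz(formula, rule)
        ppm = 1e6 * (observed_mz - theo) / theo
        if abs(ppm) <= window_ppm:
            hits.append(
                Annotation(
                    observed_mz=observed_mz,
                    formula=_as_formula(formula),
                    rule=rule,
                    theoretical_mz=theo,
                    ppm_error=ppm,
                    putative_name=name,
                )
            )
    hits.sort(key=lambda a: abs(a.ppm_error))
    return hits


@dataclass(frozen=True)
class FragmentRule:
    """A diagnostic fragment or neutral loss implying a lipid class."""

    name: str
    kind: str  # "diagnostic_fragment" | "neutral_loss"
    value: float  # fragment m/z, or neutral-loss mass in Da
    implies: str

    def __post_init__(self) -> None:
        if self.kind not in ("diagnostic_fragment", "neutral_loss"):
            raise ValueError(f"unknown fragment-rule kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError("fragment-rule value must be positive")


# Head-group diagnostics. Masses derived from compositions, not the nominal
# 184/59/141/185 shorthand: phosphocholine fragment C5H15NO4P+ (as a cation),
# trimethylamine loss C3H9N, phosphoethanolamine head loss C2H8NO4P,
# phosphoserine head loss C3H8NO6P.
_PHOSPHOCHOLINE_FRAGMENT = monoisotopic_mass("C5H15NO4P") - ELECTRON_MASS  # 184.0733
_TRIMETHYLAMINE_LOSS = monoisotopic_mass("C3H9N")  # 59.0735
_PE_HEAD_LOSS = monoisotopic_mass("C2H8NO4P")  # 141.0191
_PS_HEAD_LOSS = monoisotopic_mass("C3H8NO6P")  # 185.0089

FRAGMENT_RULES: tuple[FragmentRule, ...] = (
    FragmentRule("phosphocholine head", "diagnostic_fragment",
                 _PHOSPHOCHOLINE_FRAGMENT, "PC/SM"),
    FragmentRule("trimethylamine loss", "neutral_loss",
                 _TRIMETHYLAMINE_LOSS, "PC/SM"),
    FragmentRule("phosphoethanolamine head loss", "neutral_loss",
                 _PE_HEAD_LOSS, "PE"),
    FragmentRule("phosphoserine head loss", "neutral_loss",
                 _PS_HEAD_LOSS, "PS"),
)


def classify_headgroup(
    precursor_mz: float,
    fragment_mzs: Sequence[float],
    tol_mz: float = 0.01,
) -> list[str]:
    """Call phospholipid head-group classes from MSn fragment evidence.

    PC/SM requires both the m/z 184.0733 phosphocholine fragment and an
    [M+H-59]+ trimethylamine-loss peak; PE and PS are each called from their
    single characteristic head-group neutral loss. Labels accumulate, so
    ambiguous evidence is preserved rather than resolved.
    """
    if len(fragment_mzs) == 0:
        raise ValueError("fragment list must be non-empty")

    def seen(target: float) -> bool:
        return any(abs(f - target) <= tol_mz for f in fragment_mzs)

    labels: list[str] = []
    if seen(_PHOSPHOCHOLINE_FRAGMENT) and seen(precursor_mz - _TRIMETHYLAMINE_LOSS):
        labels.append("PC/SM")
    if seen(precursor_mz - _PE_HEAD_LOSS):
        labels.append("PE")
    if seen(precursor_mz - _PS_HEAD_LOSS):
        labels.append("PS")
    return labels


def load_rules(path: str | Path) -> dict[str, AdductRule]:
    """Load an adduct-rule registry from editable JSON.

    Format: ``{"name": {"delta": {"H": 1}, "charge": 1, "n_c13": 0}, ...}``.
    """
    raw = json.loads(Path(path).read_text())
    return {
        name: AdductRule(name, spec.get("delta", {}), spec.get("charge", 1),
                         spec.get("n_c13", 0))
        for name, spec in raw.items()
    }


def bundled_formulas() -> list[tuple[Formula, str]]:
    """Small bundled table of lipid elemental compositions with names."""
    path = Path(__file__).parent / "data" / "lipid_formulas.tsv"
    out: list[tuple[Formula, str]] = []
    for line in path.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        formula, name = line.split("\t")[:2]
        out.append((parse_formula(formula), name))
    return out
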