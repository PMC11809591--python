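"""Elemental-formula algebra, isotope tables and fragment bookkeeping.

Monoisotopic masses of derivatized metabolite ions, neutral-loss arithmetic for
in-source fragments (EI radical dissociations, APCI neutral eliminations from
[M + H]+), and forward isotopologue-pattern models used by the natural-isotope
abundance (NIA) correction.

Mass-spectrometric conventions: a fragment of a TMS/MEOX-derivatized metabolite
carries two kinds of carbon — *labelable* carbons inherited from the parent
metabolite (subject to tracer labeling) and *derivatization* carbons from the
silyl/methoxyamine moieties, which only ever carry natural-abundance isotopes.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "AMBIENT_13C_FRACTION",
    "ElementIsotopes",
    "MolecularFormula",
    "FragmentSpec",
    "NeutralLoss",
    "FormulaError",
    "isotope_table",
    "parse_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "isotope_mass_shift",
    "apply_loss",
    "derive_fragment",
    "theoretical_isotopologue_pattern",
    "natural_shift_distribution",
    "load_fragment_library",
    "STANDARD_LOSSES",
]

#: CODATA electron mass in amu; subtracted once per positive charge so that
#: reported m/z refers to the ion, not the neutral.
ELECTRON_MASS = 0.000548579909065

#: Ambient 13C fraction used throughout this package (1.109 % 13C in ambient
#: carbon); override via ``isotope_table(p13_natural=...)``.
AMBIENT_13C_FRACTION = 0.01109


class FormulaError(ValueError):
    """Malformed or chemically impossible molecular formula."""


@dataclass(frozen=True)
class ElementIsotopes:
    """Stable isotopes of one element: (mass in amu, abundance fraction)."""

    symbol: str
    isotopes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.isotopes]
        total = sum(a for _, a in self.isotopes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.symbol}: abundances sum to {total}, not 1")
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError(f"{self.symbol}: isotope masses must be strictly increasing")

    @property
    def monoisotopic(self) -> float:
        return self.isotopes[0][0]

    def shift_distribution(self) -> np.ndarray:
        """Probability over integer mass shifts relative to the lightest isotope."""
        shifts = [int(round(m - self.monoisotopic)) for m, _ in self.isotopes]
        out = np.zeros(max(shifts) + 1)
        for s, (_, a) in zip(shifts, self.isotopes):
            out[s] += a
        return out


# Atomic masses: AME2020; abundances: IUPAC representative values. Carbon is the
# exception — its 13C fraction defaults to the ambient 1.109 % convention and is
# user-configurable, since tracer experiments correct against ambient carbon.
_MASSES = {
    "H": ((1.00782503224, 0.999885), (2.01410177812, 0.000115)),
    "C": None,  # built per requested 13C abundance
    "N": ((14.00307400443, 0.99636), (15.00010889888, 0.00364)),
    "O": ((15.99491461957, 0.99757), (16.99913175650, 0.00038), (17.99915961286, 0.00205)),
    "P": ((30.97376199842, 1.0),),
    "S": ((31.97207117441, 0.9499), (32.97145890982, 0.0075),
          (33.96786700400, 0.0425), (35.96708071000, 0.0001)),
    "Si": ((27.97692653465, 0.92223), (28.97649466490, 0.04685), (29.97377013600, 0.03092)),
}

_MASS_12C = 12.0
_MASS_13C = 13.00335483507


def isotope_table(p13_natural: float = AMBIENT_13C_FRACTION) -> dict[str, ElementIsotopes]:
    """Isotope table with a configurable ambient 13C abundance."""
    if not 0.0 <= p13_natural < 1.0:
        raise ValueError("p13_natural must be in [0, 1)")
    table = {}
    for symbol, iso in _MASSES.items():
        if symbol == "C":
            iso = ((_MASS_12C, 1.0 - p13_natural), (_MASS_13C, p13_natural))
        table[symbol] = ElementIsotopes(symbol, tuple(iso))
    return table


_DEFAULT_TABLE = isotope_table()

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts plus a signed integer charge."""

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("formula must contain at least one element")
        for el, n in self.counts:
            if n < 0:
                raise FormulaError(f"negative count for element {el}")

    @classmethod
    def from_dict(cls, counts: dict[str, int], charge: int = 0) -> "MolecularFormula":
        items = tuple(sorted((el, n) for el, n in counts.items() if n != 0))
        return cls(items, charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def count(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula.from_dict(merged, self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"cannot subtract {other}: negative count for element {el}"
                )
        return MolecularFormula.from_dict(merged, self.charge - other.charge)

    def __str__(self) -> str:  # Hill notation
        d = self.as_dict()
        parts = []
        for el in ("C", "H"):
            if el in d:
                n = d.pop(el)
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(d):
            n = d[el]
            parts.append(el + (str(n) if n > 1 else ""))
        sign = ""
        if self.charge:
            sign = ("+" if self.charge > 0 else "-") * abs(self.charge)
        return "".join(parts) + sign


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string, e.g. ``"C15H39O7PSi4"``.

    An optional trailing ``+`` or ``-`` sets a single positive/negative charge;
    no in-formula isotope syntax (tracer labeling is handled separately).
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    body = text.strip()
    charge = 0
    while body and body[-1] in "+-":
        charge += 1 if body[-1] == "+" else -1
        body = body[:-1]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _FORMULA_TOKEN.match(body, pos)
        if not m or not m.group(1):
            raise FormulaError(f"unparseable token at {body[pos:]!r} in {text!r}")
        el, num = m.group(1), m.group(2)
        if el not in _MASSES:
            raise FormulaError(f"unrecognized element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if not counts:
        raise FormulaError(f"no elements found in {text!r}")
    return MolecularFormula.from_dict(counts, charge)


def monoisotopic_mass(
    formula: MolecularFormula | str,
    table: dict[str, ElementIsotopes] | None = None,
) -> float:
    """Monoisotopic mass (neutral) or m/z (charged ion, electron-mass corrected).

    For a charge of ±q the electron masses are subtracted/added and the result
    divided by |q|, because instruments report ion m/z, not neutral mass.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    table = table or _DEFAULT_TABLE
    mass = 0.0
    for el, n in formula.counts:
        if el not in table:
            raise FormulaError(f"unknown element {el!r}")
        mass += n * table[el].monoisotopic
    if formula.charge:
        mass -= formula.charge * ELECTRON_MASS
        mass /= abs(formula.charge)
    return mass


def nominal_mass(formula: MolecularFormula | str) -> int:
    """Integer-rounded monoisotopic mass; used only for fragment naming."""
    return int(round(monoisotopic_mass(formula)))


def isotope_mass_shift(n_13c: int) -> float:
    """Mass shift caused by ``n_13c`` 12C→13C exchanges (+1.0034 amu each)."""
    if n_13c < 0:
        raise ValueError("n_13c must be >= 0")
    return n_13c * (_MASS_13C - _MASS_12C)


@dataclass(frozen=True)
class NeutralLoss:
    """A neutral loss (radical or closed-shell) removable from a parent ion."""

    name: str
    formula: MolecularFormula
    carbons_removed: frozenset[int] = frozenset()


_H = MolecularFormula.from_dict({"H": 1})

#: Neutral losses referenced by the shipped fragment library. EI dissociations
#: release radicals from [M]+; APCI eliminations remove closed-shell neutrals
#: from [M + H]+.
STANDARD_LOSSES: dict[str, NeutralLoss] = {
    "CH3": NeutralLoss("CH3", parse_formula("CH3")),
    "CH4": NeutralLoss("CH4", parse_formula("CH4")),
    "TMSOH": NeutralLoss("TMSOH", parse_formula("C3H10OSi")),
    "TMSCOO": NeutralLoss("TMSCOO", parse_formula("C4H9O2Si"), frozenset({1})),
    "TMSCOOH": NeutralLoss("TMSCOOH", parse_formula("C4H10O2Si"), frozenset({1})),
    "CO": NeutralLoss("CO", parse_formula("CO"), frozenset({1})),
    "CO2": NeutralLoss("CO2", parse_formula("CO2"), frozenset({1})),
}


def apply_loss(
    parent: MolecularFormula,
    loss: NeutralLoss | None,
    protonate: bool = False,
) -> MolecularFormula:
    """Fragment formula after a neutral loss; charge fixed at +1.

    ``protonate=True`` models the APCI route: one H is added ([M + H]+) before
    the neutral elimination. ``loss=None`` (or an empty loss) is the identity.
    """
    f = parent
    if protonate:
        f = f + _H
    if loss is not None:
        f = f - loss.formula
    return MolecularFormula.from_dict(f.as_dict(), charge=+1)


@dataclass(frozen=True)
class FragmentSpec:
    """A measurable ion and its parent-carbon bookkeeping.

    ``retained_positions`` are the parent-metabolite carbon positions still
    present in the fragment (the labelable carbons); derivatization carbons
    come from TMS/MEOX moieties and are never tracer-labeled.
    """

    id: str
    formula: MolecularFormula
    retained_positions: frozenset[int]
    n_derivatization_carbons: int
    instrument_mode: str = "APCI"
    note: str = ""

    def __post_init__(self) -> None:
        n_c = self.formula.count("C")
        if len(self.retained_positions) + self.n_derivatization_carbons != n_c:
            raise ValueError(
                f"{self.id}: labelable ({len(self.retained_positions)}) + derivatization "
                f"({self.n_derivatization_carbons}) carbons != total C ({n_c})"
            )

    @property
    def n_labelable_carbons(self) -> int:
        return len(self.retained_positions)


def derive_fragment(
    parent: FragmentSpec,
    loss: NeutralLoss,
    fragment_id: str,
    protonate: bool = False,
) -> FragmentSpec:
    """Apply a neutral loss to a parent species, tracking retained positions."""
    formula = apply_loss(parent.formula, loss, protonate=protonate)
    retained = parent.retained_positions - loss.carbons_removed
    n_deriv = formula.count("C") - len(retained)
    if n_deriv < 0:
        raise ValueError(f"{fragment_id}: loss removes more carbons than available")
    return FragmentSpec(
        id=fragment_id,
        formula=formula,
        retained_positions=frozenset(retained),
        n_derivatization_carbons=n_deriv,
        instrument_mode=parent.instrument_mode,
    )


def _binomial_vector(n: int, p: float) -> np.ndarray:
    k = np.arange(n + 1)
    from scipy.stats import binom

    return binom.pmf(k, n, p)


def _convolve_power(dist: np.ndarray, n: int, max_len: int) -> np.ndarray:
    """``dist`` convolved with itself ``n`` times, truncated to ``max_len``."""
    result = np.array([1.0])
    base = dist.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:max_len]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:max_len]
    return result


def natural_shift_distribution(
    formula: MolecularFormula | str,
    table: dict[str, ElementIsotopes] | None = None,
    skip_carbon: int = 0,
    carbon_only: bool = False,
    max_len: int = 64,
) -> np.ndarray:
    """Natural-abundance isotopologue pattern (integer mass-shift distribution).

    ``skip_carbon`` carbons are excluded (they are handled separately as
    labelable positions). ``carbon_only=True`` ignores heavy isotopes of all
    non-carbon elements — appropriate when high mass resolution separates e.g.
    29Si/30Si isotopologues from 13C isotopologues.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    table = table or _DEFAULT_TABLE
    pattern = np.array([1.0])
    for el, n in formula.counts:
        if el == "C":
            n -= skip_carbon
            if n < 0:
                raise ValueError("skip_carbon exceeds carbon count")
        elif carbon_only:
            continue
        if n == 0:
            continue
        pattern = np.convolve(pattern, _convolve_power(table[el].shift_distribution(), n, max_len))[:max_len]
    return pattern


def theoretical_isotopologue_pattern(
    frag: FragmentSpec,
    p13_labelable: float,
    p13_natural: float = AMBIENT_13C_FRACTION,
    purity: float = 1.0,
    carbon_only: bool = False,
    length: int | None = None,
) -> np.ndarray:
    """Forward model of an observed isotopologue abundance pattern.

    Each labelable position is tracer-derived with probability
    ``p13_labelable`` (carrying 13C with probability ``purity``) and otherwise
    ambient (13C with probability ``p13_natural``); derivatization carbons and
    all non-carbon elements contribute their natural-abundance patterns.
    Returns a probability vector over M+0 … (sums to 1 before truncation).
    """
    for name, p in (("p13_labelable", p13_labelable), ("p13_natural", p13_natural),
                    ("purity", purity)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    q = p13_labelable * purity + (1.0 - p13_labelable) * p13_natural
    n_lab = frag.n_labelable_carbons
    pattern = _binomial_vector(n_lab, q) if n_lab else np.array([1.0])
    table = isotope_table(p13_natural)
    nat = natural_shift_distribution(
        frag.formula, table=table, skip_carbon=n_lab, carbon_only=carbon_only
    )
    pattern = np.convolve(pattern, nat)
    if length is not None:
        full = np.zeros(length)
        k = min(length, len(pattern))
        full[:k] = pattern[:k]
        pattern = full
    return pattern


def _parse_positions(text: str) -> frozenset[int]:
    text = text.strip()
    if not text or text == "-":
        return frozenset()
    return frozenset(int(p) for p in text.split(","))


def load_fragment_library(path=None) -> dict[tuple[str, str], FragmentSpec]:
    """Load the fragment library TSV, keyed by (fragment id, instrument mode).

    The shipped default covers the 3PGA (4TMS) fragments 459 and 357, the G6P
    (1MEOX)(6TMS) fragment 706, the phosphate-moiety qualifier fragments
    299/315, and the sorbitol/glucose [M + H − CH4]+ ions. User libraries with
    the same columns extend or replace it.
    """
    if path is None:
        ref = importlib.resources.files("posiso") / "data" / "fragments.tsv"
        lines = ref.read_text().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    header = None
    library: dict[tuple[str, str], FragmentSpec] = {}
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        formula = parse_formula(row["formula"])
        spec = FragmentSpec(
            id=row["id"],
            formula=formula,
            retained_positions=_parse_positions(row["retained_positions"]),
            n_derivatization_carbons=int(row["n_derivatization_carbons"]),
            instrument_mode=row["instrument_mode"],
            note=row.get("note", ""),
        )
        library[(spec.id, spec.instrument_mode)] = spec
    return library


def get_fragment(
    library: dict[tuple[str, str], FragmentSpec], fragment_id: str, mode: str | None = None
) -> FragmentSpec:
    """Look up a fragment by id, optionally disambiguating by instrument mode."""
    if mode is not None:
        key = (fragment_id, mode)
        if key in library:
            return library[key]
        raise KeyError(f"fragment {fragment_id!r} ({mode}) not in library")
    matches = [spec for (fid, _), spec in library.items() if fid == fragment_id]
    if not matches:
        raise KeyError(f"fragment {fragment_id!r} not in library")
    return matches[0]
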