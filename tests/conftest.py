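"""Shared fixtures and independent oracles for the test suite.

The isotope-pattern oracles here deliberately avoid the package's convolution
code path: they enumerate isotope assignments (exact product enumeration for
tiny formulas, per-element multinomial enumeration with a mass-shift window
for real fragments) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from posiso import synthetic
from posiso.chem import isotope_table, load_fragment_library, parse_formula
from posiso.isocorrect import IsotopologueMeasurement


@pytest.fixture(scope="session")
def library():
    return load_fragment_library()


@pytest.fixture(scope="session")
def frag_357(library):
    return library[("3PGA_357", "APCI")]


@pytest.fixture(scope="session")
def frag_459(library):
    return library[("3PGA_459", "APCI")]


@pytest.fixture(scope="session")
def frag_g6p(library):
    return library[("G6P_706", "APCI")]


def enumerate_pattern_tiny(formula_text: str, p13: float, max_shift: int = 16) -> np.ndarray:
    """Exact isotope-assignment enumeration for formulas with few atoms.

    Expands every atom into its isotope choices and sums probabilities per
    integer mass shift. Exponential in atom count — tiny formulas only.
    """
    table = isotope_table(p13)
    formula = parse_formula(formula_text)
    atoms = []
    for el, n in formula.counts:
        iso = table[el].isotopes
        mono = table[el].monoisotopic
        choices = [(int(round(m - mono)), ab) for m, ab in iso]
        atoms.extend([choices] * n)
    assert sum(len(c) ** 0 for c in atoms) == len(atoms)
    out = np.zeros(max_shift + 1)
    for combo in itertools.product(*atoms):
        shift = sum(s for s, _ in combo)
        prob = math.prod(ab for _, ab in combo)
        if shift <= max_shift:
            out[shift] += prob
    return out


def _element_shift_states(el_isotopes, n_atoms: int, max_shift: int):
    """All (shift, probability) states of ``n_atoms`` of one element.

    Enumerates heavy-isotope count vectors with multinomial probabilities,
    pruned at ``max_shift``; exact within the window.
    """
    iso = el_isotopes.isotopes
    mono = el_isotopes.monoisotopic
    shifts = [int(round(m - mono)) for m, _ in iso]
    probs = [ab for _, ab in iso]
    states = []
    heavy = list(zip(shifts[1:], probs[1:]))

    def recurse(idx, remaining, shift, log_terms, counts):
        if shift > max_shift:
            return
        if idx == len(heavy):
            ks = counts + [remaining]
            coef = math.factorial(n_atoms)
            p = probs[0] ** remaining
            for k, (_, pk) in zip(counts, heavy):
                coef //= math.factorial(k)
                p *= pk**k
            coef //= math.factorial(remaining)
            states.append((shift, coef * p))
            return
        s_k, _ = heavy[idx]
        for k in range(remaining + 1):
            if shift + k * s_k > max_shift:
                break
            recurse(idx + 1, remaining - k, shift + k * s_k, log_terms, counts + [k])

    recurse(0, n_atoms, 0, 0.0, [])
    return states


def enumerate_natural_pattern(formula_text: str, p13: float, skip_carbon: int = 0,
                              max_shift: int = 8) -> np.ndarray:
    """Windowed exact natural-abundance pattern by multinomial enumeration."""
    table = isotope_table(p13)
    formula = parse_formula(formula_text)
    per_element = []
    for el, n in formula.counts:
        if el == "C":
            n -= skip_carbon
        if n <= 0:
            continue
        per_element.append(_element_shift_states(table[el], n, max_shift))
    out = np.zeros(max_shift + 1)
    for combo in itertools.product(*per_element):
        shift = sum(s for s, _ in combo)
        if shift <= max_shift:
            out[shift] += math.prod(p for _, p in combo)
    return out


def measurements_from_frame(df: pd.DataFrame) -> list[IsotopologueMeasurement]:
    return [
        IsotopologueMeasurement(
            s, f, g.sort_values("isotopologue_index")["abundance"].to_numpy()
        )
        for (s, f), g in df.groupby(["sample_id", "fragment_id"])
    ]


@pytest.fixture(scope="session")
def noise_free_wt_bundle():
    cfg = synthetic.preset(
        "WT", "HC-HC", seed=1, noise=synthetic.NoiseModel(0.0, 0.0)
    )
    return synthetic.emit_isotopologue_table(cfg), cfg
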