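"""Carbon-fate maps from glucose (via G6P) to 3PGA, and the RuBisCO mapping.

Each map lists the 3PGA molecules produced per stoichiometric unit of
substrate as ordered source triples (which substrate carbon feeds the 1-C,
2-C and 3-C position of that product). Positional enrichments predicted from
a tracer specification and an EMP/OPP flux mixture reproduce the validation
logic of positionally labeled glucose feedings:

EMP glycolysis splits fructose-1,6-bisphosphate so that glucose carbons 3 and
4 become 1-C of the two 3PGA products, 2/5 become 2-C, and 1/6 become 3-C.

The oxidative PPP decarboxylates 1-C of G6P and converts 3 G6P into 5 3PGA:
three products carry G6P carbons (4,5,6) on (1-C,2-C,3-C); the remaining two
arise from transketolase/transaldolase rearrangement of the 2-C/3-C carbons
and have either 2-C or 3-C of G6P at their 1-C position (canonical
non-oxidative PPP fate map; user-overridable).

RuBisCO carboxylation of RuBP yields two 3PGA: one whose 1-C is the
assimilated CO2 carbon with RuBP 2-C/1-C at its 2-C/3-C, and one carrying
RuBP carbons (3,4,5) on (1-C,2-C,3-C).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CarbonFateMap",
    "TracerSpec",
    "PathwayMixture",
    "emp_map",
    "opp_map",
    "rubisco_map",
    "predict_positional_enrichment",
    "rubisco_pool_enrichment",
    "map_to_table",
]


@dataclass(frozen=True)
class CarbonFateMap:
    """Products of one pathway per stoichiometric unit of substrate.

    ``products``: ordered source triples (source atom feeding 1-C, 2-C, 3-C);
    glucose/G6P sources are position ints 1..6, RuBP sources "R1".."R5",
    assimilated CO2 is "CO2". ``weights``: molar product yields per unit.
    ``glucose_per_unit``: substrate consumed per stoichiometric unit (for
    yield-per-glucose bookkeeping).
    """

    pathway: str
    products: tuple[tuple[object, object, object], ...]
    weights: tuple[float, ...]
    glucose_per_unit: float = 1.0

    def __post_init__(self) -> None:
        if len(self.products) != len(self.weights):
            raise ValueError("one weight per product required")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be > 0")

    @property
    def pga_per_glucose(self) -> float:
        return sum(self.weights) / self.glucose_per_unit


@dataclass(frozen=True)
class TracerSpec:
    """Positionally 13C-labeled glucose: labeled positions and purity."""

    positions: frozenset[int]
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not self.positions <= frozenset(range(1, 7)):
            raise ValueError("tracer positions must be within 1..6")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")

    def p_labeled(self, source: object) -> float:
        return self.purity if source in self.positions else 0.0


@dataclass(frozen=True)
class PathwayMixture:
    """Glucose-consumption flux fractions through EMP and OPP."""

    f_emp: float
    f_opp: float

    def __post_init__(self) -> None:
        if self.f_emp < 0 or self.f_opp < 0:
            raise ValueError("flux fractions must be >= 0")
        if abs(self.f_emp + self.f_opp - 1.0) > 1e-9:
            raise ValueError("f_emp + f_opp must equal 1")


def emp_map() -> CarbonFateMap:
    """EMP glycolysis: 1 glucose -> 2 3PGA.

    Top half: (1-C<-g3, 2-C<-g2, 3-C<-g1); bottom half: (1-C<-g4, 2-C<-g5,
    3-C<-g6).
    """
    return CarbonFateMap(
        pathway="EMP",
        products=((3, 2, 1), (4, 5, 6)),
        weights=(1.0, 1.0),
        glucose_per_unit=1.0,
    )


def opp_map() -> CarbonFateMap:
    """Oxidative PPP: 3 G6P -> 3 CO2 (from 1-C) + 5 3PGA.

    Three products carry (g4, g5, g6); the two rearranged products place g2
    and g3 at 1-C with their 2-C/3-C drawn from the recombined 2-C/3-C pool
    (transketolase/transaldolase). Primed atoms from different G6P molecules
    are positionally equivalent for enrichment predictions.
    """
    return CarbonFateMap(
        pathway="OPP",
        products=(
            (4, 5, 6),
            (4, 5, 6),
            (4, 5, 6),
            (2, 3, 2),  # 1-C <- g2; 2-C/3-C from the rearranged g2/g3 pool
            (3, 3, 2),  # 1-C <- g3
        ),
        weights=(1.0, 1.0, 1.0, 1.0, 1.0),
        glucose_per_unit=3.0,
    )


def rubisco_map() -> CarbonFateMap:
    """RuBisCO carboxylation: RuBP + CO2 -> 2 3PGA.

    Product A: 1-C <- CO2, 2-C <- RuBP-C2, 3-C <- RuBP-C1 (RuBP 1,2-C2 map
    inversely onto 2,3-C2 of 3PGA). Product B: RuBP (3,4,5) -> (1-C,2-C,3-C).
    """
    return CarbonFateMap(
        pathway="RUBISCO",
        products=(("CO2", "R2", "R1"), ("R3", "R4", "R5")),
        weights=(1.0, 1.0),
        glucose_per_unit=1.0,
    )


def _pool_positions(maps_and_weights, p_labeled) -> tuple[float, float, float]:
    """Product-weighted positional label probabilities (pos1, pos2, pos3)."""
    tot_w = 0.0
    acc = [0.0, 0.0, 0.0]
    for fate_map, pool_weight in maps_and_weights:
        unit = pool_weight / sum(fate_map.weights)
        for product, w in zip(fate_map.products, fate_map.weights):
            for k, source in enumerate(product):
                acc[k] += unit * w * p_labeled(source)
        tot_w += pool_weight
    if tot_w <= 0:
        raise ValueError("empty pathway mixture")
    return tuple(a / tot_w for a in acc)  # type: ignore[return-value]


def predict_positional_enrichment(
    tracer: TracerSpec,
    mixture: PathwayMixture = PathwayMixture(1.0, 0.0),
    yield_weighting: bool = True,
) -> tuple[float, float, float]:
    """Steady-state (e1, e23, e123) of the 3PGA pool for a glucose tracer.

    Pathway pools are weighted by molar 3PGA yield per consumed glucose
    (2 for EMP, 5/3 for OPP) times the flux fraction — enrichment is a
    property of the 3PGA pool, and the routes yield different 3PGA amounts
    per glucose. ``yield_weighting=False`` weights by raw flux fraction
    instead (the difference is small at f_opp ~ 0.11).
    """
    pools = []
    if mixture.f_emp > 0:
        m = emp_map()
        w = mixture.f_emp * (m.pga_per_glucose if yield_weighting else 1.0)
        pools.append((m, w))
    if mixture.f_opp > 0:
        m = opp_map()
        w = mixture.f_opp * (m.pga_per_glucose if yield_weighting else 1.0)
        pools.append((m, w))
    p1, p2, p3 = _pool_positions(pools, tracer.p_labeled)
    e1 = p1
    e23 = (p2 + p3) / 2.0
    e123 = (p1 + p2 + p3) / 3.0
    return e1, e23, e123


def rubisco_pool_enrichment(
    e_co2: float, e_rubp: float | dict[str, float]
) -> tuple[float, float, float]:
    """(e1, e23, e123) of freshly produced 3PGA from one carboxylation round.

    ``e_rubp`` is either a scalar enrichment applied to all five RuBP carbons
    or a per-position mapping {"R1": ..., ..., "R5": ...}.
    """
    if isinstance(e_rubp, dict):
        lookup = dict(e_rubp)
    else:
        lookup = {f"R{i}": float(e_rubp) for i in range(1, 6)}
    lookup["CO2"] = float(e_co2)
    p1, p2, p3 = _pool_positions([(rubisco_map(), 1.0)], lambda s: lookup[s])
    return p1, (p2 + p3) / 2.0, (p1 + p2 + p3) / 3.0


def map_to_table(fate_map: CarbonFateMap) -> pd.DataFrame:
    """Serialize a fate map as a tidy table (for inspection or user override)."""
    rows = []
    for i, (product, w) in enumerate(zip(fate_map.products, fate_map.weights)):
        for pos, source in zip((1, 2, 3), product):
            rows.append({
                "pathway": fate_map.pathway,
                "product": i,
                "pga_position": pos,
                "source": source,
                "weight": w,
            })
    return pd.DataFrame(rows)
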