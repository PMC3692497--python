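"""Relative-rate decomposition and absolute substitution rates.

Given pairwise distances K_AB between two ingroup species and K_AC, K_BC
to an outgroup C, the distance of each ingroup lineage to their common
ancestor O follows the relative-rate decomposition

    K_OA = (K_AB + K_AC - K_BC) / 2,
    K_OB = (K_AB + K_BC - K_AC) / 2,

so K_OA + K_OB = K_AB by construction.  Dividing an ancestor-to-tip
distance by the divergence time T (Ma) gives the absolute rate, reported
in units of 1e-8 substitutions/site/year: rate = K_O / (T * 1e6) * 1e8.
Reporting rounds distances and rates to 3 decimals and rate ratios to 1
decimal (half-up, matching the conventional table format); internal
computation keeps full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .likelihood import pairwise_ml_distance
from .seqio import Alignment, complete_deletion


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.0675 -> 0.068 at 3 digits).

    Values are first snapped to 10 decimals so binary float dust (e.g.
    (0.155 + 0.203 - 0.223)/2 = 0.06749999999999999) rounds the way the
    exact decimal arithmetic would.
    """
    q = Decimal(1).scaleb(-ndigits)
    snapped = Decimal(repr(round(x, 10)))
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DistanceTriple:
    species_a: str
    species_b: str
    outgroup_c: str
    k_ab: float
    k_ac: float
    k_bc: float

    def __post_init__(self) -> None:
        if min(self.k_ab, self.k_ac, self.k_bc) < 0:
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class RateEstimate:
    lineage: str
    k_o: float  # ancestor-to-tip distance, substitutions/site
    time_Ma: float
    rate_1e8: float  # substitutions/site/year in 1e-8 units


def ancestor_distances(triple: DistanceTriple) -> tuple[float, float]:
    """(K_OA, K_OB) from the relative-rate decomposition.

    Violations of the triangle condition (K_AB > K_AC + K_BC) or negative
    results are reported as-is with a warning so rate-test violations
    stay visible.
    """
    if triple.k_ab > triple.k_ac + triple.k_bc:
        warnings.warn(
            f"triangle violation for ({triple.species_a}, {triple.species_b}; "
            f"{triple.outgroup_c}): K_AB > K_AC + K_BC"
        )
    k_oa = (triple.k_ab + triple.k_ac - triple.k_bc) / 2.0
    k_ob = (triple.k_ab + triple.k_bc - triple.k_ac) / 2.0
    if k_oa < 0 or k_ob < 0:
        warnings.warn(
            f"negative ancestor distance for ({triple.species_a}, "
            f"{triple.species_b}; {triple.outgroup_c}); reported as-is"
        )
    return k_oa, k_ob


def absolute_rate(k_o: float, time_Ma: float) -> float:
    """Rate in 1e-8 substitutions/site/year (full precision)."""
    if time_Ma <= 0:
        raise ValueError("divergence time must be positive")
    return k_o / (time_Ma * 1e6) * 1e8


def rate_ratio(rate_high: float, rate_low: float, ndigits: int = 3) -> float:
    """Fold difference of two *reported* (3-decimal) rates, to 1 decimal."""
    hi = round_half_up(rate_high, ndigits)
    lo = round_half_up(rate_low, ndigits)
    if lo == 0:
        raise ValueError("denominator rate rounds to zero")
    return round_half_up(hi / lo, 1)


@dataclass
class RatePair:
    """One column of the rate table: an ingroup pair with its outgroup."""

    species_a: str
    species_b: str
    outgroup: str
    time_Ma: float
    k_ab: float
    k_ac: float
    k_bc: float
    n_sites: int | None = None

    @classmethod
    def from_alignment(
        cls, alignment: Alignment, species_a: str, species_b: str,
        outgroup: str, time_Ma: float, model,
    ) -> "RatePair":
        """ML distances from an aligned triple after complete deletion."""
        sub = Alignment(
            [r for r in alignment.records
             if r.identifier in (species_a, species_b, outgroup)],
            alphabet=alignment.alphabet,
        )
        if len(sub.records) != 3:
            missing = {species_a, species_b, outgroup} - set(alignment.taxa)
            raise ValueError(f"species missing from alignment: {sorted(missing)}")
        sub = complete_deletion(sub)
        seq = {r.identifier: r.residues for r in sub.records}
        return cls(
            species_a, species_b, outgroup, time_Ma,
            k_ab=pairwise_ml_distance(seq[species_a], seq[species_b], model),
            k_ac=pairwise_ml_distance(seq[species_a], seq[outgroup], model),
            k_bc=pairwise_ml_distance(seq[species_b], seq[outgroup], model),
            n_sites=sub.n_sites,
        )


def rate_estimates(pair: RatePair) -> tuple[RateEstimate, RateEstimate]:
    triple = DistanceTriple(
        pair.species_a, pair.species_b, pair.outgroup,
        pair.k_ab, pair.k_ac, pair.k_bc,
    )
    k_oa, k_ob = ancestor_distances(triple)
    return (
        RateEstimate(pair.species_a, k_oa, pair.time_Ma,
                     absolute_rate(k_oa, pair.time_Ma)),
        RateEstimate(pair.species_b, k_ob, pair.time_Ma,
                     absolute_rate(k_ob, pair.time_Ma)),
    )


def build_rate_table(pairs: list[RatePair]) -> pd.DataFrame:
    """Distances-and-rates report, one column per species pair.

    Rows: site count, divergence time, the three pairwise distances, the
    two ancestor-to-tip distances and the two absolute rates; distances
    and rates reported at 3 decimals (half-up), full-precision values in
    the returned attrs under ``"full_precision"``.
    """
    if not pairs:
        raise ValueError("no pairs given")
    columns = {}
    full = {}
    for pair in pairs:
        a, b, c = pair.species_a, pair.species_b, pair.outgroup
        est_a, est_b = rate_estimates(pair)
        col = {
            "n_sites": pair.n_sites,
            "time_Ma": pair.time_Ma,
            f"K({a}-{c})": round_half_up(pair.k_ac, 3),
            f"K({b}-{c})": round_half_up(pair.k_bc, 3),
            f"K({a}-{b})": round_half_up(pair.k_ab, 3),
            f"K(O-{a})": round_half_up(est_a.k_o, 3),
            f"K(O-{b})": round_half_up(est_b.k_o, 3),
            f"rate(O-{a})x1e-8": round_half_up(est_a.rate_1e8, 3),
            f"rate(O-{b})x1e-8": round_half_up(est_b.rate_1e8, 3),
        }
        name = f"{a},{b}"
        columns[name] = col
        full[name] = {"est_a": est_a, "est_b": est_b}
    table = pd.DataFrame(columns)
    table.attrs["full_precision"] = full
    return table


def species_by_rate(pairs: list[RatePair]) -> list[tuple[str, float]]:
    """Species sorted from lower to higher reported rate.

    A species appearing in several pairs keeps its lowest reported rate
    (ties broken by name).
    """
    best: dict[str, float] = {}
    for pair in pairs:
        for est in rate_estimates(pair):
            r = round_half_up(est.rate_1e8, 3)
            if est.lineage not in best or r < best[est.lineage]:
                best[est.lineage] = r
    return sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
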