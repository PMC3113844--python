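"""Per-site mutation-rate tables, weighting, and hotspot exclusion sets.

Control-region sites mutate at wildly different rates: a minority of
hypervariable positions are hit again and again while most sites are hit
rarely.  Network construction therefore down-weights fast sites (so that a
recurrent hit at a hotspot costs less parsimony than a hit at a slow site)
and rho-based dating excludes the fastest sites outright when the
calibration demands it.  This module houses the relative-rate table, the
rate-to-weight rule, and the named exclusion sets.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .haplotypes import RCRS_LENGTH

#: Weight assigned to a site mutating at the regional average rate.
DEFAULT_WEIGHT = 8


def weight_for_rate(relative_rate: float, mode: str = "linear") -> int:
    """Integer network weight for a site's relative mutation rate.

    The anchor points are: average rate (1.0) -> weight 8, twice the
    average (2.0) -> weight 6.  The default ``linear`` rule extends those
    anchors as ``w = round(10 - 2 r)`` clipped to [1, 10].  A strict
    ``inverse`` mode (``w = round(8 / r)``, floor 1) is provided for
    sensitivity analysis; note it does *not* reproduce the second anchor.
    """
    if relative_rate <= 0:
        raise ValueError(f"relative rate must be positive, got {relative_rate}")
    if mode == "linear":
        w = math.floor(10.0 - 2.0 * relative_rate + 0.5)
        return max(1, min(10, int(w)))
    if mode == "inverse":
        return max(1, int(math.floor(8.0 / relative_rate + 0.5)))
    raise ValueError(f"unknown weighting mode {mode!r}")


@dataclass(frozen=True)
class SiteRateTable:
    """Relative mutation rate per np; 1.0 means the regional average."""

    rates: Mapping[int, float]

    def __post_init__(self) -> None:
        for pos, r in self.rates.items():
            if not 1 <= pos <= RCRS_LENGTH:
                raise ValueError(f"position {pos} outside rCRS")
            if r <= 0:
                raise ValueError(f"non-positive rate {r} at np {pos}")

    def rate_at(self, position: int) -> float:
        """Sites absent from the table default to the average rate (1.0)."""
        return self.rates.get(position, 1.0)

    @classmethod
    def from_tsv(cls, text: str) -> "SiteRateTable":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        pos_col, rate_col = df.columns[:2]
        return cls(dict(zip(df[pos_col].astype(int), df[rate_col].astype(float))))

    def to_tsv(self) -> str:
        df = pd.DataFrame(
            sorted(self.rates.items()), columns=["np", "relative_rate"]
        )
        return df.to_csv(sep="\t", index=False)


@dataclass(frozen=True)
class WeightScheme:
    """Integer weight per np; sites not listed get ``default_weight``."""

    weights: Mapping[int, int] = field(default_factory=dict)
    default_weight: int = DEFAULT_WEIGHT

    def __post_init__(self) -> None:
        if self.default_weight < 1:
            raise ValueError("default weight must be >= 1")
        for pos, w in self.weights.items():
            if w < 1:
                raise ValueError(f"weight {w} at np {pos} must be >= 1")

    def weight_at(self, position: int) -> int:
        return self.weights.get(position, self.default_weight)

    @classmethod
    def from_rate_table(
        cls, table: SiteRateTable, mode: str = "linear"
    ) -> "WeightScheme":
        return cls(
            {pos: weight_for_rate(r, mode) for pos, r in table.rates.items()}
        )

    @classmethod
    def uniform(cls, weight: int = 1) -> "WeightScheme":
        return cls({}, weight)


# Named exclusion lists. The five HVR-I network sites are classified as
# fast-evolving in at least one site-by-site hotspot survey; the four extra
# HVR-II sites (applied together with suppression of indels in
# polynucleotide stretches) have rates around six times the average; the
# rho list collects every site with an estimated rate three or more times
# its region's average, and is applied with indels excluded altogether.
NETWORK_HVR1_SITES = frozenset({16093, 16129, 16189, 16311, 16362})
NETWORK_HVR2_EXTRA_SITES = frozenset({146, 150, 152, 195})
RHO_FAST_HVR1_SITES = frozenset(
    {
        16093, 16126, 16129, 16148, 16163, 16172, 16183, 16187, 16189, 16192,
        16223, 16230, 16270, 16278, 16293, 16294, 16309, 16311, 16319, 16362,
    }
)
RHO_FAST_HVR2_SITES = frozenset(
    {
        64, 73, 93, 146, 150, 151, 152, 153, 182, 185, 186, 189, 195, 198,
        199, 200, 207, 236, 247, 263, 316,
    }
)


@dataclass(frozen=True)
class ExclusionSet:
    """A named set of sites (and optionally indel classes) to ignore."""

    label: str
    positions: frozenset[int] = frozenset()
    exclude_poly_indels: bool = False
    exclude_indels: bool = False

    def __contains__(self, position: int) -> bool:
        return position in self.positions

    def union(self, other: "ExclusionSet", label: str | None = None) -> "ExclusionSet":
        return ExclusionSet(
            label or f"{self.label}+{other.label}",
            self.positions | other.positions,
            self.exclude_poly_indels or other.exclude_poly_indels,
            self.exclude_indels or other.exclude_indels,
        )


_BUILTINS = {
    "network_hvr1": ExclusionSet("network_hvr1", NETWORK_HVR1_SITES),
    "network_hvr2_extra": ExclusionSet(
        "network_hvr2_extra", NETWORK_HVR2_EXTRA_SITES, exclude_poly_indels=True
    ),
    "rho_fast_sites": ExclusionSet(
        "rho_fast_sites",
        RHO_FAST_HVR1_SITES | RHO_FAST_HVR2_SITES,
        exclude_indels=True,
    ),
}


def builtin_exclusions(label: str) -> ExclusionSet:
    """Return a built-in exclusion set by name.

    Known labels: ``network_hvr1`` (5 HVR-I hotspots ignored for network
    building), ``network_hvr2_extra`` (4 HVR-II sites plus poly-stretch
    indels, applied on top of the HVR-I list for the joint analysis) and
    ``rho_fast_sites`` (41 fast sites plus all indels, for dating under a
    phylogenetically calibrated rate).
    """
    try:
        return _BUILTINS[label]
    except KeyError:
        raise ValueError(
            f"unknown exclusion set {label!r}; known: {sorted(_BUILTINS)}"
        ) from None


def network_exclusions(joint: bool = False) -> ExclusionSet:
    """The exclusion set for network construction (HVR-I, or joint HVR-I+II)."""
    base = builtin_exclusions("network_hvr1")
    if joint:
        base = base.union(builtin_exclusions("network_hvr2_extra"), "network_joint")
    return base
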