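"""Geographic dispersion of mtDNA lineages.

Ancestral haplotypes that entered a continent early are expected to be
carried by populations scattered over great distances, while recently
derived lineages should cluster near their place of origin.  This module
computes great-circle distances between carrier populations, pools the
pairwise distances per lineage class, and compares the ancestral and
derived distance distributions with a Mann-Whitney U test (midranks for
ties, tie-corrected normal approximation with continuity correction, and
exact enumeration for small samples).
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class PopulationSite:
    id: str
    latitude: float
    longitude: float
    label: str = ""

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} out of range")


def haversine_km(a: PopulationSite, b: PopulationSite) -> float:
    """Great-circle distance on a sphere of radius 6371.0088 km."""
    phi1, phi2 = math.radians(a.latitude), math.radians(b.latitude)
    dphi = phi2 - phi1
    dlam = math.radians(b.longitude - a.longitude)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def read_coordinates_tsv(text: str) -> list[PopulationSite]:
    df = pd.read_csv(io.StringIO(text), sep="\t", keep_default_na=False)
    return [
        PopulationSite(
            str(r["population_id"]),
            float(r["latitude"]),
            float(r["longitude"]),
            str(r.get("label", "") or ""),
        )
        for _, r in df.iterrows()
    ]


def write_coordinates_tsv(sites: list[PopulationSite]) -> str:
    df = pd.DataFrame(
        [(s.id, s.latitude, s.longitude, s.label) for s in sites],
        columns=["population_id", "latitude", "longitude", "label"],
    )
    return df.to_csv(sep="\t", index=False)


@dataclass(frozen=True)
class LineageOccurrence:
    """The set of populations in which one lineage was observed."""

    lineage_key: str
    population_ids: frozenset[str]
    class_label: str = ""

    def __post_init__(self) -> None:
        if not self.population_ids:
            raise ValueError("a lineage occurrence needs at least one population")


@dataclass
class DistanceSample:
    """Pooled interpopulation distances for one lineage class."""

    class_label: str
    distances: list[float]
    n_lineages: int
    n_singletons: int

    @property
    def mean_km(self) -> float:
        return float(np.mean(self.distances)) if self.distances else float("nan")

    @property
    def frac_below_1000km(self) -> float:
        if not self.distances:
            return float("nan")
        return float(np.mean([d < 1000.0 for d in self.distances]))


def lineage_distances(
    occurrences: list[LineageOccurrence],
    sites: list[PopulationSite],
    class_label: str,
) -> DistanceSample:
    """All unordered pairs of distinct carrier populations, pooled across
    the lineages of one class.  Single-carrier lineages contribute nothing
    (logged)."""
    by_id = {s.id: s for s in sites}
    distances: list[float] = []
    n_lineages = n_singletons = 0
    for occ in occurrences:
        if occ.class_label != class_label:
            continue
        missing = sorted(p for p in occ.population_ids if p not in by_id)
        if missing:
            raise ValueError(
                f"lineage {occ.lineage_key}: no coordinates for {missing}"
            )
        pops = sorted(occ.population_ids)
        if len(pops) < 2:
            n_singletons += 1
            logger.debug(
                "lineage %s has a single carrier population; skipped",
                occ.lineage_key,
            )
            continue
        n_lineages += 1
        for a, b in itertools.combinations(pops, 2):
            distances.append(haversine_km(by_id[a], by_id[b]))
    return DistanceSample(class_label, distances, n_lineages, n_singletons)


@dataclass
class GeoTestResult:
    """Mann-Whitney comparison of two pooled distance samples.

    ``U`` is min(U1, U2); both one-sided statistics are also kept since
    reporting conventions differ.  ``Z`` is signed: positive when sample 1
    ranks above sample 2.
    """

    U: float
    Z: float
    p: float
    n1: int
    n2: int
    u1: float = 0.0
    u2: float = 0.0
    method: str = "normal"
    mean1_km: float = float("nan")
    mean2_km: float = float("nan")
    frac_below_1000km_1: float = float("nan")
    frac_below_1000km_2: float = float("nan")


def _exact_two_sided_p(pooled: np.ndarray, n1: int, u1_obs: float) -> float:
    """Exact two-sided p by enumerating all assignments of the pooled values
    to group 1 (midranks preserved, so ties are handled)."""
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    d_obs = abs(u1_obs - mu)
    count = total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in itertools.combinations(range(n), n1):
        u1 = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u1 - mu) >= d_obs - 1e-9:
            count += 1
    return count / total


def mann_whitney(
    x: list[float], y: list[float], method: str = "auto"
) -> GeoTestResult:
    """Two-sided Mann-Whitney U test.

    ``method``: ``"exact"`` enumerates all rank assignments (feasible for
    n1+n2 <= ~12 and used automatically below that), ``"normal"`` uses the
    tie-corrected normal approximation with continuity correction,
    ``"auto"`` picks between them.
    """
    x, y = list(map(float, x)), list(map(float, y))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.asarray(x + y)
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        z = 0.0
    else:
        diff = u1 - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
    p_normal = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    if method == "auto":
        method = "exact" if n <= 12 else "normal"
    if method == "exact":
        p = _exact_two_sided_p(pooled, n1, u1)
    elif method == "normal":
        p = p_normal
    else:
        raise ValueError(f"unknown method {method!r}")
    return GeoTestResult(
        U=min(u1, u2), Z=float(z), p=float(p), n1=n1, n2=n2,
        u1=float(u1), u2=float(u2), method=method,
    )


def compare_dispersion(
    occurrences: list[LineageOccurrence],
    sites: list[PopulationSite],
    class1: str,
    class2: str,
    method: str = "auto",
) -> GeoTestResult:
    """Compare the pooled interpopulation distances of two lineage classes."""
    s1 = lineage_distances(occurrences, sites, class1)
    s2 = lineage_distances(occurrences, sites, class2)
    res = mann_whitney(s1.distances, s2.distances, method=method)
    res.mean1_km = s1.mean_km
    res.mean2_km = s2.mean_km
    res.frac_below_1000km_1 = s1.frac_below_1000km
    res.frac_below_1000km_2 = s2.frac_below_1000km
    return res


def results_table(rows: list[tuple[str, GeoTestResult]]) -> str:
    lines = [
        "comparison\tn1\tn2\tmean1_km\tmean2_km\tfrac1_lt_1000km\t"
        "frac2_lt_1000km\tU\tu1\tu2\tZ\tp\tmethod"
    ]
    for name, r in rows:
        lines.append(
            f"{name}\t{r.n1}\t{r.n2}\t{r.mean1_km:.1f}\t{r.mean2_km:.1f}\t"
            f"{r.frac_below_1000km_1:.3f}\t{r.frac_below_1000km_2:.3f}\t"
            f"{r.U:.1f}\t{r.u1:.1f}\t{r.u2:.1f}\t{r.Z:.2f}\t{r.p:.4g}\t{r.method}"
        )
    return "\n".join(lines) + "\n"
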