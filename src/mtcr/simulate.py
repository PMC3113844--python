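"""Synthetic control-region panels with known truth.

The generator emulates a literature-compiled panel of haplogroup-defined
control-region sequences: a genealogy (star or Yule) of known root age,
mutations placed as per-site Poisson processes under heterogeneous relative
rates (a minority of hotspot sites several-fold above the regional
average, recurrent hits allowed so back mutations arise), a fraction of
tips lacking HVR-II coverage, and carrier populations placed on a
continent-scale coordinate field in which derived lineages are
geographically more clustered than the ancestral motif.

The reference sequence is synthetic (base = "ACGT"[np % 4]); real analyses
never need literal bases because everything is variant-coded.  What the
generator deliberately does not emulate: selection, population structure in
the genealogy, rate heterogeneity beyond a two-class hotspot model, and
sequencing error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .haplotypes import (
    DELETION,
    HVR1_FULL,
    HVR1_NETWORK,
    HVR2_FULL,
    HaploPanel,
    Haplotype,
    Region,
    SUBSTITUTION,
    Variant,
    transition,
)
from .dating import RateConfig, rho_stat, saillard_variance, tmrca
from .geography import LineageOccurrence, PopulationSite
from .network import MPTree, NetNode, MJParams, collapse_panel
from .sites import RHO_FAST_HVR1_SITES, RHO_FAST_HVR2_SITES, SiteRateTable

import networkx as nx

CENTER_LAT, CENTER_LON = -15.0, -60.0
KM_PER_DEG_LAT = 111.32

#: Default hotspot relative rate (>= 3x the average, as the named
#: fast-site lists assume).
HOTSPOT_RATE = 4.0


def synthetic_reference_base(position: int) -> str:
    """Deterministic synthetic reference base at an rCRS position."""
    return "ACGT"[position % 4]


def default_rate_table(
    regions: tuple[Region, ...], hotspot_rate: float = HOTSPOT_RATE
) -> SiteRateTable:
    """Two-class rate table: named fast sites at ``hotspot_rate``, the rest
    scaled so the mean relative rate within each region is exactly 1.0
    (1.0 means the regional average, which is the table's own invariant)."""
    fast = RHO_FAST_HVR1_SITES | RHO_FAST_HVR2_SITES
    rates: dict[int, float] = {}
    for region in regions:
        positions = range(region.start, region.end + 1)
        hot = [p for p in positions if p in fast]
        cold = [p for p in positions if p not in fast]
        n = len(region)
        if hot:
            cold_rate = (n - hotspot_rate * len(hot)) / len(cold)
            if cold_rate <= 0:
                raise ValueError("hotspot rate too high for region size")
        else:
            cold_rate = 1.0
        for p in hot:
            rates[p] = hotspot_rate
        for p in cold:
            rates[p] = cold_rate
    return SiteRateTable(rates)


def default_root_motif(regions: tuple[Region, ...]) -> frozenset[Variant]:
    """A haplogroup-style root motif over the simulated regions:
    transitions at the canonical control-region motif positions that fall
    inside the regions, plus the 249 and 290-291 deletions when HVR-II is
    simulated."""
    sub_positions = (73, 194, 263, 16051, 16223, 16298, 16325, 16327)
    del_positions = (249, 290, 291)
    variants = []
    for pos in sub_positions:
        if any(r.contains(pos) for r in regions):
            ref = synthetic_reference_base(pos)
            variants.append(Variant(pos, SUBSTITUTION, ref, transition(ref)))
    for pos in del_positions:
        if any(r.contains(pos) for r in regions):
            variants.append(
                Variant(pos, DELETION, ref_allele=synthetic_reference_base(pos))
            )
    return frozenset(variants)


@dataclass
class SimConfig:
    """The stated world of the generator.

    Defaults emulate a compiled continental panel: 170 sequences (of which
    ~40% lack HVR-II), a root age of 400 generations (~10 ky at 25 yr per
    generation), a pedigree-scale base rate of 11.7e-6 mutations/site/
    generation, ~50 sampled populations, and derived lineages dispersed
    with sigma = 0.4 x the ancestral dispersal scale.
    """

    seed: int
    n_tips: int = 170
    genealogy_model: str = "yule"
    T_true: float = 400.0
    base_rate: float = 11.7e-6
    per_site_rates: SiteRateTable | None = None
    region_set: tuple[Region, ...] = (HVR2_FULL, HVR1_FULL)
    root_motif: frozenset[Variant] | None = None
    n_populations: int = 50
    dispersal_sigma_ancestral: float = 2700.0
    dispersal_sigma_derived: float = 1080.0
    missing_hvr2_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.n_tips < 1 or self.n_populations < 1:
            raise ValueError("counts must be positive")
        if self.T_true < 0 or self.base_rate < 0:
            raise ValueError("T_true and base_rate must be non-negative")
        if not 0 <= self.missing_hvr2_fraction <= 1:
            raise ValueError("missing_hvr2_fraction must be in [0,1]")
        if self.dispersal_sigma_ancestral <= 0 or self.dispersal_sigma_derived <= 0:
            raise ValueError("dispersal sigmas must be positive")
        if self.genealogy_model not in ("star", "yule"):
            raise ValueError(f"unknown genealogy model {self.genealogy_model!r}")
        if not self.region_set:
            raise ValueError("region_set must not be empty")


@dataclass
class SimTruth:
    """What actually happened in a simulation, for oracle checks."""

    true_T: float
    root_id: str
    tree_edges: list[tuple[str, str, float]]
    tip_mutation_counts: dict[str, int]
    tip_population: dict[str, str]
    tip_class: dict[str, str]
    tip_lineage: dict[str, str]
    site_hit_totals: dict[int, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_T": self.true_T,
                "root_id": self.root_id,
                "tree_edges": self.tree_edges,
                "tip_mutation_counts": self.tip_mutation_counts,
                "tip_population": self.tip_population,
                "tip_class": self.tip_class,
                "tip_lineage": self.tip_lineage,
                "site_hit_totals": {str(k): v for k, v in self.site_hit_totals.items()},
            },
            indent=1,
        )


def _yule_edges(
    rng: np.random.Generator, n_tips: int, depth: float
) -> list[tuple[str, str, float]]:
    """A Yule (pure-birth) genealogy with root age ``depth``; ultrametric.

    Split depths follow the pure-birth waiting times Exp(k) for k lineages,
    rescaled so tips sit exactly at ``depth``.
    """
    if n_tips == 1:
        return [("root", "T000", depth)]
    waits = [rng.exponential(1.0 / k) for k in range(2, n_tips)]
    split_depths = [0.0] + list(np.cumsum(waits))
    tip_depth = split_depths[-1] + rng.exponential(1.0 / n_tips)
    scale = depth / tip_depth if tip_depth > 0 else 0.0
    split_depths = [d * scale for d in split_depths]
    edges: list[tuple[str, str, float]] = []
    next_internal = 0
    # active: list of (node_id, branch_start_depth)
    active = []
    for _ in range(2):
        active.append((f"I{next_internal}", 0.0))
        next_internal += 1
        edges.append(("root", active[-1][0], None))  # length fixed at split
    starts = {nid: s for nid, s in active}
    for d in split_depths[1:]:
        i = rng.integers(len(active))
        nid, s0 = active.pop(i)
        _set_length(edges, nid, d - s0)
        for _ in range(2):
            child = f"I{next_internal}"
            next_internal += 1
            edges.append((nid, child, None))
            active.append((child, d))
    out = []
    tip_no = 0
    tip_names = {}
    for nid, s0 in active:
        _set_length(edges, nid, depth - s0)
        tip_names[nid] = f"T{tip_no:03d}"
        tip_no += 1
    renamed = []
    for parent, child, length in edges:
        renamed.append(
            (
                tip_names.get(parent, parent),
                tip_names.get(child, child),
                float(length),
            )
        )
    return renamed


def _set_length(edges, node_id, length):
    for i, (p, c, l) in enumerate(edges):
        if c == node_id and l is None:
            edges[i] = (p, c, float(length))
            return
    raise KeyError(node_id)


def simulate_panel(
    cfg: SimConfig,
) -> tuple[HaploPanel, list[PopulationSite], SimTruth]:
    """Generate a panel, its population coordinates and the ground truth.

    Mutations toggle a site between the parental state and its partner
    allele (transitions), so recurrent hits at hotspots produce genuine
    back mutations.  Indels in the root motif are static clade markers.
    """
    rng = np.random.default_rng(cfg.seed)
    regions = tuple(sorted(cfg.region_set))
    rate_table = cfg.per_site_rates or default_rate_table(regions)
    root_motif = (
        cfg.root_motif if cfg.root_motif is not None else default_root_motif(regions)
    )
    motif_subs = {v.position: v for v in root_motif if v.kind == SUBSTITUTION}
    motif_indels = [v for v in root_motif if v.kind != SUBSTITUTION]

    sites = [
        p
        for r in regions
        for p in range(r.start, r.end + 1)
        if not any(v.position == p for v in motif_indels)
    ]
    sites = sorted(sites)
    positions = np.array(sites)
    lam = cfg.base_rate * np.array([rate_table.rate_at(p) for p in sites])

    root_state = np.array([1 if p in motif_subs else 0 for p in sites], dtype=np.int8)

    if cfg.genealogy_model == "star":
        edges = [
            ("root", f"T{i:03d}", float(cfg.T_true)) for i in range(cfg.n_tips)
        ]
    else:
        edges = _yule_edges(rng, cfg.n_tips, float(cfg.T_true))

    states = {"root": root_state}
    hits_along = {"root": np.zeros(len(sites), dtype=np.int64)}
    site_totals = np.zeros(len(sites), dtype=np.int64)
    for parent, child, length in edges:  # edges are in preorder
        counts = rng.poisson(lam * length)
        site_totals += counts
        states[child] = (states[parent] + counts) % 2
        hits_along[child] = hits_along[parent] + counts

    tips = sorted(c for _, c, _ in edges if c.startswith("T"))

    # coverage: which tips lack HVR-II
    has_hvr2 = any(r.intersect(HVR2_FULL) for r in regions)
    n_missing = int(round(cfg.missing_hvr2_fraction * len(tips))) if has_hvr2 else 0
    missing_tips = set(
        rng.choice(tips, size=n_missing, replace=False)
    ) if n_missing else set()

    # lineage classes over the HVR-I network window
    window = HVR1_NETWORK
    in_window = (positions >= window.start) & (positions <= window.end)
    root_window = root_state[in_window]

    haplotypes = []
    tip_lineage: dict[str, str] = {}
    tip_class: dict[str, str] = {}
    for tip in tips:
        state = states[tip]
        covered = regions
        if tip in missing_tips:
            covered = tuple(
                r for r in regions if r.intersect(HVR2_FULL) is None
            )
        variants = []
        for i, p in enumerate(sites):
            if not any(r.contains(p) for r in covered):
                continue
            ref = synthetic_reference_base(p)
            if p in motif_subs:
                derived = motif_subs[p].derived_allele
            else:
                derived = transition(ref)
            if state[i] == 1:
                variants.append(Variant(p, SUBSTITUTION, ref, derived))
        for v in motif_indels:
            if any(r.contains(v.position) for r in covered):
                variants.append(v)
        fp = tuple(state[in_window])
        lineage = "anc" if fp == tuple(root_window) else (
            "lin_" + "".join(map(str, fp))
        )
        tip_lineage[tip] = lineage
        tip_class[tip] = "ancestral" if lineage == "anc" else "derived"
        haplotypes.append(
            Haplotype(
                id=tip,
                variants=frozenset(variants),
                covered_regions=covered,
            )
        )

    # populations: group each lineage's carriers into populations of size
    # ~n_tips/n_populations; ancestral carriers disperse with sigma_ancestral
    # around the continental centre, each derived lineage's carriers with
    # sigma_derived around a lineage-specific centre.
    group_size = max(1, round(cfg.n_tips / cfg.n_populations))
    lineages: dict[str, list[str]] = {}
    for tip in tips:
        lineages.setdefault(tip_lineage[tip], []).append(tip)
    pop_sites: list[PopulationSite] = []
    tip_population: dict[str, str] = {}
    pop_no = 0
    for lineage in sorted(lineages):
        members = sorted(lineages[lineage])
        if lineage == "anc":
            center = (0.0, 0.0)
            sigma = cfg.dispersal_sigma_ancestral
        else:
            center = tuple(
                rng.normal(0.0, cfg.dispersal_sigma_ancestral, size=2)
            )
            sigma = cfg.dispersal_sigma_derived
        for start in range(0, len(members), group_size):
            chunk = members[start : start + group_size]
            pop_no += 1
            pid = f"P{pop_no:03d}"
            dx, dy = rng.normal(center, sigma)
            lat = CENTER_LAT + dy / KM_PER_DEG_LAT
            lat = max(-89.0, min(89.0, lat))
            lon = CENTER_LON + dx / (KM_PER_DEG_LAT * math.cos(math.radians(lat)))
            lon = max(-180.0, min(180.0, lon))
            pop_sites.append(PopulationSite(pid, lat, lon, lineage))
            for tip in chunk:
                tip_population[tip] = pid

    haplotypes = [
        replace(h, population_id=tip_population[h.id]) for h in haplotypes
    ]
    varying = np.zeros(len(sites), dtype=bool)
    for t in tips:
        varying |= states[t] == 1
    columns = tuple(
        (p, SUBSTITUTION, 1)
        for i, p in enumerate(sites)
        if varying[i] or p in motif_subs
    )
    columns += tuple((v.position, v.kind, 1) for v in motif_indels)
    columns = tuple(sorted(columns))
    ref_alleles = {
        c: ("" if c[1] == "insertion" else synthetic_reference_base(c[0]))
        for c in columns
    }
    panel = HaploPanel(haplotypes, "rCRS", columns, ref_alleles)

    truth = SimTruth(
        true_T=float(cfg.T_true),
        root_id="root",
        tree_edges=[(p, c, l) for p, c, l in edges],
        tip_mutation_counts={t: int(hits_along[t].sum()) for t in tips},
        tip_population=tip_population,
        tip_class=tip_class,
        tip_lineage=tip_lineage,
        site_hit_totals={int(p): int(n) for p, n in zip(positions, site_totals)},
    )
    return panel, pop_sites, truth


def root_haplotype(cfg: SimConfig) -> Haplotype:
    """The root motif as a haplotype covering the simulated regions."""
    regions = tuple(sorted(cfg.region_set))
    motif = (
        cfg.root_motif if cfg.root_motif is not None else default_root_motif(regions)
    )
    return Haplotype(id="root", variants=motif, covered_regions=regions)


def star_tree_from_panel(
    panel: HaploPanel,
    root: Haplotype,
    params: MJParams | None = None,
) -> MPTree:
    """Raw-mismatch star tree: every collapsed haplotype class joined to the
    root by an edge carrying their differing sites.

    Valid as a genealogy exactly when the true genealogy is a star (the
    recovery-experiment setting); it is also the rho "raw mismatch" mode in
    tree form.
    """
    from .haplotypes import pairwise_distance

    params = params or MJParams(annotate_sites=())
    nodes = collapse_panel(panel, params)
    g = nx.Graph()
    root_sig_nodes = [
        n for n in nodes if n.haplotype.labels() == root.labels()
    ]
    if root_sig_nodes:
        root_id = root_sig_nodes[0].id
    else:
        root_id = "root"
        g.add_node(
            root_id,
            node=NetNode(root_id, root, sampled=False, multiplicity=0),
        )
    for n in nodes:
        g.add_node(n.id, node=n)
    for n in nodes:
        if n.id == root_id:
            continue
        d, keys = pairwise_distance(
            root,
            n.haplotype,
            weights=params.weights,
            excluded=params.excluded,
            merge_contiguous_deletions=params.merge_contiguous_deletions,
        )
        g.add_edge(root_id, n.id, weight=d, keys=tuple(keys))
    return MPTree(g, g.size(weight="weight"), root=root_id)


@dataclass
class RecoveryReport:
    """Outcome of a parameter-recovery experiment on star genealogies."""

    n_reps: int
    coverage: float
    true_t_years: float
    tmrca_years: list[float] = field(default_factory=list)
    delta_t_years: list[float] = field(default_factory=list)

    @property
    def mean_tmrca(self) -> float:
        return float(np.mean(self.tmrca_years))

    @property
    def mean_delta_t(self) -> float:
        return float(np.mean([d for d in self.delta_t_years if d is not None]))


def recovery_experiment(
    cfg: SimConfig, rate_cfg: RateConfig, n_reps: int = 200
) -> RecoveryReport:
    """Simulate star panels at a known age and check that T_hat +/- 2 Delta T
    covers the truth.  Replicate r uses seed cfg.seed + r."""
    if cfg.genealogy_model != "star":
        raise ValueError("recovery experiments require a star genealogy")
    if rate_cfg.mode == "genealogical":
        true_years = cfg.T_true * rate_cfg.generation_years
    else:
        true_years = cfg.T_true
    hits = 0
    t_list: list[float] = []
    dt_list: list[float] = []
    root = root_haplotype(cfg)
    for r in range(n_reps):
        c = replace(cfg, seed=cfg.seed + r)
        panel, _, _ = simulate_panel(c)
        tree = star_tree_from_panel(panel, root)
        rho, n = rho_stat(tree, tree.root, rate_cfg.site_exclusions)
        sigma = saillard_variance(tree, tree.root, rate_cfg.site_exclusions) ** 0.5
        res = tmrca(rho, sigma, rate_cfg, n)
        t_list.append(res.tmrca_years)
        dt = res.delta_t_years
        dt_list.append(dt)
        if dt is not None and abs(res.tmrca_years - true_years) <= 2 * dt:
            hits += 1
    return RecoveryReport(
        n_reps=n_reps,
        coverage=hits / n_reps,
        true_t_years=true_years,
        tmrca_years=t_list,
        delta_t_years=dt_list,
    )


def panel_occurrences(truth: SimTruth) -> list[LineageOccurrence]:
    """Lineage occurrence records (ancestral vs derived classes) from a
    simulation's truth."""
    pops: dict[str, set[str]] = {}
    cls: dict[str, str] = {}
    for tip, lineage in truth.tip_lineage.items():
        pops.setdefault(lineage, set()).add(truth.tip_population[tip])
        cls[lineage] = truth.tip_class[tip]
    return [
        LineageOccurrence(lineage, frozenset(p), cls[lineage])
        for lineage, p in sorted(pops.items())
    ]


def dispersion_power(
    cfg: SimConfig, n_reps: int = 100, alpha: float = 0.05
) -> float:
    """Fraction of replicates in which the ancestral-vs-derived dispersion
    test rejects at level ``alpha``.  Replicate r uses seed cfg.seed + r."""
    from .geography import compare_dispersion

    rejections = 0
    usable = 0
    for r in range(n_reps):
        c = replace(cfg, seed=cfg.seed + r)
        _, sites, truth = simulate_panel(c)
        occ = panel_occurrences(truth)
        try:
            res = compare_dispersion(occ, sites, "ancestral", "derived")
        except ValueError:
            continue
        usable += 1
        if res.p < alpha:
            rejections += 1
    if usable == 0:
        raise RuntimeError("no replicate produced two comparable classes")
    return rejections / usable
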