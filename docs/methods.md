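# Methods

This note documents the models, conventions and numerical choices behind
`mtcr`, in the spirit of a methods appendix: what each stage assumes, which
parameters matter, and what the synthetic-data tests do and do not
establish.

## Haplotype encoding and comparison

Haplotypes are sets of variants against the rCRS (1-based positions;
circularity is not modelled). Insertions are keyed to the anchor position
plus an insert index (`310.1C` = first insertion after np 310); deletions
are per-position. A variant table row may leave columns blank; contiguous
blank columns become one missing interval of that record's coverage.

Pairwise distances use **pairwise complete deletion**: only sites covered
in both records are compared. This is forced by real compilations, which
mix HVR-I-only and HVR-I+II records; the alternative (listwise deletion)
would discard most of the panel. A maximal run of contiguous deleted
positions counts as one mutational event by default (the 290–291d
dinucleotide deletion is one event), switchable off. Each differing site
contributes its integer site weight (uniform weight 1 when no scheme is
given).

An open formatting question in published tables — a blank cell at a single
internal site in an otherwise complete row — is treated as genuinely
missing at that site, not as a typographic identity mark.

## Site weights and exclusions

The weighting rule is anchored at two documented points: a site at the
regional average relative rate (1.0) gets weight 8, a site at twice the
average gets weight 6. Although such rules are described as "inverse
proportional", the two anchors are linear, not reciprocal (a reciprocal
rule would give 2.0 → 4); the default is therefore the linear rule
`w = round(10 − 2r)` clipped to [1, 10], with a strict-inverse mode
(`w = round(8/r)`, floor 1) available for sensitivity analysis. Sites
missing from a rate table default to the average rate.

Three built-in exclusion sets mirror standard practice:

- `network_hvr1`: {16093, 16129, 16189, 16311, 16362} — hypervariable
  HVR-I positions ignored during network construction;
- `network_hvr2_extra`: {146, 150, 152, 195} plus indels in
  polynucleotide stretches (303–315, 514–524, 16184–16193), applied on
  top of the HVR-I list for joint HVR-I+II networks;
- `rho_fast_sites`: 20 HVR-I + 21 HVR-II positions with rates ≥3× their
  regional average, plus all indels — applied to mutation counts when
  dating under the phylogenetically calibrated rate.

## Median-joining networks

Stage 1 is the **minimum-spanning network** (MSN): repeatedly take the
minimal distance joining two components and add *every* cross-component
link within `epsilon` of it (components assessed before the step's links
are added). `epsilon = 0`, the default, reproduces the strict MSN — the
union of all minimum spanning trees.

Stage 2 adds **median vectors**. Each round proposes the site-wise
majority consensus of every connected triplet in the current MSN. Where a
site shows three distinct states no median is proposed (no quasi-median
generation; control-region panels are overwhelmingly biallelic per site).
Candidates are ranked by connection cost d(u,m)+d(v,m)+d(w,m); all
candidates at the minimal cost (within `epsilon`) whose inclusion does not
lengthen the minimum spanning tree are admitted, and the process repeats
until no admissible median remains (a round cap guards termination). The
admission test uses the minimum spanning *tree* length, not the MSN
length, because the MSN length is inflated by ties a new median creates
and would wrongly veto medians lying on genuinely shortest connections.

The returned network is the MSN over the final node set united with the
MSN over the sampled nodes alone, so the plain MSN is always a subgraph;
median vectors left pendant or isolated are pruned. Tie-breaking is
lexicographic on node ids throughout: the algorithm is deterministic, and
permuting input order changes node ids at most, never edge structure.

## Maximum-parsimony extraction

MP trees are minimum-weighted-length trees spanning all sampled nodes,
with median vectors as optional Steiner points. The exact search
enumerates median subsets, takes minimum spanning trees of each connected
induced subgraph, and collects every distinct tree attaining the global
minimum (an ascending spanning-tree iterator, cut off at the minimum
weight). This is exponential in the median count, so a size cap (default
25 nodes) guards it; above the cap the default behaviour is a documented
heuristic — one minimum spanning tree with unsampled leaves pruned, so the
tree count becomes a lower bound — with a warning, and `mode="exact"`
refuses instead. Tests verify the exact search against an independent
Dreyfus–Wagner dynamic program and brute-force edge enumeration.

**Back mutations** on a tree are counted per differing-site key: each edge
bearing a key beyond the first implies one extra state change; the count
sums these excesses. Excluding designated hotspot sites and rebuilding
never increased this count on any tested panel, echoing the rationale for
exclusion lists.

## ρ dating

ρ is the multiplicity-weighted mean number of (non-excluded) mutations on
the tree path from a designated root to each sampled sequence; sampled
sequences identical to the root count with distance 0. Computing ρ on tree
paths rather than raw mismatches means back mutations are counted, not
cancelled; a raw-mismatch mode exists for comparison and equals the
path-based value exactly when the tree is back-mutation-free.

The variance estimator is σ² = Σₑ nₑ²·lₑ / n² over tree edges, where nₑ
counts sampled sequences below the edge and lₑ its non-excluded
mutations. On a star of n singleton tips this reduces to σ² = ρ/n.

Conversion to years uses an explicit effective sequence length L, never
inferred from the data:

- genealogical convention: μ = 11.7 mutations/base/10⁶ generations on raw
  sequences, T = ρ/(L·μ·10⁻⁶) generations × generation span (default 25
  years; 30 is a documented variant);
- phylogenetic convention: μ = 9.883×10⁻² mutations/base/10⁶ years with
  the `rho_fast_sites` exclusions applied to the counts. Whether L is
  also reduced by the excluded sites is configurable and off by default,
  since published usage keeps L unchanged.

ΔT = T·σ/ρ identically. For the joint HVR-I+II window the stated ranges
give L = 360 + 316 = 676 (the documented default preset); published TMRCA
values back-calculate to L ≈ 625, which ships as an alternative preset.
Published phylogenetic-rate TMRCAs for these data do not back-calculate
from the stated rate and any stated L under the linear formula; that
conversion convention is undocumented upstream, so those cells are not
reproduced or targeted here.

## Geographic dispersion

Great-circle distances use the haversine formula on a sphere of radius
6371.0088 km (IUGG mean); geodetic-library values may differ by <0.2%.
For each lineage, every unordered pair of distinct carrier populations
contributes one distance; distances pool across the lineages of a class
(single-carrier lineages contribute nothing and are logged). The
ancestral-vs-derived comparison is a two-sided Mann-Whitney U test:
midranks for ties, tie-corrected normal approximation with continuity
correction, and exact enumeration of all rank assignments when
n₁+n₂ ≤ 12. Both U₁ and U₂ are reported alongside min(U₁,U₂), since
reporting conventions differ.

## Synthetic data

The generator emulates a literature-compiled continental panel. Stated
world (defaults chosen once):

- 170 sequences, ~40% lacking HVR-II — the compiled-panel proportions;
- genealogy: Yule by default (a compiled panel is a genealogy); star for
  recovery experiments, where E[ρ] is exact;
- root age T = 400 generations (~10 ky at 25 yr/gen, the scale of the
  panels this emulates), base rate 11.7×10⁻⁶ mutations/site/generation;
- per-site rates: the named fast sites at 4× (≥3×, as the exclusion lists
  assume), the remainder scaled so each region's mean relative rate is
  exactly 1.0 — the defining property of a relative-rate table;
- mutations are per-site Poisson with parent-state toggling between the
  reference and its transition partner, so recurrent hits at hotspots
  produce genuine back mutations; root-motif indels are static clade
  markers (no indel mutation channel by default);
- ~50 populations (≈3 sequences each, a compilation-like granularity);
  the ancestral class disperses around the continental centre with
  σ = 2700 km (mean pairwise distance ≈ 1.77σ ≈ 4.8×10³ km, continental
  scale), each derived lineage around its own centre with
  σ = 0.4 × 2700 = 1080 km;
- one explicit seed governs all randomness; replicate r uses seed + r.

The reference sequence is synthetic (`base = "ACGT"[np mod 4]`), flagged
as such; variant-coded analyses never need literal rCRS bases. The
generator does **not** emulate selection, population structure within the
genealogy, rate variation beyond the two-class hotspot model, sequencing
error, or insertion mutation — so green tests establish the correctness
of the estimators under the stated model, not robustness to those
realities.

The recovery experiment simulates star panels, builds the (known) star
tree from root mismatches, and checks that T̂ ± 2ΔT covers the truth;
with 100 tips and λ ≈ 1.47 expected mutations per tip, coverage is ≈ 95%.
The dispersion-power experiment runs the full ancestral-vs-derived test
per replicate and reports the rejection rate at α = 0.05.

## Known limitations

- Quasi-median generation is not implemented; panels with frequent
  triallelic sites would need it.
- The exact MP search is exponential in the median-vector count; above the
  size cap only the heuristic tree (a lower bound on the tree count) is
  available.
- MJ networks are heuristic constructions: the admitted median set — and
  hence MP tree counts on tie-rich data — can differ from other
  implementations' tie handling.
- ρ-based dating inherits the known fragility of the estimator (wide
  type-I error under non-star genealogies); the package reports ΔT from
  the Saillard estimator and makes no further uncertainty claims.
- Distances are spherical, not ellipsoidal; no map rendering.
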