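"""Control-region haplotypes encoded as variants against the rCRS.

Human mtDNA population studies conventionally report a sequence not as a
string of bases but as the list of positions at which it differs from the
revised Cambridge Reference Sequence (rCRS), e.g. ``16051G`` for an A->G
substitution at nucleotide position (np) 16051, ``249d`` for a deletion and
``310.1C`` for a cytosine inserted after np 310.  This module holds the
domain types for that encoding (:class:`Region`, :class:`Variant`,
:class:`Haplotype`, :class:`HaploPanel`), a parser/serializer for the
tab-separated variant-table dialect used to publish such panels, trimming
to analysis windows, a weighted pairwise distance, and FASTA export.

Coordinates are 1-based rCRS positions throughout.  Circularity of the
mitochondrial genome is not modelled: no region wraps the origin.
"""

from __future__ import annotations

import io
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RCRS_LENGTH = 16569

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

BASES = frozenset("ACGT")

#: Polynucleotide (homopolymer / repeat) stretches of the control region in
#: which indels are conventionally treated as unscorable length variants.
POLY_STRETCHES = ((303, 315), (514, 524), (16184, 16193))

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def transition(base: str) -> str:
    """Return the transition partner of ``base`` (A<->G, C<->T)."""
    return _TRANSITION[base.upper()]


@dataclass(frozen=True, order=True)
class Region:
    """A closed interval of rCRS positions, 1-based and inclusive."""

    start: int
    end: int
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= RCRS_LENGTH):
            raise ValueError(
                f"invalid region {self.start}..{self.end}: must satisfy "
                f"1 <= start <= end <= {RCRS_LENGTH}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def intersect(self, other: "Region") -> "Region | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        if lo > hi:
            return None
        return Region(lo, hi, self.label or other.label)


#: 315-bp HVR-I window used for network construction (np 16051-16365).
HVR1_NETWORK = Region(16051, 16365, "HVR-I/315")
#: Full HVR-I as used for the joint HVR-I+II analysis (np 16024-16383).
HVR1_FULL = Region(16024, 16383, "HVR-I")
#: HVR-II (np 57-372).
HVR2_FULL = Region(57, 372, "HVR-II")

FULL_RANGE = Region(1, RCRS_LENGTH, "rCRS")


@dataclass(frozen=True)
class Variant:
    """A single difference from the rCRS.

    Insertions are keyed to the np *after* which the inserted base sits;
    ``insert_index`` orders multiple insertions after the same anchor.
    """

    position: int
    kind: str
    ref_allele: str = ""
    derived_allele: str = ""
    insert_index: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise ValueError(f"variant position {self.position} outside rCRS")
        if self.kind == SUBSTITUTION:
            if self.ref_allele not in BASES or self.derived_allele not in BASES:
                raise ValueError(f"substitution alleles must be bases: {self}")
            if self.ref_allele == self.derived_allele:
                raise ValueError(f"substitution with identical alleles: {self}")
        elif self.kind == DELETION:
            if self.derived_allele != "":
                raise ValueError(f"deletion with a derived allele: {self}")
        elif self.kind == INSERTION:
            if self.ref_allele != "" or self.derived_allele not in BASES:
                raise ValueError(f"malformed insertion: {self}")
            if self.insert_index < 1:
                raise ValueError(f"insert_index must be >= 1: {self}")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def key(self) -> tuple:
        """Identity of the mutated site: (position, kind, insert_index)."""
        return (self.position, self.kind, self.insert_index)

    @property
    def label(self) -> str:
        if self.kind == SUBSTITUTION:
            return f"{self.position}{self.derived_allele}"
        if self.kind == DELETION:
            return f"{self.position}d"
        return f"{self.position}.{self.insert_index}{self.derived_allele}"


def key_label(key: tuple) -> str:
    """Human-readable label for a canonical differing-site key.

    Canonical keys are produced by :func:`pairwise_distance`:
    ``("sub", np)``, ``("ins", np, index)`` and ``("del", start, end)``
    (a deletion key may span a merged run of contiguous deleted positions).
    """
    kind = key[0]
    if kind == "sub":
        return str(key[1])
    if kind == "ins":
        return f"{key[1]}.{key[2]}"
    start, end = key[1], key[2]
    return f"{start}d" if start == end else f"{start}-{end}d"


def key_position(key: tuple) -> int:
    return key[1]


def key_is_indel(key: tuple) -> bool:
    return key[0] in ("ins", "del")


def is_excluded(excluded, position: int, kind: str) -> bool:
    """Whether a site is suppressed by an exclusion specification.

    ``excluded`` may be ``None``, a plain set of np positions, or any object
    exposing ``positions`` plus optional ``exclude_indels`` /
    ``exclude_poly_indels`` flags (duck-typed so that
    :class:`mtcr.sites.ExclusionSet` works without a circular import).
    """
    if excluded is None:
        return False
    if isinstance(excluded, (set, frozenset)):
        return position in excluded
    if position in getattr(excluded, "positions", ()):
        return True
    if kind != "sub" and kind != SUBSTITUTION:
        if getattr(excluded, "exclude_indels", False):
            return True
        if getattr(excluded, "exclude_poly_indels", False):
            return any(a <= position <= b for a, b in POLY_STRETCHES)
    return False


def key_is_excluded(key: tuple, excluded) -> bool:
    return is_excluded(excluded, key[1], key[0])


def _merge_regions(regions: Iterable[Region]) -> tuple[Region, ...]:
    regs = sorted(regions, key=lambda r: (r.start, r.end))
    merged: list[Region] = []
    for r in regs:
        if merged and r.start <= merged[-1].end + 1:
            last = merged[-1]
            if r.end > last.end:
                merged[-1] = Region(last.start, r.end, last.label)
        else:
            merged.append(r)
    return tuple(merged)


def _subtract_intervals(
    regions: Sequence[Region], holes: Sequence[tuple[int, int]]
) -> tuple[Region, ...]:
    out: list[Region] = []
    for r in regions:
        pieces = [(r.start, r.end)]
        for lo, hi in holes:
            nxt = []
            for a, b in pieces:
                if hi < a or lo > b:
                    nxt.append((a, b))
                    continue
                if a < lo:
                    nxt.append((a, lo - 1))
                if hi < b:
                    nxt.append((hi + 1, b))
            pieces = nxt
        out.extend(Region(a, b, r.label) for a, b in pieces)
    return tuple(sorted(out))


def intersect_regions(
    a: Sequence[Region], b: Sequence[Region]
) -> tuple[Region, ...]:
    out = []
    for ra in a:
        for rb in b:
            ix = ra.intersect(rb)
            if ix is not None:
                out.append(ix)
    return _merge_regions(out)


@dataclass(frozen=True)
class Haplotype:
    """One individual's sequence, as a set of variants plus its coverage."""

    id: str
    variants: frozenset[Variant] = frozenset()
    covered_regions: tuple[Region, ...] = (FULL_RANGE,)
    population_id: str | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError(f"haplotype {self.id}: duplicate variant keys")
        for v in self.variants:
            if not self.covers(v.position):
                raise ValueError(
                    f"haplotype {self.id}: variant {v.label} outside coverage"
                )

    def covers(self, position: int) -> bool:
        return any(r.contains(position) for r in self.covered_regions)

    @property
    def fully_missing(self) -> bool:
        return not self.covered_regions

    def by_key(self) -> dict[tuple, Variant]:
        return {v.key: v for v in self.variants}

    def labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.variants)


@dataclass
class HaploPanel:
    """A validated collection of haplotypes sharing one reference."""

    haplotypes: list[Haplotype]
    reference_label: str = "rCRS"
    #: Table columns as parsed: tuples ``(position, kind, insert_index)``.
    columns: tuple[tuple, ...] = ()
    #: Reference allele per column key ("" for insertion columns).
    ref_alleles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [h.id for h in self.haplotypes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate haplotype ids in panel")

    def __len__(self) -> int:
        return len(self.haplotypes)

    def get(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.id == hap_id:
                return h
        raise KeyError(hap_id)

    def to_json(self) -> str:
        def enc_region(r: Region) -> dict:
            return {"start": r.start, "end": r.end, "label": r.label}

        def enc_variant(v: Variant) -> dict:
            return {
                "position": v.position,
                "kind": v.kind,
                "ref_allele": v.ref_allele,
                "derived_allele": v.derived_allele,
                "insert_index": v.insert_index,
            }

        return json.dumps(
            {
                "reference_label": self.reference_label,
                "columns": [list(c) for c in self.columns],
                "ref_alleles": {
                    "|".join(map(str, k)): v for k, v in self.ref_alleles.items()
                },
                "haplotypes": [
                    {
                        "id": h.id,
                        "population_id": h.population_id,
                        "flagged": h.flagged,
                        "variants": sorted(
                            (enc_variant(v) for v in h.variants),
                            key=lambda d: (d["position"], d["kind"], d["insert_index"]),
                        ),
                        "covered_regions": [enc_region(r) for r in h.covered_regions],
                    }
                    for h in self.haplotypes
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "HaploPanel":
        raw = json.loads(text)
        haps = []
        for h in raw["haplotypes"]:
            haps.append(
                Haplotype(
                    id=h["id"],
                    population_id=h.get("population_id"),
                    flagged=h.get("flagged", False),
                    variants=frozenset(Variant(**v) for v in h["variants"]),
                    covered_regions=tuple(
                        Region(r["start"], r["end"], r.get("label", ""))
                        for r in h["covered_regions"]
                    ),
                )
            )
        cols = tuple(tuple(c) for c in raw.get("columns", []))
        refs = {}
        for k, v in raw.get("ref_alleles", {}).items():
            pos, kind, idx = k.split("|")
            refs[(int(pos), kind, int(idx))] = v
        return cls(haps, raw.get("reference_label", "rCRS"), cols, refs)


_COLUMN_RE = re.compile(r"^(\d+)(i)(\d*)$|^(\d+)$")


def _parse_header(header: Sequence[str]):
    """Split header cells into metadata columns and position columns."""
    meta_cols: list[int] = []
    pos_cols: list[tuple[int, tuple]] = []  # (cell index, column key)
    seen = set()
    for j, name in enumerate(header[1:], start=1):
        name = name.strip()
        m = _COLUMN_RE.match(name)
        if not m:
            meta_cols.append(j)
            continue
        if m.group(4) is not None:
            key = (int(m.group(4)), SUBSTITUTION, 1)
        else:
            idx = int(m.group(3)) if m.group(3) else 1
            key = (int(m.group(1)), INSERTION, idx)
        if key in seen:
            raise ValueError(f"duplicate position column {name!r}")
        seen.add(key)
        pos_cols.append((j, key))
    return meta_cols, pos_cols


def parse_variant_table(table_text: str, reference_label: str = "rCRS") -> HaploPanel:
    """Parse a tab-separated variant table into a :class:`HaploPanel`.

    Dialect: the header row names rCRS positions (an integer, or an integer
    followed by ``i`` for insertion columns); a reference row labelled with
    ``reference_label`` gives the reference alleles; body cells are ``.``
    (identity with the reference), a base (substitution, or the inserted
    base in an insertion column), ``d`` (deletion) or blank (no data).
    Runs of contiguous blank columns in a row become one missing interval
    of that haplotype's coverage.  Leading non-positional columns (e.g. a
    birthplace) are carried as the population label.
    """
    lines = [ln for ln in table_text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError("variant table needs a header and a reference row")
    rows = [ln.rstrip("\n").split("\t") for ln in lines]
    header = rows[0]
    meta_cols, pos_cols = _parse_header(header)
    if not pos_cols:
        raise ValueError("no position columns found in header")

    ref_row = None
    body = []
    for r in rows[1:]:
        r = list(r) + [""] * (len(header) - len(r))
        if r[0].strip() == reference_label:
            if ref_row is not None:
                raise ValueError("multiple reference rows")
            ref_row = r
        else:
            body.append(r)
    if ref_row is None:
        raise ValueError(f"reference row {reference_label!r} not found")

    ref_alleles: dict[tuple, str] = {}
    for j, key in pos_cols:
        cell = ref_row[j].strip()
        if key[1] == INSERTION:
            if cell not in ("", "-", "."):
                raise ValueError(
                    f"reference allele for insertion column {header[j]} must be empty"
                )
            ref_alleles[key] = ""
        else:
            if cell.upper() not in BASES:
                raise ValueError(
                    f"reference allele {cell!r} in column {header[j]} is not a base"
                )
            ref_alleles[key] = cell.upper()

    haplotypes = []
    for r in body:
        hap_id = r[0].strip()
        if not hap_id:
            raise ValueError("row with empty sample id")
        population = r[meta_cols[0]].strip() if meta_cols else None
        variants: set[Variant] = set()
        blanks: list[int] = []  # indices into pos_cols
        for k, (j, key) in enumerate(pos_cols):
            cell = r[j].strip()
            pos, kind, idx = key
            ref = ref_alleles[key]
            if cell == "":
                blanks.append(k)
            elif cell == ".":
                pass
            elif cell.lower() == "d":
                if kind == INSERTION:
                    raise ValueError(
                        f"deletion symbol in insertion column {header[j]}, row {hap_id}"
                    )
                variants.add(Variant(pos, DELETION, ref_allele=ref))
            elif cell.upper() in BASES:
                base = cell.upper()
                if kind == INSERTION:
                    variants.add(
                        Variant(pos, INSERTION, derived_allele=base, insert_index=idx)
                    )
                elif base == ref:
                    warnings.warn(
                        f"row {hap_id}, column {header[j]}: cell equals the "
                        "reference allele; no variant recorded"
                    )
                else:
                    variants.add(Variant(pos, SUBSTITUTION, ref, base))
            else:
                raise ValueError(
                    f"unknown cell symbol {cell!r} in row {hap_id}, column {header[j]}"
                )
        holes = []
        if blanks:
            run_start = blanks[0]
            prev = blanks[0]
            for k in blanks[1:] + [None]:
                if k is not None and k == prev + 1:
                    prev = k
                    continue
                holes.append(
                    (pos_cols[run_start][1][0], pos_cols[prev][1][0])
                )
                if k is not None:
                    run_start = prev = k
        covered = _subtract_intervals([FULL_RANGE], holes)
        haplotypes.append(
            Haplotype(
                id=hap_id,
                population_id=population or None,
                variants=frozenset(variants),
                covered_regions=covered,
            )
        )
    columns = tuple(key for _, key in pos_cols)
    return HaploPanel(haplotypes, reference_label, columns, ref_alleles)


def serialize_variant_table(
    panel: HaploPanel, population_header: str = "Population"
) -> str:
    """Write a panel back to the variant-table TSV dialect."""
    columns = panel.columns
    if not columns:
        keys = sorted(
            {v.key for h in panel.haplotypes for v in h.variants},
            key=lambda k: (k[0], k[1] == INSERTION, k[2]),
        )
        columns = tuple(keys)
    refs = dict(panel.ref_alleles)
    for key in columns:
        if key not in refs:
            for h in panel.haplotypes:
                v = h.by_key().get(key)
                if v is not None:
                    refs[key] = v.ref_allele
                    break
            else:
                refs[key] = "N" if key[1] != INSERTION else ""

    def col_name(key: tuple) -> str:
        pos, kind, idx = key
        if kind == INSERTION:
            return f"{pos}i" if idx == 1 else f"{pos}i{idx}"
        return str(pos)

    has_pop = any(h.population_id for h in panel.haplotypes)
    out = ["Sample ID"] + (["Population"] if has_pop else [])
    out = ["\t".join(out + [col_name(k) for k in columns])]
    ref_cells = [refs[k] if k[1] != INSERTION else "-" for k in columns]
    out.append(
        "\t".join([panel.reference_label] + ([""] if has_pop else []) + ref_cells)
    )
    for h in panel.haplotypes:
        by_key = h.by_key()
        cells = []
        for key in columns:
            pos, kind, idx = key
            if not h.covers(pos):
                cells.append("")
                continue
            if kind == INSERTION:
                v = by_key.get((pos, INSERTION, idx))
            else:
                # a plain position column holds either a substitution or a
                # deletion at that np
                v = by_key.get((pos, SUBSTITUTION, 1)) or by_key.get(
                    (pos, DELETION, 1)
                )
            if v is None:
                cells.append(".")
            elif v.kind == DELETION:
                cells.append("d")
            else:
                cells.append(v.derived_allele)
        row = [h.id] + ([h.population_id or ""] if has_pop else []) + cells
        out.append("\t".join(row))
    return "\n".join(out) + "\n"


def trim_to_regions(panel: HaploPanel, regions: Sequence[Region]) -> HaploPanel:
    """Restrict a panel to the given analysis windows.

    Variants outside the windows are dropped and coverage is intersected;
    haplotypes left with zero coverage are retained but flagged.
    """
    if not regions:
        raise ValueError("empty region list")
    regs = _merge_regions(regions)
    haps = []
    for h in panel.haplotypes:
        covered = intersect_regions(h.covered_regions, regs)
        variants = frozenset(
            v for v in h.variants if any(r.contains(v.position) for r in regs)
        )
        haps.append(
            replace(
                h,
                variants=variants,
                covered_regions=covered,
                flagged=h.flagged or not covered,
            )
        )
    columns = tuple(
        k for k in panel.columns if any(r.contains(k[0]) for r in regs)
    )
    refs = {k: v for k, v in panel.ref_alleles.items() if k in columns}
    return HaploPanel(haps, panel.reference_label, columns, refs)


def pairwise_distance(
    h1: Haplotype,
    h2: Haplotype,
    weights=None,
    excluded=None,
    merge_contiguous_deletions: bool = True,
) -> tuple[float, list[tuple]]:
    """Weighted mutational distance between two haplotypes.

    Only positions covered in *both* haplotypes and not excluded are
    compared (pairwise complete-deletion, so mixed HVR-I-only and
    HVR-I+II records remain comparable).  Each differing site contributes
    its weight; a maximal run of contiguous deleted positions counts as a
    single event by default.  Returns ``(distance, differing_keys)`` where
    keys are canonical tuples (see :func:`key_label`).
    """
    weight_at = (lambda p: 1) if weights is None else weights.weight_at
    k1, k2 = h1.by_key(), h2.by_key()
    diff_keys: list[tuple] = []
    del_positions: list[int] = []
    for key in set(k1) | set(k2):
        pos, kind, idx = key
        if not (h1.covers(pos) and h2.covers(pos)):
            continue
        if is_excluded(excluded, pos, kind):
            continue
        v1, v2 = k1.get(key), k2.get(key)
        a1 = v1.derived_allele if v1 is not None else None
        a2 = v2.derived_allele if v2 is not None else None
        present1, present2 = v1 is not None, v2 is not None
        if present1 == present2 and a1 == a2:
            continue
        if kind == DELETION:
            del_positions.append(pos)
        elif kind == INSERTION:
            diff_keys.append(("ins", pos, idx))
        else:
            diff_keys.append(("sub", pos))
    if del_positions:
        del_positions.sort()
        if merge_contiguous_deletions:
            run_start = prev = del_positions[0]
            for p in del_positions[1:] + [None]:
                if p is not None and p == prev + 1:
                    prev = p
                    continue
                diff_keys.append(("del", run_start, prev))
                if p is not None:
                    run_start = prev = p
        else:
            diff_keys.extend(("del", p, p) for p in del_positions)
    diff_keys.sort(key=lambda k: (k[1], k[0], k[2] if len(k) > 2 else 0))
    distance = sum(weight_at(k[1]) for k in diff_keys)
    return distance, diff_keys


def export_fasta(
    panel: HaploPanel, reference_segment: str, region: Region
) -> str:
    """Reconstruct literal sequences over ``region`` and emit FASTA.

    Substitutions replace the reference base, deletions remove it,
    insertions are placed after their anchor np (ordered by insert index)
    and uncovered stretches are written as ``N``.
    """
    reference_segment = reference_segment.upper()
    if len(reference_segment) != len(region):
        raise ValueError(
            f"reference segment length {len(reference_segment)} != region "
            f"length {len(region)}"
        )
    records = []
    for h in panel.haplotypes:
        outside = [v for v in h.variants if not region.contains(v.position)]
        if outside:
            raise ValueError(
                f"haplotype {h.id} has variants outside {region.start}.."
                f"{region.end}: {sorted(v.label for v in outside)}"
            )
        by_key = h.by_key()
        subs = {v.position: v for v in h.variants if v.kind == SUBSTITUTION}
        dels = {v.position for v in h.variants if v.kind == DELETION}
        inserts: dict[int, list[Variant]] = {}
        for v in h.variants:
            if v.kind == INSERTION:
                inserts.setdefault(v.position, []).append(v)
        chars: list[str] = []
        for pos in range(region.start, region.end + 1):
            ref_base = reference_segment[pos - region.start]
            if not h.covers(pos):
                chars.append("N")
            elif pos in dels:
                pass
            elif pos in subs:
                chars.append(subs[pos].derived_allele)
            else:
                chars.append(ref_base)
            for ins in sorted(inserts.get(pos, []), key=lambda v: v.insert_index):
                chars.append(ins.derived_allele)
        records.append(
            SeqRecord(Seq("".join(chars)), id=h.id, description="")
        )
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def diff_against_reference(
    sequence: str, reference_segment: str, region: Region
) -> frozenset[Variant]:
    """Call substitutions of an aligned literal sequence vs the reference.

    Intended for round-trip checks on substitution-only haplotypes; the two
    strings must be the same length (no indels) and ``N`` is skipped.
    """
    sequence, reference_segment = sequence.upper(), reference_segment.upper()
    if len(sequence) != len(reference_segment) or len(sequence) != len(region):
        raise ValueError("sequence, reference and region lengths differ")
    out = set()
    for i, (a, b) in enumerate(zip(reference_segment, sequence)):
        if b == "N" or a == b:
            continue
        out.add(Variant(region.start + i, SUBSTITUTION, a, b))
    return frozenset(out)
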