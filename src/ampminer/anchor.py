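"""Pseudochromosome construction from a genetic linkage map.

Markers from an external linkage map (linkage group + centimorgan position
+ flanking sequence) are located on the assembly by exact, unique substring
match of the flank on either strand. Scaffolds then enter the build only
with at least two placed markers (the minimum for an orientation signal and
a guard against spurious placements); each eligible scaffold is assigned
the majority linkage group of its markers, positioned at the median cM of
those markers, and oriented by the sign of the Spearman rank correlation
between marker base-pair offset and cM. Ordered, oriented scaffolds are
joined with fixed-length N gaps into pseudochromosomes, described by AGP
2.0 rows, and feature coordinates lift over from scaffold to chromosome
space.

Coordinates are 0-based half-open internally; AGP rows, liftover results
and all emitted tables are 1-based inclusive, matching the formats'
standards.
"""

from __future__ import annotations

import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as _scipy_stats

from ._util import revcomp

MIN_FLANK = 20
DEFAULT_GAP_LENGTH = 100
MARKER_TSV_COLUMNS = ("marker_id", "linkage_group", "cM", "flank_id")


@dataclass(frozen=True)
class Marker:
    marker_id: str
    linkage_group: int
    cM: float
    flank: str

    def __post_init__(self):
        if len(self.flank) < MIN_FLANK:
            raise ValueError(
                f"marker {self.marker_id}: flank shorter than {MIN_FLANK} bp "
                "is unplaceable"
            )
        if not (self.cM >= 0 and self.cM == self.cM):
            raise ValueError(f"marker {self.marker_id}: cM must be finite and >= 0")


@dataclass(frozen=True)
class MarkerPlacement:
    marker_id: str
    scaffold_id: str
    offset: int  # 0-based position of the flank start on the forward strand
    strand: str


@dataclass(frozen=True)
class ScaffoldAssignment:
    scaffold_id: str
    linkage_group: int
    anchor_cM: float  # median cM of its markers on the winning LG
    orientation: str  # '+', '-' or '?' (treated as '+')
    n_markers: int


@dataclass(frozen=True)
class AGPRow:
    """One AGP 2.0 row; component ('W') or unknown gap ('U')."""

    obj: str
    obj_beg: int  # 1-based inclusive
    obj_end: int
    part_number: int
    component_type: str  # 'W' or 'U'
    fields: tuple  # W: (component_id, beg, end, orientation)
    #               U: (gap_length, gap_type, linkage, evidence)

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.obj,
                self.obj_beg,
                self.obj_end,
                self.part_number,
                self.component_type,
                *self.fields,
            )
        )


@dataclass
class PseudochromosomeBuild:
    chromosome_id: str
    components: list[tuple[str, str]]  # (scaffold_id, orientation) in order
    agp_rows: list[AGPRow]
    length: int


# ---------------------------------------------------------------------------
# marker I/O

def load_markers(marker_tsv: str | Path, flank_fasta: str | Path) -> list[Marker]:
    """Read the marker table (``marker_id linkage_group cM flank_id``) and
    its companion flank FASTA."""
    from Bio import SeqIO

    flanks = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(flank_fasta), "fasta")}
    df = pd.read_csv(marker_tsv, sep="\t")
    missing = set(MARKER_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    markers = []
    for row in df.itertuples(index=False):
        if row.flank_id not in flanks:
            raise ValueError(f"marker {row.marker_id}: flank {row.flank_id} not in FASTA")
        markers.append(
            Marker(str(row.marker_id), int(row.linkage_group), float(row.cM), flanks[row.flank_id])
        )
    return markers


# ---------------------------------------------------------------------------
# placement

def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def place_markers(
    markers: Sequence[Marker], scaffolds: Mapping[str, str]
) -> tuple[list[MarkerPlacement], list[tuple[str, str]]]:
    """Place each marker whose flank (or its reverse complement) occurs
    exactly once across all scaffolds; others are dropped with a reason
    ('absent' or 'ambiguous'). Drops are data, not errors."""
    placements: list[MarkerPlacement] = []
    dropped: list[tuple[str, str]] = []
    upper = {sid: seq.upper() for sid, seq in scaffolds.items()}
    for marker in markers:
        flank = marker.flank.upper()
        rc = revcomp(flank)
        matches: list[MarkerPlacement] = []
        for sid, seq in upper.items():
            for pos in _find_all(seq, flank):
                matches.append(MarkerPlacement(marker.marker_id, sid, pos, "+"))
            if rc != flank:
                for pos in _find_all(seq, rc):
                    matches.append(MarkerPlacement(marker.marker_id, sid, pos, "-"))
        if not matches:
            dropped.append((marker.marker_id, "absent"))
        elif len(matches) > 1:
            dropped.append((marker.marker_id, "ambiguous"))
        else:
            placements.append(matches[0])
    return placements, dropped


def enforce_min_markers(
    placements: Sequence[MarkerPlacement], min_markers: int = 2
) -> tuple[dict[str, list[MarkerPlacement]], list[str]]:
    """Partition scaffolds into those with at least ``min_markers`` placed
    markers (eligible for anchoring) and the excluded rest."""
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    by_scaffold: dict[str, list[MarkerPlacement]] = defaultdict(list)
    for p in placements:
        by_scaffold[p.scaffold_id].append(p)
    eligible = {s: ps for s, ps in by_scaffold.items() if len(ps) >= min_markers}
    excluded = sorted(s for s in by_scaffold if s not in eligible)
    return eligible, excluded


# ---------------------------------------------------------------------------
# linkage-group assignment and ordering

def assign_linkage_group(
    scaffold_id: str,
    scaffold_placements: Sequence[MarkerPlacement],
    markers_by_id: Mapping[str, Marker],
    min_markers: int = 2,
) -> ScaffoldAssignment | None:
    """Majority-vote linkage group over the scaffold's markers; anchor
    position is the median cM of the winning-LG markers. A tied vote, or
    fewer than ``min_markers`` markers on the winning LG, disqualifies the
    scaffold (returns None)."""
    lgs = [markers_by_id[p.marker_id].linkage_group for p in scaffold_placements]
    votes = Counter(lgs).most_common()
    if len(votes) > 1 and votes[0][1] == votes[1][1]:
        return None  # tie: conflicted scaffold
    lg, n_win = votes[0]
    if n_win < min_markers:
        return None
    cms = [
        markers_by_id[p.marker_id].cM
        for p in scaffold_placements
        if markers_by_id[p.marker_id].linkage_group == lg
    ]
    orientation = _orientation(scaffold_placements, markers_by_id, lg)
    return ScaffoldAssignment(
        scaffold_id=scaffold_id,
        linkage_group=lg,
        anchor_cM=statistics.median(cms),
        orientation=orientation,
        n_markers=n_win,
    )


def _orientation(
    scaffold_placements: Sequence[MarkerPlacement],
    markers_by_id: Mapping[str, Marker],
    lg: int,
) -> str:
    """Sign of the Spearman rank correlation between marker bp offset and
    cM: '+' if increasing, '-' if decreasing, '?' if flat (all cM equal)."""
    pairs = [
        (p.offset, markers_by_id[p.marker_id].cM)
        for p in scaffold_placements
        if markers_by_id[p.marker_id].linkage_group == lg
    ]
    offsets, cms = zip(*sorted(pairs))
    if len(set(cms)) == 1 or len(set(offsets)) == 1:
        return "?"
    rho = _scipy_stats.spearmanr(offsets, cms).statistic
    if rho > 0:
        return "+"
    if rho < 0:
        return "-"
    return "?"


def order_and_orient(
    assignments: Sequence[ScaffoldAssignment],
) -> list[tuple[str, str]]:
    """Order one linkage group's scaffolds by ascending anchor cM (ties by
    scaffold id) and resolve '?' orientations to '+'."""
    lgs = {a.linkage_group for a in assignments}
    if len(lgs) > 1:
        raise ValueError(f"assignments span multiple linkage groups: {sorted(lgs)}")
    ordered = sorted(assignments, key=lambda a: (a.anchor_cM, a.scaffold_id))
    return [
        (a.scaffold_id, "+" if a.orientation == "?" else a.orientation)
        for a in ordered
    ]


# ---------------------------------------------------------------------------
# build, AGP, liftover

def build_pseudochromosomes(
    orders: Mapping[int, Sequence[tuple[str, str]]],
    scaffolds: Mapping[str, str],
    gap_length: int = DEFAULT_GAP_LENGTH,
    chromosome_prefix: str = "Chr",
) -> dict[str, PseudochromosomeBuild]:
    """Join each linkage group's ordered, oriented scaffolds with
    ``gap_length`` unknown-gap ('U') records into one pseudochromosome per
    group. Linkage group g becomes object ``Chr{g}``."""
    builds: dict[str, PseudochromosomeBuild] = {}
    for lg in sorted(orders):
        chrom = f"{chromosome_prefix}{lg}"
        rows: list[AGPRow] = []
        pos = 0  # 0-based running object offset
        part = 0
        components: list[tuple[str, str]] = []
        for idx, (sid, orientation) in enumerate(orders[lg]):
            if sid not in scaffolds:
                raise KeyError(f"scaffold {sid} has no sequence")
            if idx > 0 and gap_length > 0:
                part += 1
                rows.append(
                    AGPRow(chrom, pos + 1, pos + gap_length, part, "U",
                           (gap_length, "scaffold", "yes", "map"))
                )
                pos += gap_length
            length = len(scaffolds[sid])
            part += 1
            rows.append(
                AGPRow(chrom, pos + 1, pos + length, part, "W",
                       (sid, 1, length, orientation))
            )
            pos += length
            components.append((sid, orientation))
        builds[chrom] = PseudochromosomeBuild(chrom, components, rows, pos)
    return builds


def build_sequences(
    builds: Mapping[str, PseudochromosomeBuild], scaffolds: Mapping[str, str]
) -> dict[str, str]:
    """Realise pseudochromosome sequences from AGP rows ('-' components
    appear reverse-complemented, gaps as N runs)."""
    out: dict[str, str] = {}
    for chrom, build in builds.items():
        parts: list[str] = []
        for row in build.agp_rows:
            if row.component_type == "U":
                parts.append("N" * int(row.fields[0]))
            else:
                sid, _, _, orientation = row.fields
                seq = scaffolds[sid]
                parts.append(revcomp(seq) if orientation == "-" else seq)
        out[chrom] = "".join(parts)
        assert len(out[chrom]) == build.length
    return out


def write_agp(builds: Mapping[str, PseudochromosomeBuild], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for chrom in sorted(builds, key=lambda c: builds[c].agp_rows[0].obj):
            for row in builds[chrom].agp_rows:
                fh.write(row.to_line() + "\n")


def liftover(
    builds: Mapping[str, PseudochromosomeBuild] | PseudochromosomeBuild,
    scaffold_id: str,
    start: int,
    end: int,
    strand: str = "+",
) -> tuple[str, int, int, str] | None:
    """Lift a scaffold feature (1-based inclusive) to chromosome
    coordinates; returns None for features on unanchored scaffolds.

    On '-' placed scaffolds the interval is mirrored and the strand
    flipped, so the lifted interval always spells the same sequence (up to
    strand) in the chromosome FASTA.
    """
    if isinstance(builds, PseudochromosomeBuild):
        builds = {builds.chromosome_id: builds}
    if not (1 <= start <= end):
        raise ValueError(f"bad feature interval [{start}, {end}]")
    for build in builds.values():
        for row in build.agp_rows:
            if row.component_type != "W" or row.fields[0] != scaffold_id:
                continue
            _, comp_beg, comp_end, orientation = row.fields
            scaf_len = comp_end - comp_beg + 1
            if end > scaf_len:
                raise ValueError(
                    f"feature [{start}, {end}] exceeds scaffold {scaffold_id} "
                    f"length {scaf_len}"
                )
            if orientation == "-":
                new_start = row.obj_beg - 1 + (scaf_len - end + 1)
                new_end = row.obj_beg - 1 + (scaf_len - start + 1)
                new_strand = "-" if strand == "+" else "+"
            else:
                new_start = row.obj_beg - 1 + start
                new_end = row.obj_beg - 1 + end
                new_strand = strand
            return build.chromosome_id, new_start, new_end, new_strand
    return None


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class AnchorResult:
    builds: dict[str, PseudochromosomeBuild]
    assignments: list[ScaffoldAssignment]
    placements: list[MarkerPlacement]
    dropped_markers: list[tuple[str, str]]
    unplaced_scaffolds: list[str]
    report: dict


def anchor_pipeline(
    markers: Sequence[Marker],
    scaffolds: Mapping[str, str],
    min_markers: int = 2,
    gap_length: int = DEFAULT_GAP_LENGTH,
    chromosome_prefix: str = "Chr",
) -> AnchorResult:
    """Run the full anchoring chain: place markers, enforce the >=2-marker
    rule, assign linkage groups, order/orient, and build AGP objects."""
    markers_by_id = {m.marker_id: m for m in markers}
    placements, dropped = place_markers(markers, scaffolds)
    eligible, excluded = enforce_min_markers(placements, min_markers)

    assignments: list[ScaffoldAssignment] = []
    conflicted: list[str] = []
    for sid in sorted(eligible):
        a = assign_linkage_group(sid, eligible[sid], markers_by_id, min_markers)
        if a is None:
            conflicted.append(sid)
        else:
            assignments.append(a)

    by_lg: dict[int, list[ScaffoldAssignment]] = defaultdict(list)
    for a in assignments:
        by_lg[a.linkage_group].append(a)
    orders = {lg: order_and_orient(by_lg[lg]) for lg in by_lg}
    builds = build_pseudochromosomes(
        orders, scaffolds, gap_length=gap_length, chromosome_prefix=chromosome_prefix
    )

    anchored = {a.scaffold_id for a in assignments}
    unplaced = sorted(set(scaffolds) - anchored)
    anchored_bases = sum(len(scaffolds[s]) for s in anchored)
    total_bases = sum(len(s) for s in scaffolds.values())
    report = {
        "n_markers": len(markers),
        "n_markers_placed": len(placements),
        "n_markers_dropped": len(dropped),
        "n_scaffolds": len(scaffolds),
        "n_scaffolds_anchored": len(anchored),
        "n_scaffolds_excluded_few_markers": len(excluded),
        "n_scaffolds_conflicted": len(conflicted),
        "n_chromosomes": len(builds),
        "anchored_bases": anchored_bases,
        "anchored_fraction": anchored_bases / total_bases if total_bases else 0.0,
    }
    return AnchorResult(builds, assignments, placements, dropped, unplaced, report)
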