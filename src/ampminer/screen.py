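"""Homology-based antimicrobial-peptide (AMP) gene screening.

Peptide queries from an APD3-style database (FASTA headers
``>ID|name|class``) are searched against a coding-sequence gene set the
way a protein-vs-translated-nucleotide (tblastn-style) search would run:
each CDS is translated in all six frames and every query is aligned to
every frame by exact Smith-Waterman local dynamic programming (BLOSUM62,
affine gaps open 11 / extend 1, so a gap of length g costs 11 + g).
Running the full DP instead of a seeded heuristic makes scores
deterministic and directly testable; it is practical because gene-set
screens at this scale are small.

Significance follows the Karlin-Altschul formula with the gapped BLOSUM62
constants (lambda = 0.267, K = 0.041):

    bitscore = (lambda * S - ln K) / ln 2
    E        = m * n * 2**(-bitscore)

with m the query length and n the total translated database length. No
edge-effect or finite-size corrections are applied, so E-values are not
numerically identical to NCBI BLAST's; the screen's thresholds (E <= 1e-5
and query alignment ratio >= 0.5) dominate the outcome.

Surviving hits are deduplicated to one best hit per gene, classified by
the best hit's query class, renamed class-plus-serial (e.g. Thrombin1),
and optionally localised to pseudochromosomes via a linkage-map build.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from ._util import revcomp
from .metrics import natural_chromosome_key

# Karlin-Altschul constants for gapped BLOSUM62, open 11 / extend 1
LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_MIN_QUERY_RATIO = 0.5

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]
_SUBMAT = np.array(_BLOSUM62, dtype=np.int32)

FRAMES = (1, 2, 3, -1, -2, -3)


# ---------------------------------------------------------------------------
# query database

@dataclass(frozen=True)
class AMPQuery:
    """One peptide query with its APD3-style class annotation."""

    query_id: str
    name: str
    amp_class: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 5:
            raise ValueError(f"query {self.query_id}: peptide shorter than 5 aa")
        bad = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ValueError(
                f"query {self.query_id}: non-standard residues {sorted(bad)}"
            )


def read_query_db(path: str | Path) -> list[AMPQuery]:
    """Parse a query FASTA with ``>ID|name|class`` headers.

    Malformed headers and duplicate IDs raise with the offending record
    named; an empty database is an error.
    """
    queries: list[AMPQuery] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.description.split("|")
        if len(parts) != 3 or not all(p.strip() for p in parts):
            raise ValueError(
                f"malformed query header (expected 'ID|name|class'): "
                f"'>{record.description}'"
            )
        qid, name, amp_class = (p.strip() for p in parts)
        if qid in seen:
            raise ValueError(f"duplicate query id: {qid}")
        seen.add(qid)
        queries.append(
            AMPQuery(qid, name, amp_class.lower(), str(record.seq).upper())
        )
    if not queries:
        raise ValueError(f"query database {path} is empty")
    return queries


def write_query_db(queries: Iterable[AMPQuery], path: str | Path) -> None:
    with open(path, "w") as fh:
        for q in queries:
            fh.write(f">{q.query_id}|{q.name}|{q.amp_class}\n{q.sequence}\n")


# ---------------------------------------------------------------------------
# six-frame translation

def six_frame_translate(cds: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six frames.

    Standard genetic code; stop codons stay in-frame as '*' (they simply
    score badly in the alignment), codons containing N become 'X'.
    Frames -1..-3 are the +1..+3 frames of the reverse complement.
    """
    seq = cds.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("CDS contains characters outside {A,C,G,T,N}")
    frames: dict[int, str] = {}
    rc = revcomp(seq)
    for off in range(3):
        for sign, s in ((1, seq), (-1, rc)):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            frames[sign * (off + 1)] = str(Seq(sub).translate()) if sub else ""
    return frames


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment (Gotoh affine-gap DP)

@njit(cache=False)
def _sw_fill(q, t, sub, first_gap, gap_ext):  # pragma: no cover - jitted
    n, m = q.shape[0], t.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), -10**8, np.int32)
    F = np.full((n + 1, m + 1), -10**8, np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - first_gap, E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - first_gap, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    return H, E, F, best, bi, bj


@dataclass(frozen=True)
class LocalAlignment:
    """Best-scoring local alignment of a peptide pair (1-based inclusive)."""

    raw_score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float  # percent over aligned columns (gaps included)
    aligned_columns: int


def _encode_peptide(seq: str) -> np.ndarray:
    return np.array(
        [_AA_INDEX.get(aa, _X_INDEX) for aa in seq.upper()], dtype=np.int64
    )


def local_align(query: str, target: str) -> LocalAlignment | None:
    """Best local alignment of ``query`` vs ``target`` under BLOSUM62 with
    affine gaps (open 11 / extend 1). Returns None if no positive-scoring
    alignment exists. Ties on the end cell break toward the earliest
    (query, target) position; the traceback prefers match over gap states.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    q = _encode_peptide(query)
    t = _encode_peptide(target)
    H, E, F, best, bi, bj = _sw_fill(
        q, t, _SUBMAT, np.int32(GAP_OPEN + GAP_EXTEND), np.int32(GAP_EXTEND)
    )
    if best <= 0:
        return None

    i, j = bi, bj
    state = "H"
    matches = 0
    columns = 0
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + _SUBMAT[q[i - 1], t[j - 1]]:
                columns += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query, consume target
            columns += 1
            if E[i, j] == H[i, j - 1] - (GAP_OPEN + GAP_EXTEND):
                state = "H"
            j -= 1
        else:  # gap in target, consume query
            columns += 1
            if F[i, j] == H[i - 1, j] - (GAP_OPEN + GAP_EXTEND):
                state = "H"
            i -= 1
    return LocalAlignment(
        raw_score=int(best),
        query_start=i + 1,
        query_end=bi,
        target_start=j + 1,
        target_end=bj,
        identity=100.0 * matches / columns,
        aligned_columns=columns,
    )


def evalue_from_score(
    raw_score: int, query_length: int, total_translated_db_length: int
) -> tuple[float, float]:
    """(bitscore, E-value) under the Karlin-Altschul statistics described
    in the module docstring."""
    if query_length <= 0 or total_translated_db_length <= 0:
        raise ValueError("lengths must be positive")
    bitscore = (LAMBDA * raw_score - math.log(KA_K)) / math.log(2)
    evalue = query_length * total_translated_db_length * 2.0 ** (-bitscore)
    return bitscore, evalue


# ---------------------------------------------------------------------------
# screening

@dataclass(frozen=True)
class AlignmentHit:
    """One query-vs-gene alignment (best frame), BLAST-tabular-like."""

    query_id: str
    gene_id: str
    frame: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    raw_score: int
    bitscore: float
    evalue: float
    identity: float
    query_alignment_ratio: float


def translated_db_length(cds_set: Mapping[str, str]) -> int:
    """Total residue count of the six-frame translated database."""
    return sum(
        len(frame) for cds in cds_set.values() for frame in six_frame_translate(cds).values()
    )


def align_queries(
    queries: Sequence[AMPQuery],
    cds_set: Mapping[str, str],
    db_length: int | None = None,
) -> list[AlignmentHit]:
    """Align every query against every gene's six frames; keep the best
    frame per (query, gene). Unfiltered."""
    if db_length is None:
        db_length = translated_db_length(cds_set)
    hits: list[AlignmentHit] = []
    for gene_id, cds in cds_set.items():
        frames = six_frame_translate(cds)
        for q in queries:
            best: tuple[int, int, LocalAlignment] | None = None
            for frame in FRAMES:
                pep = frames[frame]
                if not pep:
                    continue
                aln = local_align(q.sequence, pep)
                if aln is None:
                    continue
                if best is None or aln.raw_score > best[0]:
                    best = (aln.raw_score, frame, aln)
            if best is None:
                continue
            _, frame, aln = best
            bitscore, evalue = evalue_from_score(
                aln.raw_score, len(q.sequence), db_length
            )
            hits.append(
                AlignmentHit(
                    query_id=q.query_id,
                    gene_id=gene_id,
                    frame=frame,
                    query_start=aln.query_start,
                    query_end=aln.query_end,
                    target_start=aln.target_start,
                    target_end=aln.target_end,
                    raw_score=aln.raw_score,
                    bitscore=bitscore,
                    evalue=evalue,
                    identity=aln.identity,
                    query_alignment_ratio=(aln.query_end - aln.query_start + 1)
                    / len(q.sequence),
                )
            )
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_query_ratio: float = DEFAULT_MIN_QUERY_RATIO,
) -> list[AlignmentHit]:
    """Keep hits with E <= evalue_max and query alignment ratio >=
    min_query_ratio (hits covering less than half the query are noise)."""
    if evalue_max <= 0 or min_query_ratio <= 0:
        raise ValueError("thresholds must be positive")
    return [
        h
        for h in hits
        if h.evalue <= evalue_max and h.query_alignment_ratio >= min_query_ratio
    ]


def deduplicate(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """One best hit per gene: lowest E-value, ties by higher identity,
    then lower query_id — so one gene yields at most one putative AMP."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.gene_id)
        if cur is None or (h.evalue, -h.identity, h.query_id) < (
            cur.evalue,
            -cur.identity,
            cur.query_id,
        ):
            best[h.gene_id] = h
    return [best[g] for g in sorted(best)]


# ---------------------------------------------------------------------------
# catalog

@dataclass
class PutativeAMPGene:
    """A deduplicated, classified, renamed AMP candidate."""

    gene_id: str
    amp_class: str
    assigned_name: str
    hit: AlignmentHit
    chromosome: str | None = None  # None means unplaced
    start: int | None = None  # 1-based inclusive
    end: int | None = None
    strand: str | None = None

    @property
    def placed(self) -> bool:
        return self.chromosome is not None


def _location_sort_key(gene: PutativeAMPGene) -> tuple:
    if gene.placed:
        return (0, natural_chromosome_key(gene.chromosome), gene.start, gene.gene_id)
    return (1, (), 0, gene.gene_id)


def classify_and_name(
    dedup_hits: Sequence[AlignmentHit],
    queries: Sequence[AMPQuery],
    locations: Mapping[str, tuple[str, int, int, str]] | None = None,
) -> tuple[list[PutativeAMPGene], list[tuple[str, int]]]:
    """Assign each gene the class of its best-hit query and a class-serial
    name (``Thrombin1``, ``Thrombin2``, ...).

    Serials run within each class in (chromosome, start) order for placed
    genes, then gene_id for unplaced ones, so the naming is deterministic.
    Returns the catalog and the class distribution sorted by descending
    count (ties alphabetically).
    """
    by_id = {q.query_id: q for q in queries}
    missing = [h.query_id for h in dedup_hits if h.query_id not in by_id]
    if missing:
        raise ValueError(f"hits reference unknown queries: {sorted(set(missing))}")

    catalog: list[PutativeAMPGene] = []
    for h in dedup_hits:
        loc = (locations or {}).get(h.gene_id)
        catalog.append(
            PutativeAMPGene(
                gene_id=h.gene_id,
                amp_class=by_id[h.query_id].amp_class,
                assigned_name="",
                hit=h,
                chromosome=None if loc is None else loc[0],
                start=None if loc is None else loc[1],
                end=None if loc is None else loc[2],
                strand=None if loc is None else loc[3],
            )
        )
    catalog.sort(key=_location_sort_key)
    serial: dict[str, int] = {}
    for gene in catalog:
        serial[gene.amp_class] = serial.get(gene.amp_class, 0) + 1
        stem = gene.amp_class[:1].upper() + gene.amp_class[1:]
        gene.assigned_name = f"{stem}{serial[gene.amp_class]}"
    distribution = sorted(serial.items(), key=lambda kv: (-kv[1], kv[0]))
    return catalog, distribution


def localize_catalog(
    catalog: Sequence[PutativeAMPGene],
    gene_coords: Mapping[str, tuple[str, int, int, str]],
    builds,
) -> tuple[list[PutativeAMPGene], dict]:
    """Lift each catalog gene's scaffold coordinates onto the
    pseudochromosome builds; genes on unanchored scaffolds (or missing from
    the coordinate table) stay unplaced.

    ``gene_coords`` maps gene_id -> (scaffold_id, start, end, strand),
    1-based inclusive. Returns the updated catalog and a per-chromosome
    report (counts, max/min chromosome, mean per chromosome exact and
    floored).
    """
    from .anchor import liftover  # local import to avoid a cycle

    updated: list[PutativeAMPGene] = []
    warnings: list[str] = []
    for gene in catalog:
        coords = gene_coords.get(gene.gene_id)
        if coords is None:
            warnings.append(f"{gene.gene_id}: absent from coordinate table")
            updated.append(replace_location(gene, None))
            continue
        scaffold_id, start, end, strand = coords
        lifted = liftover(builds, scaffold_id, start, end, strand)
        updated.append(replace_location(gene, lifted))
    return updated, location_report(updated, warnings)


def location_report(catalog: Sequence[PutativeAMPGene], warnings=()) -> dict:
    """Per-chromosome counts over a localised catalog, with the max/min
    chromosomes and the mean per chromosome (exact and floored)."""
    per_chrom: dict[str, int] = {}
    for gene in catalog:
        if gene.placed:
            per_chrom[gene.chromosome] = per_chrom.get(gene.chromosome, 0) + 1
    n_placed = sum(per_chrom.values())
    report = {
        "n_genes": len(catalog),
        "n_placed": n_placed,
        "n_unplaced": len(catalog) - n_placed,
        "per_chromosome": dict(
            sorted(per_chrom.items(), key=lambda kv: natural_chromosome_key(kv[0]))
        ),
        "warnings": list(warnings),
    }
    if per_chrom:
        counts = sorted(per_chrom.items(), key=lambda kv: (-kv[1], kv[0]))
        n_chrom = len(per_chrom)
        report.update(
            max_chromosome=counts[0][0],
            min_chromosome=counts[-1][0],
            mean_per_chromosome=n_placed / n_chrom,
            mean_per_chromosome_floor=n_placed // n_chrom,
        )
    return report


def replace_location(gene: PutativeAMPGene, lifted) -> PutativeAMPGene:
    """Return a copy of ``gene`` with its location set from a liftover
    result (None or (chromosome, start, end, strand))."""
    if lifted is None:
        return replace(gene, chromosome=None, start=None, end=None, strand=None)
    chrom, start, end, strand = lifted
    return replace(gene, chromosome=chrom, start=start, end=end, strand=strand)


def screen(
    queries: Sequence[AMPQuery],
    cds_set: Mapping[str, str],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_query_ratio: float = DEFAULT_MIN_QUERY_RATIO,
    gene_coords: Mapping[str, tuple[str, int, int, str]] | None = None,
    builds=None,
) -> dict:
    """Full screen: align, filter, deduplicate, classify/rename and (when a
    build is given) localise. Returns a dict with ``hits`` (surviving),
    ``catalog``, ``distribution`` and, if localised, ``location_report``."""
    hits = align_queries(queries, cds_set)
    kept = filter_hits(hits, evalue_max=evalue_max, min_query_ratio=min_query_ratio)
    dedup = deduplicate(kept)
    locations: dict[str, tuple[str, int, int, str]] | None = None
    if gene_coords is not None and builds is not None:
        from .anchor import liftover

        locations = {}
        for h in dedup:
            coords = gene_coords.get(h.gene_id)
            if coords is None:
                continue
            lifted = liftover(builds, *coords)
            if lifted is not None:
                locations[h.gene_id] = lifted
    catalog, distribution = classify_and_name(dedup, queries, locations)
    result = {
        "n_hits_raw": len(hits),
        "hits": kept,
        "catalog": catalog,
        "distribution": distribution,
    }
    if locations is not None:
        result["location_report"] = location_report(catalog)
    return result
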