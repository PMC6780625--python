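"""Synthetic study generator: a random genome with planted AMP homologs,
fragmentation into scaffolds, a consistent linkage map, sequencing reads,
and expression count tables — all with recorded ground truth.

Every pipeline stage can therefore be tested end to end without any
download: the k-mer stage sees reads simulated from a genome of known
size, the anchoring stage sees scaffolds whose true order/orientation and
marker map are recorded, and the homology screen sees a gene set in which
some genes are mutated back-translations of known peptide queries
(recoverable positives) and the rest are decoys (guaranteed negatives).

Conventions: chromosome-level truth is kept in 0-based half-open
coordinates internally; emitted tables (gene coordinates, markers) are
1-based inclusive, matching the analysis modules. All generators take an
explicit seed (default 17) and are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._util import revcomp
from .screen import AMPQuery

DEFAULT_SEED = 17
DEFAULT_GC = 0.414  # giant-grouper genome-wide GC content
CM_PER_BP = 1.0 / 250_000  # fixed linear genetic-map rate: 1 cM per 250 kb
TISSUES = ("brain", "liver", "muscle")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
_SENSE_CODONS = sorted(_TABLE.forward_table)
_STOP_CODONS = sorted(_TABLE.stop_codons)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ScaffoldRecord:
    scaffold_id: str
    chromosome_id: str
    order_index: int
    orientation: str
    start: int  # 0-based half-open span on the chromosome
    end: int


@dataclass
class GenePlacement:
    gene_id: str
    scaffold_id: str
    start: int  # 1-based inclusive, on the emitted scaffold
    end: int
    strand: str
    query_id: str | None  # source peptide query, None for decoys


@dataclass
class MarkerTruthRecord:
    marker_id: str
    linkage_group: int
    cM: float
    scaffold_id: str
    offset: int  # 0-based flank start on the emitted scaffold


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study."""

    seed: int
    chromosomes: dict[str, str]
    scaffolds: dict[str, str]
    scaffold_layout: list[ScaffoldRecord]
    cds: dict[str, str] = field(default_factory=dict)
    gene_placements: list[GenePlacement] = field(default_factory=list)
    marker_truth: list[MarkerTruthRecord] = field(default_factory=list)
    expression_truth: pd.DataFrame | None = None
    # chromosome-coordinate gene truth, used to remap across fragmentation
    _gene_chrom: list[tuple[str, str, int, int, str, str | None]] = field(
        default_factory=list, repr=False
    )

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def gene_coords(self) -> dict[str, tuple[str, int, int, str]]:
        """gene_id -> (scaffold_id, start, end, strand), 1-based inclusive."""
        return {
            g.gene_id: (g.scaffold_id, g.start, g.end, g.strand)
            for g in self.gene_placements
        }


# ---------------------------------------------------------------------------
# genome

def gen_genome(
    seed: int = DEFAULT_SEED,
    n_chromosomes: int = 2,
    chromosome_length: int = 100_000,
    gc: float = DEFAULT_GC,
) -> SyntheticTruth:
    """Random genome of ``n_chromosomes`` chromosomes at the requested GC
    content. Until fragmentation, each chromosome doubles as a single
    forward scaffold."""
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if chromosome_length < 10_000:
        raise ValueError("chromosome_length must be >= 10,000")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chromosomes: dict[str, str] = {}
    layout: list[ScaffoldRecord] = []
    for i in range(1, n_chromosomes + 1):
        codes = rng.choice(4, size=chromosome_length, p=p)
        chromosomes[f"chr{i}"] = _BASES[codes].tobytes().decode("ascii")
        layout.append(
            ScaffoldRecord(f"chr{i}", f"chr{i}", 0, "+", 0, chromosome_length)
        )
    return SyntheticTruth(
        seed=seed,
        chromosomes=chromosomes,
        scaffolds=dict(chromosomes),
        scaffold_layout=layout,
    )


# ---------------------------------------------------------------------------
# peptide queries (APD3-style synthetic stand-in)

def gen_queries(
    seed: int = DEFAULT_SEED,
    n_per_class: int = 2,
    classes: Sequence[str] = ("thrombin", "lectin", "hepcidin", "defensin"),
    length_range: tuple[int, int] = (25, 60),
) -> list[AMPQuery]:
    """Synthetic stand-in for a curated AMP query database: random
    peptides with class-annotated ids/names in the ``>ID|name|class``
    header convention."""
    rng = np.random.default_rng(seed)
    queries: list[AMPQuery] = []
    qid = 1001
    for cls in classes:
        for i in range(1, n_per_class + 1):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "".join(rng.choice(list(_AA20), size=length))
            queries.append(AMPQuery(str(qid), f"{cls}_pep{i}", cls, seq))
            qid += 1
    return queries


# ---------------------------------------------------------------------------
# gene planting

def _back_translate(peptide: str, rng: np.random.Generator) -> str:
    """Back-translate with uniformly random synonymous codons."""
    return "".join(
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in peptide
    )


def _mutate_peptide(
    peptide: str, substitution_rate: float, rng: np.random.Generator
) -> str:
    out = []
    for aa in peptide:
        if rng.random() < substitution_rate:
            choices = _AA20.replace(aa, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(
        _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))] for _ in range(n_codons)
    )


def plant_amp_genes(
    truth: SyntheticTruth,
    queries: Sequence[AMPQuery],
    n_genes: int,
    substitution_rate: float = 0.05,
    decoy_genes: int = 0,
    seed: int = DEFAULT_SEED,
    flank_codons: tuple[int, int] = (5, 15),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant ``n_genes`` mutated homologs of the queries plus
    ``decoy_genes`` unrelated genes into the genome.

    Each planted CDS is ATG + random sense-codon padding + a uniform
    synonymous back-translation of the (point-mutated) query peptide +
    padding + stop; decoys are random sense codons with no query-derived
    segment. Genes are written into non-overlapping chromosome intervals
    that never straddle a scaffold boundary, on a random strand. Returns
    the CDS set and a 1-based gene coordinate table (scaffold coords).
    """
    if not 0 <= substitution_rate <= 0.3:
        raise ValueError("substitution_rate must be in [0, 0.3]")
    if n_genes > 0 and not queries:
        raise ValueError("no queries to plant")
    rng = np.random.default_rng(seed)

    specs: list[tuple[str | None, str]] = []  # (query_id, cds)
    for i in range(n_genes):
        q = queries[int(rng.integers(len(queries)))]
        pep = _mutate_peptide(q.sequence, substitution_rate, rng)
        pad5 = _random_cds(int(rng.integers(*flank_codons)), rng)
        pad3 = _random_cds(int(rng.integers(*flank_codons)), rng)
        stop = _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
        specs.append((q.query_id, "ATG" + pad5 + _back_translate(pep, rng) + pad3 + stop))
    mean_len = int(np.mean([len(c) for _, c in specs]) // 3) if specs else 40
    for i in range(decoy_genes):
        n_codons = max(20, mean_len + int(rng.integers(-10, 11)))
        specs.append((None, "ATG" + _random_cds(n_codons, rng) + "TAA"))

    # place into non-overlapping intervals within single scaffold spans
    spans = [
        (rec.chromosome_id, rec.start, rec.end) for rec in truth.scaffold_layout
    ]
    total_space = sum(e - s for _, s, e in spans)
    need = sum(len(c) for _, c in specs)
    if need * 2 > total_space:
        raise ValueError(
            f"gene set ({need} bp) exceeds available genome space "
            f"({total_space} bp at 50% occupancy)"
        )
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in truth.chromosomes}
    placements: list[tuple[str, str, int, int, str, str | None]] = []
    order = rng.permutation(len(specs))
    for rank, idx in enumerate(order):
        query_id, cds = specs[idx]
        length = len(cds)
        for attempt in range(1000):
            chrom, s0, e0 = spans[int(rng.integers(len(spans)))]
            if e0 - s0 < length:
                continue
            start = int(rng.integers(s0, e0 - length + 1))
            end = start + length
            if any(start < oe and os_ < end for os_, oe in occupied[chrom]):
                continue
            break
        else:
            raise ValueError("could not place genes: genome too crowded")
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = truth.chromosomes[chrom]
        insert = cds if strand == "+" else revcomp(cds)
        truth.chromosomes[chrom] = seq[:start] + insert + seq[end:]
        placements.append((f"_tmp{idx}", chrom, start, end, strand, query_id))

    # name genes in chromosomal order, keep CDS keyed by final id
    placements.sort(key=lambda t: (t[1], t[2]))
    final: list[tuple[str, str, int, int, str, str | None]] = []
    for i, (_tmp, chrom, start, end, strand, query_id) in enumerate(placements, 1):
        final.append((f"gene_{i:04d}", chrom, start, end, strand, query_id))
    truth._gene_chrom = final
    truth.cds = {}
    for gene_id, chrom, start, end, strand, _q in final:
        seg = truth.chromosomes[chrom][start:end]
        truth.cds[gene_id] = seg if strand == "+" else revcomp(seg)
    _refresh_scaffolds(truth)
    return truth.cds, gene_coordinate_table(truth)


def gene_coordinate_table(truth: SyntheticTruth) -> pd.DataFrame:
    return pd.DataFrame(
        [asdict(g) for g in truth.gene_placements],
        columns=["gene_id", "scaffold_id", "start", "end", "strand", "query_id"],
    )


def _refresh_scaffolds(truth: SyntheticTruth) -> None:
    """Re-derive emitted scaffold sequences and scaffold-coordinate gene
    placements from chromosome-level truth and the current layout."""
    truth.scaffolds = {}
    for rec in truth.scaffold_layout:
        seg = truth.chromosomes[rec.chromosome_id][rec.start : rec.end]
        truth.scaffolds[rec.scaffold_id] = revcomp(seg) if rec.orientation == "-" else seg
    truth.gene_placements = []
    for gene_id, chrom, start, end, strand, query_id in truth._gene_chrom:
        rec = next(
            (
                r
                for r in truth.scaffold_layout
                if r.chromosome_id == chrom and r.start <= start and end <= r.end
            ),
            None,
        )
        if rec is None:
            raise AssertionError(
                f"{gene_id} straddles a scaffold boundary — fragmentation bug"
            )
        length = rec.end - rec.start
        if rec.orientation == "+":
            s0, e0, st = start - rec.start, end - rec.start, strand
        else:
            s0 = length - (end - rec.start)
            e0 = length - (start - rec.start)
            st = "-" if strand == "+" else "+"
        truth.gene_placements.append(
            GenePlacement(gene_id, rec.scaffold_id, s0 + 1, e0, st, query_id)
        )


# ---------------------------------------------------------------------------
# fragmentation

def fragment_to_scaffolds(
    truth: SyntheticTruth,
    n_scaffolds_per_chromosome: int,
    seed: int = DEFAULT_SEED,
    min_length: int = 500,
) -> SyntheticTruth:
    """Partition each chromosome into ``n`` scaffolds at random breakpoints
    (never inside a planted gene, never producing a scaffold shorter than
    ``min_length``), reverse-complementing each scaffold with probability
    0.5. Scaffold ids are drawn from a shuffled pool so their
    lexicographic order carries no information about the true layout."""
    n = n_scaffolds_per_chromosome
    if n < 1:
        raise ValueError("n_scaffolds_per_chromosome must be >= 1")
    rng = np.random.default_rng(seed)

    total = len(truth.chromosomes) * n
    ids = [f"scaffold_{i:04d}" for i in rng.permutation(total) ]
    layout: list[ScaffoldRecord] = []
    id_iter = iter(ids)
    for chrom in truth.chromosomes:
        length = len(truth.chromosomes[chrom])
        if n * min_length > length:
            raise ValueError(
                f"{chrom}: cannot cut {length} bp into {n} scaffolds of "
                f">= {min_length} bp"
            )
        forbidden = [
            (s, e)
            for _g, c, s, e, _st, _q in truth._gene_chrom
            if c == chrom
        ]
        allowed = np.ones(length + 1, dtype=bool)
        allowed[0] = allowed[length] = False
        for s, e in forbidden:
            allowed[s + 1 : e] = False  # cuts at s or e are fine, inside is not
        candidates = np.flatnonzero(allowed)
        if len(candidates) < n - 1:
            raise ValueError(f"not enough cut sites on {chrom} for {n} scaffolds")
        cuts = None
        for _try in range(200):  # resample until min_length holds
            trial = np.sort(rng.choice(candidates, size=n - 1, replace=False))
            spans = np.diff([0, *trial.tolist(), length])
            if (spans >= min_length).all():
                cuts = trial
                break
        if cuts is None:
            raise ValueError(
                f"{chrom}: could not find {n - 1} cut sites keeping all "
                f"scaffolds >= {min_length} bp (gene layout too crowded)"
            )
        bounds = [0, *cuts.tolist(), length]
        for k in range(n):
            orientation = "+" if rng.random() < 0.5 else "-"
            layout.append(
                ScaffoldRecord(
                    next(id_iter), chrom, k, orientation, bounds[k], bounds[k + 1]
                )
            )
    truth.scaffold_layout = layout
    _refresh_scaffolds(truth)
    return truth


# ---------------------------------------------------------------------------
# linkage map

def gen_linkage_map(
    truth: SyntheticTruth,
    markers_per_scaffold: int = 3,
    flank: int = 40,
    seed: int = DEFAULT_SEED,
    jitter_cM: float = 0.0,
    cm_per_bp: float = CM_PER_BP,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Markers whose cM position is a fixed linear function of true
    chromosomal position (1 cM / 250 kb by default) plus optional uniform
    jitter, with the true genomic context as flanking sequence so exact
    matching can relocate them.

    Returns the marker table (``marker_id linkage_group cM flank_id``) and
    the flank sequences; the truth record keeps each marker's scaffold and
    offset. Linkage group g is chromosome g, 1-based in dict order.
    """
    if flank < 20:
        raise ValueError("flank shorter than 20 bp is unplaceable")
    if markers_per_scaffold < 1:
        raise ValueError("markers_per_scaffold must be >= 1")
    rng = np.random.default_rng(seed)
    lg_of = {c: i + 1 for i, c in enumerate(truth.chromosomes)}

    rows = []
    flanks: dict[str, str] = {}
    truth.marker_truth = []
    m = 0
    for rec in truth.scaffold_layout:
        length = rec.end - rec.start
        if length < flank:
            continue
        offsets = rng.choice(length - flank + 1, size=min(markers_per_scaffold, length - flank + 1), replace=False)
        for off in sorted(int(o) for o in offsets):
            m += 1
            marker_id = f"mk_{m:05d}"
            # chromosome position of the flank start
            if rec.orientation == "+":
                chrom_pos = rec.start + off
            else:
                chrom_pos = rec.start + (length - off - flank)
            cm = chrom_pos * cm_per_bp
            if jitter_cM > 0:
                cm += rng.uniform(-jitter_cM, jitter_cM)
            cm = max(cm, 0.0)
            flank_id = f"fl_{m:05d}"
            flanks[flank_id] = truth.scaffolds[rec.scaffold_id][off : off + flank]
            rows.append(
                {
                    "marker_id": marker_id,
                    "linkage_group": lg_of[rec.chromosome_id],
                    "cM": cm,
                    "flank_id": flank_id,
                }
            )
            truth.marker_truth.append(
                MarkerTruthRecord(
                    marker_id, lg_of[rec.chromosome_id], cm, rec.scaffold_id, off
                )
            )
    return pd.DataFrame(rows), flanks


# ---------------------------------------------------------------------------
# reads

def sim_reads(
    truth: SyntheticTruth,
    coverage: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> list[str]:
    """Single-end reads at the requested fold coverage: uniform start
    positions, random strand, i.i.d. substitution errors, no indels.
    The read count is round(coverage * genome_length / read_length)."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chroms = list(truth.chromosomes)
    lengths = np.array([len(truth.chromosomes[c]) for c in chroms])
    if read_length > lengths.min():
        raise ValueError("read_length exceeds the shortest chromosome")
    n_reads = int(round(coverage * lengths.sum() / read_length))

    genome = "".join(truth.chromosomes[c] for c in chroms)
    codes = _CODE[np.frombuffer(genome.encode("ascii"), dtype=np.uint8)].astype(np.int8)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    weights = (lengths - read_length + 1).astype(float)
    which = rng.choice(len(chroms), size=n_reads, p=weights / weights.sum())
    starts = offsets[which] + (
        rng.random(n_reads) * (lengths[which] - read_length + 1)
    ).astype(np.int64)

    mat = codes[starts[:, None] + np.arange(read_length)[None, :]].astype(np.int8)
    flip = rng.random(n_reads) < 0.5
    mat[flip] = (3 - mat[flip])[:, ::-1]
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.int8)
        mat = np.where(err, (mat + shift) % 4, mat)
    byte_mat = _BASES[mat]
    return [row.tobytes().decode("ascii") for row in byte_mat]


# ---------------------------------------------------------------------------
# expression

def gen_expression_profiles(
    gene_ids: Sequence[str],
    tissues: Sequence[str] = TISSUES,
    seed: int = DEFAULT_SEED,
    frac_silent: float = 0.3,
) -> pd.DataFrame:
    """Per-gene, per-tissue relative abundances: log-normal expression
    with a ``frac_silent`` chance of a gene being off in a tissue."""
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=1.0, sigma=1.5, size=(len(gene_ids), len(tissues)))
    silent = rng.random(vals.shape) < frac_silent
    vals[silent] = 0.0
    for j in range(vals.shape[1]):  # keep every tissue expressible
        if not vals[:, j].any():
            vals[rng.integers(vals.shape[0]), j] = 1.0
    return pd.DataFrame(vals, index=list(gene_ids), columns=list(tissues))


def sim_counts(
    gene_lengths: Mapping[str, int],
    tissue_profiles: pd.DataFrame,
    library_size: int = 1_000_000,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Multinomial read counts per tissue with sampling probability
    proportional to abundance x effective length (longer transcripts catch
    more reads); column totals equal ``library_size`` exactly. Output has
    the counts-table layout (``length`` column + one column per tissue)."""
    genes = list(tissue_profiles.index)
    missing = [g for g in genes if g not in gene_lengths]
    if missing:
        raise KeyError(f"no length for genes: {missing[:5]}")
    if (tissue_profiles < 0).any().any():
        raise ValueError("profiles must be non-negative")
    rng = np.random.default_rng(seed)
    lengths = np.array([gene_lengths[g] for g in genes], dtype=float)
    out = pd.DataFrame(index=genes)
    out["length"] = lengths.astype(int)
    for tissue in tissue_profiles.columns:
        weights = tissue_profiles[tissue].to_numpy() * lengths
        if weights.sum() <= 0:
            raise ValueError(f"all-zero expression profile for tissue {tissue}")
        out[tissue] = rng.multinomial(library_size, weights / weights.sum())
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# truth evaluation

def evaluate_anchoring(truth: SyntheticTruth, builds) -> dict:
    """Compare an anchoring result against the recorded layout.

    Order accuracy is the fraction of anchored scaffolds at their true
    rank among the anchored scaffolds of their chromosome (so an
    unanchorable scaffold does not shift everything after it); orientation
    accuracy the fraction with the true orientation. Linkage group g
    corresponds to chromosome g in truth dict order.
    """
    lg_of = {c: i + 1 for i, c in enumerate(truth.chromosomes)}
    true_by_chrom: dict[int, list[ScaffoldRecord]] = {}
    for rec in truth.scaffold_layout:
        true_by_chrom.setdefault(lg_of[rec.chromosome_id], []).append(rec)
    for recs in true_by_chrom.values():
        recs.sort(key=lambda r: r.order_index)

    n = order_ok = orient_ok = 0
    for chrom_id, build in builds.items():
        lg = int("".join(ch for ch in chrom_id if ch.isdigit()))
        anchored = {sid for sid, _o in build.components}
        true_order = [
            (r.scaffold_id, r.orientation)
            for r in true_by_chrom.get(lg, [])
            if r.scaffold_id in anchored
        ]
        true_rank = {sid: k for k, (sid, _o) in enumerate(true_order)}
        true_orient = dict(true_order)
        for k, (sid, orientation) in enumerate(build.components):
            n += 1
            if true_rank.get(sid) == k:
                order_ok += 1
            if true_orient.get(sid) == orientation:
                orient_ok += 1
    return {
        "n_scaffolds": n,
        "order_accuracy": order_ok / n if n else 0.0,
        "orientation_accuracy": orient_ok / n if n else 0.0,
    }


def evaluate_screen(truth: SyntheticTruth, catalog, queries) -> dict:
    """Planted-gene recovery of a screen catalog: fraction of planted
    genes called, fraction with the source query's class, and the number
    of decoy genes called."""
    class_of = {q.query_id: q.amp_class for q in queries}
    planted = {
        g.gene_id: class_of[g.query_id]
        for g in truth.gene_placements
        if g.query_id is not None
    }
    called = {g.gene_id: g.amp_class for g in catalog}
    recovered = [g for g in planted if g in called]
    class_ok = [g for g in recovered if called[g] == planted[g]]
    return {
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "gene_recovery": len(recovered) / len(planted) if planted else 1.0,
        "class_recovery": len(class_ok) / len(planted) if planted else 1.0,
        "decoy_calls": sorted(set(called) - set(planted)),
    }


# ---------------------------------------------------------------------------
# writers

def write_fasta(seqs: Mapping[str, str], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_fastq(reads: Iterable[str], path: str | Path) -> None:
    """Phred+33 FASTQ with constant quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads, 1):
            fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_marker_files(
    markers: pd.DataFrame, flanks: Mapping[str, str], tsv_path, fasta_path
) -> None:
    markers.to_csv(tsv_path, sep="\t", index=False)
    write_fasta(flanks, fasta_path)


def write_truth_jsonl(truth: SyntheticTruth, path: str | Path) -> None:
    """Ground-truth record as JSON lines (one object per fact), sequences
    omitted for compactness."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"kind": "meta", "seed": truth.seed,
                             "genome_length": truth.genome_length}) + "\n")
        for rec in truth.scaffold_layout:
            fh.write(json.dumps({"kind": "scaffold", **asdict(rec)}) + "\n")
        for g in truth.gene_placements:
            fh.write(json.dumps({"kind": "gene", **asdict(g)}) + "\n")
        for mk in truth.marker_truth:
            fh.write(json.dumps({"kind": "marker", **asdict(mk)}) + "\n")
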