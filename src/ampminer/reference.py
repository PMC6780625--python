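"""Published giant-grouper (*Epinephelus lanceolatus*) genome-survey
figures, used as worked-example inputs.

These are the printed inputs of the survey arithmetic — the k-mer totals
from the sequencing libraries, the assembly and repeat base counts, the
annotation tallies, and the 24-row pseudochromosome characteristics
table — so the summary statistics can be recomputed and checked against
their published values.
"""

from __future__ import annotations

import pandas as pd

# k-mer survey (k = 17)
KMER_TOTAL_OCCURRENCES = 20_970_039_103
KMER_PEAK_DEPTH = 18

# sequencing yield (bases)
ILLUMINA_BASES = 82.80e9
PACBIO_BASES = 31.15e9

# assembly totals (bases)
CONTIG_TOTAL_BP = 1_128_030_970
SCAFFOLD_TOTAL_BP = 1_128_030_990
CONTIG_N50_BP = 1_469_414
SCAFFOLD_N50_BP = 1_505_601

# repeat annotation (bases)
REPEAT_BP = 508_638_319
TRANSPOSABLE_ELEMENT_BP = 478_176_524

# gene-set annotation
GENES_TOTAL = 24_794
GENES_SUPPORTED = 23_149  # genes with functional-database support

# pseudochromosome characteristics: (chromosome, length in Mb, genes, scaffolds)
_CHROMOSOME_ROWS = [
    ("Chr1", 39.05, 917, 53),
    ("Chr2", 41.84, 899, 54),
    ("Chr3", 20.61, 374, 18),
    ("Chr4", 50.74, 1198, 78),
    ("Chr5", 41.95, 912, 53),
    ("Chr6", 50.39, 978, 72),
    ("Chr7", 44.01, 1062, 55),
    ("Chr8", 54.01, 1051, 56),
    ("Chr9", 52.56, 1127, 70),
    ("Chr10", 45.93, 1209, 49),
    ("Chr11", 41.12, 820, 41),
    ("Chr12", 35.95, 918, 45),
    ("Chr13", 54.06, 1359, 56),
    ("Chr14", 47.27, 947, 60),
    ("Chr15", 38.31, 894, 35),
    ("Chr16", 39.82, 728, 57),
    ("Chr17", 40.89, 858, 47),
    ("Chr18", 34.17, 675, 58),
    ("Chr19", 31.81, 898, 24),
    ("Chr20", 22.54, 491, 24),
    ("Chr21", 45.46, 1007, 68),
    ("Chr22", 44.25, 944, 80),
    ("Chr23", 42.07, 1035, 43),
    ("Chr24", 40.81, 905, 60),
]


def chromosome_table() -> pd.DataFrame:
    """The 24 pseudochromosomes as a chromosome table (lengths in bp)."""
    df = pd.DataFrame(
        _CHROMOSOME_ROWS, columns=["chromosome", "length_mb", "n_genes", "n_scaffolds"]
    )
    df["length_bp"] = (df.pop("length_mb") * 1e6).round().astype(int)
    return df[["chromosome", "length_bp", "n_genes", "n_scaffolds"]]
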