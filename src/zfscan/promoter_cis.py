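"""Promoter extraction and cis-regulatory element counting.

Promoters are the 2 kb immediately upstream of the annotated gene span
(strand-aware, truncated with a flag at contig edges, returned 5'->3'
relative to transcription).  Elements are IUPAC consensus strings from a
user-replaceable motif table; matching is exact-consensus on both strands
with leftmost-greedy non-overlap per motif and strand.  Because consensus
tables differ between prediction services, absolute counts are a function
of the supplied table — the bundled default covers the classic hormone- and
stress-response elements (ABRE, MBS, LTR, DRE, CGTCA/TGACG, GARE, P-box,
TATC-box, TCA, SARE, AuxRR, TGA, TC-rich repeats).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io_formats import GeneModel, SequenceRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class PromoterHit:
    gene_id: str
    motif_id: str
    offset: int  # 0-based from the promoter 5' end (sense orientation)
    strand: str  # "sense" | "antisense"


@dataclass
class Promoter:
    gene_id: str
    sequence: str
    truncated: bool


def load_motif_table(path=None) -> pd.DataFrame:
    """Motif table (motif_id, consensus, stimulus); bundled default if no path."""
    if path is None:
        with resources.files("zfscan.data").joinpath("motifs.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    required = {"motif_id", "consensus", "stimulus"}
    if not required.issubset(table.columns):
        raise ValueError(f"motif table needs columns {sorted(required)}")
    if table["motif_id"].duplicated().any():
        dupes = table.loc[table["motif_id"].duplicated(), "motif_id"].tolist()
        raise ValueError(f"duplicate motif ids: {dupes}")
    for consensus in table["consensus"]:
        if any(ch not in IUPAC for ch in str(consensus).upper()):
            raise ValueError(f"non-IUPAC consensus {consensus!r}")
    if table["stimulus"].isna().any() or (table["stimulus"].astype(str) == "").any():
        raise ValueError("every motif needs a stimulus")
    return table


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def consensus_regex(consensus: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[ch]}]" for ch in consensus.upper()))


def extract_upstream(
    genome: dict[str, str] | list[SequenceRecord],
    gene: GeneModel,
    length: int = 2000,
) -> Promoter:
    """The ``length`` bases upstream of the gene, 5'->3' on the coding strand.

    Plus strand: bases ending just before the gene start.  Minus strand:
    bases just after the gene end, reverse-complemented.  Truncated (with
    flag) where the contig is too short; a gene flush against the contig
    edge yields an empty, flagged promoter.
    """
    if isinstance(genome, list):
        genome = {rec.id: rec.residues for rec in genome}
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} not in genome")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        end0 = gene.start - 1           # 0-based exclusive end of promoter
        start0 = max(end0 - length, 0)
        seq = chrom[start0:end0]
        truncated = end0 - length < 0
    else:
        start0 = gene.end               # 0-based inclusive start downstream of gene end
        end0 = min(start0 + length, len(chrom))
        seq = reverse_complement(chrom[start0:end0])
        truncated = start0 + length > len(chrom)
    return Promoter(gene_id=gene.gene_id, sequence=seq, truncated=truncated)


def scan_motifs(promoter: Promoter | SequenceRecord, motifs: pd.DataFrame) -> list[PromoterHit]:
    """Non-overlapping (leftmost-greedy, per motif and strand) consensus hits.

    Both strands are scanned; a palindromic motif matching its own reverse
    complement at the same locus counts once, as sense.  Offsets are 0-based
    on the promoter's sense orientation.
    """
    if isinstance(promoter, SequenceRecord):
        promoter = Promoter(gene_id=promoter.id, sequence=promoter.residues, truncated=False)
    seq = promoter.sequence.upper()
    hits: list[PromoterHit] = []
    for _, row in motifs.iterrows():
        consensus = str(row["consensus"]).upper()
        if len(consensus) > len(seq):
            continue
        pat = consensus_regex(consensus)
        sense_offsets = _greedy_find(pat, seq)
        for off in sense_offsets:
            hits.append(PromoterHit(promoter.gene_id, row["motif_id"], off, "sense"))
        rc_pat = consensus_regex(reverse_complement(consensus))
        palindromic = reverse_complement(consensus) == consensus
        for off in _greedy_find(rc_pat, seq):
            if palindromic and off in sense_offsets:
                continue
            hits.append(PromoterHit(promoter.gene_id, row["motif_id"], off, "antisense"))
    hits.sort(key=lambda h: (h.motif_id, h.offset, h.strand))
    return hits


def _greedy_find(pat: re.Pattern, seq: str) -> list[int]:
    offsets = []
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            return offsets
        offsets.append(m.start())
        pos = m.end()


def element_count_matrix(
    hits: list[PromoterHit],
    motifs: pd.DataFrame,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Gene x stimulus count table with a per-gene total column.

    Genes with no hits keep an all-zero row when listed in ``gene_ids``.
    """
    stim_of = dict(zip(motifs["motif_id"], motifs["stimulus"]))
    stimuli = sorted(set(motifs["stimulus"]))
    for h in hits:
        if h.motif_id not in stim_of:
            raise KeyError(f"hit references unknown motif {h.motif_id!r}")
    genes = sorted(set(gene_ids or []) | {h.gene_id for h in hits})
    table = pd.DataFrame(0, index=genes, columns=stimuli, dtype=int)
    for h in hits:
        table.loc[h.gene_id, stim_of[h.motif_id]] += 1
    table["total"] = table.sum(axis=1)
    table.index.name = "gene_id"
    return table
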