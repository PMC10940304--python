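"""Readers and writers for the standard formats the pipeline consumes.

FASTA parsing goes through :mod:`Bio.SeqIO`, GFF3 through :mod:`gffutils`
(in-memory database) and newick through :mod:`Bio.Phylo`; this module adds
the validation and the small amount of gene-model arithmetic the analysis
needs (longest-isoform selection, intron statistics).

Coordinate convention: gene-model coordinates are GFF3-style 1-based
inclusive everywhere in memory.  The single place where they are converted
to Python 0-based half-open slices is :func:`zfscan.promoter_cis.extract_upstream`.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
from Bio import Phylo, SeqIO
from Bio.Phylo.BaseTree import Clade, Tree

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*-.")  # gaps allowed: aligned FASTA
NUCLEOTIDE_ALPHABET = set("ACGTN-.")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class SequenceRecord:
    """A single validated sequence (protein or nucleotide), stored uppercase."""

    id: str
    residues: str
    alphabet: str = "protein"  # "protein" | "nucleotide"
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise FormatError(f"empty sequence for record {self.id!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else NUCLEOTIDE_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise FormatError(
                    f"illegal {self.alphabet} character {ch!r} at position "
                    f"{pos + 1} in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def sorted_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        ex = self.sorted_exons()
        return ex[0][0], ex[-1][1]


@dataclass
class GeneModel:
    """One gene with its transcripts; 1-based inclusive intervals as in GFF3."""

    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


def read_fasta(path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated records (order preserved).

    Raises :class:`FormatError` on duplicate ids or characters outside the
    declared alphabet.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = re.sub(r"\s", "", str(rec.seq))
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=seq,
                alphabet=alphabet,
                description=rec.description,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` objects (one per gene).

    Requires gene / mRNA / exon / CDS features linked by ID/Parent.  Orphan
    mRNAs and exons outside their gene span are errors.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    gene_ids = {g.id for g in db.features_of_type("gene")}
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        model = GeneModel(
            gene_id=g.id,
            chromosome=g.seqid,
            strand=g.strand,
            start=g.start,
            end=g.end,
        )
        for mrna in db.children(g, featuretype="mRNA", order_by="start"):
            t = Transcript(transcript_id=mrna.id)
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                if ex.start < g.start or ex.end > g.end:
                    raise FormatError(
                        f"exon {ex.start}-{ex.end} of {mrna.id!r} outside the "
                        f"span of gene {g.id!r} ({g.start}-{g.end})"
                    )
                t.exons.append((ex.start, ex.end))
            for c in db.children(mrna, featuretype="CDS", order_by="start"):
                t.cds.append((c.start, c.end))
            if not t.exons:
                raise FormatError(f"mRNA {mrna.id!r} has no exon features")
            if not t.cds:
                raise FormatError(f"mRNA {mrna.id!r} has no CDS features")
            _check_exons(t, mrna.id)
            model.transcripts.append(t)
        genes.append(model)
    # orphan mRNAs: any mRNA whose Parent is not a known gene
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or any(p not in gene_ids for p in parents):
            raise FormatError(f"mRNA {mrna.id!r} has no gene parent")
    return genes


def _check_exons(t: Transcript, name: str) -> None:
    ex = t.sorted_exons()
    for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
        if s2 <= e1:
            raise FormatError(f"overlapping exons in transcript {name!r}")
    for cs, ce in t.cds:
        if not any(s <= cs and ce <= e for s, e in ex):
            raise FormatError(
                f"CDS {cs}-{ce} of transcript {name!r} not contained in an exon"
            )


def select_longest_isoform(
    gene: GeneModel, proteins: Sequence[SequenceRecord]
) -> SequenceRecord:
    """Pick the protein of the gene's longest transcript.

    Protein records are matched to transcripts by id.  Ties on length break
    toward the lexicographically smaller transcript id.
    """
    by_id = {p.id: p for p in proteins}
    best: tuple[int, str] | None = None
    for t in gene.transcripts:
        if t.transcript_id not in by_id:
            raise FormatError(
                f"no protein record for transcript {t.transcript_id!r} "
                f"of gene {gene.gene_id!r}"
            )
        key = (-len(by_id[t.transcript_id]), t.transcript_id)
        if best is None or key < best:
            best = key
    assert best is not None
    return by_id[best[1]]


def count_introns(gene: GeneModel, proteins: Sequence[SequenceRecord] | None = None) -> tuple[int, list[int]]:
    """Intron count and lengths for the gene's longest-isoform transcript.

    When ``proteins`` is given the longest isoform is chosen by protein
    length (the family-analysis rule); otherwise by exon span.  Intron
    length is the gap between consecutive sorted exons
    (``next.start - prev.end - 1``).
    """
    if not gene.transcripts:
        raise FormatError(f"gene {gene.gene_id!r} has no transcripts")
    if proteins is not None:
        chosen = select_longest_isoform(gene, proteins).id
        t = gene.transcript(chosen)
    else:
        t = max(
            gene.transcripts,
            key=lambda t: (sum(e - s + 1 for s, e in t.exons), t.transcript_id),
        )
    ex = t.sorted_exons()
    if not ex:
        raise FormatError(f"transcript {t.transcript_id!r} has no exons")
    lengths = [s2 - e1 - 1 for (s1, e1), (s2, e2) in zip(ex, ex[1:])]
    return len(ex) - 1, lengths


# --- newick ---------------------------------------------------------------

_NEWICK_UNSAFE = re.compile(r"[\s(),:;\[\]']")


def sanitize_label(label: str) -> str:
    """Replace newick metacharacters and whitespace with underscores."""
    return _NEWICK_UNSAFE.sub("_", label)


def write_newick(tree: Tree, path) -> None:
    """Write a Bio.Phylo tree as newick; leaf labels are sanitized in place."""
    for leaf in tree.get_terminals():
        leaf.name = sanitize_label(leaf.name)
    Phylo.write(tree, str(path), "newick")


def read_newick(path) -> Tree:
    return Phylo.read(str(path), "newick")


def tree_to_newick(tree: Tree) -> str:
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip()
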