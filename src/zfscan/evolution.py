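"""Duplicate-pair selection, Nei-Gojobori (1986) Ka/Ks, and divergence dating.

Recently duplicated gene pairs are taken as mutual nearest neighbours in
protein p-distance ("most similar proteins").  Their coding sequences are
codon-aligned by back-translating the protein alignment, Ka and Ks are
estimated with the NG86 counting method under the Jukes-Cantor correction,
and divergence time follows ``T = Ks / (2 lambda) * 1e-6`` million years
with a default synonymous rate ``lambda = 6.5e-9`` per site per generation.

NG86 conventions used here:

* synonymous-site fractions are computed per codon and averaged over the
  two sequences; a mutation to a stop codon counts as neither synonymous
  nor nonsynonymous (such positions contribute fewer than 1 site, so a
  codon's S + N can fall slightly below 3);
* observed differences are partitioned by averaging, with equal weight,
  over all minimal mutational pathways between the two codons, skipping
  pathways that pass through a stop codon (if every pathway does, all are
  used — a degenerate case flagged in the docs);
* codons containing ``N`` or an alignment gap are skipped entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .io_formats import SequenceRecord
from .phylogeny import DistanceMatrix

DEFAULT_LAMBDA = 6.5e-9

BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}


def _build_table() -> None:
    aa = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in BASES:
        for b2 in BASES:
            for b3 in BASES:
                _CODON_TABLE[b1 + b2 + b3] = aa[i]
                i += 1


_build_table()

STOP_CODONS = {c for c, a in _CODON_TABLE.items() if a == "*"}


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 (S, N) site counts for one codon.

    Each position contributes ``n_syn/3`` synonymous and ``n_nonsyn/3``
    nonsynonymous sites over its three possible point mutations; mutations
    creating a stop codon contribute to neither.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = _CODON_TABLE[codon]
    s = n = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            if _CODON_TABLE[mut] == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def codon_differences(a: str, b: str) -> tuple[float, float]:
    """NG86 (syn, nonsyn) observed differences between two codons.

    Averages over all minimal mutational pathways with equal weight,
    skipping pathways through stop codons.
    """
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        cur = a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((sd, nd, through_stop))
    valid = [(s, n) for s, n, stop in pathways if not stop]
    if not valid:
        valid = [(s, n) for s, n, _ in pathways]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites; NaN when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    ka: float
    ks: float
    lambda_: float = DEFAULT_LAMBDA

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.ka) or math.isnan(self.ks))

    @property
    def ratio(self) -> float:
        if not self.defined or self.ks == 0:
            return float("nan")
        return self.ka / self.ks

    @property
    def t_mya(self) -> float:
        if math.isnan(self.ks):
            return float("nan")
        return divergence_time(self.ks, self.lambda_)

    @property
    def selection(self) -> str:
        return selection_call(self.ka, self.ks)


def find_duplicate_pairs(dm: DistanceMatrix) -> list[tuple[str, str]]:
    """Mutual nearest-neighbour gene pairs, each gene in at most one pair.

    Ties at the minimum break toward the lexicographically smallest partner
    label; returned pairs are (smaller, larger) label, list sorted.
    """
    n = len(dm)
    if n < 2:
        return []
    order = np.argsort(dm.labels)  # lexicographic preference under ties
    nearest = {}
    for i in range(n):
        best = None
        for j in order:
            if j == i:
                continue
            if best is None or dm.d[i, j] < dm.d[i, best]:
                best = j
        nearest[i] = best
    pairs = []
    for i in range(n):
        j = nearest[i]
        if j is not None and nearest[j] == i and i < j:
            a, b = sorted((dm.labels[i], dm.labels[j]))
            pairs.append((a, b))
    return sorted(pairs)


def codon_align(
    protein_aln_a: str,
    protein_aln_b: str,
    cds_a: SequenceRecord | str,
    cds_b: SequenceRecord | str,
) -> tuple[str, str]:
    """Back-translate an aligned protein pair onto its coding sequences.

    Each aligned residue becomes its source codon and each gap ``---``.
    The CDS must translate (stop excluded) to the ungapped protein.
    """
    out = []
    for aln, cds in ((protein_aln_a, cds_a), (protein_aln_b, cds_b)):
        seq = cds.residues if isinstance(cds, SequenceRecord) else cds.upper()
        if len(seq) % 3:
            raise ValueError("CDS length is not a multiple of 3")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        residues = [c for c in aln if c not in "-."]
        if len(residues) != len(codons):
            raise ValueError(
                f"protein alignment has {len(residues)} residues but CDS has "
                f"{len(codons)} codons"
            )
        for idx, (res, codon) in enumerate(zip(residues, codons)):
            if "N" not in codon and translate_codon(codon) != res:
                raise ValueError(
                    f"codon {idx + 1} ({codon}) translates to "
                    f"{translate_codon(codon)!r}, protein has {res!r}"
                )
        it = iter(codons)
        out.append("".join(next(it) if ch not in "-." else "---" for ch in aln))
    if len(out[0]) != len(out[1]):
        raise ValueError("aligned proteins have unequal lengths")
    return out[0], out[1]


def kaks_ng86(codon_aln_a: str, codon_aln_b: str) -> tuple[float, float]:
    """NG86 (Ka, Ks) for a pair of aligned codon sequences.

    Returns NaN for a rate whose Jukes-Cantor correction diverges
    (proportion >= 3/4).
    """
    if len(codon_aln_a) != len(codon_aln_b) or len(codon_aln_a) % 3:
        raise ValueError("codon alignments must be equal length, multiple of 3")
    S = N = sd = nd = 0.0
    n_used = 0
    for i in range(0, len(codon_aln_a), 3):
        ca, cb = codon_aln_a[i : i + 3], codon_aln_b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        s, n = codon_differences(ca, cb)
        sd += s
        nd += n
        n_used += 1
    if n_used == 0:
        raise ValueError("no comparable (ungapped, unambiguous) codons")
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    return jukes_cantor(pn), jukes_cantor(ps)


def divergence_time(ks: float, lambda_: float = DEFAULT_LAMBDA) -> float:
    """Divergence time in million years: ``T = Ks / (2 lambda) * 1e-6``."""
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    return ks / (2.0 * lambda_) * 1e-6


def selection_call(ka: float, ks: float) -> str:
    """Classify the Ka/Ks ratio: purifying (<1), neutral (=1), positive (>1)."""
    if math.isnan(ka) or math.isnan(ks) or ks == 0:
        return "undefined"
    ratio = ka / ks
    if ratio < 1:
        return "purifying"
    if ratio > 1:
        return "positive"
    return "neutral"


def analyze_pair(
    gene_a: str,
    gene_b: str,
    protein_aln_a: str,
    protein_aln_b: str,
    cds_a,
    cds_b,
    lambda_: float = DEFAULT_LAMBDA,
) -> KaKsResult:
    aln_a, aln_b = codon_align(protein_aln_a, protein_aln_b, cds_a, cds_b)
    ka, ks = kaks_ng86(aln_a, aln_b)
    return KaKsResult(gene_a=gene_a, gene_b=gene_b, ka=ka, ks=ks, lambda_=lambda_)
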