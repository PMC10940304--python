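"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates, at reduced scale, the inputs of a genome-wide
zinc-finger family survey: a proteome with C2H2 fingers of known type and
arrangement, a small genome + GFF3 with 2-kb promoters carrying planted
cis-elements, CDS pairs mutated to target Ka/Ks values, a pseudo-alignment
with subgroup-structured clades, and an FPKM matrix with planted
low-expression and stage-specific genes.

Design notes that make recovery *exact* rather than merely likely:

* protein filler (linkers, termini, X-spacers) is drawn from an alphabet
  with no C or H — a C2H2 skeleton match outside a planted finger is
  impossible — and no Q/A/L/G either, so the planted QALGGH window is
  always the unique best-scoring window;
* promoter background is drawn from {A, C} only; every motif in the
  bundled table has at least one fixed G/T (sense) and A/C (antisense),
  so background alone can never match on either strand, and the generator
  re-scans each promoter to verify the planted counts before returning;
* CDS pairs use codons of the xC[TC] form (Ala/Pro/Ser/Thr families),
  which have exactly 1 synonymous and 2 nonsynonymous NG86 sites each;
  synonymous mutations toggle the third base T<->C and nonsynonymous
  mutations swap the first base, so realized counts are unambiguous.

The default family is 40 genes across 10 subgroups (a 1/5-scale echo of a
real plant C2H2 family); all randomness flows through one seeded
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord
from .promoter_cis import IUPAC, Promoter, load_motif_table, reverse_complement, scan_motifs

# Filler alphabet: no C/H (no spurious skeletons), no Q/A/L/G (no spurious
# QALGGH windows).
FILLER = "DEFIKMNPRSTVWY"
QALGG = "QALGG"

DEFAULT_ARCHITECTURE_MIX = {
    "1i-Q": 6,
    "1i-M": 4,
    "2i-Q": 6,
    "2i-M": 4,
    "2i-Mx": 4,
    "3i-M": 3,
    "3i-Mx": 4,
    "4i-Mx": 3,
    "t1-Mx": 3,
    "t2-Mx": 3,
}

EXPRESSION_SAMPLES = ["RS", "SS", "LS", "LV", "LB", "LIF", "LPF"]

# motifs safe for exact-recovery planting (no reverse-complement duals in
# the default table, no cross-substring relationships)
_PLANT_MOTIFS = ["ABRE", "MBS", "LTR", "DRE", "P-box"]


@dataclass
class SyntheticSpec:
    """Declarative plan for one synthetic dataset."""

    seed: int = 17
    n_genes: int = 40
    architecture_mix: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ARCHITECTURE_MIX)
    )
    promoter_motif_plan: dict[str, dict[str, int]] | None = None
    kaks_pair_plan: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.1, 0.02)] * 5
    )
    expression_plan: dict[str, str] | None = None  # gene -> low|stage|uniform
    promoter_length: int = 2000

    def __post_init__(self) -> None:
        if sum(self.architecture_mix.values()) != self.n_genes:
            raise ValueError("architecture_mix counts must sum to n_genes")
        if any(v < 0 for v in self.architecture_mix.values()):
            raise ValueError("architecture counts must be nonnegative")

    def gene_ids(self) -> list[str]:
        return [f"g{i:03d}" for i in range(1, self.n_genes + 1)]


def default_spec(seed: int = 17) -> SyntheticSpec:
    """The default 40-gene study plan, with per-gene promoter and
    expression plans drawn from the seed."""
    spec = SyntheticSpec(seed=seed)
    rng = np.random.default_rng(seed)
    genes = spec.gene_ids()
    plan: dict[str, dict[str, int]] = {}
    for g in genes:
        plan[g] = {
            "ABRE": int(rng.integers(0, 4)),
            "MBS": int(rng.integers(0, 3)),
            "LTR": int(rng.integers(0, 3)),
            "DRE": int(rng.integers(0, 2)),
            "P-box": int(rng.integers(0, 2)),
        }
    spec.promoter_motif_plan = plan
    classes = ["low"] * 8 + ["stage"] * 6 + ["uniform"] * (len(genes) - 14)
    rng.shuffle(classes)
    spec.expression_plan = dict(zip(genes, classes))
    return spec


# --- proteome -------------------------------------------------------------


def _parse_label(label: str) -> tuple[str, int, str]:
    """Split a subgroup label into (arrangement, n_domains, suffix)."""
    try:
        arr, suffix = label.split("-")
    except ValueError:
        raise ValueError(f"bad subgroup label {label!r}") from None
    if suffix not in {"Q", "M", "D", "Mx"}:
        raise ValueError(f"bad type suffix in {label!r}")
    if arr == "t1":
        n = 3
    elif arr == "t2":
        n = 4
    elif arr.endswith("i") and arr[:-1].isdigit():
        n = int(arr[:-1])
        if n < 1:
            raise ValueError(f"bad domain count in {label!r}")
    else:
        raise ValueError(f"bad arrangement in {label!r}")
    if suffix == "Mx" and n < 2:
        raise ValueError(f"{label!r} is unsatisfiable: Mx needs >= 2 domains")
    return arr, n, suffix


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(FILLER), size=n))


def _domain_types(rng: np.random.Generator, n: int, suffix: str) -> list[str]:
    if suffix == "Q":
        return ["Q"] * n
    if suffix == "D":
        return ["D"] * n
    if suffix == "M":
        return [f"M{int(rng.integers(1, 6))}" for _ in range(n)]
    # Mx: guarantee at least two distinct type categories
    pool = ["Q", "M1", "M2", "M3", "M4", "M5", "D"]
    while True:
        types = [pool[int(rng.integers(0, len(pool)))] for _ in range(n)]
        cats = {("M" if t.startswith("M") else t) for t in types}
        if len(cats) >= 2:
            return types


def _build_domain(rng: np.random.Generator, type_label: str) -> tuple[str, dict]:
    """One finger sequence starting at its first Cys, plus coordinate info."""
    gap1 = int(rng.integers(2, 5))       # Cys-Cys intervening residues
    window5 = list(QALGG)
    if type_label.startswith("M"):
        k = int(type_label[1])
        for pos in rng.choice(5, size=k, replace=False):
            window5[pos] = str(rng.choice(list(FILLER)))
    core = "C" + _filler(rng, gap1) + "C" + _filler(rng, 7) + "".join(window5) + "H"
    if type_label == "D":
        seq = core
    else:
        g2 = int(rng.integers(3, 6))     # His-His intervening residues
        seq = core + _filler(rng, g2) + "H"
    return seq, {"type": type_label, "length": len(seq)}


def _linkers(rng: np.random.Generator, arr: str, n: int) -> list[int]:
    dispersed = lambda: int(rng.integers(15, 41))
    tandem = lambda: int(rng.integers(3, 12))
    if n < 2:
        return []
    if arr == "t1":
        return [tandem(), dispersed()]
    if arr == "t2":
        return [tandem()] + [dispersed() for _ in range(n - 2)]
    return [dispersed() for _ in range(n - 1)]


def generate_proteome(spec: SyntheticSpec) -> tuple[list[SequenceRecord], dict]:
    """Proteins with planted fingers; ground truth maps gene id to the
    planned subgroup, domain coordinates, and domain types."""
    rng = np.random.default_rng(spec.seed)
    labels: list[str] = []
    for label in sorted(spec.architecture_mix):
        _parse_label(label)
        labels.extend([label] * spec.architecture_mix[label])
    records: list[SequenceRecord] = []
    truth: dict[str, dict] = {}
    for gene_id, label in zip(spec.gene_ids(), labels):
        arr, n, suffix = _parse_label(label)
        types = _domain_types(rng, n, suffix)
        if suffix == "Mx":
            # label is derivable from types by construction
            pass
        linkers = _linkers(rng, arr, n)
        nterm = _filler(rng, int(rng.integers(5, 16)))
        parts = [nterm]
        domains = []
        pos = len(nterm)
        for i, t in enumerate(types):
            seq, info = _build_domain(rng, t)
            domains.append({"start": pos, "end": pos + info["length"], "type": t})
            parts.append(seq)
            pos += info["length"]
            if i < len(linkers):
                parts.append(_filler(rng, linkers[i]))
                pos += linkers[i]
        parts.append(_filler(rng, int(rng.integers(5, 16))))
        protein = "".join(parts)
        records.append(
            SequenceRecord(
                id=gene_id,
                residues=protein,
                alphabet="protein",
                description=f"{gene_id} planted={label} seed={spec.seed}",
            )
        )
        truth[gene_id] = {
            "subgroup": label,
            "n_domains": n,
            "domains": domains,
            "linkers": linkers,
        }
    return records, truth


# --- genome + GFF3 + promoters -------------------------------------------


def _ac_background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["A", "C"], size=n, p=[0.55, 0.45]))


def _motif_instance(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        ch if ch in "ACGT" else str(rng.choice(list(IUPAC[ch])))
        for ch in consensus.upper()
    )


def _check_plantable(motifs: pd.DataFrame) -> None:
    for _, row in motifs.iterrows():
        cons = str(row["consensus"]).upper()
        fixed = [c for c in cons if c in "ACGT"]
        if not set(fixed) & set("GT") or not set(fixed) & set("AC"):
            raise ValueError(
                f"motif {row['motif_id']!r} has no strand-distinguishing fixed "
                "base; cannot guarantee exact planted counts on an A/C background"
            )


def _build_promoter(
    rng: np.random.Generator,
    length: int,
    plan: dict[str, int],
    motifs: pd.DataFrame,
    gene_id: str,
    max_attempts: int = 50,
) -> str:
    """Sense-strand promoter with exactly the planned motif counts."""
    consensus_of = dict(zip(motifs["motif_id"], motifs["consensus"]))
    wanted = {m: c for m, c in plan.items() if c > 0}
    for m in wanted:
        if m not in consensus_of:
            raise KeyError(f"promoter plan references unknown motif {m!r}")
    instances = []
    for m, c in sorted(wanted.items()):
        instances.extend(
            (m, _motif_instance(rng, consensus_of[m])) for _ in range(c)
        )
    total_len = sum(len(s) for _, s in instances)
    if total_len + 10 * len(instances) > length:
        raise ValueError(
            f"promoter of {gene_id} too short ({length} bp) for planned elements"
        )
    for _ in range(max_attempts):
        seq = list(_ac_background(rng, length))
        slots = []
        ok = True
        for m, inst in instances:
            for _ in range(200):
                off = int(rng.integers(0, length - len(inst) + 1))
                if all(off + len(inst) + 10 <= s or s_end + 10 <= off for s, s_end in slots):
                    slots.append((off, off + len(inst)))
                    seq[off : off + len(inst)] = list(inst)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        promoter = "".join(seq)
        counts = _scan_counts(promoter, motifs, gene_id)
        if all(counts.get(m, 0) == plan.get(m, 0) for m in set(counts) | set(plan)):
            return promoter
    raise RuntimeError(f"could not realize promoter plan for {gene_id}")


def _scan_counts(promoter: str, motifs: pd.DataFrame, gene_id: str) -> dict[str, int]:
    hits = scan_motifs(Promoter(gene_id, promoter, False), motifs)
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.motif_id] = counts.get(h.motif_id, 0) + 1
    return counts


def generate_genome_and_gff(
    spec: SyntheticSpec, motifs: pd.DataFrame | None = None
) -> tuple[list[SequenceRecord], str, dict]:
    """Two-contig genome, GFF3 text, and promoter/structure ground truth.

    Genes alternate strand; half are intronless; the first gene of the
    second contig sits 500 bp from the contig start (truncated promoter).
    Promoters carry the planted motif plan exactly.
    """
    if motifs is None:
        motifs = load_motif_table()
    _check_plantable(motifs)
    rng = np.random.default_rng(spec.seed + 1)
    plan = spec.promoter_motif_plan or {g: {} for g in spec.gene_ids()}
    genes = spec.gene_ids()
    half = (len(genes) + 1) // 2
    chrom_of = {g: ("chr1" if i < half else "chr2") for i, g in enumerate(genes)}
    sequences: dict[str, list[str]] = {"chr1": [], "chr2": []}
    lengths: dict[str, int] = {"chr1": 0, "chr2": 0}
    gff = ["##gff-version 3"]
    truth: dict[str, dict] = {}
    spacer = 300
    for i, g in enumerate(genes):
        chrom = chrom_of[g]
        strand = "+" if i % 2 == 0 else "-"
        first_on_chr2 = chrom == "chr2" and lengths["chr2"] == 0
        if first_on_chr2:
            strand = "+"
        prom_len = 500 if first_on_chr2 else spec.promoter_length
        promoter = _build_promoter(rng, prom_len, plan.get(g, {}), motifs, g)
        n_exons = 1 if i % 2 == 0 else int(rng.integers(2, 4))
        exon_lens = [int(rng.integers(150, 500)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(31, 400)) for _ in range(n_exons - 1)]
        body_len = sum(exon_lens) + sum(intron_lens)
        body = _ac_background(rng, body_len)
        if strand == "+":
            block = promoter + body + _ac_background(rng, spacer)
            gene_start = lengths[chrom] + prom_len + 1
        else:
            block = _ac_background(rng, spacer) + body + reverse_complement(promoter)
            gene_start = lengths[chrom] + spacer + 1
        gene_end = gene_start + body_len - 1
        sequences[chrom].append(block)
        lengths[chrom] += len(block)
        # exon coordinates (file order, ascending)
        exons = []
        pos = gene_start
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + el - 1))
            pos += el + (intron_lens[k] if k < len(intron_lens) else 0)
        mrna_id = f"{g}.t1"
        attrs = f"ID={g}"
        gff.append(f"{chrom}\tzfscan\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t{attrs}")
        gff.append(
            f"{chrom}\tzfscan\tmRNA\t{gene_start}\t{gene_end}\t.\t{strand}\t.\tID={mrna_id};Parent={g}"
        )
        for k, (s, e) in enumerate(exons, 1):
            gff.append(
                f"{chrom}\tzfscan\texon\t{s}\t{e}\t.\t{strand}\t.\tID={mrna_id}.exon{k};Parent={mrna_id}"
            )
            gff.append(
                f"{chrom}\tzfscan\tCDS\t{s}\t{e}\t.\t{strand}\t0\tID={mrna_id}.cds{k};Parent={mrna_id}"
            )
        truth[g] = {
            "chromosome": chrom,
            "strand": strand,
            "start": gene_start,
            "end": gene_end,
            "promoter_length": prom_len,
            "truncated": prom_len < spec.promoter_length,
            "motif_counts": {m: c for m, c in plan.get(g, {}).items()},
            "n_introns": n_exons - 1,
            "intron_lengths": intron_lens,
        }
    genome = [
        SequenceRecord(
            id=c,
            residues="".join(sequences[c]),
            alphabet="nucleotide",
            description=f"{c} synthetic seed={spec.seed}",
        )
        for c in ("chr1", "chr2")
    ]
    return genome, "\n".join(gff) + "\n", truth


# --- CDS pairs for Ka/Ks -------------------------------------------------

_XC_FAMILIES = "GCAT"  # first bases of the xCN codon families (Ala/Pro/Thr/Ser)


def generate_cds_pair(
    ks_target: float, ka_target: float, n_codons: int = 300, seed: int = 0
) -> tuple[SequenceRecord, SequenceRecord, dict]:
    """A CDS pair whose NG86 estimates recover the targets in expectation.

    The ancestor uses only xC[TC] codons (S=1, N=2 NG86 sites per codon).
    Synonymous substitution counts are drawn Binomial(S_total, ps) with
    ``ps`` the Jukes-Cantor-inverted target, and placed as third-base
    T<->C toggles; nonsynonymous counts Binomial(N_total, pn), placed as
    first-base swaps between families.  One mutation per codon, never a
    stop.  Returns both sequences plus the realized mutation counts.
    """
    import math

    for t in (ks_target, ka_target):
        if t < 0:
            raise ValueError("targets must be nonnegative")
    ps = 0.75 * (1.0 - math.exp(-4.0 * ks_target / 3.0))
    pn = 0.75 * (1.0 - math.exp(-4.0 * ka_target / 3.0))
    rng = np.random.default_rng(seed)
    codons = [
        str(rng.choice(list(_XC_FAMILIES))) + "C" + str(rng.choice(["T", "C"]))
        for _ in range(n_codons)
    ]
    s_total = n_codons           # 1 synonymous site per codon
    n_total = 2 * n_codons       # 2 nonsynonymous sites per codon
    n_syn = int(rng.binomial(s_total, ps))
    n_nonsyn = int(rng.binomial(n_total, pn))
    if n_syn + n_nonsyn > n_codons:
        raise ValueError(
            f"targets infeasible at {n_codons} codons "
            f"({n_syn + n_nonsyn} single-codon mutations needed)"
        )
    sites = rng.choice(n_codons, size=n_syn + n_nonsyn, replace=False)
    mutated = list(codons)
    for idx in sites[:n_syn]:
        c = mutated[idx]
        mutated[idx] = c[:2] + ("C" if c[2] == "T" else "T")
    for idx in sites[n_syn:]:
        c = mutated[idx]
        others = [b for b in _XC_FAMILIES if b != c[0]]
        mutated[idx] = str(rng.choice(others)) + c[1:]
    cds_a = SequenceRecord(
        id=f"dupA_s{seed}", residues="".join(codons), alphabet="nucleotide"
    )
    cds_b = SequenceRecord(
        id=f"dupB_s{seed}", residues="".join(mutated), alphabet="nucleotide"
    )
    realized = {
        "n_syn": n_syn,
        "n_nonsyn": n_nonsyn,
        "ps": n_syn / s_total,
        "pn": n_nonsyn / n_total,
    }
    return cds_a, cds_b, realized


# --- pseudo-MSA for phylogeny --------------------------------------------


def generate_msa(
    spec: SyntheticSpec,
    proteome_truth: dict | None = None,
    length: int = 120,
    within_mut: int = 4,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Equal-length pseudo-alignment with one well-separated clade per
    subgroup: a random ancestor per subgroup, each member a few point
    mutations away.  Returns the records and the gene -> subgroup map."""
    rng = np.random.default_rng(spec.seed + 2)
    if proteome_truth is None:
        _, proteome_truth = generate_proteome(spec)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    subgroup_of = {g: info["subgroup"] for g, info in proteome_truth.items()}
    ancestors: dict[str, str] = {}
    for sg in sorted(set(subgroup_of.values())):
        ancestors[sg] = "".join(rng.choice(alphabet, size=length))
    records = []
    for g in spec.gene_ids():
        seq = list(ancestors[subgroup_of[g]])
        for pos in rng.choice(length, size=within_mut, replace=False):
            seq[pos] = str(rng.choice(alphabet))
        records.append(SequenceRecord(id=g, residues="".join(seq), alphabet="protein"))
    return records, subgroup_of


# --- expression + DE ------------------------------------------------------


def generate_expression_matrix(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """FPKM table (genes x 7 stages) realizing the expression plan.

    ``low`` genes have all values below 1 (mean < 1 guaranteed); ``stage``
    genes peak in exactly one stage (RS); ``uniform`` genes are moderately
    and evenly expressed.
    """
    rng = np.random.default_rng(spec.seed + 3)
    plan = spec.expression_plan or {g: "uniform" for g in spec.gene_ids()}
    rows = {}
    truth = {"low": [], "stage": [], "uniform": []}
    for g in spec.gene_ids():
        cls = plan.get(g, "uniform")
        if cls == "low":
            vals = rng.uniform(0.0, 0.85, size=len(EXPRESSION_SAMPLES))
        elif cls == "stage":
            vals = rng.uniform(0.0, 0.5, size=len(EXPRESSION_SAMPLES))
            vals[0] = rng.uniform(50.0, 200.0)  # RS
        else:
            vals = rng.uniform(5.0, 50.0, size=len(EXPRESSION_SAMPLES))
        rows[g] = np.round(vals, 3)
        truth[cls if cls in truth else "uniform"].append(g)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=EXPRESSION_SAMPLES)
    df.index.name = "gene_id"
    return df, truth


def generate_de_table(
    spec: SyntheticSpec, n_up: int = 6, n_down: int = 8
) -> tuple[pd.DataFrame, dict]:
    """DE rows with exactly ``n_up`` up- and ``n_down`` down-regulated
    significant genes (FDR < 0.05) in the leaf/drought contrast, plus
    nonsignificant filler rows."""
    rng = np.random.default_rng(spec.seed + 4)
    genes = spec.gene_ids()
    if n_up + n_down > len(genes):
        raise ValueError("DE plan larger than the gene family")
    chosen = list(rng.choice(genes, size=n_up + n_down, replace=False))
    rows = []
    for g in chosen[:n_up]:
        rows.append((g, "leaf", "drought_vs_control", float(np.round(rng.uniform(1, 4), 3)),
                     float(np.round(rng.uniform(1e-5, 0.04), 6))))
    for g in chosen[n_up:]:
        rows.append((g, "leaf", "drought_vs_control", float(np.round(-rng.uniform(1, 4), 3)),
                     float(np.round(rng.uniform(1e-5, 0.04), 6))))
    others = [g for g in genes if g not in chosen]
    for g in others[:10]:
        rows.append((g, "leaf", "drought_vs_control", float(np.round(rng.normal(0, 0.5), 3)),
                     float(np.round(rng.uniform(0.06, 0.9), 6))))
    for g in others[:8]:
        rows.append((g, "root", "salt_vs_control", float(np.round(rng.normal(0, 1.0), 3)),
                     float(np.round(rng.uniform(0.06, 0.9), 6))))
    df = pd.DataFrame(rows, columns=["gene_id", "tissue", "condition_pair", "log2fc", "fdr"])
    truth = {"up": sorted(chosen[:n_up]), "down": sorted(chosen[n_up:])}
    return df, truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
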