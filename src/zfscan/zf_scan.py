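"""C2H2 zinc-finger domain detection, typing, and architecture nomenclature.

A C2H2 finger is recognised by its metal-coordinating skeleton
``C-X(2,4)-C-X(12)-H`` with an optional second histidine 3-5 residues after
the first (``H-X(3,5)-H``).  The plant-specific QALGGH hexapeptide sits at
the end of the 12-residue span, its histidine doubling as the first skeleton
histidine.  Typing follows the QALGGH integrity:

* ``Q``  — intact QALGGH and both histidines present;
* ``M1``-``M5`` — 1-5 degraded positions in the QALGGH window, both
  histidines present;
* ``D``  — second histidine absent (whatever the window looks like).

Whole proteins are then binned by finger count and spacing: fingers joined
by a linker of at most ``TANDEM_MAX_LINKER`` (11) residues are *tandem*;
proteins of three (``t1``) or four-plus (``t2``) fingers with at least one
tandem pair form the tandem groups, everything else is dispersed
(``1i``/``2i``/``3i``/``4i``/...).  A type suffix ``Q``/``M``/``D``/``Mx``
records whether the finger types are homogeneous or mixed.

The F/L anchors of the textbook pattern are deliberately not required:
degraded (M-type) fingers routinely lose them, and requiring them would
silently drop the very fingers the classification is about.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)

QALGGH = "QALGGH"
TANDEM_MAX_LINKER = 11  # residues; "separated by up to 11 amino acids"

# skeleton geometry (counts of intervening residues)
_CC_GAP = range(2, 5)       # between the two cysteines
_C2_H1_GAP = 12             # between second Cys and first His
_H1_H2_GAP = range(3, 6)    # between the two histidines
_MAX_DEGRADATION = 5        # beyond this the window is no longer a QALGGH relic


@dataclass
class ZFDomain:
    """One detected C2H2 finger (0-based half-open protein coordinates).

    ``start`` is the first coordinating cysteine and ``end`` is one past the
    last coordinating residue (second His, or first His for D-type fingers).
    """

    start: int
    end: int
    cys1: int
    cys2: int
    his1: int
    his2: int | None
    qalggh_window: str
    degradation: int
    type_label: str

    @property
    def is_tandem_capable(self) -> bool:
        return True

    @property
    def last_coordinating(self) -> int:
        return self.his1 if self.his2 is None else self.his2


@dataclass
class ProteinArchitecture:
    """Ordered fingers of one protein plus the derived subgroup label."""

    protein_id: str
    domains: list[ZFDomain]
    linker_lengths: list[int] = field(default_factory=list)
    tandem_flags: list[bool] = field(default_factory=list)
    subgroup: str = ""
    systematic_name: str = ""


def degradation_count(window: str) -> int:
    """Hamming distance of a 6-residue window to QALGGH."""
    if len(window) != len(QALGGH):
        raise ValueError(f"QALGGH window must be 6 residues, got {len(window)}")
    return sum(a != b for a, b in zip(window.upper(), QALGGH))


def _best_window(span: str) -> tuple[str, int]:
    """Leftmost minimum-Hamming 6-mer of ``span`` against QALGGH."""
    best = (7, 0)  # (degradation, offset)
    for off in range(len(span) - len(QALGGH) + 1):
        d = degradation_count(span[off : off + 6])
        if d < best[0]:
            best = (d, off)
    window = span[best[1] : best[1] + 6]
    return window, best[0]


def scan_domains(protein: SequenceRecord | str) -> list[ZFDomain]:
    """Find all non-overlapping C2H2 fingers, scanning left to right.

    Matching is greedy: the leftmost skeleton match is accepted (smallest
    Cys-Cys gap first) and scanning resumes after its last coordinating
    residue.  Fingers whose best QALGGH window is degraded at all six
    positions are rejected and logged — they are outside the Q/M/D scheme.
    """
    seq = protein.residues if isinstance(protein, SequenceRecord) else protein.upper()
    name = protein.id if isinstance(protein, SequenceRecord) else "<seq>"
    domains: list[ZFDomain] = []
    i = 0
    n = len(seq)
    while i < n:
        hit = _match_at(seq, i)
        if hit is None:
            i += 1
            continue
        cys1, cys2, his1, his2 = hit
        # QALGGH window: best 6-mer in the region ending at (and including) his1
        span = seq[cys2 + 1 : his1 + 1]
        window, deg = _best_window(span)
        if deg > _MAX_DEGRADATION and his2 is not None:
            logger.warning(
                "%s: skeleton match at %d rejected (QALGGH fully degraded: %s)",
                name, cys1, window,
            )
            i = cys1 + 1
            continue
        last = his1 if his2 is None else his2
        type_label = _type_label(deg, his2)
        domains.append(
            ZFDomain(
                start=cys1,
                end=last + 1,
                cys1=cys1,
                cys2=cys2,
                his1=his1,
                his2=his2,
                qalggh_window=window,
                degradation=deg,
                type_label=type_label,
            )
        )
        i = last + 1
    return domains


def _match_at(seq: str, pos: int):
    """Leftmost skeleton match starting at or after ``pos``."""
    n = len(seq)
    for c1 in range(pos, n):
        if seq[c1] != "C":
            continue
        for gap in _CC_GAP:
            c2 = c1 + gap + 1
            if c2 >= n or seq[c2] != "C":
                continue
            h1 = c2 + _C2_H1_GAP + 1
            if h1 >= n or seq[h1] != "H":
                continue
            h2 = None
            for g2 in _H1_H2_GAP:
                cand = h1 + g2 + 1
                if cand < n and seq[cand] == "H":
                    h2 = cand
                    break
            return c1, c2, h1, h2
    return None


def _type_label(deg: int, his2: int | None) -> str:
    if his2 is None:
        return "D"
    if deg == 0:
        return "Q"
    return f"M{deg}"


def classify_architecture(domains: Sequence[ZFDomain]) -> str:
    """Subgroup label (e.g. ``2i-Q``, ``t1-Mx``) from the ordered fingers.

    Tandem groups require three or more fingers with at least one tandem
    pair; two tandem fingers stay ``2i-*`` (no tandem two-finger class is
    defined) and are reported via a warning.
    """
    if not domains:
        raise ValueError("cannot classify a protein with no C2H2 domains")
    linkers = linker_lengths(domains)
    tandem = [l <= TANDEM_MAX_LINKER for l in linkers]
    suffix = _type_suffix(domains)
    n = len(domains)
    if n >= 3 and any(tandem):
        return f"t1-{suffix}" if n == 3 else f"t2-{suffix}"
    if n == 2 and tandem[0]:
        logger.warning(
            "two-domain protein with tandem spacing (linker %d) labelled 2i-%s",
            linkers[0], suffix,
        )
    return f"{n}i-{suffix}"


def linker_lengths(domains: Sequence[ZFDomain]) -> list[int]:
    """Residues strictly between consecutive fingers' coordinating spans."""
    return [
        b.cys1 - a.last_coordinating - 1
        for a, b in zip(domains, domains[1:])
    ]


def _type_suffix(domains: Sequence[ZFDomain]) -> str:
    kinds = {("M" if d.type_label.startswith("M") else d.type_label) for d in domains}
    if kinds == {"Q"}:
        return "Q"
    if kinds == {"M"}:
        return "M"
    if kinds == {"D"}:
        return "D"
    return "Mx"


def build_architecture(protein: SequenceRecord) -> ProteinArchitecture | None:
    """Scan one protein and classify it; ``None`` when no finger is found."""
    domains = scan_domains(protein)
    if not domains:
        return None
    linkers = linker_lengths(domains)
    return ProteinArchitecture(
        protein_id=protein.id,
        domains=domains,
        linker_lengths=linkers,
        tandem_flags=[l <= TANDEM_MAX_LINKER for l in linkers],
        subgroup=classify_architecture(domains),
    )


def assign_names(
    architectures: Sequence[ProteinArchitecture],
    gene_positions: Mapping[str, tuple[str, int]],
    prefix: str = "C2H2",
) -> dict[str, str]:
    """Systematic names ``<prefix>.<subgroup>.<NN>`` by genomic order.

    Within each subgroup, genes sorted by (chromosome, start) get zero-padded
    ordinals.  Mutates ``systematic_name`` on the inputs and returns the map.
    """
    seen: set[str] = set()
    for arch in architectures:
        if arch.protein_id in seen:
            raise ValueError(f"duplicate gene id {arch.protein_id!r}")
        seen.add(arch.protein_id)
        if arch.protein_id not in gene_positions:
            raise ValueError(f"no genomic position for {arch.protein_id!r}")
    names: dict[str, str] = {}
    by_subgroup: dict[str, list[ProteinArchitecture]] = {}
    for arch in architectures:
        by_subgroup.setdefault(arch.subgroup, []).append(arch)
    for subgroup, members in by_subgroup.items():
        members.sort(key=lambda a: (*gene_positions[a.protein_id], a.protein_id))
        for i, arch in enumerate(members, start=1):
            name = f"{prefix}.{subgroup}.{i:02d}"
            arch.systematic_name = name
            names[arch.protein_id] = name
    return names


def summarize_family(architectures: Iterable[ProteinArchitecture]) -> pd.DataFrame:
    """Counts per subgroup plus a total row (the family-overview table)."""
    counts: dict[str, int] = {}
    for arch in architectures:
        counts[arch.subgroup] = counts.get(arch.subgroup, 0) + 1
    rows = [{"subgroup": k, "n_proteins": v} for k, v in sorted(counts.items())]
    rows.append({"subgroup": "total", "n_proteins": sum(counts.values())})
    return pd.DataFrame(rows, columns=["subgroup", "n_proteins"])


def domains_table(architectures: Iterable[ProteinArchitecture]) -> pd.DataFrame:
    """Per-domain table with 1-based inclusive output coordinates."""
    rows = []
    for arch in architectures:
        for d in arch.domains:
            rows.append(
                {
                    "protein_id": arch.protein_id,
                    "start": d.start + 1,
                    "end": d.end,
                    "type": d.type_label,
                    "degradation": d.degradation,
                    "qalggh_window": d.qalggh_window,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "start", "end", "type", "degradation", "qalggh_window"],
    )


def architectures_table(architectures: Iterable[ProteinArchitecture]) -> pd.DataFrame:
    rows = []
    for arch in architectures:
        rows.append(
            {
                "protein_id": arch.protein_id,
                "n_domains": len(arch.domains),
                "types": ",".join(d.type_label for d in arch.domains),
                "linkers": ",".join(str(l) for l in arch.linker_lengths),
                "subgroup": arch.subgroup,
                "systematic_name": arch.systematic_name,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "n_domains", "types", "linkers", "subgroup", "systematic_name"],
    )
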