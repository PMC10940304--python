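"""ProtParam-style physicochemical profiling of protein sequences.

Five quantities per protein: average molecular weight (Da), isoelectric
point (Bjellqvist pKa set, bisection on the Henderson-Hasselbalch net
charge), GRAVY (Kyte-Doolittle mean hydropathy), the Guruprasad instability
index (dipeptide DIWV table, unstable above 40.00), and the Ikai aliphatic
index.  The dipeptide and hydropathy tables are the published ones shipped
with Biopython (:mod:`Bio.SeqUtils.ProtParamData`); the arithmetic is done
here so the conventions are explicit and testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils.ProtParamData import DIWV, kd as KYTE_DOOLITTLE

from .io_formats import SequenceRecord

INSTABILITY_THRESHOLD = 40.00

# Average (not monoisotopic) residue masses, Da (ProtParam convention).
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Bjellqvist pKa values as used by ProtParam.
PKA_SIDECHAIN = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0, "H": 5.98, "K": 10.0, "R": 12.0}
PKA_CTERM = 3.55
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_ACIDIC = {"D", "E", "C", "Y"}
_BASIC = {"H", "K", "R"}


@dataclass
class PhyschemProfile:
    length_aa: int
    mw_da: float
    pi: float
    gravy: float
    instability_index: float
    aliphatic_index: float

    @property
    def unstable(self) -> bool:
        return self.instability_index > INSTABILITY_THRESHOLD


def _residues(protein: SequenceRecord | str) -> str:
    seq = protein.residues if isinstance(protein, SequenceRecord) else protein.upper()
    return seq.rstrip("*")


def _check_standard(seq: str, allow_x: bool) -> str:
    for pos, ch in enumerate(seq):
        if ch not in RESIDUE_MASS and not (allow_x and ch == "X"):
            raise ValueError(f"non-standard residue {ch!r} at position {pos + 1}")
    return seq


def molecular_weight(protein: SequenceRecord | str, allow_x: bool = False) -> float:
    """Average-isotopic protein mass: sum of residue masses plus one water.

    ``X`` residues raise by default; with ``allow_x`` they contribute the
    mean of the 20 standard residue masses.
    """
    seq = _check_standard(_residues(protein), allow_x)
    if not seq:
        raise ValueError("empty sequence")
    mean_mass = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)
    return sum(RESIDUE_MASS.get(ch, mean_mass) for ch in seq) + WATER_MASS


def net_charge(seq_or_counts, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH.

    Accepts a sequence (string/record) or a precomputed composition of the
    form ``(counts_dict, nterm_residue)``.
    """
    if isinstance(seq_or_counts, tuple):
        counts, nterm = seq_or_counts
    else:
        seq = _residues(seq_or_counts)
        if not seq:
            raise ValueError("empty sequence")
        counts = {aa: seq.count(aa) for aa in PKA_SIDECHAIN}
        nterm = seq[0]
    pos = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM.get(nterm, PKA_NTERM_DEFAULT)))
    neg = -1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    charge = pos + neg
    for aa, n in counts.items():
        if n == 0:
            continue
        pka = PKA_SIDECHAIN[aa]
        if aa in _BASIC:
            charge += n / (1.0 + 10 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(protein: SequenceRecord | str, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on the monotone charge curve."""
    seq = _residues(protein)
    if not seq:
        raise ValueError("empty sequence")
    comp = ({aa: seq.count(aa) for aa in PKA_SIDECHAIN}, seq[0])
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(comp, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(protein: SequenceRecord | str, allow_x: bool = False) -> float:
    """Mean Kyte-Doolittle hydropathy; ``X`` excluded from the mean if allowed."""
    seq = _check_standard(_residues(protein), allow_x)
    vals = [KYTE_DOOLITTLE[ch] for ch in seq if ch in KYTE_DOOLITTLE]
    if not vals:
        raise ValueError("no standard residues for GRAVY")
    return sum(vals) / len(vals)


def instability_index(protein: SequenceRecord | str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights."""
    seq = _check_standard(_residues(protein), allow_x=False)
    if len(seq) < 2:
        raise ValueError("instability index needs at least 2 residues")
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def aliphatic_index(protein: SequenceRecord | str, allow_x: bool = False) -> float:
    """Ikai aliphatic index from mole percent of Ala, Val, Ile, Leu."""
    seq = _check_standard(_residues(protein), allow_x)
    denom = sum(1 for ch in seq if ch in RESIDUE_MASS)
    if denom == 0:
        raise ValueError("no standard residues for aliphatic index")
    x = lambda aa: 100.0 * seq.count(aa) / denom
    return x("A") + 2.9 * x("V") + 3.9 * (x("I") + x("L"))


def profile(protein: SequenceRecord | str, allow_x: bool = False) -> PhyschemProfile:
    seq = _residues(protein)
    return PhyschemProfile(
        length_aa=len(seq),
        mw_da=molecular_weight(seq, allow_x=allow_x),
        pi=isoelectric_point(seq),
        gravy=gravy(seq, allow_x=allow_x),
        instability_index=instability_index(seq.replace("X", "") if allow_x else seq),
        aliphatic_index=aliphatic_index(seq, allow_x=allow_x),
    )


def profile_table(proteins, allow_x: bool = False) -> pd.DataFrame:
    """Per-protein profile table (columns: id, length, mw, pi, gravy,
    instability, aliphatic, unstable)."""
    rows = []
    for rec in proteins:
        p = profile(rec, allow_x=allow_x)
        rows.append(
            {
                "id": rec.id,
                "length": p.length_aa,
                "mw": round(p.mw_da, 2),
                "pi": round(p.pi, 2),
                "gravy": round(p.gravy, 3),
                "instability": round(p.instability_index, 2),
                "aliphatic": round(p.aliphatic_index, 2),
                "unstable": p.unstable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "length", "mw", "pi", "gravy", "instability", "aliphatic", "unstable"],
    )
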