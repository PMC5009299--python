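"""Per-gene descriptive properties: protein length, molecular weight,
isoelectric point, gene length and exon/intron counts.

Molecular weights use average (not monoisotopic) residue masses, the
convention of the usual web calculators.  The isoelectric point solves
net charge(pH) = 0 by bisection; the pKa set defaults to the EMBOSS
values (Bjellqvist's set is available via ``pka_set="bjellqvist"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .formats_io import GeneModel, GenomeAnnotation, SequenceRecord

#: average residue masses (Da); free amino acid minus one water
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.02
#: mean residue mass, used for X only when explicitly allowed
MEAN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)

#: pKa sets: (N-terminus, C-terminus, sidechains K R H D E C Y)
PKA_SETS = {
    "emboss": {
        "nterm": 8.6, "cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    "bjellqvist": {
        "nterm": 7.5, "cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


@dataclass
class ProteinProperties:
    protein_id: str
    length_aa: int
    mw_da: float
    pi: float
    gene_length_bp: int
    n_exons: int
    n_introns: int

    def __post_init__(self) -> None:
        if self.n_introns != self.n_exons - 1:
            raise ValueError("n_introns must equal n_exons - 1")
        if not self.mw_da > 0:
            raise ValueError("molecular weight must be positive")
        if not 0 < self.pi < 14:
            raise ValueError("pI out of range")


def molecular_weight(protein_seq: str, allow_x: bool = False) -> float:
    """Average molecular weight in daltons (residue masses + one water)."""
    if not protein_seq:
        raise ValueError("empty protein sequence")
    total = WATER_MASS
    for aa in protein_seq:
        if aa == "X":
            if not allow_x:
                raise ValueError(
                    "sequence contains X; pass allow_x=True to substitute the mean residue mass"
                )
            total += MEAN_RESIDUE_MASS
        elif aa in AVERAGE_RESIDUE_MASS:
            total += AVERAGE_RESIDUE_MASS[aa]
        else:
            raise ValueError(f"unknown residue {aa!r}")
    return total


def net_charge(protein_seq: str, ph: float, pka_set: str = "emboss") -> float:
    """Net charge at a given pH from Henderson-Hasselbalch terms."""
    pka = PKA_SETS[pka_set]
    charge = 1.0 / (1.0 + 10 ** (ph - pka["nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["cterm"] - ph))
    for aa in protein_seq:
        if aa in _BASIC:
            charge += 1.0 / (1.0 + 10 ** (ph - pka[aa]))
        elif aa in _ACIDIC:
            charge -= 1.0 / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    protein_seq: str, pka_set: str = "emboss", tolerance: float = 1e-4
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The termini always ionize, so the root exists even for sequences
    without ionizable side chains.
    """
    if not protein_seq:
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(protein_seq, mid, pka_set)
        if abs(c) < tolerance:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gene_structure_stats(gene_model: GeneModel) -> tuple[int, int, int]:
    """(gene_length_bp, n_exons, n_introns) for one transcript."""
    if not gene_model.exons:
        raise ValueError(f"gene model {gene_model.transcript_id} has zero exons")
    n_exons = len(gene_model.exons)
    return gene_model.end - gene_model.start, n_exons, n_exons - 1


def properties_table(
    proteins: list[SequenceRecord],
    annotation: GenomeAnnotation,
    names: dict[str, str] | None = None,
    pka_set: str = "emboss",
) -> pd.DataFrame:
    """One row per protein: name, chromosome, gene/protein metrics."""
    by_transcript = annotation.by_transcript()
    rows = []
    for rec in proteins:
        model = by_transcript.get(rec.id)
        if model is None:
            raise KeyError(f"transcript {rec.id} absent from annotation")
        seq = rec.seq.rstrip("*")
        glen, n_ex, n_in = gene_structure_stats(model)
        rows.append({
            "protein_id": rec.id,
            "name": (names or {}).get(rec.id, "."),
            "chromosome": model.chromosome,
            "gene_length_bp": glen,
            "n_exons": n_ex,
            "n_introns": n_in,
            "length_aa": len(seq),
            "mw_kda": round(molecular_weight(seq, allow_x=True) / 1000.0, 2),
            "pi": round(isoelectric_point(seq, pka_set), 2),
        })
    return pd.DataFrame(rows)
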