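"""Standard genetic code helpers shared across modules."""

from __future__ import annotations

from Bio.Data import CodonTable

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, stops mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_table.stop_codons)

#: amino acid -> list of codons (stops excluded)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        AA_TO_CODONS.setdefault(_aa, []).append(_codon)

BASES = "ACGT"


def translate_cds(cds: str) -> str:
    """Translate a CDS (length divisible by 3); stops render as '*'."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))


def codons_of(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
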