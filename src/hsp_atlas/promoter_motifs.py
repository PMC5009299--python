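"""Promoter extraction and IUPAC-degenerate cis-element scanning.

Promoters are the 2 kb immediately upstream of each gene (strand-aware).
The shipped catalog of cis-regulatory elements is written as IUPAC
consensus strings (R = A/G, Y = C/T, ... N = any); scanning tests every
promoter position on both strands and reports all, possibly
overlapping, occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import GenomeAnnotation, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class MotifDefinition:
    """A named cis-element with an IUPAC consensus (5'->3')."""

    name: str
    consensus: str
    function_note: str = ""

    def __post_init__(self) -> None:
        cons = self.consensus.upper().replace("U", "T")
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)} in {self.name}")
        object.__setattr__(self, "consensus", cons)


@dataclass
class MotifHit:
    gene_id: str
    motif_name: str
    position: int  # 0-based offset in the promoter, 5'->3' on coding strand
    strand_of_match: str  # '+' or '-'
    matched_seq: str


@dataclass
class PromoterSequence:
    gene_id: str
    seq: str
    truncated: bool = False


def reverse_complement_iupac(consensus: str) -> str:
    return consensus.translate(_IUPAC_COMPLEMENT)[::-1]


def load_catalog(path: str | Path | None = None) -> list[MotifDefinition]:
    """Load the motif catalog TSV (name, consensus, function).

    Without a path the catalog shipped with the package is used.
    """
    if path is None:
        src = resources.files("hsp_atlas").joinpath("data/cis_elements.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    out = []
    for ln in lines[1:]:  # skip header
        cols = ln.split("\t")
        out.append(MotifDefinition(cols[0], cols[1], cols[2] if len(cols) > 2 else ""))
    if not out:
        raise ValueError("empty motif catalog")
    return out


def catalog_by_name(catalog: list[MotifDefinition]) -> dict[str, MotifDefinition]:
    return {m.name: m for m in catalog}


# ---------------------------------------------------------------------------
# Promoter extraction


def extract_promoters(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    length: int = 2000,
) -> dict[str, PromoterSequence]:
    """Upstream promoter per gene locus, 5'->3' on the coding strand.

    For + genes the window is ``[start-length, start)``; for - genes the
    reverse complement of ``[end, end+length)``.  Windows are truncated
    at chromosome edges (flagged).
    """
    promoters: dict[str, PromoterSequence] = {}
    for gene_id, models in annotation.loci().items():
        m = models[0]
        if m.chromosome not in genome:
            raise KeyError(f"gene {gene_id}: chromosome {m.chromosome} absent from genome")
        chrom_seq = genome[m.chromosome]
        start = min(x.start for x in models)
        end = max(x.end for x in models)
        if m.strand == "+":
            lo = max(0, start - length)
            seq = chrom_seq[lo:start]
            truncated = start - length < 0
        else:
            hi = min(len(chrom_seq), end + length)
            seq = reverse_complement(chrom_seq[end:hi])
            truncated = end + length > len(chrom_seq)
        promoters[gene_id] = PromoterSequence(gene_id, seq, truncated)
    return promoters


# ---------------------------------------------------------------------------
# Scanning


def _allowed_table(consensus: str) -> np.ndarray:
    """(m, 5) boolean table: consensus position j admits base index b.

    A subject N is matched by nothing except a consensus N.
    """
    m = len(consensus)
    table = np.zeros((m, 5), dtype=bool)
    for j, sym in enumerate(consensus):
        for b in IUPAC[sym]:
            table[j, _BASE_INDEX[b]] = True
        table[j, 4] = sym == "N"
    return table


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    return lut[arr]


def _match_positions(enc: np.ndarray, table: np.ndarray) -> np.ndarray:
    m = table.shape[0]
    n = enc.shape[0]
    if n < m:
        return np.empty(0, dtype=int)
    ok = np.ones(n - m + 1, dtype=bool)
    for j in range(m):
        ok &= table[j, enc[j : j + n - m + 1]]
    return np.nonzero(ok)[0]


def iupac_scan(
    promoter: str,
    catalog: list[MotifDefinition],
    gene_id: str = "",
    both_strands: bool = True,
) -> list[MotifHit]:
    """All occurrences of every catalog motif in one promoter.

    Minus-strand hits are windows whose reverse complement satisfies the
    consensus; their position is still the window start on the promoter.
    """
    promoter = promoter.upper().replace("U", "T")
    bad = set(promoter) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid promoter characters {sorted(bad)}")
    enc = _encode(promoter)
    hits: list[MotifHit] = []
    for motif in catalog:
        for strand, pattern in (("+", motif.consensus), ("-", reverse_complement_iupac(motif.consensus))):
            if strand == "-" and not both_strands:
                continue
            for pos in _match_positions(enc, _allowed_table(pattern)):
                hits.append(
                    MotifHit(
                        gene_id=gene_id,
                        motif_name=motif.name,
                        position=int(pos),
                        strand_of_match=strand,
                        matched_seq=promoter[pos : pos + len(pattern)],
                    )
                )
    hits.sort(key=lambda h: (h.motif_name, h.position, h.strand_of_match))
    return hits


def scan_promoters(
    promoters: dict[str, PromoterSequence],
    catalog: list[MotifDefinition],
    both_strands: bool = True,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for gene_id in sorted(promoters):
        hits.extend(
            iupac_scan(promoters[gene_id].seq, catalog, gene_id=gene_id, both_strands=both_strands)
        )
    return hits


def presence_matrix(
    hits: list[MotifHit],
    genes: list[str],
    catalog: list[MotifDefinition],
) -> pd.DataFrame:
    """gene x motif occurrence counts (all genes/motifs, zeros kept)."""
    df = pd.DataFrame(
        0, index=sorted(genes), columns=[m.name for m in catalog], dtype=int
    )
    for h in hits:
        if h.gene_id in df.index:
            df.loc[h.gene_id, h.motif_name] += 1
    return df


def unique_elements(
    presence: pd.DataFrame, family_of: dict[str, str] | None = None
) -> dict[str, list[tuple[str, str]]]:
    """Motifs present in exactly one gene of each family.

    Returns family -> [(motif_name, the single gene carrying it)].
    With ``family_of`` omitted all genes form one family ("all").
    """
    if family_of is None:
        family_of = {g: "all" for g in presence.index}
    out: dict[str, list[tuple[str, str]]] = {}
    families = sorted(set(family_of.get(g) for g in presence.index) - {None})
    for fam in families:
        members = [g for g in presence.index if family_of.get(g) == fam]
        sub = (presence.loc[members] > 0)
        uniques = []
        for motif in presence.columns:
            carriers = sub.index[sub[motif]].tolist()
            if len(carriers) == 1:
                uniques.append((motif, carriers[0]))
        out[fam] = uniques
    return out


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "motif_name": h.motif_name,
                "position": h.position,
                "strand": h.strand_of_match,
                "matched_seq": h.matched_seq,
            }
            for h in hits
        ],
        columns=["gene_id", "motif_name", "position", "strand", "matched_seq"],
    )
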