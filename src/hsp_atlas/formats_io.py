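"""Readers and writers for the standard formats the pipeline consumes.

All coordinates exposed by this module are 0-based half-open.  File
formats keep their own conventions (GFF3 and Bismark-style cytosine
reports are 1-based); the conversion happens here and nowhere else.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
VALID_CONTEXTS = ("CpG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence (nucleotide over ACGTN or protein over 20 aa + X)."""

    id: str
    description: str
    seq: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class GeneModel:
    """One transcript of one gene, 0-based half-open coordinates."""

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        if not self.start < self.end:
            raise ValueError(f"start must be < end for {self.transcript_id}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = -1
        for s, e in self.exons:
            if s < prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus the gene models living on them."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        seen: set[str] = set()
        for g in self.genes:
            key = (g.gene_id, g.transcript_id)
            if key in seen:
                raise ValueError(f"duplicate transcript {key}")
            seen.add(key)
            if g.chromosome in lengths and g.end > lengths[g.chromosome]:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chromosome}"
                )

    def transcripts_of(self, gene_id: str) -> list[GeneModel]:
        return [g for g in self.genes if g.gene_id == gene_id]

    def by_transcript(self) -> dict[str, GeneModel]:
        return {g.transcript_id: g for g in self.genes}

    def loci(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.gene_id, []).append(g)
        return out


@dataclass
class CytosineCall:
    """Methylation evidence at one cytosine (0-based position)."""

    chromosome: str
    position: int
    strand: str
    context: str
    count_methylated: int
    count_total: int

    def __post_init__(self) -> None:
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown methylation context {self.context!r}")
        if self.count_methylated < 0 or self.count_total < 0:
            raise ValueError("negative methylation counts")
        if self.count_methylated > self.count_total:
            raise ValueError("count_methylated exceeds count_total")


# ---------------------------------------------------------------------------
# FASTA


def _looks_nucleotide(seq: str) -> bool:
    return set(seq.upper()) <= (NUCLEOTIDE_ALPHABET | {"U"})


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Parameters
    ----------
    alphabet:
        ``"nucleotide"``, ``"protein"`` or ``"auto"`` (infer per record).
        Nucleotide records are upper-cased with U mapped to T on read.
    """
    if alphabet not in ("auto", "nucleotide", "protein"):
        raise ValueError(f"unknown alphabet mode {alphabet!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        is_nuc = alphabet == "nucleotide" or (
            alphabet == "auto" and _looks_nucleotide(seq)
        )
        if is_nuc:
            seq = seq.replace("U", "T")
            bad = set(seq) - NUCLEOTIDE_ALPHABET
        else:
            bad = set(seq) - PROTEIN_ALPHABET - {"*"}
        if bad:
            raise ValueError(
                f"invalid characters {sorted(bad)} in record {rec.id!r}"
            )
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, desc, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def _parse_attrs(text: str) -> dict[str, str]:
    return {k.strip(): v.strip() for k, v in _ATTR_RE.findall(text)}


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read gene/mRNA/exon/CDS features into a GenomeAnnotation.

    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open.  Chromosome lengths come from ``##sequence-region``
    pragmas when present, otherwise from the furthest feature end.
    """
    chrom_lengths: dict[str, int] = {}
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    subfeatures: list[tuple[str, str, int, int]] = []  # (type, parent, start, end)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                chrom_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols
            start, end = int(start1) - 1, int(end1)  # to 0-based half-open
            a = _parse_attrs(attrs)
            if ftype == "gene":
                genes[a["ID"]] = {
                    "chromosome": seqid,
                    "strand": strand,
                    "start": start,
                    "end": end,
                }
            elif ftype in ("mRNA", "transcript"):
                mrnas[a["ID"]] = {
                    "gene": a["Parent"],
                    "chromosome": seqid,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "exons": [],
                    "cds": [],
                }
            elif ftype in ("exon", "CDS"):
                for parent in a["Parent"].split(","):
                    subfeatures.append((ftype, parent, start, end))
    for ftype, parent, start, end in subfeatures:
        if parent not in mrnas:
            raise ValueError(f"orphan Parent reference {parent!r} in {path}")
        key = "exons" if ftype == "exon" else "cds"
        mrnas[parent][key].append((start, end))
    models: list[GeneModel] = []
    for tid, m in sorted(mrnas.items()):
        if m["gene"] not in genes:
            raise ValueError(f"orphan Parent reference {m['gene']!r} in {path}")
        g = genes[m["gene"]]
        for s, e in m["exons"] + m["cds"]:
            if s < g["start"] or e > g["end"]:
                raise ValueError(
                    f"exon/CDS ({s},{e}) outside gene span of {m['gene']}"
                )
        models.append(
            GeneModel(
                gene_id=m["gene"],
                transcript_id=tid,
                chromosome=m["chromosome"],
                strand=m["strand"],
                start=m["start"],
                end=m["end"],
                exons=m["exons"],
                cds=m["cds"],
            )
        )
    for m in models:
        chrom_lengths.setdefault(m.chromosome, 0)
        chrom_lengths[m.chromosome] = max(chrom_lengths[m.chromosome], m.end)
    models.sort(key=lambda g: (g.chromosome, g.start, g.transcript_id))
    return GenomeAnnotation(sorted(chrom_lengths.items()), models)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write a GenomeAnnotation as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        loci = annotation.loci()
        for gene_id in sorted(loci, key=lambda gid: (loci[gid][0].chromosome, loci[gid][0].start)):
            models = loci[gene_id]
            g_start = min(m.start for m in models)
            g_end = max(m.end for m in models)
            chrom, strand = models[0].chromosome, models[0].strand
            fh.write(
                f"{chrom}\tatlas\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={gene_id}\n"
            )
            for m in sorted(models, key=lambda x: x.transcript_id):
                fh.write(
                    f"{chrom}\tatlas\tmRNA\t{m.start + 1}\t{m.end}\t.\t{strand}\t.\t"
                    f"ID={m.transcript_id};Parent={gene_id}\n"
                )
                for s, e in m.exons:
                    fh.write(
                        f"{chrom}\tatlas\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"Parent={m.transcript_id}\n"
                    )
                for s, e in m.cds:
                    fh.write(
                        f"{chrom}\tatlas\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                        f"Parent={m.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Bismark-style cytosine report

_CONTEXT_ALIASES = {"CpG": "CpG", "CPG": "CpG", "CG": "CpG", "CHG": "CHG", "CHH": "CHH"}


def read_cytosine_report(path: str | Path) -> list[CytosineCall]:
    """Read a 6-column cytosine report (1-based positions on disk).

    Columns: chromosome, position, strand, count_methylated,
    count_unmethylated, context.
    """
    calls: list[CytosineCall] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            chrom, pos1, strand, n_meth, n_unmeth, context = cols[:6]
            if context not in _CONTEXT_ALIASES:
                raise ValueError(f"unknown context token {context!r}")
            meth, unmeth = int(n_meth), int(n_unmeth)
            if meth < 0 or unmeth < 0:
                raise ValueError(f"negative counts at {chrom}:{pos1}")
            calls.append(
                CytosineCall(
                    chromosome=chrom,
                    position=int(pos1) - 1,
                    strand=strand,
                    context=_CONTEXT_ALIASES[context],
                    count_methylated=meth,
                    count_total=meth + unmeth,
                )
            )
    return calls


def write_cytosine_report(calls: Iterable[CytosineCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chromosome}\t{c.position + 1}\t{c.strand}\t"
                f"{c.count_methylated}\t{c.count_total - c.count_methylated}\t{c.context}\n"
            )


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a dendropy tree; bootstrap supports become internal labels."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and math.isnan(edge.length):
            raise ValueError("NaN branch length in tree")
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
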