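"""Cytosine-context classification and per-gene methylation summaries.

Contexts follow the plant convention: CpG, CHG and CHH (H = A, C or T),
read strand-aware from the genome sequence.  Counts are aggregated per
gene for the gene body ``[start, end)`` and a TSS window (2 kb upstream,
strand-aware, matching the promoter definition); a cytosine falling in
several regions is counted in each of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import CytosineCall, GenomeAnnotation

_H = set("ACT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CONTEXT_ORDER = ("CpG", "CHG", "CHH")
REGIONS = ("gene_body", "tss")


@dataclass
class MethylationSummary:
    gene_id: str
    cultivar: str
    region: str
    context: str
    n_methylated_cytosines: int
    n_covered_cytosines: int


def classify_context(
    genome: dict[str, str],
    chromosome: str,
    position: int,
    strand: str,
    with_flag: bool = False,
):
    """Context of the cytosine at ``position`` (0-based) on ``strand``.

    On the minus strand the sequence is read as the complement in the
    5'->3' direction (towards lower coordinates).  A cytosine too close
    to the contig end for its full trinucleotide context is classed CHH
    (flagged when ``with_flag``).
    """
    seq = genome[chromosome]
    if strand == "+":
        if seq[position] != "C":
            raise ValueError(
                f"base at {chromosome}:{position} (+) is {seq[position]!r}, not C"
            )
        nxt = seq[position + 1] if position + 1 < len(seq) else None
        nxt2 = seq[position + 2] if position + 2 < len(seq) else None
    elif strand == "-":
        if seq[position] != "G":
            raise ValueError(
                f"base at {chromosome}:{position} (-) is {seq[position]!r}, not C on minus strand"
            )
        nxt = _COMP[seq[position - 1]] if position - 1 >= 0 else None
        nxt2 = _COMP[seq[position - 2]] if position - 2 >= 0 else None
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if nxt is None:
        return ("CHH", True) if with_flag else "CHH"
    if nxt == "G":
        return ("CpG", False) if with_flag else "CpG"
    if nxt2 is None:
        return ("CHH", True) if with_flag else "CHH"
    context = "CHG" if (nxt in _H and nxt2 == "G") else "CHH"
    return (context, False) if with_flag else context


def _gene_regions(
    annotation: GenomeAnnotation, tss_upstream: int
) -> list[tuple[str, str, str, int, int]]:
    """(gene_id, region, chromosome, start, end) windows, strand-aware."""
    out = []
    chrom_len = dict(annotation.chromosomes)
    for gene_id, models in sorted(annotation.loci().items()):
        m = models[0]
        start = min(x.start for x in models)
        end = max(x.end for x in models)
        out.append((gene_id, "gene_body", m.chromosome, start, end))
        if m.strand == "+":
            out.append((gene_id, "tss", m.chromosome, max(0, start - tss_upstream), start))
        else:
            limit = chrom_len.get(m.chromosome, end + tss_upstream)
            out.append((gene_id, "tss", m.chromosome, end, min(limit, end + tss_upstream)))
    return out


def region_methylation(
    calls: list[CytosineCall],
    annotation: GenomeAnnotation,
    cultivar: str = "",
    tss_upstream: int = 2000,
    min_coverage: int = 5,
    min_fraction: float = 0.5,
) -> list[MethylationSummary]:
    """Aggregate methylated/covered cytosine counts per gene x region x context.

    A cytosine is *covered* iff its total count is at least
    ``min_coverage`` and *methylated* iff additionally its methylated
    fraction is at least ``min_fraction``.
    """
    by_chrom: dict[str, dict[str, np.ndarray]] = {}
    for chrom in {c.chromosome for c in calls}:
        sub = [c for c in calls if c.chromosome == chrom]
        sub.sort(key=lambda c: c.position)
        positions = np.array([c.position for c in sub], dtype=np.int64)
        covered = np.array([c.count_total >= min_coverage for c in sub])
        methylated = covered & np.array([
            c.count_total > 0 and c.count_methylated / c.count_total >= min_fraction
            for c in sub
        ])
        contexts = np.array([c.context for c in sub])
        by_chrom[chrom] = {
            "pos": positions, "covered": covered,
            "methylated": methylated, "context": contexts,
        }
    summaries: list[MethylationSummary] = []
    for gene_id, region, chrom, start, end in _gene_regions(annotation, tss_upstream):
        counts = {ctx: [0, 0] for ctx in CONTEXT_ORDER}  # [methylated, covered]
        if chrom in by_chrom:
            d = by_chrom[chrom]
            lo = int(np.searchsorted(d["pos"], start, side="left"))
            hi = int(np.searchsorted(d["pos"], end, side="left"))
            for ctx in CONTEXT_ORDER:
                mask = d["context"][lo:hi] == ctx
                counts[ctx][0] = int((d["methylated"][lo:hi] & mask).sum())
                counts[ctx][1] = int((d["covered"][lo:hi] & mask).sum())
        for ctx in CONTEXT_ORDER:
            summaries.append(
                MethylationSummary(
                    gene_id=gene_id, cultivar=cultivar, region=region, context=ctx,
                    n_methylated_cytosines=counts[ctx][0],
                    n_covered_cytosines=counts[ctx][1],
                )
            )
    return summaries


def summaries_to_frame(summaries: list[MethylationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id, "cultivar": s.cultivar, "region": s.region,
                "context": s.context,
                "n_methylated": s.n_methylated_cytosines,
                "n_covered": s.n_covered_cytosines,
            }
            for s in summaries
        ]
    )


def cultivar_comparison(
    summary_t: list[MethylationSummary],
    summary_s: list[MethylationSummary],
) -> pd.DataFrame:
    """Join tolerant (T) and susceptible (S) summaries per gene.

    ``difference`` is S - T methylated-cytosine counts.  Genes present
    in only one cultivar are kept with a ``missing`` flag.  A totals row
    per region x context is appended (gene_id = 'TOTAL').
    """
    t = summaries_to_frame(summary_t).drop(columns="cultivar")
    s = summaries_to_frame(summary_s).drop(columns="cultivar")
    merged = t.merge(
        s, on=["gene_id", "region", "context"], how="outer",
        suffixes=("_T", "_S"),
    )
    merged["missing"] = (
        merged["n_methylated_T"].isna() | merged["n_methylated_S"].isna()
    )
    merged["difference"] = merged["n_methylated_S"] - merged["n_methylated_T"]
    totals = (
        merged.groupby(["region", "context"], as_index=False)[
            ["n_methylated_T", "n_covered_T", "n_methylated_S", "n_covered_S", "difference"]
        ]
        .sum()
    )
    totals.insert(0, "gene_id", "TOTAL")
    totals["missing"] = False
    out = pd.concat([merged, totals], ignore_index=True)
    cols = ["gene_id", "region", "context", "n_methylated_T", "n_covered_T",
            "n_methylated_S", "n_covered_S", "difference", "missing"]
    return out[cols]
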