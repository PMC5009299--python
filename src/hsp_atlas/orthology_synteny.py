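"""Reciprocal-best-hit orthology and the synteny summary table.

Orthology between the focal genome and each comparison genome uses the
reciprocal-best-hit (RBH) criterion on global-alignment identity: a
pair is kept iff each protein is the other's best-identity hit and the
identity clears the cutoff (default 80%).  The summary table counts,
per comparison genome, the focal family genes with an ortholog; its
per-genome percentages are taken over the genes orthologous anywhere,
and the overall percentage over the whole family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .formats_io import SequenceRecord
from .phylogenetics import align_pair_global


@dataclass
class OrthologPair:
    focal_gene: str
    other_genome: str
    other_gene: str
    identity: float


@dataclass
class SyntenySummary:
    total_family_genes: int
    n_orthologous: int  # focal genes with >= 1 ortholog in any genome
    per_genome_counts: dict[str, int] = field(default_factory=dict)

    @property
    def overall_percent(self) -> float:
        return 100.0 * self.n_orthologous / self.total_family_genes

    @property
    def per_genome_percent(self) -> dict[str, float]:
        denom = self.n_orthologous
        return {
            g: (100.0 * c / denom if denom else 0.0)
            for g, c in self.per_genome_counts.items()
        }

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        rows = [
            {
                "genome": g,
                "n_orthologs": self.per_genome_counts[g],
                "percent": round(self.per_genome_percent[g], decimals),
            }
            for g in sorted(self.per_genome_counts)
        ]
        rows.append({
            "genome": "any",
            "n_orthologs": self.n_orthologous,
            "percent": round(self.overall_percent, decimals),
        })
        return pd.DataFrame(rows, columns=["genome", "n_orthologs", "percent"])


def _identity_matrix(
    a: list[SequenceRecord], b: list[SequenceRecord], identity_min: float
) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for ra in a:
        for rb in b:
            la, lb = len(ra.seq), len(rb.seq)
            # identity over alignment columns cannot exceed the length ratio
            if min(la, lb) / max(la, lb) < identity_min:
                continue
            _, ident = align_pair_global(ra.seq, rb.seq)
            out[(ra.id, rb.id)] = ident
    return out


def reciprocal_best_hits(
    proteome_focal: list[SequenceRecord],
    proteome_other: list[SequenceRecord],
    other_genome: str = "other",
    identity_min: float = 0.8,
) -> list[OrthologPair]:
    """RBH ortholog pairs between two proteomes.

    Best-hit ties break on the lexicographically smallest partner id.
    """
    if not proteome_focal or not proteome_other:
        raise ValueError("both proteomes must be non-empty")
    ident = _identity_matrix(proteome_focal, proteome_other, identity_min)
    best_fo: dict[str, tuple[float, str]] = {}
    best_of: dict[str, tuple[float, str]] = {}
    for (f, o), v in sorted(ident.items()):
        if v < identity_min:
            continue
        if f not in best_fo or v > best_fo[f][0]:
            best_fo[f] = (v, o)
        if o not in best_of or v > best_of[o][0]:
            best_of[o] = (v, f)
    pairs = []
    for f, (v, o) in sorted(best_fo.items()):
        if best_of.get(o, (None, None))[1] == f:
            pairs.append(OrthologPair(f, other_genome, o, v))
    return pairs


def synteny_summary(
    ortholog_sets: dict[str, list[OrthologPair]] | dict[str, set[str]],
    family_genes: list[str],
) -> SyntenySummary:
    """Count orthologous family genes per genome and overall.

    ``ortholog_sets`` maps genome name to its ortholog pairs (or
    directly to the set of orthologous focal genes).
    """
    if not family_genes:
        raise ValueError("empty family gene set")
    family = set(family_genes)
    per_genome: dict[str, set[str]] = {}
    for genome, pairs in ortholog_sets.items():
        if isinstance(pairs, (set, frozenset)):
            genes = set(pairs)
        else:
            genes = {p.focal_gene for p in pairs}
        per_genome[genome] = genes & family
    union = set().union(*per_genome.values()) if per_genome else set()
    return SyntenySummary(
        total_family_genes=len(family),
        n_orthologous=len(union),
        per_genome_counts={g: len(s) for g, s in per_genome.items()},
    )


def links_table(ortholog_sets: dict[str, list[OrthologPair]]) -> pd.DataFrame:
    rows = [
        {
            "focal_gene": p.focal_gene,
            "other_genome": p.other_genome,
            "other_gene": p.other_gene,
            "identity": round(p.identity, 4),
        }
        for genome in sorted(ortholog_sets)
        for p in ortholog_sets[genome]
    ]
    return pd.DataFrame(
        rows, columns=["focal_gene", "other_genome", "other_gene", "identity"]
    )
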