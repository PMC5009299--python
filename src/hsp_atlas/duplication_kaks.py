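"""Paralog detection, tandem/segmental classification, Nei-Gojobori
Ka/Ks estimation and divergence dating.

Ka/Ks follows the Nei-Gojobori (1986) counting method with the
Jukes-Cantor multiple-hit correction.  Synonymous site counts exclude
changes to stop codons from the possible-change count; observed
differences average over all mutational pathways between two codons,
excluding pathways that pass through a stop codon (with a uniform
fallback when every pathway is blocked).  Divergence times follow
T = Ks / (2 lambda) with a synonymous clock rate lambda of 6.5e-9
substitutions per synonymous site per year.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from .codons import BASES, CODON_TO_AA, STOP_CODONS, codons_of, translate_cds
from .formats_io import GenomeAnnotation, SequenceRecord
from .phylogenetics import align_pair_global

DEFAULT_LAMBDA = 6.5e-9  # synonymous substitutions / synonymous site / year


@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    type: str  # "tandem" | "segmental"
    separation_bp: int | None = None
    chain_id: str | None = None
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.type not in ("tandem", "segmental"):
            raise ValueError(f"unknown duplication type {self.type!r}")
        if self.separation_bp is not None and self.separation_bp < 0:
            raise ValueError("separation_bp must be >= 0")


@dataclass
class KaKsEstimate:
    ka: float
    ks: float
    N: float
    S: float
    Nd: float
    Sd: float
    lambda_rate: float = DEFAULT_LAMBDA
    omega_defined: bool = True

    @property
    def omega(self) -> float:
        if not self.omega_defined:
            raise ValueError("omega undefined: Ks = 0")
        return self.ka / self.ks

    @property
    def t_mya(self) -> float:
        return divergence_time(self.ks, self.lambda_rate)


# ---------------------------------------------------------------------------
# Candidate paralog pairs


def paralog_pairs(
    proteins: list[SequenceRecord],
    family_of: dict[str, str],
    identity_min: float = 0.8,
) -> list[tuple[str, str, float]]:
    """Unordered within-family protein pairs with global identity >= cutoff.

    ``family_of`` maps protein/gene ids to family labels; proteins
    without a family are skipped.
    """
    members = [p for p in proteins if family_of.get(p.id) is not None]
    out: list[tuple[str, str, float]] = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            if family_of[a.id] != family_of[b.id]:
                continue
            # cheap length pre-filter: identity over columns can never
            # exceed the length ratio
            la, lb = len(a.seq), len(b.seq)
            if min(la, lb) / max(la, lb) < identity_min:
                continue
            _, identity = align_pair_global(a.seq, b.seq)
            if identity >= identity_min:
                out.append((a.id, b.id, identity))
    return out


def find_anchor_pairs(
    proteins: list[SequenceRecord],
    identity_min: float = 0.8,
    kmer: int = 4,
    min_shared_fraction: float = 0.1,
) -> list[tuple[str, str, float]]:
    """All genome-wide high-identity pairs (family plus background).

    A cheap shared-k-mer screen precedes alignment: two proteins whose
    global identity clears ``identity_min`` necessarily share a large
    fraction of their k-mers, while unrelated proteins share almost
    none, so the screen prunes the quadratic pair space without losing
    true anchors.
    """
    kmers = [
        {p.seq[i : i + kmer] for i in range(len(p.seq) - kmer + 1)} for p in proteins
    ]
    out: list[tuple[str, str, float]] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a, b = proteins[i], proteins[j]
            la, lb = len(a.seq), len(b.seq)
            if min(la, lb) / max(la, lb) < identity_min:
                continue
            shared = len(kmers[i] & kmers[j])
            if shared < min_shared_fraction * min(len(kmers[i]), len(kmers[j])):
                continue
            _, identity = align_pair_global(a.seq, b.seq)
            if identity >= identity_min:
                out.append((a.id, b.id, identity))
    return out


# ---------------------------------------------------------------------------
# Tandem / segmental classification


def classify_tandem(
    pairs: list[tuple[str, str, float]],
    annotation: GenomeAnnotation,
    max_intervening: int = 10,
    max_separation_bp: int = 150_000,
) -> list[DuplicationPair]:
    """Tandem pairs: same chromosome, few intervening genes, close by.

    Separation is the inner gap between the two gene spans.
    """
    loci = annotation.loci()
    spans: dict[str, tuple[str, int, int]] = {}
    for gid, models in loci.items():
        spans[gid] = (
            models[0].chromosome,
            min(m.start for m in models),
            max(m.end for m in models),
        )
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gid, (chrom, start, _end) in spans.items():
        by_chrom.setdefault(chrom, []).append((start, gid))
    for lst in by_chrom.values():
        lst.sort()
    out: list[DuplicationPair] = []
    for gene_a, gene_b, identity in pairs:
        for g in (gene_a, gene_b):
            if g not in spans:
                raise KeyError(f"gene {g} missing from annotation")
        ca, sa, ea = spans[gene_a]
        cb, sb, eb = spans[gene_b]
        if ca != cb:
            continue
        lo, hi = min(ea, eb), max(sa, sb)
        separation = max(0, hi - lo)
        if separation > max_separation_bp:
            continue
        intervening = sum(
            1
            for start, gid in by_chrom[ca]
            if gid not in (gene_a, gene_b) and lo <= start < hi
        )
        if intervening > max_intervening:
            continue
        out.append(
            DuplicationPair(
                gene_a=gene_a, gene_b=gene_b, type="tandem",
                separation_bp=separation, identity=identity,
            )
        )
    return out


def _longest_monotone_chain(ranks: list[int], max_gap: int) -> list[int]:
    """Indices of the longest strictly monotone (either direction) chain.

    Consecutive chain members may differ by at most ``max_gap`` in rank.
    Plain O(n^2) DP; anchor lists are short.
    """
    best: list[int] = []
    for direction in (1, -1):
        seq = [direction * r for r in ranks]
        n = len(seq)
        length = [1] * n
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                if seq[j] < seq[i] and abs(ranks[i] - ranks[j]) <= max_gap:
                    if length[j] + 1 > length[i]:
                        length[i] = length[j] + 1
                        prev[i] = j
        k = max(range(n), key=lambda i: length[i])
        chain = []
        while k != -1:
            chain.append(k)
            k = prev[k]
        chain.reverse()
        if len(chain) > len(best):
            best = chain
    return best


def classify_segmental(
    pairs: list[tuple[str, str, float]],
    anchor_pairs: list[tuple[str, str, float]],
    annotation: GenomeAnnotation,
    min_chain: int = 3,
    max_gap_genes: int = 25,
) -> list[DuplicationPair]:
    """Segmental pairs: members of collinear duplicated blocks.

    ``anchor_pairs`` are all high-identity paralog pairs genome-wide
    (family members and background).  For every chromosome pair, the
    anchors are chained by longest strictly monotone subsequence over
    gene ranks; a non-tandem family pair inside a chain of at least
    ``min_chain`` anchors is segmental.
    """
    if min_chain < 2:
        raise ValueError("min_chain must be >= 2")
    loci = annotation.loci()
    chrom_of: dict[str, str] = {}
    rank_of: dict[str, int] = {}
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gid, models in loci.items():
        chrom_of[gid] = models[0].chromosome
        by_chrom.setdefault(models[0].chromosome, []).append(
            (min(m.start for m in models), gid)
        )
    for lst in by_chrom.values():
        lst.sort()
        for rank, (_s, gid) in enumerate(lst):
            rank_of[gid] = rank
    # group anchors by (chromA, chromB) with A/B oriented consistently
    grouped: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for a, b, _ident in anchor_pairs:
        if a not in chrom_of or b not in chrom_of:
            raise KeyError(f"anchor gene {a if a not in chrom_of else b} not in annotation")
        ca, cb = chrom_of[a], chrom_of[b]
        if ca == cb:
            continue  # within-chromosome pairs belong to the tandem branch
        if ca <= cb:
            grouped.setdefault((ca, cb), []).append((a, b))
        else:
            grouped.setdefault((cb, ca), []).append((b, a))
    chained: dict[frozenset, str] = {}
    for (ca, cb), anchors in sorted(grouped.items()):
        anchors.sort(key=lambda ab: rank_of[ab[0]])
        ranks_b = [rank_of[b] for _a, b in anchors]
        chain_idx = _longest_monotone_chain(ranks_b, max_gap_genes)
        if len(chain_idx) >= min_chain:
            chain_id = f"{ca}:{cb}"
            for k in chain_idx:
                chained[frozenset(anchors[k])] = chain_id
    out: list[DuplicationPair] = []
    for a, b, identity in pairs:
        key = frozenset((a, b))
        if key in chained:
            out.append(
                DuplicationPair(
                    gene_a=a, gene_b=b, type="segmental",
                    chain_id=chained[key], identity=identity,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Codon alignment


def codon_align(
    protein_row_a: str,
    protein_row_b: str,
    cds_a: str,
    cds_b: str,
) -> tuple[str, str]:
    """Back-translate an aligned protein pair onto its CDS pair.

    Each aligned residue becomes its codon, each protein gap '---'.
    Terminal stop codons are trimmed; a translation mismatch is an
    error naming the offending position.
    """
    for label, cds in (("a", cds_a), ("b", cds_b)):
        if len(cds) % 3 != 0:
            raise ValueError(f"cds_{label} length not divisible by 3")
    prot_a = translate_cds(cds_a).rstrip("*")
    prot_b = translate_cds(cds_b).rstrip("*")
    ungapped_a = protein_row_a.replace("-", "").rstrip("*")
    ungapped_b = protein_row_b.replace("-", "").rstrip("*")
    for label, expected, observed in (
        ("a", ungapped_a, prot_a), ("b", ungapped_b, prot_b)
    ):
        if expected != observed:
            pos = next(
                (k for k, (x, y) in enumerate(zip(expected, observed)) if x != y),
                min(len(expected), len(observed)),
            )
            raise ValueError(
                f"translation of cds_{label} disagrees with protein row at residue {pos}"
            )
    out_a, out_b = [], []
    ia = ib = 0
    for ra, rb in zip(protein_row_a, protein_row_b):
        if ra == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if rb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# Nei-Gojobori


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> float:
    """Synonymous sites of one codon; stop-creating changes excluded."""
    aa = CODON_TO_AA[codon]
    syn_sites = 0.0
    for pos in range(3):
        syn = possible = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            possible += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if possible:
            syn_sites += syn / possible
    return syn_sites


@lru_cache(maxsize=None)
def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over mutational pathways."""
    positions = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        cur = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        results.append((syn, nonsyn, through_stop))
    usable = [(s, n) for s, n, blocked in results if not blocked]
    if not usable:
        usable = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def _jc_correct(p: float, what: str) -> float:
    if p >= 0.75:
        raise ValueError(f"{what} proportion {p:.3f} at or beyond saturation (>= 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(
    codon_aln_a: str, codon_aln_b: str, lambda_rate: float = DEFAULT_LAMBDA
) -> KaKsEstimate:
    """Nei-Gojobori Ka/Ks on a pairwise codon alignment.

    Codon columns containing a gap are excluded; site counts are
    averaged over the two sequences; observed differences use pathway
    averaging; proportions are Jukes-Cantor corrected.
    """
    if len(codon_aln_a) != len(codon_aln_b):
        raise ValueError("codon alignment rows differ in length")
    cod_a, cod_b = codons_of(codon_aln_a), codons_of(codon_aln_b)
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for a, b in zip(cod_a, cod_b):
        if "-" in a or "-" in b:
            continue
        if a in STOP_CODONS or b in STOP_CODONS:
            continue
        n_codons += 1
        S += (_codon_sites(a) + _codon_sites(b)) / 2.0
        sd, nd = _codon_differences(a, b)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codon columns")
    N = 3.0 * n_codons - S
    if S <= 0:
        raise ValueError("zero synonymous sites")
    pS, pN = Sd / S, Nd / N
    ks = _jc_correct(pS, "synonymous")
    ka = _jc_correct(pN, "nonsynonymous")
    return KaKsEstimate(
        ka=ka, ks=ks, N=N, S=S, Nd=Nd, Sd=Sd,
        lambda_rate=lambda_rate, omega_defined=ks > 0,
    )


def kaks_for_pair(
    protein_a: str, protein_b: str, cds_a: str, cds_b: str,
    lambda_rate: float = DEFAULT_LAMBDA,
) -> KaKsEstimate:
    """Align proteins globally, back-translate, and run Nei-Gojobori."""
    (row_a, row_b, _score), _ident = align_pair_global(protein_a, protein_b)
    aln_a, aln_b = codon_align(row_a, row_b, cds_a, cds_b)
    return nei_gojobori(aln_a, aln_b, lambda_rate)


def divergence_time(ks: float, lambda_rate: float = DEFAULT_LAMBDA) -> float:
    """Divergence time in Mya: T = Ks / (2 lambda) / 1e6."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if lambda_rate <= 0:
        raise ValueError("lambda must be positive")
    return ks / (2.0 * lambda_rate) / 1e6


# ---------------------------------------------------------------------------
# Tabular report


def kaks_table(
    dup_pairs: list[DuplicationPair],
    proteins: dict[str, str],
    cds: dict[str, str],
    lambda_rate: float = DEFAULT_LAMBDA,
) -> pd.DataFrame:
    rows = []
    for p in dup_pairs:
        est = kaks_for_pair(
            proteins[p.gene_a], proteins[p.gene_b],
            cds[p.gene_a], cds[p.gene_b], lambda_rate,
        )
        rows.append({
            "gene_a": p.gene_a, "gene_b": p.gene_b, "type": p.type,
            "ka": round(est.ka, 6), "ks": round(est.ks, 6),
            "omega": round(est.omega, 6) if est.omega_defined else float("nan"),
            "t_mya": round(est.t_mya, 3),
        })
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "type", "ka", "ks", "omega", "t_mya"])
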