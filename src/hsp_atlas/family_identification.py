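"""Profile-based gene-family identification, isoform collapse and naming.

Each family is represented by a position-specific scoring matrix (PSSM)
built from a seed alignment.  Proteins are scored by optimal local
profile-to-sequence alignment with affine gaps; significance comes from
a Gumbel null fitted to scores of per-protein shuffles, converted to an
E-value over the scanned database.  Proteins at or below the E-value
inclusion threshold are family members; a protein matching several
family profiles is assigned to the family with the smallest E-value.

Member genes are then collapsed to one primary transcript per locus
(longest CDS) and named in ascending chromosomal order.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .formats_io import GenomeAnnotation, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_INDEX["X"] = 20  # unknown residue: scores zero against every column

#: Swiss-Prot-style background amino-acid frequencies
DEFAULT_BACKGROUND = np.array([
    0.0825, 0.0137, 0.0545, 0.0675, 0.0386, 0.0707, 0.0227, 0.0596,
    0.0584, 0.0966, 0.0242, 0.0406, 0.0470, 0.0393, 0.0553, 0.0656,
    0.0534, 0.0687, 0.0108, 0.0292,
])
DEFAULT_BACKGROUND = DEFAULT_BACKGROUND / DEFAULT_BACKGROUND.sum()


@dataclass
class ProfileMatrix:
    """Log-odds profile over the 20 amino acids (bits per column)."""

    family: str
    scores: np.ndarray  # (n_columns, 20)
    gap_open: float = -11.0
    gap_extend: float = -1.0
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile contains non-finite scores")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class FamilyAssignment:
    protein_id: str
    family: str
    score: float  # bits
    evalue: float
    domain_spans: list[tuple[int, int]] = field(default_factory=list)
    assigned_name: str = ""
    gene_id: str = ""


def build_profile(
    seed_alignment: list[SequenceRecord] | list[str],
    family: str = "",
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> ProfileMatrix:
    """PSSM from an aligned seed set.

    score(col, aa) = log2( (count + pseudocount*bg(aa)) / (n + pseudocount)
    / bg(aa) ) where n is the number of non-gap residues in the column.
    Columns with more than ``max_gap_fraction`` gaps are dropped.
    """
    rows = [r.seq if isinstance(r, SequenceRecord) else r for r in seed_alignment]
    if len(rows) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("seed alignment rows have unequal lengths")
    bad = set("".join(rows)) - set(AMINO_ACIDS) - {"-", "."}
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in seed alignment")
    bg = DEFAULT_BACKGROUND if background is None else np.asarray(background, float)
    columns = []
    for j in range(width):
        col = [r[j] for r in rows]
        residues = [c for c in col if c not in "-."]
        if len(residues) < len(col) * (1.0 - max_gap_fraction):
            continue
        counts = np.zeros(20)
        for c in residues:
            counts[_AA_INDEX[c]] += 1
        n = len(residues)
        freqs = (counts + pseudocount * bg) / (n + pseudocount)
        columns.append(np.log2(freqs / bg))
    if not columns:
        raise ValueError("no usable columns in seed alignment")
    return ProfileMatrix(family=family, scores=np.array(columns))


# ---------------------------------------------------------------------------
# Local profile-sequence alignment (Smith-Waterman, affine gaps)


@njit(cache=True)
def _sw_profile(enc, prof, gap_open, gap_extend):  # pragma: no cover - jitted
    n = enc.shape[0]
    L = prof.shape[0]
    H = np.zeros((n + 1, L + 1))
    E = np.full((n + 1, L + 1), -1e30)  # gap in profile (consume sequence)
    F = np.full((n + 1, L + 1), -1e30)  # gap in sequence (consume profile)
    start = np.zeros((n + 1, L + 1), dtype=np.int32)
    best = 0.0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        aa = enc[i - 1]
        for j in range(1, L + 1):
            s = prof[j - 1, aa] if aa < 20 else 0.0
            e = max(H[i - 1, j] + gap_open, E[i - 1, j] + gap_extend)
            f = max(H[i, j - 1] + gap_open, F[i, j - 1] + gap_extend)
            h = H[i - 1, j - 1] + s
            m = max(0.0, h, e, f)
            H[i, j] = m
            E[i, j] = e
            F[i, j] = f
            if m == 0.0:
                start[i, j] = i
            elif m == h:
                start[i, j] = start[i - 1, j - 1]
            elif m == e:
                start[i, j] = start[i - 1, j]
            else:
                start[i, j] = start[i, j - 1]
            if m > best:
                best = m
                best_i = i
                best_j = j
    return best, start[best_i, best_j], best_i


def _encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - error path
        raise ValueError(f"invalid residue {exc} in protein sequence") from exc


def score_protein(profile: ProfileMatrix, seq: str) -> tuple[float, tuple[int, int]]:
    """Best local alignment score (bits) and its span on the protein."""
    enc = _encode_protein(seq)
    best, s, e = _sw_profile(
        enc, profile.scores, profile.gap_open, profile.gap_extend
    )
    return float(best), (int(s), int(e))


def scan_proteome(
    profiles: list[ProfileMatrix] | ProfileMatrix,
    proteins: list[SequenceRecord],
    evalue_threshold: float = 0.01,
    n_decoys: int = 200,
    seed: int = 0,
) -> list[FamilyAssignment]:
    """Scan every protein against every family profile.

    The null score distribution per (protein, profile) comes from
    ``n_decoys`` residue shuffles of that protein fitted to a Gumbel;
    E-value = database size x P(score >= s).  Proteins with E at or
    below ``evalue_threshold`` for at least one family are returned,
    assigned to the family with the smallest E-value.
    """
    if isinstance(profiles, ProfileMatrix):
        profiles = [profiles]
    if not proteins:
        raise ValueError("empty proteome")
    if n_decoys < 50:
        raise ValueError("n_decoys < 50 gives an unstable Gumbel fit")
    rng = np.random.default_rng(seed)
    db_size = len(proteins)
    out: list[FamilyAssignment] = []
    for rec in proteins:
        enc = _encode_protein(rec.seq)
        shuffles = [rng.permutation(enc) for _ in range(n_decoys)]
        best_assignment: FamilyAssignment | None = None
        for profile in profiles:
            score, span = score_protein(profile, rec.seq)
            decoy_scores = np.array([
                _sw_profile(s, profile.scores, profile.gap_open, profile.gap_extend)[0]
                for s in shuffles
            ])
            loc, scale = stats.gumbel_r.fit(decoy_scores)
            evalue = db_size * float(stats.gumbel_r.sf(score, loc, scale))
            if evalue <= evalue_threshold:
                cand = FamilyAssignment(
                    protein_id=rec.id,
                    family=profile.family,
                    score=score,
                    evalue=evalue,
                    domain_spans=[span],
                )
                if best_assignment is None or cand.evalue < best_assignment.evalue:
                    best_assignment = cand
        if best_assignment is not None:
            out.append(best_assignment)
    return out


# ---------------------------------------------------------------------------
# Isoform collapse and chromosomal naming


def collapse_isoforms(
    assignments: list[FamilyAssignment], annotation: GenomeAnnotation
) -> list[FamilyAssignment]:
    """Keep one transcript per gene locus: longest CDS, ties by id."""
    by_transcript = annotation.by_transcript()
    per_locus: dict[str, list[FamilyAssignment]] = {}
    for a in assignments:
        if a.protein_id not in by_transcript:
            raise ValueError(f"transcript {a.protein_id} has no parent gene in annotation")
        model = by_transcript[a.protein_id]
        a.gene_id = model.gene_id
        per_locus.setdefault(model.gene_id, []).append(a)
    kept: list[FamilyAssignment] = []
    for gene_id in sorted(per_locus):
        group = per_locus[gene_id]
        group.sort(key=lambda a: (-by_transcript[a.protein_id].cds_length, a.protein_id))
        kept.append(group[0])
    return kept


def _natural_key(name: str) -> tuple:
    return tuple(
        int(tok) if tok.isdigit() else tok
        for tok in re.split(r"(\d+)", name)
    )


def assign_names(
    assignments: list[FamilyAssignment],
    annotation: GenomeAnnotation,
    prefix: str = "Si",
) -> list[FamilyAssignment]:
    """Name members in ascending chromosomal order within each family.

    Genes are sorted by (chromosome natural order, start) and numbered
    ``<prefix><FAMILY>-NN``; the small-HSP family keeps its lowercase
    's' after the prefix (``SisHSP-NN``).
    """
    by_transcript = annotation.by_transcript()
    for a in assignments:
        if a.protein_id not in by_transcript:
            raise ValueError(f"transcript {a.protein_id} not in annotation")
    families: dict[str, list[FamilyAssignment]] = {}
    for a in assignments:
        families.setdefault(a.family, []).append(a)
    for family in sorted(families):
        members = families[family]
        members.sort(
            key=lambda a: (
                _natural_key(by_transcript[a.protein_id].chromosome),
                by_transcript[a.protein_id].start,
                a.protein_id,
            )
        )
        for i, a in enumerate(members, start=1):
            a.assigned_name = f"{prefix}{family}-{i:02d}"
    return assignments
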