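"""Synthetic genome, expression, qPCR and methylation data with known truth.

The generator emulates the inputs of a genome-wide gene-family survey:
a small multi-chromosome genome carrying planted family members (each
with a family-specific conserved domain), background genes, tandem and
segmental duplicate pairs with controlled synonymous divergence,
promoter-planted cis-elements, negative-binomial expression counts with
tissue/stress effects, qPCR Ct tables, and two-cultivar differential
methylation.  A TruthManifest records every planted entity so that each
pipeline stage can be scored against ground truth.

Default family sizes (20/9/27/20/37, totalling 113 members) follow the
published survey this pipeline re-implements at desk scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .codons import AA_TO_CODONS, BASES, CODON_TO_AA, STOP_CODONS, codons_of, translate_cds
from .formats_io import (
    CytosineCall,
    GeneModel,
    GenomeAnnotation,
    SequenceRecord,
    reverse_complement,
    write_cytosine_report,
    write_fasta,
    write_gff3,
)
from .promoter_motifs import IUPAC, catalog_by_name, load_catalog

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Swiss-Prot-style average amino-acid frequencies; keeps synthetic
# proteins in a realistic molecular-weight band.
AA_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

DEFAULT_FAMILY_SIZES = {"HSP100": 20, "HSP90": 9, "HSP70": 27, "HSP60": 20, "sHSP": 37}

CULTIVARS = ("tolerant", "susceptible")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SampleSpec:
    sample_id: str
    tissue: str
    condition: str
    library_size: int


@dataclass
class ExpressionDesign:
    """RNA-seq style design: samples plus per-gene log2 effects."""

    samples: list[SampleSpec] = field(default_factory=lambda: [
        SampleSpec("root", "root", "control", 5_000_000),
        SampleSpec("stem", "stem", "control", 4_500_000),
        SampleSpec("leaf", "leaf", "control", 5_500_000),
        SampleSpec("spica", "spica", "control", 4_000_000),
        SampleSpec("drought", "leaf", "drought", 5_000_000),
        SampleSpec("drought_control", "leaf", "control", 5_000_000),
    ])
    #: gene_id -> sample_id -> log2 fold effect relative to baseline
    log2_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    nb_dispersion: float = 0.1
    base_log_rpkm_mean: float = 4.0
    base_log_rpkm_sd: float = 1.0


@dataclass
class QpcrDesign:
    """qPCR design: per-(gene, cultivar) log2 induction under treatment."""

    #: (gene_id, cultivar) -> log2 fold change treated vs control
    log2_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    reference_gene: str = "Act2"
    tissue: str = "leaf"
    condition: str = "heat"
    timepoint: str = "1h"
    n_biological: int = 2
    n_technical: int = 3
    ct_noise_sd: float = 0.15
    bio_shift_sd: float = 0.3
    reference_ct: float = 20.0


@dataclass
class OrthologDesign:
    """Comparison-genome emulation for the orthology/synteny stage.

    Per genome: how many of the focal family genes carry an ortholog
    and at what synonymous divergence (Ks) / selection strength
    (omega).  Defaults mirror the comparative picture of the published
    survey: a close relative with ~98% of the orthologous genes down to
    a distant one with ~55%, and Ks chosen so that T = Ks/2λ lands at
    ~18/20/37/57 Mya.  Omega stays small enough that ortholog proteins
    keep ~85%+ identity and remain recoverable at the 80% RBH cutoff.
    The union of orthologous focal genes is capped at ``union_size``
    (86 by default, ~76% of the 113-member family).
    """

    genomes: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "sorghum_like": {"ks": 0.234, "omega": 0.19, "count": 84},
        "maize_like": {"ks": 0.260, "omega": 0.17, "count": 76},
        "rice_like": {"ks": 0.481, "omega": 0.09, "count": 65},
        "brachypodium_like": {"ks": 0.741, "omega": 0.06, "count": 47},
    })
    union_size: int = 86


@dataclass
class MethylationDesign:
    """Per-cultivar, per-region, per-context methylation probabilities.

    Defaults encode the qualitative structure the survey reports: CpG >
    CHG > CHH within every region, gene bodies more methylated than TSS
    windows, and the tolerant cultivar hypomethylated relative to the
    susceptible one.  The magnitudes are placeholders (no public counts
    exist to calibrate against).
    """

    p: dict[str, dict[str, dict[str, float]]] = field(default_factory=lambda: {
        "tolerant": {
            "gene_body": {"CpG": 0.55, "CHG": 0.35, "CHH": 0.10},
            "tss": {"CpG": 0.30, "CHG": 0.18, "CHH": 0.06},
        },
        "susceptible": {
            "gene_body": {"CpG": 0.75, "CHG": 0.50, "CHH": 0.16},
            "tss": {"CpG": 0.42, "CHG": 0.26, "CHH": 0.09},
        },
    })
    coverage_mean: float = 10.0

    def validate(self) -> None:
        for cult, regions in self.p.items():
            for region, ctx in regions.items():
                for c, v in ctx.items():
                    if not 0.0 <= v <= 1.0:
                        raise ValueError(
                            f"methylation probability out of [0,1]: {cult}/{region}/{c}={v}"
                        )


@dataclass
class SyntheticConfig:
    """Everything the generator needs; fixed seed => byte-identical files."""

    seed: int = 0
    n_chromosomes: int = 9
    chromosome_length_bp: int = 500_000
    family_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_FAMILY_SIZES))
    n_background_genes: int = 500
    n_tandem_pairs: int = 4
    n_segmental_pairs: int = 4
    segmental_block_anchors: int = 5
    target_ks_values: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    ka_ks_ratio_true: float = 0.1
    anchor_ks: float = 0.15
    #: (motif_name, gene_id) pairs planted once each in that gene's promoter
    planted_motifs: tuple[tuple[str, str], ...] = (
        ("ABRE3HVA22", "HSP100_13"),
        ("EMBP1TAEM", "HSP100_07"),
        ("GADOWNAT", "HSP90_04"),
        ("E2FAT", "HSP70_08"),
        ("OCTAMOTIF2", "HSP60_10"),
        ("HY5AT", "sHSP_24"),
    )
    domain_length_aa: int = 80
    n_seed_sequences: int = 8
    seed_divergence: float = 0.10
    flank_length_range: tuple[int, int] = (20, 80)
    background_length_range: tuple[int, int] = (100, 300)
    max_exons: int = 4
    intron_length_range: tuple[int, int] = (80, 300)
    intergenic_gap_range: tuple[int, int] = (2500, 4500)
    promoter_length: int = 2000
    #: family loci carrying two / three splice variants
    isoform_two: tuple[str, ...] = ("HSP100_10", "HSP60_08", "sHSP_05", "HSP90_05")
    isoform_three: tuple[str, ...] = ("HSP70_10",)
    expression: ExpressionDesign = field(default_factory=ExpressionDesign)
    qpcr: QpcrDesign = field(default_factory=QpcrDesign)
    methylation: MethylationDesign = field(default_factory=MethylationDesign)
    orthologs: OrthologDesign = field(default_factory=OrthologDesign)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.family_sizes.values()):
            raise ValueError("family sizes must be positive")
        if self.n_background_genes <= 0:
            raise ValueError("n_background_genes must be positive")
        for ks in self.target_ks_values:
            if not 0 < ks <= 0.7:
                raise ValueError("target Ks values must lie in (0, 0.7]")
        if not 0 <= self.ka_ks_ratio_true <= 1:
            raise ValueError("ka_ks_ratio_true must be a fraction in [0,1]")


# ---------------------------------------------------------------------------
# Truth manifest


@dataclass
class TruthManifest:
    family_of: dict[str, str] = field(default_factory=dict)
    duplicate_pairs: list[dict] = field(default_factory=list)
    planted_motifs: list[dict] = field(default_factory=list)
    isoform_loci: dict[str, int] = field(default_factory=dict)
    expression_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    qpcr_effects: list[dict] = field(default_factory=list)
    methylation_rates: dict = field(default_factory=dict)
    true_orthologs: dict[str, list[str]] = field(default_factory=dict)

    def to_yaml(self) -> str:
        payload = {
            "family_of": dict(sorted(self.family_of.items())),
            "duplicate_pairs": self.duplicate_pairs,
            "planted_motifs": self.planted_motifs,
            "isoform_loci": dict(sorted(self.isoform_loci.items())),
            "expression_effects": {
                g: dict(sorted(v.items()))
                for g, v in sorted(self.expression_effects.items())
            },
            "qpcr_effects": self.qpcr_effects,
            "methylation_rates": self.methylation_rates,
            "true_orthologs": {
                g: sorted(v) for g, v in sorted(self.true_orthologs.items())
            },
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TruthManifest":
        d = yaml.safe_load(text)
        return cls(
            family_of=d.get("family_of", {}),
            duplicate_pairs=d.get("duplicate_pairs", []),
            planted_motifs=d.get("planted_motifs", []),
            isoform_loci=d.get("isoform_loci", {}),
            expression_effects=d.get("expression_effects", {}),
            qpcr_effects=d.get("qpcr_effects", []),
            methylation_rates=d.get("methylation_rates", {}),
            true_orthologs=d.get("true_orthologs", {}),
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    outdir: Path
    genome: dict[str, str]
    annotation: GenomeAnnotation
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    seed_alignments: dict[str, list[SequenceRecord]]
    manifest: TruthManifest
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Independent difference recount (defines truth for evolved pairs)


@lru_cache(maxsize=None)
def _syn_site_fraction(codon: str) -> float:
    """Synonymous-site count of one codon (sum over its 3 positions).

    Each position contributes (#synonymous one-step changes) divided by
    the number of possible changes at that position, where changes
    producing a stop codon are excluded from both counts.
    """
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        possible = 0
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
            total += syn / possible
    return total


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) difference counts averaged over mutational pathways.

    All orders of the differing positions are enumerated; pathways that
    pass through a stop codon are excluded (with a uniform fallback if
    every pathway is blocked).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        pathways.append((syn, nonsyn, blocked))
    open_paths = [(s, n) for s, n, b in pathways if not b]
    if not open_paths:  # all pathways blocked: fall back to equal weights
        open_paths = [(s, n) for s, n, _ in pathways]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"proportion {p} at or beyond Jukes-Cantor saturation")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def recount_truth(cds_a: str, cds_b: str) -> dict[str, float]:
    """Exhaustive recount of realized Ka/Ks between two equal-length CDS."""
    codons_a, codons_b = codons_of(cds_a), codons_of(cds_b)
    if len(codons_a) != len(codons_b):
        raise ValueError("CDS lengths differ")
    S = sum((_syn_site_fraction(a) + _syn_site_fraction(b)) / 2
            for a, b in zip(codons_a, codons_b))
    N = 3 * len(codons_a) - S
    Sd = Nd = 0.0
    for a, b in zip(codons_a, codons_b):
        sd, nd = _pathway_counts(a, b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return {
        "S": S, "N": N, "Sd": Sd, "Nd": Nd,
        "pS": pS, "pN": pN,
        "ks": _jukes_cantor(pS), "ka": _jukes_cantor(pN),
    }


# ---------------------------------------------------------------------------
# Codon-pair evolution


def evolve_cds_pair(
    cds: str,
    target_ks: float,
    omega: float,
    seed: int | np.random.Generator = 0,
) -> tuple[str, float, float]:
    """Evolve a copy of ``cds`` to a target synonymous divergence.

    Random single-nucleotide codon changes are proposed; synonymous
    changes are always accepted, nonsynonymous ones with probability
    ``omega``, and changes creating stop codons never.  Proposals stop
    once the proportion of synonymous differences reaches the value
    whose Jukes-Cantor correction equals ``target_ks``.  Returns the
    mutated CDS together with the realized (Ks, Ka) truth computed by
    exhaustive recount.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    if any(c in STOP_CODONS for c in codons_of(cds)):
        raise ValueError("internal stop codon in CDS")
    if target_ks < 0:
        raise ValueError("target_ks must be non-negative")
    p_target = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
    if p_target >= 0.75:
        raise ValueError("target_ks beyond Jukes-Cantor saturation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if target_ks == 0:
        return cds, 0.0, 0.0
    seq = list(cds)
    n = len(seq)
    max_proposals = 500 * n
    for _ in range(max_proposals):
        pos = int(rng.integers(n))
        new_base = BASES[int(rng.integers(4))]
        if new_base == seq[pos]:
            continue
        ci = pos // 3
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        alt = codon[: pos % 3] + new_base + codon[pos % 3 + 1 :]
        if alt in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[alt] == CODON_TO_AA[codon]
        if not synonymous and rng.random() >= omega:
            continue
        seq[pos] = new_base
        if synonymous:
            truth = recount_truth(cds, "".join(seq))
            if truth["pS"] >= p_target:
                return "".join(seq), truth["ks"], truth["ka"]
    raise RuntimeError("evolution did not reach target Ks within proposal budget")


# ---------------------------------------------------------------------------
# Genome simulation helpers


_AA_LIST = list(AA_FREQS)
_AA_PROBS = np.array([AA_FREQS[a] for a in _AA_LIST])
_AA_PROBS = _AA_PROBS / _AA_PROBS.sum()


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(len(_AA_LIST), size=length - 1, p=_AA_PROBS)
    return "M" + "".join(_AA_LIST[i] for i in body)


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[int(rng.integers(20))]
    return "".join(out)


def _protein_to_cds(rng: np.random.Generator, protein: str) -> str:
    parts = []
    for aa in protein:
        options = AA_TO_CODONS[aa]
        parts.append(options[int(rng.integers(len(options)))])
    return "".join(parts)


@dataclass
class _Gene:
    gene_id: str
    family: str | None
    cds_variants: list[str]  # variant 0 is primary (longest)
    strand: str = "+"
    chromosome: str = ""
    start: int = -1
    exon_plan: list[tuple[int, int]] = field(default_factory=list)  # sense coords
    genomic_seq: str = ""

    @property
    def length(self) -> int:
        return len(self.genomic_seq)


def _build_gene_structure(rng: np.random.Generator, gene: _Gene, cfg: SyntheticConfig) -> None:
    """Choose exon/intron layout and build the sense-strand genomic string."""
    cds = gene.cds_variants[0]
    n_exons = int(rng.integers(1, cfg.max_exons + 1))
    n_exons = min(n_exons, max(1, len(cds) // 60))
    cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_exons - 1, replace=False).tolist()) if n_exons > 1 else []
    bounds = [0] + cuts + [len(cds)]
    pieces = []
    exon_plan = []
    offset = 0
    for i in range(n_exons):
        chunk = cds[bounds[i] : bounds[i + 1]]
        exon_plan.append((offset, offset + len(chunk)))
        pieces.append(chunk)
        offset += len(chunk)
        if i < n_exons - 1:
            ilen = int(rng.integers(*cfg.intron_length_range))
            intron = "".join(BASES[b] for b in rng.integers(0, 4, size=ilen))
            pieces.append(intron)
            offset += ilen
    gene.exon_plan = exon_plan
    gene.genomic_seq = "".join(pieces)


def _variant_exons(exon_plan: list[tuple[int, int]], cds_len_full: int, cds_len_variant: int) -> list[tuple[int, int]]:
    """Exons of a truncated splice variant, in sense coordinates."""
    out = []
    consumed = 0
    for s, e in exon_plan:
        elen = e - s
        if consumed + elen <= cds_len_variant:
            out.append((s, e))
            consumed += elen
        else:
            keep = cds_len_variant - consumed
            if keep > 0:
                out.append((s, s + keep))
            break
    return out


def simulate_genome(config: SyntheticConfig, outdir: str | Path) -> SyntheticDataset:
    """Emit genome FASTA, GFF3, proteome, CDS, seed alignments and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "seeds").mkdir(exist_ok=True)
    cfg = config
    manifest = TruthManifest()
    catalog = catalog_by_name(load_catalog())

    rng_domains = np.random.default_rng([cfg.seed, 1])
    rng_prot = np.random.default_rng([cfg.seed, 2])
    rng_evo = np.random.default_rng([cfg.seed, 3])
    rng_struct = np.random.default_rng([cfg.seed, 4])
    rng_place = np.random.default_rng([cfg.seed, 5])
    rng_genome = np.random.default_rng([cfg.seed, 6])
    rng_motif = np.random.default_rng([cfg.seed, 7])

    # --- family domain profiles and seed alignments
    families = sorted(cfg.family_sizes)
    consensus: dict[str, str] = {}
    seed_alignments: dict[str, list[SequenceRecord]] = {}
    for fam in families:
        cons = _random_protein(rng_domains, cfg.domain_length_aa)
        consensus[fam] = cons
        seed_alignments[fam] = [
            SequenceRecord(
                f"{fam}_seed{i + 1:02d}", "",
                _mutate_protein(rng_domains, cons, cfg.seed_divergence),
            )
            for i in range(cfg.n_seed_sequences)
        ]

    # --- proteins and CDS
    genes: dict[str, _Gene] = {}
    for fam in families:
        for i in range(1, cfg.family_sizes[fam] + 1):
            gid = f"{fam}_{i:02d}"
            flank_n = int(rng_prot.integers(*cfg.flank_length_range))
            flank_c = int(rng_prot.integers(*cfg.flank_length_range))
            domain = _mutate_protein(rng_prot, consensus[fam], cfg.seed_divergence)
            protein = (
                "M"
                + _random_protein(rng_prot, flank_n)[1:]
                + domain
                + _random_protein(rng_prot, flank_c)[1:]
            )
            cds = _protein_to_cds(rng_prot, protein)
            genes[gid] = _Gene(gid, fam, [cds])
            manifest.family_of[gid] = fam
    for i in range(1, cfg.n_background_genes + 1):
        gid = f"BG_{i:04d}"
        length = int(rng_prot.integers(*cfg.background_length_range))
        protein = _random_protein(rng_prot, length)
        genes[gid] = _Gene(gid, None, [_protein_to_cds(rng_prot, protein)])

    # --- duplicate pair selection (round-robin over the larger families)
    fam_cycle = sorted(families, key=lambda f: -cfg.family_sizes[f])
    pointers = {f: 1 for f in families}

    def next_pair(kind_index: int) -> tuple[str, str]:
        fam = fam_cycle[kind_index % len(fam_cycle)]
        while pointers[fam] + 1 > cfg.family_sizes[fam]:
            fam = fam_cycle[(kind_index + 1) % len(fam_cycle)]
        a, b = pointers[fam], pointers[fam] + 1
        pointers[fam] += 2
        return f"{fam}_{a:02d}", f"{fam}_{b:02d}"

    ks_cycle = itertools.cycle(cfg.target_ks_values)
    tandem_pairs: list[dict] = []
    for k in range(cfg.n_tandem_pairs):
        ga, gb = next_pair(k)
        target = next(ks_cycle)
        evolved, ks_true, ka_true = evolve_cds_pair(
            genes[ga].cds_variants[0], target, cfg.ka_ks_ratio_true, rng_evo
        )
        genes[gb].cds_variants = [evolved]
        tandem_pairs.append({
            "gene_a": ga, "gene_b": gb, "type": "tandem",
            "target_ks": float(target), "realized_ks": float(ks_true),
            "realized_ka": float(ka_true),
        })
    segmental_pairs: list[dict] = []
    for k in range(cfg.n_segmental_pairs):
        ga, gb = next_pair(cfg.n_tandem_pairs + k)
        target = next(ks_cycle)
        evolved, ks_true, ka_true = evolve_cds_pair(
            genes[ga].cds_variants[0], target, cfg.ka_ks_ratio_true, rng_evo
        )
        genes[gb].cds_variants = [evolved]
        segmental_pairs.append({
            "gene_a": ga, "gene_b": gb, "type": "segmental",
            "target_ks": float(target), "realized_ks": float(ks_true),
            "realized_ka": float(ka_true), "chain_id": f"block{k + 1}",
        })

    # --- segmental anchor blocks: background copies with modest divergence
    n_anchors = cfg.segmental_block_anchors
    total_bg = cfg.n_background_genes
    needed = cfg.n_segmental_pairs * n_anchors
    if 2 * needed > total_bg:
        raise ValueError("not enough background genes for segmental blocks")
    blocks: list[dict] = []
    for k in range(cfg.n_segmental_pairs):
        a_ids = [f"BG_{k * n_anchors + j + 1:04d}" for j in range(n_anchors)]
        b_ids = [f"BG_{total_bg - needed + k * n_anchors + j + 1:04d}" for j in range(n_anchors)]
        for aid, bid in zip(a_ids, b_ids):
            evolved, _, _ = evolve_cds_pair(
                genes[aid].cds_variants[0], cfg.anchor_ks, 0.2, rng_evo
            )
            genes[bid].cds_variants = [evolved]
        fam_pair = segmental_pairs[k]
        insert_at = n_anchors // 2
        order_a = a_ids[:insert_at] + [fam_pair["gene_a"]] + a_ids[insert_at:]
        order_b = b_ids[:insert_at] + [fam_pair["gene_b"]] + b_ids[insert_at:]
        if k % 2 == 1:
            order_b = order_b[::-1]  # exercise reversed-orientation blocks
        blocks.append({"order_a": order_a, "order_b": order_b, "chain_id": f"block{k + 1}"})
        fam_pair["anchors"] = [[a, b] for a, b in zip(a_ids, b_ids)]

    # --- splice variants on designated family loci
    for gid in cfg.isoform_two + cfg.isoform_three:
        if gid not in genes:
            raise ValueError(f"isoform locus {gid} not among generated genes")
        n_var = 3 if gid in cfg.isoform_three else 2
        cds = genes[gid].cds_variants[0]
        n_codons = len(cds) // 3
        fractions = [0.7, 0.5][: n_var - 1]
        for frac in fractions:
            keep = max(30, int(n_codons * frac)) * 3
            genes[gid].cds_variants.append(cds[:keep])
        manifest.isoform_loci[gid] = n_var

    # --- gene structures
    for gid in sorted(genes):
        _build_gene_structure(rng_struct, genes[gid], cfg)
        genes[gid].strand = "+" if rng_struct.random() < 0.5 else "-"

    # --- placement
    in_block = {g for blk in blocks for g in blk["order_a"] + blk["order_b"]}
    in_tandem = {g for p in tandem_pairs for g in (p["gene_a"], p["gene_b"])}
    singles = sorted(set(genes) - in_block - in_tandem)
    order = rng_place.permutation(len(singles))
    units: list[dict] = [{"kind": "single", "genes": [singles[i]]} for i in order]
    # tandem separations: endpoints pin the observed range, middles log-uniform
    seps = []
    for k in range(cfg.n_tandem_pairs):
        if k == 0:
            seps.append(400)
        elif k == cfg.n_tandem_pairs - 1:
            seps.append(101_400)
        else:
            seps.append(int(np.exp(rng_place.uniform(np.log(400), np.log(101_400)))))
    tandem_units = [
        {"kind": "tandem", "genes": [p["gene_a"], p["gene_b"]], "sep": s, "pair": p}
        for p, s in zip(tandem_pairs, seps)
    ]
    block_units = []
    for blk in blocks:
        block_units.append({"kind": "block", "genes": blk["order_a"], "mate": blk["chain_id"] + "A"})
        block_units.append({"kind": "block", "genes": blk["order_b"], "mate": blk["chain_id"] + "B"})
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    offsets = {c: 0 for c in chrom_names}
    placements: dict[str, list[tuple]] = {c: [] for c in chrom_names}
    block_chrom: dict[str, str] = {}

    def place_unit(unit: dict, chrom: str) -> None:
        pos = offsets[chrom]
        gene_list = unit["genes"]
        for idx, gid in enumerate(gene_list):
            gap = (
                unit.get("sep", 0)
                if unit["kind"] == "tandem" and idx == 1
                else int(rng_place.integers(*cfg.intergenic_gap_range))
            )
            pos += gap
            g = genes[gid]
            g.chromosome = chrom
            g.start = pos
            placements[chrom].append((pos, gid))
            pos += g.length
        offsets[chrom] = pos

    def best_chrom(exclude: str | None = None) -> str:
        candidates = [c for c in chrom_names if c != exclude]
        return min(candidates, key=lambda c: (offsets[c], c))

    for unit in tandem_units + block_units:
        if unit["kind"] == "block":
            tag = unit["mate"]
            if tag.endswith("B"):
                partner = block_chrom.get(tag[:-1] + "A")
                chrom = best_chrom(exclude=partner)
            else:
                chrom = best_chrom()
            block_chrom[tag] = chrom
        else:
            chrom = best_chrom()
        place_unit(unit, chrom)
    for unit in units:
        place_unit(unit, best_chrom())
    over = [c for c in chrom_names if offsets[c] > cfg.chromosome_length_bp]
    if over:
        raise ValueError(
            f"genes cannot be placed within {cfg.chromosome_length_bp} bp on {over}; "
            "increase chromosome_length_bp"
        )

    # --- assemble genome
    genome: dict[str, str] = {}
    for chrom in chrom_names:
        arr = rng_genome.integers(0, 4, size=cfg.chromosome_length_bp)
        chars = np.array(list(BASES))[arr]
        for pos, gid in placements[chrom]:
            g = genes[gid]
            piece = g.genomic_seq if g.strand == "+" else reverse_complement(g.genomic_seq)
            chars[pos : pos + g.length] = list(piece)
        genome[chrom] = "".join(chars)

    # --- plant promoter motifs
    genome_mut = {c: list(s) for c, s in genome.items()}
    for motif_name, gid in cfg.planted_motifs:
        if motif_name not in catalog:
            raise ValueError(f"unknown motif {motif_name!r}")
        if gid not in genes:
            raise ValueError(f"planted motif target gene {gid!r} does not exist")
        cons = catalog[motif_name].consensus
        expansion = "".join(
            IUPAC[sym][int(rng_motif.integers(len(IUPAC[sym])))] for sym in cons
        )
        g = genes[gid]
        offset = int(rng_motif.integers(0, cfg.promoter_length - len(cons)))
        if g.strand == "+":
            gpos = g.start - cfg.promoter_length + offset
            genome_mut[g.chromosome][gpos : gpos + len(cons)] = list(expansion)
        else:
            gene_end = g.start + g.length
            gpos = gene_end + cfg.promoter_length - offset - len(cons)
            genome_mut[g.chromosome][gpos : gpos + len(cons)] = list(
                reverse_complement(expansion)
            )
        manifest.planted_motifs.append({
            "gene_id": gid, "motif_name": motif_name, "offset": int(offset),
            "sequence": expansion,
        })
    genome = {c: "".join(chars) for c, chars in genome_mut.items()}

    # --- annotation, proteome, CDS records
    models: list[GeneModel] = []
    proteins: list[SequenceRecord] = []
    cds_records: list[SequenceRecord] = []
    for gid in sorted(genes):
        g = genes[gid]
        full_len = len(g.cds_variants[0])
        for v, cds in enumerate(g.cds_variants):
            tid = f"{gid}.{v + 1}"
            sense_exons = (
                g.exon_plan if v == 0 else _variant_exons(g.exon_plan, full_len, len(cds))
            )
            if g.strand == "+":
                exons = [(g.start + s, g.start + e) for s, e in sense_exons]
            else:
                L = g.length
                exons = sorted(
                    (g.start + L - e, g.start + L - s) for s, e in sense_exons
                )
            models.append(
                GeneModel(
                    gene_id=gid,
                    transcript_id=tid,
                    chromosome=g.chromosome,
                    strand=g.strand,
                    start=g.start,
                    end=g.start + g.length,
                    exons=exons,
                    cds=list(exons),
                )
            )
            proteins.append(SequenceRecord(tid, f"gene={gid}", translate_cds(cds)))
            cds_records.append(SequenceRecord(tid, f"gene={gid}", cds))
    annotation = GenomeAnnotation(
        [(c, cfg.chromosome_length_bp) for c in chrom_names], models
    )
    manifest.duplicate_pairs = tandem_pairs + segmental_pairs
    for p, s in zip(tandem_pairs, seps):
        p["separation_bp"] = int(s)

    paths = {
        "genome": outdir / "genome.fa",
        "gff3": outdir / "annotation.gff3",
        "proteins": outdir / "proteins.faa",
        "cds": outdir / "cds.fna",
        "manifest": outdir / "manifest.yaml",
    }
    write_fasta([SequenceRecord(c, "", genome[c]) for c in chrom_names], paths["genome"])
    write_gff3(annotation, paths["gff3"])
    write_fasta(proteins, paths["proteins"])
    write_fasta(cds_records, paths["cds"])
    for fam in families:
        p = outdir / "seeds" / f"{fam}.afa"
        write_fasta(seed_alignments[fam], p)
        paths[f"seeds/{fam}"] = p
    paths["manifest"].write_text(manifest.to_yaml())
    return SyntheticDataset(
        config=cfg,
        outdir=outdir,
        genome=genome,
        annotation=annotation,
        proteins=proteins,
        cds=cds_records,
        seed_alignments=seed_alignments,
        manifest=manifest,
        paths=paths,
    )


# ---------------------------------------------------------------------------
# Expression and qPCR simulation


def default_expression_effects(manifest: TruthManifest) -> dict[str, dict[str, float]]:
    """Drought induction for the first three members of every family."""
    effects: dict[str, dict[str, float]] = {}
    magnitudes = itertools.cycle([2.0, 3.0, 5.0])
    by_family: dict[str, list[str]] = {}
    for gid, fam in sorted(manifest.family_of.items()):
        by_family.setdefault(fam, []).append(gid)
    for fam in sorted(by_family):
        for gid in by_family[fam][:3]:
            effects[gid] = {"drought": next(magnitudes)}
    return effects


def simulate_expression(
    dataset: SyntheticDataset,
    design: ExpressionDesign | None = None,
    qpcr: QpcrDesign | None = None,
    seed: int | None = None,
) -> tuple[Path, Path]:
    """Emit a count table and a qPCR Ct table; record truth in the manifest."""
    import pandas as pd

    cfg = dataset.config
    design = design or cfg.expression
    qpcr = qpcr or cfg.qpcr
    if design.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, 10])

    if not design.log2_effects:
        design.log2_effects = default_expression_effects(dataset.manifest)
    primary = {m.transcript_id: m for m in dataset.annotation.genes if m.transcript_id.endswith(".1")}
    gene_ids = sorted({m.gene_id for m in dataset.annotation.genes})
    lengths = {
        gid: sum(e - s for s, e in primary[f"{gid}.1"].exons) for gid in gene_ids
    }
    base = {
        gid: float(np.exp(rng.normal(design.base_log_rpkm_mean, design.base_log_rpkm_sd)))
        for gid in gene_ids
    }
    r = 1.0 / design.nb_dispersion
    rows = {}
    for gid in gene_ids:
        row = {}
        for s in design.samples:
            effect = design.log2_effects.get(gid, {}).get(s.sample_id, 0.0)
            mean = base[gid] * (2.0 ** effect) * (lengths[gid] / 1000.0) * (s.library_size / 1e6)
            row[s.sample_id] = int(rng.negative_binomial(r, r / (r + mean))) if mean > 0 else 0
        rows[gid] = row
    counts = pd.DataFrame.from_dict(rows, orient="index")[[s.sample_id for s in design.samples]]
    counts.index.name = "gene_id"
    counts.insert(0, "length_bp", [lengths[g] for g in counts.index])
    counts_path = dataset.outdir / "counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    samples_path = dataset.outdir / "samples.tsv"
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "tissue": s.tissue, "condition": s.condition,
             "library_size": s.library_size}
            for s in design.samples
        ]
    ).to_csv(samples_path, sep="\t", index=False)
    dataset.manifest.expression_effects = design.log2_effects

    # --- qPCR Ct table
    if not qpcr.log2_effects:
        hero = sorted(dataset.manifest.family_of)[0] if dataset.manifest.family_of else None
        by_family: dict[str, list[str]] = {}
        for gid, fam in sorted(dataset.manifest.family_of.items()):
            by_family.setdefault(fam, []).append(gid)
        effects: dict[tuple[str, str], float] = {}
        magnitudes = itertools.cycle([5.0, 3.0, 1.0, 2.0, 4.0])
        for fam in sorted(by_family):
            gid = by_family[fam][-1]  # last member of each family
            m = next(magnitudes)
            effects[(gid, "tolerant")] = m
            effects[(gid, "susceptible")] = m / 4.0
        qpcr.log2_effects = effects
    rng_q = np.random.default_rng([seed, 11])
    target_genes = sorted({g for g, _ in qpcr.log2_effects})
    ct_rows = []
    base_ct = {g: float(rng_q.uniform(22, 28)) for g in target_genes}
    for cultivar in CULTIVARS:
        for condition in ("control", qpcr.condition):
            for bio in range(1, qpcr.n_biological + 1):
                # prep-level shift: shared by every gene in this RNA sample,
                # cancels through the reference gene
                prep_shift = float(rng_q.normal(0.0, qpcr.bio_shift_sd))
                for gene in target_genes + [qpcr.reference_gene]:
                    if gene == qpcr.reference_gene:
                        true_ct = qpcr.reference_ct
                    else:
                        effect = (
                            qpcr.log2_effects.get((gene, cultivar), 0.0)
                            if condition != "control"
                            else 0.0
                        )
                        true_ct = base_ct[gene] - effect
                    for tech in range(1, qpcr.n_technical + 1):
                        ct = true_ct + prep_shift + float(rng_q.normal(0.0, qpcr.ct_noise_sd))
                        ct_rows.append({
                            "gene_id": gene, "cultivar": cultivar,
                            "tissue": qpcr.tissue, "condition": condition,
                            "timepoint": qpcr.timepoint,
                            "bio_rep": bio, "tech_rep": tech,
                            "ct": round(ct, 4),
                        })
    qpcr_path = dataset.outdir / "qpcr_ct.tsv"
    pd.DataFrame(ct_rows).to_csv(qpcr_path, sep="\t", index=False)
    dataset.manifest.qpcr_effects = [
        {"gene_id": g, "cultivar": c, "log2_effect": float(v)}
        for (g, c), v in sorted(qpcr.log2_effects.items())
    ]
    dataset.paths["counts"] = counts_path
    dataset.paths["samples"] = samples_path
    dataset.paths["qpcr"] = qpcr_path
    dataset.paths["manifest"].write_text(dataset.manifest.to_yaml())
    return counts_path, qpcr_path


# ---------------------------------------------------------------------------
# Methylation simulation


def simulate_methylation(
    dataset: SyntheticDataset,
    design: MethylationDesign | None = None,
    seed: int | None = None,
) -> tuple[Path, Path]:
    """Emit one cytosine report per cultivar over family-gene regions.

    Every cytosine (both strands) inside each family gene body and its
    2 kb upstream TSS window is covered at Poisson depth; methylated
    counts are binomial with the designed per-region/context/cultivar
    probability.  Gene-body probabilities take precedence where a TSS
    window overlaps a neighbouring gene body.
    """
    from .methylation_profiling import classify_context

    cfg = dataset.config
    design = design or cfg.methylation
    design.validate()
    seed = cfg.seed if seed is None else seed
    family_gene_ids = sorted(dataset.manifest.family_of)
    loci = dataset.annotation.loci()
    # region map per chromosome: position -> region label (body wins)
    region_of: dict[str, dict[int, str]] = {}
    for gid in family_gene_ids:
        m = loci[gid][0]
        d = region_of.setdefault(m.chromosome, {})
        if m.strand == "+":
            tss_range = range(max(0, m.start - cfg.promoter_length), m.start)
        else:
            tss_range = range(m.end, min(len(dataset.genome[m.chromosome]), m.end + cfg.promoter_length))
        for pos in tss_range:
            d.setdefault(pos, "tss")
        for pos in range(m.start, m.end):
            d[pos] = "gene_body"
    paths = []
    for ci, cultivar in enumerate(CULTIVARS):
        rng = np.random.default_rng([seed, 20 + ci])
        calls: list[CytosineCall] = []
        for chrom in sorted(region_of):
            seq = dataset.genome[chrom]
            for pos in sorted(region_of[chrom]):
                base = seq[pos]
                if base == "C":
                    strand = "+"
                elif base == "G":
                    strand = "-"
                else:
                    continue
                context = classify_context(dataset.genome, chrom, pos, strand)
                region = region_of[chrom][pos]
                p = design.p[cultivar][region][context]
                cov = int(rng.poisson(design.coverage_mean))
                meth = int(rng.binomial(cov, p)) if cov > 0 else 0
                calls.append(
                    CytosineCall(chrom, pos, strand, context, meth, cov)
                )
        suffix = "T" if cultivar == "tolerant" else "S"
        path = dataset.outdir / f"methylation_{suffix}.tsv"
        write_cytosine_report(calls, path)
        dataset.paths[f"methylation_{suffix}"] = path
        paths.append(path)
    dataset.manifest.methylation_rates = design.p
    dataset.paths["manifest"].write_text(dataset.manifest.to_yaml())
    return paths[0], paths[1]


def simulate_ortholog_proteomes(
    dataset: SyntheticDataset,
    design: OrthologDesign | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Emit one proteome FASTA per emulated comparison genome.

    Each comparison genome carries orthologs of a designed subset of
    the focal family genes, derived by evolving the focal CDS to the
    genome's characteristic Ks and translating.  Focal genes outside
    the orthologous union have no counterpart anywhere; per-genome
    subsets are nested inside the union so the synteny summary
    arithmetic is fully controlled.
    """
    cfg = dataset.config
    design = design or cfg.orthologs
    seed = cfg.seed if seed is None else seed
    # recent duplicate partners are near-identical twins and make RBH
    # assignment ambiguous; prefer genes outside duplicate pairs
    dup_members = {
        g for p in dataset.manifest.duplicate_pairs for g in (p["gene_a"], p["gene_b"])
    }
    family_genes = sorted(dataset.manifest.family_of)
    candidates = [g for g in family_genes if g not in dup_members] + [
        g for g in family_genes if g in dup_members
    ]
    union = candidates[: min(design.union_size, len(candidates))]
    cds_primary = {
        r.id.rsplit(".", 1)[0]: r.seq for r in dataset.cds if r.id.endswith(".1")
    }
    (dataset.outdir / "orthologs").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    for gi, (genome, spec_d) in enumerate(sorted(design.genomes.items())):
        rng = np.random.default_rng([seed, 30 + gi])
        count = min(int(spec_d["count"]), len(union))
        # stagger prefix/suffix subsets so the realized union covers all
        # union genes, not just the largest genome's share
        chosen = union[:count] if gi % 2 == 0 else union[len(union) - count:]
        records = []
        for gid in chosen:
            evolved, _, _ = evolve_cds_pair(
                cds_primary[gid], float(spec_d["ks"]), float(spec_d["omega"]), rng
            )
            records.append(
                SequenceRecord(f"{genome}|{gid}", f"ortholog_of={gid}", translate_cds(evolved))
            )
        path = dataset.outdir / "orthologs" / f"{genome}.faa"
        write_fasta(records, path)
        paths[genome] = path
        dataset.paths[f"orthologs/{genome}"] = path
        dataset.manifest.true_orthologs[genome] = list(chosen)
    dataset.paths["manifest"].write_text(dataset.manifest.to_yaml())
    return paths


def simulate_all(
    config: SyntheticConfig, outdir: str | Path, include_orthologs: bool = True
) -> SyntheticDataset:
    """Run the full generator: genome, orthologs, expression, methylation."""
    dataset = simulate_genome(config, outdir)
    if include_orthologs:
        simulate_ortholog_proteomes(dataset)
    simulate_expression(dataset)
    simulate_methylation(dataset)
    return dataset
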