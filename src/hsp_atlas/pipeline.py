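"""End-to-end orchestration of the gene-family survey.

``run_pipeline`` takes a validated :class:`PipelineConfig`, runs every
stage in dependency order (identification -> properties / phylogeny /
duplication -> orthology / motifs / expression / methylation) and
writes plain TSV / newick outputs, a run log, and a parameter manifest.
Reruns with the same config and seed reproduce identical files.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .duplication_kaks import (
    classify_segmental,
    classify_tandem,
    find_anchor_pairs,
    kaks_table,
    paralog_pairs,
)
from .expression_profiling import delta_delta_ct, heatmap_matrix, rpkm_matrix
from .family_identification import (
    assign_names,
    build_profile,
    collapse_isoforms,
    scan_proteome,
)
from .formats_io import read_cytosine_report, read_fasta, read_gff3, write_newick
from .methylation_profiling import (
    cultivar_comparison,
    region_methylation,
    summaries_to_frame,
)
from .orthology_synteny import links_table, reciprocal_best_hits, synteny_summary
from .phylogenetics import bootstrap_support, progressive_msa
from .promoter_motifs import (
    extract_promoters,
    hits_to_frame,
    load_catalog,
    presence_matrix,
    scan_promoters,
    unique_elements,
)
from .protein_properties import properties_table


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; unknown YAML keys rejected."""

    genome: str
    gff3: str
    proteins: str
    cds: str
    seeds_dir: str
    outdir: str
    counts: str | None = None
    samples: str | None = None
    qpcr: str | None = None
    methylation_tolerant: str | None = None
    methylation_susceptible: str | None = None
    ortholog_proteomes: dict[str, str] = field(default_factory=dict)
    motif_catalog: str | None = None
    seed: int = 0
    evalue_threshold: float = 0.01
    n_decoys: int = 200
    bootstrap_replicates: int = 100
    identity_min: float = 0.8
    max_intervening: int = 10
    max_separation_bp: int = 150_000
    min_chain: int = 3
    max_gap_genes: int = 25
    promoter_length: int = 2000
    tss_upstream: int = 2000
    min_coverage: int = 5
    min_fraction: float = 0.5
    reference_gene: str = "Act2"
    control_condition: str = "control"
    name_prefix: str = "Si"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        required = ["genome", "gff3", "proteins", "cds", "seeds_dir"]
        for name in required:
            value = getattr(self, name)
            if value is None or not Path(value).exists():
                raise FileNotFoundError(f"required input {name!r} missing: {value}")
        for name in ("counts", "samples", "qpcr", "methylation_tolerant",
                     "methylation_susceptible", "motif_catalog"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"input {name!r} does not exist: {value}")
        for genome, path in self.ortholog_proteomes.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"ortholog proteome {genome!r} missing: {path}")


def from_synthetic_dir(data_dir: str | Path, outdir: str | Path, **overrides) -> PipelineConfig:
    """Config pointing at a directory written by the synthetic generator."""
    d = Path(data_dir)
    ortho = {p.stem: str(p) for p in sorted((d / "orthologs").glob("*.faa"))} if (d / "orthologs").is_dir() else {}
    maybe = {
        "counts": d / "counts.tsv", "samples": d / "samples.tsv",
        "qpcr": d / "qpcr_ct.tsv",
        "methylation_tolerant": d / "methylation_T.tsv",
        "methylation_susceptible": d / "methylation_S.tsv",
    }
    kwargs = dict(
        genome=str(d / "genome.fa"),
        gff3=str(d / "annotation.gff3"),
        proteins=str(d / "proteins.faa"),
        cds=str(d / "cds.fna"),
        seeds_dir=str(d / "seeds"),
        outdir=str(outdir),
        ortholog_proteomes=ortho,
    )
    for key, path in maybe.items():
        kwargs[key] = str(path) if path.exists() else None
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, params: dict, index=False) -> None:
    with open(path, "w") as fh:
        param_str = " ".join(f"{k}={v}" for k, v in params.items())
        fh.write(f"# hsp-atlas {__version__} stage={stage} {param_str}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)
    log = logging.getLogger("hsp_atlas.pipeline")
    log.setLevel(logging.INFO)
    log.handlers = [logging.FileHandler(outdir / "run.log", mode="w")]
    # no timestamps: rerunning with one config must reproduce files byte-for-byte
    log.handlers[0].setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    params = asdict(config)
    (outdir / "params.yaml").write_text(yaml.safe_dump(params, sort_keys=True))
    log.info("parameters: %s", params)

    def stage(name: str):
        log.info("stage %s", name)

    try:
        stage("load")
        genome = {r.id: r.seq for r in read_fasta(config.genome, alphabet="nucleotide")}
        annotation = read_gff3(config.gff3)
        proteins = read_fasta(config.proteins, alphabet="protein")
        cds = read_fasta(config.cds, alphabet="nucleotide")
    except Exception as exc:
        log.error("stage load failed: %s", exc)
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    # --- identification
    stage("identify")
    seed_files = sorted(Path(config.seeds_dir).glob("*.afa"))
    if not seed_files:
        raise RuntimeError("stage 'identify' failed: no seed alignments (*.afa) found")
    profiles = [
        build_profile(read_fasta(p, alphabet="protein"), family=p.stem)
        for p in seed_files
    ]
    assignments = scan_proteome(
        profiles, proteins,
        evalue_threshold=config.evalue_threshold,
        n_decoys=config.n_decoys,
        seed=config.seed,
    )
    members = collapse_isoforms(assignments, annotation)
    members = assign_names(members, annotation, prefix=config.name_prefix)
    by_transcript = annotation.by_transcript()
    fam_rows = []
    for a in sorted(members, key=lambda a: a.assigned_name):
        m = by_transcript[a.protein_id]
        fam_rows.append({
            "protein_id": a.protein_id, "gene_id": a.gene_id, "family": a.family,
            "score": round(a.score, 2), "evalue": f"{a.evalue:.3g}",
            "assigned_name": a.assigned_name, "chromosome": m.chromosome,
            "start": m.start, "end": m.end,
        })
    _write_tsv(pd.DataFrame(fam_rows), outdir / "families.tsv", "identify",
               {"evalue": config.evalue_threshold, "n_decoys": config.n_decoys,
                "seed": config.seed})
    family_of_gene = {a.gene_id: a.family for a in members}
    name_of_gene = {a.gene_id: a.assigned_name for a in members}
    member_protein = {a.gene_id: a.protein_id for a in members}
    log.info("identified %d family members", len(members))

    protein_seq = {r.id: r.seq for r in proteins}
    cds_seq = {r.id: r.seq for r in cds}

    # --- properties
    stage("properties")
    member_records = [r for r in proteins if r.id in set(member_protein.values())]
    names_by_tid = {member_protein[g]: name_of_gene[g] for g in member_protein}
    props = properties_table(member_records, annotation, names=names_by_tid)
    _write_tsv(props, outdir / "properties.tsv", "properties", {})

    # --- phylogeny per family
    stage("phylogeny")
    families = sorted({a.family for a in members})
    for fam in families:
        fam_members = [a for a in members if a.family == fam]
        if len(fam_members) < 4:
            log.info("family %s too small for a bootstrap tree (%d)", fam, len(fam_members))
            continue
        seqs = [(name_of_gene[a.gene_id], protein_seq[a.protein_id]) for a in fam_members]
        msa = progressive_msa(seqs)
        tree = bootstrap_support(
            msa, n_replicates=config.bootstrap_replicates, seed=config.seed
        )
        (outdir / "trees" / f"{fam}.nwk").write_text(write_newick(tree) + "\n")

    # --- duplication + Ka/Ks
    stage("duplication")
    gene_proteins = [
        type(proteins[0])(g, "", protein_seq[t]) for g, t in sorted(member_protein.items())
    ]
    pairs = paralog_pairs(gene_proteins, family_of_gene, identity_min=config.identity_min)
    all_primary = [
        type(proteins[0])(m.gene_id, "", protein_seq[m.transcript_id])
        for m in annotation.genes
        if m.transcript_id.endswith(".1") or len(annotation.transcripts_of(m.gene_id)) == 1
    ]
    anchors = find_anchor_pairs(all_primary, identity_min=config.identity_min)
    tandem = classify_tandem(
        pairs, annotation,
        max_intervening=config.max_intervening,
        max_separation_bp=config.max_separation_bp,
    )
    tandem_keys = {frozenset((p.gene_a, p.gene_b)) for p in tandem}
    nontandem = [p for p in pairs if frozenset((p[0], p[1])) not in tandem_keys]
    segmental = classify_segmental(
        nontandem, anchors, annotation,
        min_chain=config.min_chain, max_gap_genes=config.max_gap_genes,
    )
    dup_rows = [
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "type": p.type,
         "separation_bp": p.separation_bp if p.separation_bp is not None else ".",
         "chain_id": p.chain_id or ".",
         "identity": round(p.identity, 4) if p.identity is not None else "."}
        for p in tandem + segmental
    ]
    _write_tsv(pd.DataFrame(dup_rows, columns=["gene_a", "gene_b", "type",
                                               "separation_bp", "chain_id", "identity"]),
               outdir / "duplications.tsv", "duplication",
               {"identity_min": config.identity_min})
    gene_cds = {g: cds_seq[t] for g, t in member_protein.items()}
    gene_prot = {g: protein_seq[t] for g, t in member_protein.items()}
    kaks = kaks_table(tandem + segmental, gene_prot, gene_cds)
    _write_tsv(kaks, outdir / "kaks.tsv", "kaks", {})
    log.info("%d tandem, %d segmental pairs", len(tandem), len(segmental))

    # --- orthology / synteny
    stage("orthology")
    ortholog_sets = {}
    focal_records = gene_proteins
    for genome_name, path in sorted(config.ortholog_proteomes.items()):
        other = read_fasta(path, alphabet="protein")
        ortholog_sets[genome_name] = reciprocal_best_hits(
            focal_records, other, other_genome=genome_name,
            identity_min=config.identity_min,
        )
    if ortholog_sets:
        _write_tsv(links_table(ortholog_sets), outdir / "orthology.tsv", "orthology",
                   {"identity_min": config.identity_min})
        summary = synteny_summary(ortholog_sets, sorted(family_of_gene))
        _write_tsv(summary.to_frame(), outdir / "synteny_summary.tsv", "synteny", {})
    else:
        _write_tsv(pd.DataFrame(columns=["focal_gene", "other_genome", "other_gene", "identity"]),
                   outdir / "orthology.tsv", "orthology", {})
        _write_tsv(pd.DataFrame(columns=["genome", "n_orthologs", "percent"]),
                   outdir / "synteny_summary.tsv", "synteny", {})

    # --- promoter motifs
    stage("motifs")
    catalog = load_catalog(config.motif_catalog)
    family_annotation_genes = [
        m for m in annotation.genes if m.gene_id in family_of_gene
    ]
    fam_annotation = type(annotation)(annotation.chromosomes, family_annotation_genes)
    promoters = extract_promoters(genome, fam_annotation, length=config.promoter_length)
    hits = scan_promoters(promoters, catalog)
    _write_tsv(hits_to_frame(hits), outdir / "motif_hits.tsv", "motifs",
               {"promoter_length": config.promoter_length})
    presence = presence_matrix(hits, sorted(family_of_gene), catalog)
    uniq = unique_elements(presence, family_of_gene)
    uniq_rows = [
        {"family": fam, "motif_name": motif, "gene_id": gid}
        for fam in sorted(uniq) for motif, gid in uniq[fam]
    ]
    _write_tsv(pd.DataFrame(uniq_rows, columns=["family", "motif_name", "gene_id"]),
               outdir / "unique_elements.tsv", "motifs", {})

    # --- expression
    stage("expression")
    if config.counts and config.samples:
        counts = pd.read_csv(config.counts, sep="\t", index_col=0, comment="#")
        samples = pd.read_csv(config.samples, sep="\t", comment="#")
        lengths = counts.pop("length_bp")
        lib = samples.set_index("sample_id")["library_size"]
        rpkm = rpkm_matrix(counts, lengths, lib)
        _write_tsv(rpkm.round(3), outdir / "rpkm.tsv", "expression", {}, index=True)
        _write_tsv(heatmap_matrix(rpkm, "log2p1").round(3), outdir / "rpkm_log2.tsv",
                   "expression", {"transform": "log2p1"}, index=True)
    if config.qpcr:
        ct = pd.read_csv(config.qpcr, sep="\t", comment="#")
        folds = delta_delta_ct(
            ct, reference_gene=config.reference_gene,
            control_condition=config.control_condition,
        )
        _write_tsv(folds.round(4), outdir / "qpcr_folds.tsv", "qpcr",
                   {"reference": config.reference_gene})

    # --- methylation
    stage("methylation")
    if config.methylation_tolerant and config.methylation_susceptible:
        calls_t = read_cytosine_report(config.methylation_tolerant)
        calls_s = read_cytosine_report(config.methylation_susceptible)
        sum_t = region_methylation(
            calls_t, fam_annotation, cultivar="tolerant",
            tss_upstream=config.tss_upstream,
            min_coverage=config.min_coverage, min_fraction=config.min_fraction,
        )
        sum_s = region_methylation(
            calls_s, fam_annotation, cultivar="susceptible",
            tss_upstream=config.tss_upstream,
            min_coverage=config.min_coverage, min_fraction=config.min_fraction,
        )
        comparison = cultivar_comparison(sum_t, sum_s)
        _write_tsv(pd.concat([summaries_to_frame(sum_t), summaries_to_frame(sum_s)]),
                   outdir / "methylation_summaries.tsv", "methylation",
                   {"min_coverage": config.min_coverage, "min_fraction": config.min_fraction})
        _write_tsv(comparison, outdir / "methylation.tsv", "methylation", {})
    log.info("pipeline complete")
    for h in log.handlers:
        h.close()
    return outdir
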