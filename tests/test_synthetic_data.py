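"""Ground-truth guarantees of the synthetic-data generator."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pytest

from hsp_atlas.codons import translate_cds
from hsp_atlas.formats_io import read_fasta
from hsp_atlas.promoter_motifs import extract_promoters
from hsp_atlas.synthetic_data import (
    SyntheticConfig,
    evolve_cds_pair,
    recount_truth,
    simulate_all,
)

from conftest import small_config


def _sha_tree(directory: Path) -> dict[str, str]:
    return {
        str(p.relative_to(directory)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(directory.rglob("*"))
        if p.is_file()
    }


class TestSimulateGenome:
    def test_default_family_total_is_113(self, default_dataset):
        assert len(default_dataset.manifest.family_of) == 113
        by_family: dict[str, int] = {}
        for fam in default_dataset.manifest.family_of.values():
            by_family[fam] = by_family.get(fam, 0) + 1
        assert by_family == {"HSP100": 20, "HSP90": 9, "HSP70": 27, "HSP60": 20, "sHSP": 37}

    def test_fixed_seed_byte_identical(self, tmp_path):
        a = simulate_all(small_config(seed=5), tmp_path / "a")
        b = simulate_all(small_config(seed=5), tmp_path / "b")
        assert _sha_tree(a.outdir) == _sha_tree(b.outdir)

    def test_planted_motifs_recoverable_from_emitted_files(self, small_dataset):
        # independent re-parse: go through the written FASTA, not memory
        genome = {
            r.id: r.seq
            for r in read_fasta(small_dataset.paths["genome"], alphabet="nucleotide")
        }
        promoters = extract_promoters(genome, small_dataset.annotation)
        for pm in small_dataset.manifest.planted_motifs:
            window = promoters[pm["gene_id"]].seq[
                pm["offset"] : pm["offset"] + len(pm["sequence"])
            ]
            assert window == pm["sequence"]

    def test_truth_cds_match_emitted_fasta(self, small_dataset):
        on_disk = {r.id: r.seq for r in read_fasta(small_dataset.paths["cds"], alphabet="nucleotide")}
        in_memory = {r.id: r.seq for r in small_dataset.cds}
        assert on_disk == in_memory

    def test_tandem_pairs_adjacent_and_within_observed_range(self, small_dataset):
        loci = small_dataset.annotation.loci()
        tandems = [p for p in small_dataset.manifest.duplicate_pairs if p["type"] == "tandem"]
        assert tandems
        for p in tandems:
            ma, mb = loci[p["gene_a"]][0], loci[p["gene_b"]][0]
            assert ma.chromosome == mb.chromosome
            gap = max(ma.start, mb.start) - min(ma.end, mb.end)
            assert 400 <= gap <= 101_400

    def test_segmental_pairs_on_different_chromosomes(self, small_dataset):
        loci = small_dataset.annotation.loci()
        segs = [p for p in small_dataset.manifest.duplicate_pairs if p["type"] == "segmental"]
        assert segs
        for p in segs:
            assert loci[p["gene_a"]][0].chromosome != loci[p["gene_b"]][0].chromosome

    def test_isoform_loci_have_designed_variant_counts(self, small_dataset):
        loci = small_dataset.annotation.loci()
        for gid, n in small_dataset.manifest.isoform_loci.items():
            assert len(loci[gid]) == n

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="Ks"):
            SyntheticConfig(target_ks_values=(0.9,))
        with pytest.raises(ValueError, match="positive"):
            SyntheticConfig(n_background_genes=0)


class TestEvolveCdsPair:
    CDS = None

    def _cds(self):
        rng = np.random.default_rng(1)
        from hsp_atlas.codons import AA_TO_CODONS

        aas = "ACDEFGHIKLMNPQRSTVWY"
        protein = "M" + "".join(aas[i] for i in rng.integers(0, 20, size=99))
        return "".join(
            AA_TO_CODONS[a][int(rng.integers(len(AA_TO_CODONS[a])))] for a in protein
        )

    def test_target_zero_returns_identical(self):
        cds = self._cds()
        out, ks, ka = evolve_cds_pair(cds, 0.0, 0.1, seed=0)
        assert out == cds and ks == 0.0 and ka == 0.0

    def test_omega_zero_keeps_translation_fixed(self):
        cds = self._cds()
        out, _ks, ka = evolve_cds_pair(cds, 0.2, 0.0, seed=1)
        assert translate_cds(out) == translate_cds(cds)
        assert ka == 0.0

    def test_never_creates_stops(self):
        cds = self._cds()
        out, _, _ = evolve_cds_pair(cds, 0.4, 0.5, seed=2)
        assert "*" not in translate_cds(out)

    def test_realized_ks_calibrated_to_target(self):
        """Mean realized Ks across replicates within 10% of the target."""
        cds = self._cds()
        realized = [
            evolve_cds_pair(cds, 0.2, 0.1, seed=k)[1] for k in range(50)
        ]
        assert abs(np.mean(realized) - 0.2) / 0.2 < 0.10

    def test_truth_agrees_with_recount(self):
        cds = self._cds()
        out, ks, ka = evolve_cds_pair(cds, 0.3, 0.2, seed=3)
        truth = recount_truth(cds, out)
        assert truth["ks"] == pytest.approx(ks)
        assert truth["ka"] == pytest.approx(ka)

    def test_saturated_target_rejected(self):
        with pytest.raises(ValueError):
            evolve_cds_pair(self._cds(), -0.1, 0.1)


class TestSimulatedExpression:
    def test_zero_effect_means_fold_near_one(self, small_dataset):
        import pandas as pd

        counts = pd.read_csv(small_dataset.paths["counts"], sep="\t", index_col=0)
        counts = counts.drop(columns="length_bp")
        # drought vs its control: genes without a planted effect
        effects = small_dataset.manifest.expression_effects
        unaffected = [g for g in counts.index if g not in effects]
        ratio = (counts.loc[unaffected, "drought"] + 1) / (
            counts.loc[unaffected, "drought_control"] + 1
        )
        assert 0.8 < float(np.median(ratio)) < 1.25

    def test_planted_drought_effects_visible(self, small_dataset):
        import pandas as pd

        counts = pd.read_csv(small_dataset.paths["counts"], sep="\t", index_col=0)
        effects = small_dataset.manifest.expression_effects
        for gene, per_sample in effects.items():
            if per_sample.get("drought", 0) >= 3:
                assert counts.loc[gene, "drought"] > 2 * counts.loc[gene, "drought_control"]

    def test_reference_gene_present_in_ct_table(self, small_dataset):
        import pandas as pd

        ct = pd.read_csv(small_dataset.paths["qpcr"], sep="\t")
        assert "Act2" in set(ct["gene_id"])
        # 3 technical x 2 biological per group
        grp = ct.groupby(["gene_id", "cultivar", "condition"]).size()
        assert set(grp.unique()) == {6}


class TestSimulatedMethylation:
    def test_extreme_probabilities(self, tmp_path):
        from hsp_atlas.formats_io import read_cytosine_report
        from hsp_atlas.synthetic_data import MethylationDesign, simulate_genome, simulate_methylation

        cfg = small_config(seed=9)
        ds = simulate_genome(cfg, tmp_path / "m")
        flat = lambda p: {
            "gene_body": {"CpG": p, "CHG": p, "CHH": p},
            "tss": {"CpG": p, "CHG": p, "CHH": p},
        }
        design = MethylationDesign(p={"tolerant": flat(0.0), "susceptible": flat(1.0)})
        path_t, path_s = simulate_methylation(ds, design=design)
        calls_t = read_cytosine_report(path_t)
        calls_s = read_cytosine_report(path_s)
        assert all(c.count_methylated == 0 for c in calls_t)
        assert all(c.count_methylated == c.count_total for c in calls_s)

    def test_probability_out_of_range_rejected(self):
        from hsp_atlas.synthetic_data import MethylationDesign

        bad = MethylationDesign()
        bad.p["tolerant"]["tss"]["CpG"] = 1.5
        with pytest.raises(ValueError, match="probability"):
            bad.validate()

    def test_context_ordering_in_emitted_calls(self, small_dataset):
        from hsp_atlas.formats_io import read_cytosine_report

        for key in ("methylation_T", "methylation_S"):
            calls = read_cytosine_report(small_dataset.paths[key])
            meth = {"CpG": 0, "CHG": 0, "CHH": 0}
            for c in calls:
                if c.count_total >= 5 and c.count_methylated / max(c.count_total, 1) >= 0.5:
                    meth[c.context] += 1
            assert meth["CpG"] > meth["CHG"] > meth["CHH"]
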