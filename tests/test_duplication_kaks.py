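"""Duplication classification, codon alignment and Nei-Gojobori Ka/Ks."""

from __future__ import annotations

import numpy as np
import pytest

from hsp_atlas import duplication_kaks as dk
from hsp_atlas.codons import CODON_TO_AA, STOP_CODONS
from hsp_atlas.formats_io import GeneModel, GenomeAnnotation, SequenceRecord

# ---------------------------------------------------------------------------
# Independent oracle: recursive pathway enumeration, written without
# itertools and without sharing code with the implementation.

SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")


def oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:] for b in "ACGT" if b != codon[pos]]
        alts = [a for a in alts if a not in STOP_CODONS]
        n_syn = sum(1 for a in alts if CODON_TO_AA[a] == CODON_TO_AA[codon])
        if alts:
            syn += n_syn / len(alts)
    return syn


def oracle_paths(a, b):
    """All single-step mutation paths a -> b as (syn, nonsyn, hits_stop)."""
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return [(0, 0, False)]
    paths = []

    def walk(current, remaining, syn, nonsyn, stop_seen):
        if not remaining:
            paths.append((syn, nonsyn, stop_seen))
            return
        for pos in remaining:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            is_stop = nxt in STOP_CODONS
            same_aa = CODON_TO_AA[current] == CODON_TO_AA[nxt]
            walk(
                nxt,
                [p for p in remaining if p != pos],
                syn + (1 if same_aa else 0),
                nonsyn + (0 if same_aa else 1),
                stop_seen or is_stop,
            )

    walk(a, diffs, 0, 0, False)
    return paths


def oracle_kaks(codons_a, codons_b):
    S = sum((oracle_sites(x) + oracle_sites(y)) / 2 for x, y in zip(codons_a, codons_b))
    N = 3 * len(codons_a) - S
    Sd = Nd = 0.0
    for x, y in zip(codons_a, codons_b):
        paths = oracle_paths(x, y)
        ok = [(s, n) for s, n, blocked in paths if not blocked] or [
            (s, n) for s, n, _ in paths
        ]
        Sd += sum(s for s, _ in ok) / len(ok)
        Nd += sum(n for _, n in ok) / len(ok)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = -0.75 * np.log(1 - 4 * (Sd / S) / 3)
        ka = -0.75 * np.log(1 - 4 * (Nd / N) / 3)
    return ka, ks, S, N, Sd, Nd


# ---------------------------------------------------------------------------


class TestNeiGojobori:
    def test_identical_sequences_zero(self):
        est = dk.nei_gojobori("ATGGCT", "ATGGCT")
        assert est.ka == 0.0 and est.ks == 0.0
        assert not est.omega_defined

    def test_synonymous_valine_change(self):
        pad = "ATGGCT"  # context codons keep S > 0 stable
        est = dk.nei_gojobori(pad + "GTT", pad + "GTA")
        assert est.Sd == 1.0 and est.Nd == 0.0

    def test_site_counts_sum_to_three_per_codon(self):
        est = dk.nei_gojobori("ATGGCTGTT", "ATGGCTGTA")
        assert est.S + est.N == pytest.approx(9.0)

    def test_symmetry(self):
        a = "ATGGCTGTTAAACGT"
        b = "ATGGCAGTCAAACGT"
        e1 = dk.nei_gojobori(a, b)
        e2 = dk.nei_gojobori(b, a)
        assert e1.ks == pytest.approx(e2.ks) and e1.ka == pytest.approx(e2.ka)

    def test_gap_codons_excluded(self):
        est = dk.nei_gojobori("ATG---GTT", "ATGGCAGTT")
        assert est.S + est.N == pytest.approx(6.0)

    def test_matches_pathway_oracle_on_sampled_codon_pairs(self):
        rng = np.random.default_rng(12)
        pad = ["ATG", "GCT", "CGT"]  # shared context
        for _ in range(120):
            a = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            b = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            codons_a, codons_b = pad + [a], pad + [b]
            ka_o, ks_o, S_o, N_o, Sd_o, Nd_o = oracle_kaks(codons_a, codons_b)
            est = dk.nei_gojobori("".join(codons_a), "".join(codons_b))
            assert est.S == pytest.approx(S_o, abs=1e-12)
            assert est.Sd == pytest.approx(Sd_o, abs=1e-12)
            assert est.Nd == pytest.approx(Nd_o, abs=1e-12)
            assert est.ks == pytest.approx(ks_o, abs=1e-12)
            assert est.ka == pytest.approx(ka_o, abs=1e-12)

    def test_saturation_errors(self):
        # every third position differs synonymously often enough to saturate
        a = "TTA" * 4
        b = "CTG" * 4
        with pytest.raises(ValueError, match="saturation"):
            dk.nei_gojobori(a, b)


class TestCodonAlign:
    def test_two_codon_columns(self):
        a, b = dk.codon_align("MA", "MA", "ATGGCT", "ATGGCA")
        assert (a, b) == ("ATGGCT", "ATGGCA")

    def test_gap_becomes_triple_dash(self):
        a, b = dk.codon_align("MA", "M-", "ATGGCT", "ATG")
        assert b == "ATG---"

    def test_roundtrip_recovers_cds(self):
        a, b = dk.codon_align("MAV", "M-V", "ATGGCTGTT", "ATGGTC")
        assert a.replace("---", "") == "ATGGCTGTT"
        assert b.replace("---", "") == "ATGGTC"

    def test_terminal_stop_trimmed(self):
        a, b = dk.codon_align("MA", "MA", "ATGGCTTAA", "ATGGCA")
        assert a == "ATGGCT"

    def test_translation_mismatch_names_position(self):
        with pytest.raises(ValueError, match="residue 1"):
            dk.codon_align("MV", "MV", "ATGGCT", "ATGGTT")


class TestDivergenceTime:
    def test_zero(self):
        assert dk.divergence_time(0.0) == 0.0

    def test_ks_013_is_10_mya(self):
        assert dk.divergence_time(0.13) == pytest.approx(10.0)

    def test_ks_0338_is_26_mya(self):
        assert dk.divergence_time(0.338) == pytest.approx(26.0)

    def test_linear_in_ks_inverse_in_lambda(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ks = float(rng.uniform(0, 1))
            c = float(rng.uniform(0.5, 3))
            assert dk.divergence_time(c * ks) == pytest.approx(c * dk.divergence_time(ks))
            assert dk.divergence_time(ks, lambda_rate=c * dk.DEFAULT_LAMBDA) == pytest.approx(
                dk.divergence_time(ks) / c
            )

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            dk.divergence_time(-0.1)


def _linear_annotation(genes_on_chrom: dict[str, list[tuple[str, int, int]]]):
    models = []
    for chrom, lst in genes_on_chrom.items():
        for gid, start, end in lst:
            models.append(GeneModel(gid, f"{gid}.1", chrom, "+", start, end,
                                    [(start, end)], [(start, end)]))
    return GenomeAnnotation([(c, 10**7) for c in genes_on_chrom], models)


class TestClassifyTandem:
    def test_adjacent_400bp(self):
        ann = _linear_annotation({"chr1": [("a", 1000, 2000), ("b", 2400, 3400)]})
        out = dk.classify_tandem([("a", "b", 0.95)], ann)
        assert out[0].type == "tandem" and out[0].separation_bp == 400

    def test_max_observed_distance_with_intervening_genes(self):
        genes = [("a", 0, 1000)]
        genes += [(f"x{i}", 20_000 * (i + 1), 20_000 * (i + 1) + 1000) for i in range(3)]
        genes += [("b", 102_400, 103_400)]
        ann = _linear_annotation({"chr1": genes})
        out = dk.classify_tandem([("a", "b", 0.9)], ann)
        assert len(out) == 1 and out[0].separation_bp == 101_400

    def test_different_chromosomes_not_tandem(self):
        ann = _linear_annotation({"chr1": [("a", 0, 1000)], "chr2": [("b", 0, 1000)]})
        assert dk.classify_tandem([("a", "b", 0.9)], ann) == []

    def test_too_many_intervening_genes_rejected(self):
        genes = [("a", 0, 1000)]
        genes += [(f"x{i}", 1500 + 500 * i, 1900 + 500 * i) for i in range(12)]
        genes += [("b", 9000, 10_000)]
        ann = _linear_annotation({"chr1": genes})
        assert dk.classify_tandem([("a", "b", 0.9)], ann, max_intervening=10) == []


class TestClassifySegmental:
    def _block_annotation(self, reverse_b=False):
        a_side = [(f"A{i}", 10_000 * i, 10_000 * i + 1000) for i in range(6)]
        order = list(range(6))
        if reverse_b:
            order = order[::-1]
        b_side = [(f"B{order[i]}", 10_000 * i, 10_000 * i + 1000) for i in range(6)]
        ann = _linear_annotation({"chr1": a_side, "chr2": b_side})
        anchors = [(f"A{i}", f"B{i}", 0.9) for i in range(6)]
        return ann, anchors

    def test_planted_block_detected(self):
        ann, anchors = self._block_annotation()
        fam_pair = [("A3", "B3", 0.92)]
        out = dk.classify_segmental(fam_pair, anchors, ann)
        assert len(out) == 1 and out[0].type == "segmental"

    def test_two_isolated_anchors_not_enough(self):
        ann = _linear_annotation({
            "chr1": [("A0", 0, 1000), ("A1", 500_000, 501_000)],
            "chr2": [("B0", 0, 1000), ("B1", 500_000, 501_000)],
        })
        anchors = [("A0", "B0", 0.9), ("A1", "B1", 0.9)]
        assert dk.classify_segmental([("A0", "B0", 0.9)], anchors, ann, min_chain=3) == []

    def test_reversed_orientation_block_still_detected(self):
        ann, anchors = self._block_annotation(reverse_b=True)
        out = dk.classify_segmental([("A3", "B3", 0.92)], anchors, ann)
        assert len(out) == 1

    def test_min_chain_below_two_rejected(self):
        ann, anchors = self._block_annotation()
        with pytest.raises(ValueError):
            dk.classify_segmental([], anchors, ann, min_chain=1)


class TestParalogPairs:
    def test_identical_duplicates_included_unrelated_excluded(self):
        rng = np.random.default_rng(5)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        seq = "M" + "".join(aas[i] for i in rng.integers(0, 20, 150))
        other = "M" + "".join(aas[i] for i in rng.integers(0, 20, 150))
        prots = [
            SequenceRecord("a", "", seq),
            SequenceRecord("b", "", seq),
            SequenceRecord("c", "", other),
        ]
        fam = {"a": "F", "b": "F", "c": "F"}
        pairs = dk.paralog_pairs(prots, fam)
        assert [(p[0], p[1]) for p in pairs] == [("a", "b")]
        assert pairs[0][2] == 1.0

    def test_truth_pairs_recovered_on_synthetic_data(self, small_dataset):
        primary = {
            r.id.rsplit(".", 1)[0]: r.seq for r in small_dataset.proteins
            if r.id.endswith(".1")
        }
        fam = small_dataset.manifest.family_of
        prots = [SequenceRecord(g, "", primary[g]) for g in sorted(fam)]
        found = {frozenset(p[:2]) for p in dk.paralog_pairs(prots, fam)}
        truth = {
            frozenset((p["gene_a"], p["gene_b"]))
            for p in small_dataset.manifest.duplicate_pairs
            if p["target_ks"] <= 0.4
        }
        assert truth <= found
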