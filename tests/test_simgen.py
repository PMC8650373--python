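"""Synthetic-screen generator: determinism, truth bookkeeping, read chemistry."""

import numpy as np
import pandas as pd
import pytest

from cisscout import (
    ClinicalSimSpec,
    CohortSpec,
    GenomeSpec,
    ProtocolParams,
    SpikedCIS,
    make_genome,
    simulate_clinical,
    simulate_genes,
    simulate_insertions,
    simulate_reads,
)
from cisscout.simgen import Genome, write_gff3
from cisscout.util import revcomp

from .oracles import naive_motif_scan

LTR = "CCAAACCTACAGGTGGGGTCTTTC"


class TestGenome:
    def test_fixed_seed_reproduces_sequence(self):
        spec = GenomeSpec(chromosomes=(("chr1", 1_000),), seed=7)
        g1, g2 = make_genome(spec), make_genome(spec)
        assert g1.sequences["chr1"] == g2.sequences["chr1"]
        assert set(g1.sequences["chr1"]) <= set("ACGT")

    def test_motif_index_on_literal_repeat(self):
        seq = "TTAA" * 10
        spec = GenomeSpec(
            chromosomes=(("chr1", 40),), seed=0, sequence_overrides={"chr1": seq}
        )
        g = make_genome(spec)
        assert g.motif_index["TTAA"]["chr1"].tolist() == list(range(0, 40, 4))

    def test_motif_index_matches_naive_scan(self, small_genome):
        seq = small_genome.sequences["chr1"][:100_000]
        for motif in ("TTAA", "CATG"):
            expected = naive_motif_scan(seq, motif)
            got = [p for p in small_genome.motif_index[motif]["chr1"] if p <= 100_000 - 4]
            assert got == expected

    @pytest.mark.parametrize(
        "chroms", [((("chr1", 0),)), ((("chr1", 100), ("chr1", 200)))]
    )
    def test_invalid_specs_rejected(self, chroms):
        with pytest.raises(ValueError):
            GenomeSpec(chromosomes=chroms)

    def test_coordinate_only_genome(self):
        g = Genome.from_chrom_sizes({"c1": 100, "c2": 50})
        assert g.total_length == 150 and not g.has_sequence
        idx, pos = g.global_to_chrom(np.array([0, 99, 100, 149]))
        assert idx.tolist() == [0, 0, 1, 1] and pos.tolist() == [0, 99, 0, 49]


class TestInsertions:
    def test_conservation_and_determinism(self, two_chrom_genome):
        cohort = CohortSpec(
            n_tumors=4,
            specimens_per_tumor=2,
            background_insertions_per_specimen=25,
            cis_specs=(SpikedCIS("chr1", 150_000, 10_000, 6, tumor_multiplicity=2),),
            seed=5,
        )
        t1 = simulate_insertions(two_chrom_genome, cohort)
        t2 = simulate_insertions(two_chrom_genome, cohort)
        assert len(t1) == 4 * 2 * 25 + 6 == cohort.total_insertions
        pd.testing.assert_frame_equal(t1, t2)

    def test_spike_geometry_and_multiplicity(self, two_chrom_genome):
        cis = SpikedCIS("chr1", 100_000, 10_000, 6, tumor_multiplicity=2)
        cohort = CohortSpec(4, 2, 0, (cis,), seed=9)
        truth = simulate_insertions(two_chrom_genome, cohort)
        assert len(truth) == 6
        assert truth["pos"].between(cis.start, cis.end).all()
        assert truth["pos"].max() - truth["pos"].min() <= 10_000
        assert truth.groupby("tumor_id").size().max() <= 2

    def test_full_scale_defaults_near_45k(self):
        genome = Genome.from_chrom_sizes({f"chr{i}": 125_000_000 for i in range(1, 21)})
        cohort = CohortSpec()  # screen-scale defaults
        truth = simulate_insertions(genome, cohort)
        assert cohort.n_specimens == 168
        assert abs(len(truth) - 45_000) < 1_000

    def test_oversized_spike_rejected(self, two_chrom_genome):
        cohort = CohortSpec(2, 1, 0, (SpikedCIS("chr2", 100_000, 400_000, 3),), seed=0)
        with pytest.raises(ValueError, match="exceeds chromosome"):
            simulate_insertions(two_chrom_genome, cohort)


def _motif_free(n):
    # "AC" repeats contain neither TTAA nor CATG
    return "AC" * (n // 2)


class TestReads:
    def test_read_is_primer_plus_exact_flank(self):
        # junction at 100 on the plus strand; the only cut site 30 bp downstream
        seq = _motif_free(130) + "TTAA" + _motif_free(200)
        g = make_genome(
            GenomeSpec(chromosomes=(("chr1", len(seq)),), sequence_overrides={"chr1": seq})
        )
        truth = pd.DataFrame(
            [["s1", "chr1", 100, "+", "T01", "T01S1", "background"]],
            columns=["site_id", "chrom", "pos", "strand", "tumor_id", "specimen_id", "label"],
        )
        recs, tmap, dropped = simulate_reads(g, truth, ProtocolParams(error_rate=0.0))
        assert not dropped and len(recs) == 1
        read = str(recs[0].seq)
        flank = seq[100:134]  # junction .. TTAA inclusive
        assert read.startswith(LTR + flank)
        assert read[len(LTR) + len(flank) :].startswith(revcomp("AGGGCTCCGCTTAAGGGAC")[:20])

    def test_minus_strand_flank_reverse_complemented(self):
        seq = _motif_free(100) + "CATG" + _motif_free(130) + "TTAA" + _motif_free(100)
        g = make_genome(
            GenomeSpec(chromosomes=(("chr1", len(seq)),), sequence_overrides={"chr1": seq})
        )
        truth = pd.DataFrame(
            [["s1", "chr1", 150, "-", "T01", "T01S1", "background"]],
            columns=["site_id", "chrom", "pos", "strand", "tumor_id", "specimen_id", "label"],
        )
        recs, _, dropped = simulate_reads(g, truth, ProtocolParams(error_rate=0.0))
        assert not dropped
        # fragment runs from the CATG at 100 through the junction base at 150
        frag = seq[100:151]
        assert str(recs[0].seq).startswith(LTR + revcomp(frag))

    def test_site_without_cut_in_range_emits_nothing(self):
        seq = _motif_free(3_000)
        g = make_genome(
            GenomeSpec(chromosomes=(("chr1", len(seq)),), sequence_overrides={"chr1": seq})
        )
        truth = pd.DataFrame(
            [["s1", "chr1", 10, "+", "T01", "T01S1", "background"]],
            columns=["site_id", "chrom", "pos", "strand", "tumor_id", "specimen_id", "label"],
        )
        recs, _, dropped = simulate_reads(g, truth, max_flank=2_000)
        assert recs == [] and dropped == [("s1", "no_restriction_site")]

    def test_ecorv_containing_fragment_excluded(self):
        seq = _motif_free(100) + "GATATC" + _motif_free(24) + "TTAA" + _motif_free(100)
        g = make_genome(
            GenomeSpec(chromosomes=(("chr1", len(seq)),), sequence_overrides={"chr1": seq})
        )
        truth = pd.DataFrame(
            [["s1", "chr1", 90, "+", "T01", "T01S1", "background"]],
            columns=["site_id", "chrom", "pos", "strand", "tumor_id", "specimen_id", "label"],
        )
        recs, _, dropped = simulate_reads(g, truth)
        assert recs == [] and dropped == [("s1", "ecorv_cut")]

    def test_byte_identical_fastq_for_fixed_seed(self, small_genome, tmp_path):
        cohort = CohortSpec(3, 2, 20, seed=4)
        truth = simulate_insertions(small_genome, cohort)
        out = []
        for name in ("a.fastq", "b.fastq"):
            recs, _, _ = simulate_reads(small_genome, truth, ProtocolParams(), seed=99)
            from cisscout.simgen import write_fastq

            write_fastq(recs, tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]


class TestGenes:
    def test_models_valid_and_gff3_round_trips(self, two_chrom_genome, tmp_path):
        genes = simulate_genes(two_chrom_genome, 12, seed=3)
        assert genes
        for g in genes:
            assert 0 <= g.start < g.end <= two_chrom_genome.lengths[g.chrom]
            for s, e in g.exons:
                assert g.start <= s < e <= g.end
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
        path = tmp_path / "genes.gff3"
        write_gff3(genes, path)
        from cisscout.annotate import load_gff3

        assert load_gff3(path) == genes


class TestClinical:
    def test_quartiles_of_776_patients_have_194_each(self):
        from cisscout.filters import quartile_split

        expr, _, _ = simulate_clinical(ClinicalSimSpec(n_patients=776, genes=("G1",), seed=0))
        top, bottom = quartile_split(expr, "G1")
        assert len(top) == len(bottom) == 194

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            ClinicalSimSpec(n_patients=7)

    def test_hazard_association_direction(self):
        from cisscout.filters import logrank_hr, quartile_split

        spec = ClinicalSimSpec(
            n_patients=400, genes=("G1",), hazard_ratio_per_gene={"G1": 4.0}, seed=2
        )
        expr, surv, _ = simulate_clinical(spec)
        top, bottom = quartile_split(expr, "G1")
        res = logrank_hr(top, bottom, surv)
        assert res.hazard_ratio > 1.5 and res.pvalue < 0.01

    def test_dependency_scores_centered_on_config(self):
        spec = ClinicalSimSpec(
            n_patients=50,
            genes=("ESS", "NEU"),
            dependency_score_per_gene={"ESS": -1.0},
            seed=8,
            n_cell_lines=40,
        )
        _, _, dep = simulate_clinical(spec)
        assert dep.loc["ESS"].median() < -0.7
        assert abs(dep.loc["NEU"].median()) < 0.3
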