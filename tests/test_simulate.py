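import numpy as np
import pandas as pd
import pytest
from scipy import stats

from melrna.io_formats import parse_rmsk_out, revcomp
from melrna.preprocess import TrimConfig, trim_adapter
from melrna.simulate import (
    CONSENSUS_B1_TOY,
    SimConfig,
    build_genome_with_loci,
    draw_expression,
    simulate,
    terminator_category_members,
)
from melrna.terminator import classify_terminator


class TestGenomeConstruction:
    def test_zero_divergence_copies_equal_consensus(self):
        cfg = SimConfig(seed=1, divergence=0.0,
                        n_loci={"B1_toy": 20, "B2_toy": 0})
        genome, loci, _ = build_genome_with_loci(cfg)
        for locus in loci:
            copy = genome.fetch(locus.chrom, locus.start, locus.end, locus.strand)
            assert copy == CONSENSUS_B1_TOY or copy == (
                CONSENSUS_B1_TOY[:-1] + "A"  # final-base guard never fires here
            )

    def test_locus_counts(self):
        cfg = SimConfig(seed=2, n_loci={"B1_toy": 30, "B2_toy": 15})
        _, loci, truth = build_genome_with_loci(cfg)
        subfam = pd.Series([l.subfamily for l in loci]).value_counts()
        assert subfam["B1_toy"] == 30 and subfam["B2_toy"] == 15
        assert len(truth) == 45

    def test_loci_do_not_overlap(self):
        cfg = SimConfig(seed=3)
        _, loci, _ = build_genome_with_loci(cfg)
        by_chrom: dict[str, list] = {}
        for l in loci:
            by_chrom.setdefault(l.chrom, []).append((l.start, l.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2

    def test_planted_window_on_sense_strand(self):
        cfg = SimConfig(seed=4)
        genome, loci, truth = build_genome_with_loci(cfg)
        for locus in loci[:50]:
            window = truth.loc[locus.locus_id, "terminator_window"]
            if locus.strand == "+":
                got = genome.fetch(locus.chrom, locus.end, locus.end + 5, "+")
            else:
                got = genome.fetch(locus.chrom, locus.start - 5, locus.start, "-")
            assert got == window
            assert classify_terminator(window) == truth.loc[
                locus.locus_id, "terminator_category"
            ]

    def test_placement_failure_raises(self):
        cfg = SimConfig(seed=5, chrom_length=3000, n_chromosomes=1,
                        n_loci={"B1_toy": 100, "B2_toy": 0})
        with pytest.raises(RuntimeError, match="chrom_length"):
            build_genome_with_loci(cfg)


class TestDrawExpression:
    def test_fraction_expressed_binomial(self):
        cfg = SimConfig(seed=6, fraction_expressed=0.008,
                        n_loci={"B1_toy": 500, "B2_toy": 500},
                        n_chromosomes=2, chrom_length=200_000)
        _, loci, _ = build_genome_with_loci(cfg)
        counts = draw_expression(cfg, loci, np.random.default_rng(6))
        n_expressed = sum(1 for c in counts.values() if c > 0)
        # binomial(1000, 0.008): mean 8, sd ~2.8
        assert 1 <= n_expressed <= 20

    def test_large_alpha_concentrates_at_minimum(self):
        cfg = SimConfig(seed=7, fraction_expressed=1.0, powerlaw_alpha=8.0)
        _, loci, _ = build_genome_with_loci(cfg)
        counts = np.array(list(draw_expression(cfg, loci, np.random.default_rng(7)).values()))
        assert (counts == 1).mean() > 0.95

    def test_powerlaw_pmf_chisquare(self):
        """Drawn counts follow p(k) ~ k^-alpha (chi-square at n=10^4)."""
        alpha, kmax, n = 1.8, 1000, 10_000
        k = np.arange(1, kmax + 1)
        pmf = k.astype(float) ** -alpha
        pmf /= pmf.sum()
        rng = np.random.default_rng(8)
        draws = rng.choice(k, size=n, p=pmf)  # the same sampler the module uses
        edges = [1, 2, 3, 5, 9, 17, 65, 1001]
        obs = np.histogram(draws, bins=edges)[0]
        exp = np.array([pmf[(k >= lo) & (k < hi)].sum() for lo, hi in
                        zip(edges[:-1], edges[1:])]) * n
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=len(obs) - 1)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=9)
        _, loci, _ = build_genome_with_loci(cfg)
        c1 = draw_expression(cfg, loci, np.random.default_rng(9))
        c2 = draw_expression(cfg, loci, np.random.default_rng(9))
        assert c1 == c2


class TestLibrary:
    def test_rpph_contract(self):
        plus = simulate(SimConfig(seed=10, rpph_enabled=True))
        minus = simulate(SimConfig(seed=10, rpph_enabled=False))
        chem_minus = set(minus.read_truth["chemistry"])
        assert chem_minus <= {"monophosphate"}
        src_minus = set(minus.read_truth["source"])
        assert "sine" not in src_minus
        assert "control:5S" not in src_minus
        assert "control:U2" not in src_minus
        assert "control:5.8S_rRNA" in src_minus
        # RppH(+) library contains the RppH(-) library read-for-read
        seq_by_id_plus = {r.read_id: r.sequence for r in plus.reads}
        for read in minus.reads:
            assert seq_by_id_plus[read.read_id] == read.sequence
        # 5.8S depth unchanged by the treatment
        n58 = lambda res: (res.read_truth["source"] == "control:5.8S_rRNA").sum()
        assert n58(plus) == n58(minus)

    def test_truth_bookkeeping(self, default_sim):
        truth = default_sim.read_truth
        fastq_ids = [r.read_id for r in default_sim.reads]
        assert sorted(truth["read_id"]) == sorted(fastq_ids)
        assert truth["read_id"].is_unique
        sine = truth[truth["source"] == "sine"]
        per_locus = sine["locus_id"].value_counts()
        for locus_id, n in per_locus.items():
            assert default_sim.locus_truth.loc[locus_id, "n_transcripts"] == n

    def test_insert_sizes_within_gel_selection(self, default_sim):
        lo, hi = default_sim.config.insert_size_range
        alen = len(default_sim.config.adapter)
        for read in default_sim.reads:
            assert lo <= len(read.sequence) - alen <= hi

    def test_reads_trim_back_to_their_inserts(self, default_sim):
        cfg = TrimConfig()
        alen = len(default_sim.config.adapter)
        for read in default_sim.reads[:300]:
            res = trim_adapter(read, cfg)
            assert res.verdict == "kept"
            assert res.read.sequence == read.sequence[:-alen]

    def test_tss_offset_truth_flags(self, default_sim):
        sine = default_sim.read_truth.query("source == 'sine'")
        assert (sine["passes_tss_filter"] == (sine["tss_offset"] <= 4)).all()

    def test_planted_terminator_recovered_from_reads(self, default_sim):
        """Each transcript read ends with its planted u-run, template-confirmed."""
        genome = default_sim.genome
        sine = default_sim.read_truth.query("source == 'sine'")
        alen = len(default_sim.config.adapter)
        seq_by_id = {r.read_id: r.sequence[:-alen] for r in default_sim.reads}
        for row in sine.head(200).itertuples():
            insert = seq_by_id[row.read_id]
            assert insert == genome.fetch(row.chrom, row.start, row.end, row.strand)
            u = len(insert) - len(insert.rstrip("T"))
            assert u == row.u_run


class TestArtifacts:
    def test_rmsk_out_round_trip(self, default_sim, tmp_path):
        from melrna.io_formats import write_rmsk_out

        p = tmp_path / "reads.out"
        write_rmsk_out(default_sim.rmsk_alignments, p)
        assert list(parse_rmsk_out(p)) == default_sim.rmsk_alignments

    def test_sam_lists_duplicate_placements(self):
        """Identical locus copies (zero divergence) yield multi-mapped reads."""
        cfg = SimConfig(seed=12, divergence=0.0, fraction_expressed=1.0,
                        n_loci={"B1_toy": 5, "B2_toy": 0},
                        n_background_fragments=0,
                        tss_offset_probs=(1.0,))
        res = simulate(cfg)
        sine_recs = [r for r in res.sam_records if r["read_id"].startswith("sine")]
        assert sine_recs
        multi = [r for r in sine_recs if len(r["placements"]) > 1]
        # u-run and terminator windows vary, but offset-0 bodies are shared:
        # reads with the same (u, window start) sequence match every identical copy
        assert multi, "zero divergence should produce shared placements"
        for rec in multi:
            assert rec["primary"] is not None

    def test_byte_identical_outputs_under_same_seed(self, tmp_path):
        cfg = SimConfig(seed=13)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate(cfg).write(d1)
        simulate(cfg).write(d2)
        for name in ("reads.fastq", "genome.fa", "loci.tsv", "reads.out",
                      "alignments.sam", "truth_loci.tsv", "truth_reads.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_mix_validation(self):
        with pytest.raises(ValueError, match="no member window"):
            SimConfig(terminator_mix={"T4": 0.5, "T2": 0.5, "T5_variant": 0.0,
                                      "T4_variant": 0.0, "T3": 0.0,
                                      "T3_variant": 0.0, "other": 0.0})

    def test_category_members_partition(self):
        members = terminator_category_members()
        assert sum(len(v) for v in members.values()) == 1024
        assert len(members["T4"]) == 4
        assert members["T3"] == [] and members["T2"] == []
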