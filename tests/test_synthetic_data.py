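"""Synthetic-data generator: determinism, planted-marker bookkeeping, distributions."""

import io
import math

import numpy as np
import pytest

from estmine import find_ssrs, qc_filter
from estmine.read_qc import write_fastq
from estmine.ssr_markers import revcomp
from estmine import synthetic_data as synth


def cfg(**kw):
    base = dict(n_genes=20, n_reads=500, seed=1)
    base.update(kw)
    return synth.SimulationConfig(**base)


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            cfg(snp_rate=1.5)

    def test_fraction_sum_rejected(self):
        with pytest.raises(ValueError):
            cfg(retro_fraction=0.6, contaminant_fraction=0.5)

    def test_nonpositive_distribution_rejected(self):
        with pytest.raises(ValueError):
            cfg(read_length_distribution=(306, -1))

    def test_alt_freq_bounds(self):
        with pytest.raises(ValueError):
            cfg(snp_alt_freq_choices=(0.0,))
        with pytest.raises(ValueError):
            cfg(snp_alt_freq_choices=(1.0,))

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("n_genes: 7\nn_reads: 11\nquality_model: [22, 4]\nseed: 3\n")
        c = synth.SimulationConfig.from_yaml(path)
        assert (c.n_genes, c.n_reads, c.quality_model, c.seed) == (7, 11, (22, 4), 3)


class TestTranscriptome:
    def test_zero_fractions_all_genes(self):
        transcripts, _ = synth.generate_transcriptome(
            cfg(n_genes=10, retro_fraction=0, contaminant_fraction=0)
        )
        assert len(transcripts) == 10
        assert all(t.origin == "gene" for t in transcripts)

    def test_exact_retro_proportion(self):
        transcripts, _ = synth.generate_transcriptome(
            cfg(n_genes=100, retro_fraction=0.1, contaminant_fraction=0, seed=7)
        )
        assert sum(t.origin == "retroelement" for t in transcripts) == 10
        assert len(transcripts) == 100

    def test_determinism_byte_identical_fasta(self):
        outs = []
        for _ in range(2):
            result = synth.simulate(cfg(seed=5))
            buf = io.StringIO()
            synth.write_transcripts_fasta(result.transcripts, buf)
            fq = io.StringIO()
            write_fastq(result.reads, fq)
            outs.append(buf.getvalue() + fq.getvalue())
        assert outs[0] == outs[1]

    def test_cds_within_bounds(self):
        transcripts, _ = synth.generate_transcriptome(cfg(n_genes=50, seed=2))
        for t in transcripts:
            s, e = t.cds_interval
            assert 0 <= s <= e <= len(t)
            assert set(t.sequence) <= set("ACGT")


class TestPlantSSRs:
    def test_bookkeeping(self):
        t = synth.Transcript("t1", "G" * 300, (0, 300), "gene")
        planted, locus = synth.plant_ssr(t, "AT", 6, 100)
        assert (locus.start, locus.end, locus.motif, locus.unit_size, locus.n_units) == (
            100, 112, "AT", 2, 6)
        assert planted.sequence[100:112] == "AT" * 6
        assert len(planted) == len(t)

    def test_bad_motif_rejected(self):
        t = synth.Transcript("t1", "G" * 100, (0, 99), "gene")
        with pytest.raises(ValueError):
            synth.plant_ssr(t, "AX", 6, 10)

    def test_long_run_case_discarded_by_qc(self, rng):
        # a 52-bp planted run makes any read fully containing it a QC discard
        t = synth.Transcript("t1", "".join(
            np.random.default_rng(0).choice(list("ACGT"), 400)), (0, 399), "gene")
        planted, locus = synth.plant_ssr(t, "AT", 26, 150)
        assert locus.end - locus.start == 52
        from estmine.read_qc import Read
        read = Read("r", planted.sequence[100:300], [30] * 200)
        kept, discarded, _ = qc_filter([read])
        assert not kept and discarded[0][1] == "long_ssr"

    def test_thousand_random_plants_recovered_exactly(self):
        r = np.random.default_rng(11)
        recovered = 0
        total = 0
        for i in range(1000):
            seq = "".join(r.choice(list("ACGT"), 300))
            t = synth.Transcript(f"t{i}", seq, (0, 300), "gene")
            u = int(r.choice([2, 3, 4]))
            motif = synth._random_primitive_motif(r, u)
            count = int(r.integers(4, 13))
            pos = int(r.integers(1, 300 - u * count - 1))
            planted, locus = synth.plant_ssr(t, motif, count, pos)
            total += 1
            hits = [
                l for l in find_ssrs(planted.sequence, seq_id=t.id)
                if (l.start, l.end, l.motif, l.unit_size, l.n_units)
                == (locus.start, locus.end, locus.motif, locus.unit_size, locus.n_units)
            ]
            recovered += bool(hits)
        assert recovered == total  # 100% recall with exact coordinates


class TestPlantVariants:
    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            cfg(snp_alt_freq_choices=(0.5, 0.0))

    def test_error_free_contract_no_third_allele(self):
        c = cfg(n_genes=5, n_reads=4000, base_error_rate=0.0,
                retro_fraction=0, contaminant_fraction=0, snp_rate=0.002, seed=9)
        result = synth.simulate(c)
        sites = {(tid, pos): (ref, alt)
                 for tid, pos, ref, alt, _ in result.truth.planted_snps}
        assert sites
        for read in result.reads:
            o = result.truth.read_origins[read.id]
            seq = read.sequence if o.strand == "+" else revcomp(read.sequence)
            for i, base in enumerate(seq):
                key = (o.transcript_id, o.offset + i)
                if key in sites:
                    assert base in sites[key]

    def test_observed_alt_fraction_within_binomial_bounds(self):
        c = cfg(n_genes=1, n_reads=10_000, base_error_rate=0.0, retro_fraction=0,
                contaminant_fraction=0, snp_rate=0.0, seed=4,
                gene_length_distribution=(400.0, 1.0), min_gene_length=300)
        transcripts, _ = synth.generate_transcriptome(c)
        rng = np.random.default_rng(4)
        c2 = synth.SimulationConfig(**{**c.__dict__, "snp_rate": 0.01,
                                       "snp_alt_freq_choices": (0.5,)})
        pool, truth_snps = synth.plant_variants(transcripts, c2, rng)
        reads, truth = synth.simulate_reads(pool, c2, rng)
        tid, pos, ref, alt, freq = truth_snps[0]
        n = alt_n = 0
        for read in reads:
            o = truth.read_origins[read.id]
            if o.transcript_id != tid or not (o.offset <= pos < o.offset + len(read)):
                continue
            seq = read.sequence if o.strand == "+" else revcomp(read.sequence)
            base = seq[pos - o.offset]
            n += 1
            alt_n += base == alt
        assert n > 100
        sd = math.sqrt(0.5 * 0.5 / n)
        assert abs(alt_n / n - 0.5) <= 3 * sd

    def test_design_frequencies_recorded_and_valid(self, clean_sim):
        for tid, pos, ref, alt, freq in clean_sim.truth.planted_snps:
            assert 0 < freq < 1
            assert ref != alt
            t = {t.id: t for t in clean_sim.transcripts}[tid]
            assert t.sequence[pos] == ref


class TestSimulateReads:
    def test_read_count_and_origin_conservation(self, clean_sim):
        assert len(clean_sim.reads) == clean_sim.config.n_reads
        assert len(clean_sim.truth.read_origins) == len(clean_sim.reads)

    def test_length_distribution_clt_bound(self):
        c = cfg(n_genes=10, n_reads=1000, seed=3,
                gene_length_distribution=(3000.0, 100.0),
                read_length_distribution=(306.0, 60.0))
        result = synth.simulate(c)
        lengths = [len(r) for r in result.reads]
        assert abs(np.mean(lengths) - 306) <= 3 * 60 / math.sqrt(1000)

    def test_error_free_reads_are_exact_haplotype_substrings(self, clean_sim):
        haps = clean_sim.pool.haplotypes
        for read in clean_sim.reads[:300]:
            o = clean_sim.truth.read_origins[read.id]
            seq = read.sequence if o.strand == "+" else revcomp(read.sequence)
            assert any(
                h[o.offset : o.offset + len(seq)] == seq
                for h in haps[o.transcript_id]
            )

    def test_quality_filter_fraction_matches_model(self):
        # with per-base quality ~ N(17, 6), the fraction of reads with mean
        # quality < 18 should match a direct simulation of the quality model
        c = cfg(n_genes=10, n_reads=2000, quality_model=(17.0, 6.0), seed=8)
        result = synth.simulate(c)
        _, discarded, report = qc_filter(result.reads, min_mean_q=18.0,
                                         max_ssr_run_bp=10**9)
        frac = report.n_discarded_quality / report.n_input
        r = np.random.default_rng(123)
        sims = []
        lengths = [len(x) for x in result.reads]
        for _ in range(30):
            means = np.array([
                np.clip(np.rint(r.normal(17.0, 6.0, n)), 2, 40).mean()
                for n in lengths
            ])
            sims.append(np.mean(means < 18.0))
        mu, sd = float(np.mean(sims)), float(np.std(sims)) + 1e-9
        assert abs(frac - mu) <= 5 * max(sd, math.sqrt(mu * (1 - mu) / len(lengths)))

    def test_retro_read_ids_match_transcript_origin(self, clean_sim):
        retro_tx = {t.id for t in clean_sim.transcripts if t.origin == "retroelement"}
        for rid, o in clean_sim.truth.read_origins.items():
            assert (rid in clean_sim.truth.retro_read_ids) == (
                o.transcript_id in retro_tx)


class TestFabricatedTables:
    def test_coverage_ratio_arithmetic(self):
        from estmine.annotate_summarize import ortholog_coverage
        import pandas as pd
        row = {
            "qseqid": "t1", "sseqid": "P1", "pident": 90.0, "length": 450,
            "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": 900,
            "sstart": 1, "send": 450, "evalue": 1e-30, "bitscore": 300.0,
            "slen": 900, "staxon": "Other plant", "stitle": "x",
        }
        best = pd.DataFrame([row])
        ratios, per_subject = ortholog_coverage(best, {"t1": 900}, divide_by_three=False)
        assert per_subject.iloc[0]["coverage"] == 0.5
        assert ratios.iloc[0]["ratio"] == 1.0

    def test_retro_descriptions_classified_retro(self, clean_sim):
        from estmine.retro_screen import keyword_classify
        retro_tx = {t.id for t in clean_sim.transcripts if t.origin == "retroelement"}
        table = clean_sim.annotation
        retro_rows = table[table["qseqid"].isin(retro_tx)]
        if len(retro_rows):
            frac = np.mean([
                keyword_classify(d) == "retro" for d in retro_rows["stitle"]
            ])
            assert frac >= 0.5  # keyword probability is 0.9 by default

    def test_empty_table_zero_unique_accessions(self):
        from estmine.annotate_summarize import best_hits, unique_accession_count
        import pandas as pd
        from estmine.annotate_summarize import HIT_TABLE_COLUMNS_EXTENDED
        empty = pd.DataFrame(columns=HIT_TABLE_COLUMNS_EXTENDED)
        empty["evalue"] = empty["evalue"].astype(float)
        assert unique_accession_count(best_hits(empty)) == 0

    def test_truth_tables_written(self, tmp_path, clean_sim):
        synth.write_truth_tables(clean_sim.truth, str(tmp_path / "truth"))
        import pandas as pd
        origins = pd.read_csv(tmp_path / "truth.read_origins.tsv", sep="\t")
        assert len(origins) == len(clean_sim.reads)
        snps = pd.read_csv(tmp_path / "truth.planted_snps.tsv", sep="\t")
        assert len(snps) == len(clean_sim.truth.planted_snps)
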