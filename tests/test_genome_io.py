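"""Genome reading, DGR extraction geometry, strand and wrap handling."""

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from baculopolya.genome_io import (DGR, GeneAnnotation, GenomeRecord, extract_dgr,
                                   load_core_names, read_dgr_fasta, read_genome,
                                   revcomp, select_core, write_dgr_fasta,
                                   write_fasta_gff, write_genbank)


def _genome(seq, genes, circular=True, gid="G1"):
    return GenomeRecord(gid, seq, circular, genes)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestExtractDgr:
    def test_plus_strand_linear(self, rng):
        seq = _random_seq(rng, 2000)
        g = GeneAnnotation("g1", "g1", 0, 1000, "+")
        d = extract_dgr(_genome(seq, [g], circular=False), g)
        assert (d.source_interval, len(d.sequence)) == ((900, 1350), 450)
        assert d.sequence == seq[900:1350] and not d.truncated

    def test_minus_strand_is_revcomp(self, rng):
        seq = _random_seq(rng, 2000)
        g = GeneAnnotation("g1", "g1", 1000, 2000, "-")
        d = extract_dgr(_genome(seq, [g], circular=False), g)
        assert d.sequence == revcomp(seq[650:1100]) and len(d.sequence) == 450

    def test_circular_wrap(self, rng):
        seq = _random_seq(rng, 1000)
        g = GeneAnnotation("g1", "g1", 0, 995, "+")
        d = extract_dgr(_genome(seq, [g]), g)
        assert d.sequence == seq[895:1000] + seq[0:345]
        assert len(d.sequence) == 450 and not d.truncated

    def test_linear_truncation_flagged(self, rng):
        seq = _random_seq(rng, 1100)
        g = GeneAnnotation("g1", "g1", 0, 1000, "+")
        d = extract_dgr(_genome(seq, [g], circular=False), g)
        assert d.trunc_downstream and len(d.sequence) == 200

    def test_short_gene_upstream_truncated(self, rng):
        seq = _random_seq(rng, 2000)
        g = GeneAnnotation("g1", "g1", 0, 60, "+")
        d = extract_dgr(_genome(seq, [g], circular=False), g)
        assert d.trunc_upstream and d.up_len == 60 and len(d.sequence) == 410

    def test_foreign_gene_rejected(self, rng):
        seq = _random_seq(rng, 2000)
        g = GeneAnnotation("g1", "g1", 0, 1000, "+")
        other = GeneAnnotation("gX", "gX", 0, 900, "+")
        with pytest.raises(ValueError, match="belong"):
            extract_dgr(_genome(seq, [g], circular=False), other)

    def test_strand_involution(self, rng):
        """Minus-strand extraction equals plus-strand extraction on the
        reverse-complemented genome with flipped annotations."""
        for _ in range(10):
            L = 3000
            seq = _random_seq(rng, L)
            s, e = 1200, 2100
            g = GeneAnnotation("g1", "g1", s, e, "-")
            d = extract_dgr(_genome(seq, [g]), g)
            g2 = GeneAnnotation("g1", "g1", L - e, L - s, "+")
            d2 = extract_dgr(_genome(revcomp(seq), [g2]), g2)
            assert d.sequence == d2.sequence

    def test_rel_to_genomic_round_trip(self, rng):
        """Each relative position maps back to the nucleotide it reports,
        across the circular origin and on both strands."""
        L = 1000
        seq = _random_seq(rng, L)
        from baculopolya.coords import rel_to_idx

        for strand, interval in [("+", (300, 995)), ("-", (5, 700)),
                                 ("+", (100, 800))]:
            g = GeneAnnotation("g", "g", *interval, strand)
            d = extract_dgr(_genome(seq, [g]), g)
            for rel in (-100, -3, -1, 1, 50, 350):
                gpos = d.rel_to_genomic(rel, L)
                base = seq[gpos]
                got = d.sequence[rel_to_idx(rel)]
                assert got == (base if strand == "+" else revcomp(base))


class TestGenomeFiles:
    def _record(self, rng, circular=True):
        seq = _random_seq(rng, 1500)
        genes = [GeneAnnotation("g000", "polh", 100, 700, "+"),
                 GeneAnnotation("g001", "orf1", 900, 1400, "-")]
        return _genome(seq, genes, circular=circular)

    def test_genbank_round_trip(self, rng, tmp_path):
        rec = self._record(rng)
        write_genbank(rec, tmp_path / "g.gb")
        back = read_genome(tmp_path / "g.gb", "genbank")
        assert back.circular and back.sequence == rec.sequence
        assert [(g.gene_id, g.start, g.end, g.strand) for g in back.genes] == \
               [(g.gene_id, g.start, g.end, g.strand) for g in rec.genes]

    def test_fasta_gff3_round_trip(self, rng, tmp_path):
        rec = self._record(rng)
        write_fasta_gff(rec, tmp_path / "g.fasta", tmp_path / "g.gff3")
        back = read_genome(tmp_path / "g.fasta", "fasta+gff3", gff=tmp_path / "g.gff3")
        assert back.circular and back.sequence == rec.sequence
        assert [(g.start, g.end, g.strand) for g in back.genes] == \
               [(g.start, g.end, g.strand) for g in rec.genes]

    def test_missing_topology_defaults_linear(self, rng, tmp_path, caplog):
        sr = SeqRecord(Seq(_random_seq(rng, 60)), id="T1", name="T1")
        sr.annotations["molecule_type"] = "DNA"
        sr.features.append(SeqFeature(FeatureLocation(0, 30, strand=1),
                                      type="gene", qualifiers={"gene": ["x"]}))
        SeqIO.write([sr], str(tmp_path / "t.gb"), "genbank")
        with caplog.at_level("WARNING"):
            back = read_genome(tmp_path / "t.gb")
        assert not back.circular
        assert any("topology" in r.message for r in caplog.records)

    def test_joined_location_rejected(self, rng, tmp_path):
        sr = SeqRecord(Seq(_random_seq(rng, 100)), id="T1", name="T1")
        sr.annotations["molecule_type"] = "DNA"
        loc = CompoundLocation([FeatureLocation(0, 30, strand=1),
                                FeatureLocation(50, 80, strand=1)])
        sr.features.append(SeqFeature(loc, type="gene", qualifiers={"gene": ["x"]}))
        SeqIO.write([sr], str(tmp_path / "t.gb"), "genbank")
        with pytest.raises(ValueError, match="join"):
            read_genome(tmp_path / "t.gb")

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_genome(tmp_path / "x", "bam")

    def test_dgr_fasta_round_trip(self, rng, tmp_path):
        dgrs = [DGR("G1", "g000", _random_seq(rng, 450), "+", (0, 450), 100),
                DGR("G1", "g001", _random_seq(rng, 450), "-", (0, 450), 100)]
        write_dgr_fasta(dgrs, tmp_path / "d.fasta")
        back = read_dgr_fasta(tmp_path / "d.fasta")
        assert [(d.id, d.sequence, d.strand) for d in back] == \
               [(d.id, d.sequence, d.strand) for d in dgrs]


class TestSelectCore:
    def _genes(self, names):
        return [GeneAnnotation(f"g{i}", n, i * 100, i * 100 + 50, "+")
                for i, n in enumerate(names)]

    def test_basic_match(self):
        genes = self._genes(["polh", "gp64"])
        assert [g.name for g in select_core(genes, ["polh"])] == ["polh"]

    def test_empty_table(self):
        genes = self._genes(["polh", "gp64"])
        assert select_core(genes, []) == []
        assert not any(g.is_core for g in genes)

    def test_case_insensitive_glob(self):
        genes = self._genes(["LEF-8", "lef-9", "odv-e18"])
        assert len(select_core(genes, ["lef-*"])) == 2

    def test_default_table_round_trip(self):
        names = load_core_names()
        genes = self._genes(names[:5])
        assert len(select_core(genes, names)) == 5


def test_gene_annotation_invariants():
    with pytest.raises(ValueError):
        GeneAnnotation("g", "g", 10, 10, "+")
    with pytest.raises(ValueError):
        GeneAnnotation("g", "g", 0, 5, "+")   # shorter than start+stop codon
    with pytest.raises(ValueError):
        GeneAnnotation("g", "g", 0, 30, "x")
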