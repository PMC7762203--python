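"""Generator correctness: composition, planted truth, determinism."""

import filecmp

import numpy as np
import pytest

from baculopolya.coords import rel_to_idx
from baculopolya.genome_io import extract_dgr, read_genome
from baculopolya.pas_model import ModelSpec, pair_distance
from baculopolya.motif_scan import MotifHit
from baculopolya.synthetic import (CassetteConfigError, SimParams,
                                   generate_background, generate_genome_set,
                                   plant_cassette)

UNIFORM = {b: 0.25 for b in "ACGT"}


class TestBackground:
    def test_empty(self, rng):
        assert generate_background(0, UNIFORM, rng) == ""

    def test_degenerate_composition(self, rng):
        assert generate_background(10, {"A": 1, "C": 0, "G": 0, "T": 0}, rng) == "A" * 10

    def test_negative_length(self, rng):
        with pytest.raises(ValueError):
            generate_background(-1, UNIFORM, rng)

    def test_law_of_large_numbers(self):
        s = generate_background(100_000, UNIFORM, np.random.default_rng(7))
        for b in "ACGT":
            assert abs(s.count(b) / 1e5 - 0.25) < 0.01

    def test_requested_composition_recovered(self):
        comp = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
        s = generate_background(100_000, comp, np.random.default_rng(8))
        for b, f in comp.items():
            assert abs(s.count(b) / 1e5 - f) < 0.01

    def test_reproducible(self):
        a = generate_background(500, UNIFORM, np.random.default_rng(1))
        b = generate_background(500, UNIFORM, np.random.default_rng(1))
        assert a == b


def _truth_hits(truth):
    return {c: MotifHit(c, truth.element_sequences[c], p,
                        len(truth.element_sequences[c]))
            for c, p in truth.element_positions.items()}


class TestPlantCassette:
    def test_truth_distances_inside_windows(self, improved):
        rng = np.random.default_rng(3)
        for _ in range(100):
            seq, truth = plant_cassette(improved, 0.8, rng)
            hits = _truth_hits(truth)
            a_lo, a_hi = improved.anchor_idx
            assert a_lo <= hits["PAS"].start_idx <= a_hi
            for w in improved.windows:
                d = pair_distance(w, hits[w.a], hits[w.b])
                assert w.lo <= d <= w.hi, (w.a, w.b, d)

    def test_motifs_verbatim_and_stop_codon(self, improved):
        rng = np.random.default_rng(4)
        for _ in range(50):
            seq, truth = plant_cassette(improved, 0.8, rng)
            for c, p in truth.element_positions.items():
                i = rel_to_idx(p)
                assert seq[i:i + len(truth.element_sequences[c])] == \
                    truth.element_sequences[c]
            assert seq[97:100] in ("TAA", "TAG", "TGA")

    def test_au_enrichment(self, improved):
        rng = np.random.default_rng(5)
        fracs = []
        for _ in range(100):
            seq, truth = plant_cassette(improved, 0.8, rng)
            c = rel_to_idx(truth.element_positions["PAS"]) + 3
            win = seq[max(0, c - 20):c + 20]
            fracs.append((win.count("A") + win.count("T")) / len(win))
        assert min(fracs) >= 0.70 and np.mean(fracs) >= 0.75

    def test_collapsed_windows_force_offsets(self):
        model = ModelSpec.from_dict({
            "name": "collapsed", "classes": ["USE", "PAS", "CS", "DSE"],
            "required": ["PAS", "CS"],
            "pas_anchor": {"min": 2, "max": 2},
            "windows": [
                {"a": "USE", "b": "PAS", "min": 10, "max": 10},
                {"a": "PAS", "b": "CS", "min": 5, "max": 5},
                {"a": "CS", "b": "DSE", "min": 8, "max": 8},
            ],
        })
        seq, truth = plant_cassette(model, 0.0, np.random.default_rng(1))
        # PAS start relative +2 (index 101); everything else chained off it
        assert truth.element_positions["PAS"] == 2
        assert truth.element_positions["USE"] == -13        # idx 101-10-4 = 87
        assert truth.element_positions["CS"] == 11          # cleavage 112, CA at 110
        assert truth.element_positions["DSE"] == 21         # idx 112+8 = 120

    def test_unplantable_anchor_raises(self):
        # a PAS forced to start at -4 always destroys the stop codon
        model = ModelSpec.from_dict({
            "name": "bad", "classes": ["USE", "PAS", "CS"],
            "required": ["PAS", "CS"],
            "pas_anchor": {"min": -4, "max": -4},
            "windows": [
                {"a": "USE", "b": "PAS", "min": 5, "max": 30},
                {"a": "PAS", "b": "CS", "min": 2, "max": 20},
            ],
        })
        with pytest.raises(CassetteConfigError):
            plant_cassette(model, 0.8, np.random.default_rng(1))

    def test_window_coverage(self, improved):
        """Uniform sampling sanity: independently drawn windows are fully
        realized over 500 cassettes (USE->PAS and PAS->DSE; the CS windows
        are jointly constrained and cover only their feasible subsets)."""
        rng = np.random.default_rng(6)
        seen = {("USE", "PAS"): set(), ("PAS", "DSE"): set()}
        for _ in range(500):
            _, truth = plant_cassette(improved, 0.8, rng)
            hits = _truth_hits(truth)
            for pair in seen:
                w = improved.window(*pair)
                seen[pair].add(pair_distance(w, hits[pair[0]], hits[pair[1]]))
        assert seen[("USE", "PAS")] == set(range(5, 31))
        assert seen[("PAS", "DSE")] == set(range(21, 30))


class TestGenomeSet:
    PARAMS = dict(n_genomes=1, genes_per_genome=5, genome_length=8000)

    def test_count_conservation(self, tmp_path):
        p = SimParams(**self.PARAMS, cassette_rate=1.0, seed=11)
        _, truth = generate_genome_set(p, tmp_path)
        assert truth[truth.planted.astype(bool)].gene_id.nunique() == 5

    def test_zero_rate_all_background(self):
        p = SimParams(**self.PARAMS, cassette_rate=0.0, seed=11)
        _, truth = generate_genome_set(p)
        assert not truth.planted.astype(bool).any()

    def test_byte_identical_determinism(self, tmp_path):
        p = SimParams(n_genomes=2, genes_per_genome=5, genome_length=8000, seed=11)
        generate_genome_set(p, tmp_path / "a")
        generate_genome_set(p, tmp_path / "b")
        for f in ["synthgenome000.gb", "synthgenome001.gb", "truth.tsv",
                  "params.json"]:
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f,
                               shallow=False), f

    def test_truth_consistency_strand_aware(self, tmp_path):
        """Every planted element re-read from the emitted file at its
        recorded coordinates equals the recorded sequence, on both strands
        and across the circular origin."""
        p = SimParams(n_genomes=3, genes_per_genome=8, genome_length=12_000,
                      frac_minus_strand=0.5, seed=21)
        _, truth = generate_genome_set(p, tmp_path)
        strands = set()
        for gid in truth.genome_id.unique():
            rec = read_genome(tmp_path / f"{gid}.gb")
            gmap = {g.gene_id: g for g in rec.genes}
            sub = truth[(truth.genome_id == gid) & truth.planted.astype(bool)]
            for _, row in sub.iterrows():
                d = extract_dgr(rec, gmap[row.gene_id])
                i = rel_to_idx(int(row.rel_pos))
                assert d.sequence[i:i + len(row.sequence)] == row.sequence
                strands.add(row.strand)
        assert strands == {"+", "-"}

    def test_fasta_gff3_output(self, tmp_path):
        p = SimParams(**self.PARAMS, seed=11)
        generate_genome_set(p, tmp_path, fmt="fasta+gff3")
        rec = read_genome(tmp_path / "synthgenome000.fasta", "fasta+gff3",
                          gff=tmp_path / "synthgenome000.gff3")
        assert rec.circular and len(rec.genes) == 5


class TestSimParams:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="cassette_rate"):
            SimParams(cassette_rate=1.5)

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="composition"):
            SimParams(background_composition={"A": 0.5, "C": 0.5, "G": 0.2, "T": 0.2})

    def test_genome_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            SimParams(n_genomes=1, genes_per_genome=100, genome_length=10_000)
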