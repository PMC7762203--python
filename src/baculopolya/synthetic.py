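"""Synthetic genomes and DGR sets with planted polyadenylation cassettes.

The generator emulates the input of the family-wide survey this package
models: circular dsDNA genomes of roughly 90-180 genes on both strands,
each gene's downstream region optionally carrying a full six-element
cassette (USE / UGUA / PAS / CS / DSE / Aux-DSE) whose inter-element
distances are drawn uniformly from a positional model's windows, with an
AU-enriched 40-nt neighbourhood around the PAS (default 80% AU).  Every
planted element is recorded in a ground-truth table so downstream stages
are testable without external downloads.

Distances are drawn independently and uniformly from their windows; where
windows are mutually constrained (the PAS->CS and CS->DSE draws must
compose into the PAS->DSE window) layouts are rejection-sampled, so the
jointly constrained windows are realized only over their feasible subsets.
Stop codons are drawn uniformly among TAA/TAG/TGA, restricted to choices
consistent with any planted motif overlapping the stop positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coords import DGR_LEN, DGR_UPSTREAM, idx_to_rel
from .genome_io import (GeneAnnotation, GenomeRecord, load_core_names, revcomp,
                        write_fasta_gff, write_genbank)
from .pas_model import ModelSpec

#: genome-wide background: ~60% AU, echoing the AU richness of these genomes
DEFAULT_BACKGROUND = {"A": 0.30, "C": 0.20, "G": 0.20, "T": 0.30}

#: PAS motif frequencies: canonical hexamer vs. the lepidopteran alternative
DEFAULT_PAS_PROBS = {"AATAAA": 0.80, "ATTAAA": 0.20}

STOPS = ("TAA", "TAG", "TGA")
_STOP_LO, _STOP_HI = DGR_UPSTREAM - 3, DGR_UPSTREAM  # indices 97..99

GENE_CODON_RANGE = (100, 300)  # gene lengths 300-900 nt


class CassetteConfigError(ValueError):
    """Unsatisfiable planting configuration."""


@dataclass
class TruthRecord:
    genome_id: str
    gene_id: str
    strand: str
    planted: bool
    element_positions: dict[str, int] = field(default_factory=dict)  # rel coords
    element_sequences: dict[str, str] = field(default_factory=dict)


@dataclass
class SimParams:
    n_genomes: int = 10
    genes_per_genome: int = 60
    genome_length: int = 88_000
    frac_minus_strand: float = 0.5
    au_frac_cassette: float = 0.80
    background_composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND))
    model: ModelSpec | None = None
    cassette_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.model is None:
            self.model = ModelSpec.preset("improved2020")
        for name in ("frac_minus_strand", "au_frac_cassette", "cassette_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        tot = sum(self.background_composition.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"background composition sums to {tot}, not 1")
        # every gene block needs its body plus a free 450-nt DGR and spacing
        need = self.genes_per_genome * (3 * GENE_CODON_RANGE[1] + 470)
        if self.genome_length < need:
            raise ValueError(
                f"genome_length {self.genome_length} too small for "
                f"{self.genes_per_genome} genes (need >= {need})")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("n_genomes", "genes_per_genome", "genome_length",
              "frac_minus_strand", "au_frac_cassette", "cassette_rate", "seed")}
        d["background_composition"] = dict(self.background_composition)
        d["model"] = self.model.name
        return d


def generate_background(length: int, composition: dict[str, float] | None,
                        rng: np.random.Generator) -> str:
    """Random nucleotide string with the requested base frequencies."""
    if length < 0:
        raise ValueError(f"negative length {length}")
    if length == 0:
        return ""
    comp = composition or {b: 0.25 for b in "ACGT"}
    bases = sorted(comp)
    p = np.asarray([comp[b] for b in bases], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(list(bases), size=length, p=p))


def _draw(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _choose_stop(fixed: dict[int, str], rng: np.random.Generator) -> str | None:
    """A stop codon consistent with motif-fixed characters at indices 97-99."""
    ok = [s for s in STOPS
          if all(fixed.get(_STOP_LO + p, s[p]) == s[p] for p in range(3))]
    if not ok:
        return None
    return ok[_draw(rng, 0, len(ok) - 1)]


def _gc_stem(rng: np.random.Generator, length: int) -> str:
    return "".join("CG"[_draw(rng, 0, 1)] for _ in range(length))


def _aux_motif(rng: np.random.Generator, length: int = 6, min_g: int = 4) -> str:
    n_g = _draw(rng, min_g, length)
    pos = rng.permutation(length)[:n_g]
    chars = ["A" if _draw(rng, 0, 1) else "T" for _ in range(length)]
    for p in pos:
        chars[p] = "G"
    return "".join(chars)


def _layout_cassette(model: ModelSpec, rng: np.random.Generator,
                     pas_probs: dict[str, float]) -> dict[str, tuple[int, str]] | None:
    """One attempted cassette layout: element class -> (start index, motif).

    Returns None when the draw violates a joint constraint (overlapping
    motifs, incompatible stop codon, or a composed distance outside its
    window); callers rejection-sample.
    """
    motifs = sorted(pas_probs)
    pas_motif = motifs[int(rng.choice(len(motifs),
                                      p=[pas_probs[m] for m in motifs]))]
    a_lo, a_hi = model.anchor_idx
    pas = _draw(rng, a_lo, a_hi)
    pas_end = pas + len(pas_motif)
    out = {"PAS": (pas, pas_motif)}

    use_end = None
    w = model.window("USE", "PAS")
    if w is not None:
        use_end = pas - _draw(rng, w.lo, w.hi)
        out["USE"] = (use_end - 4, "TTTT")

    w = model.window("UGUA", "PAS")
    if w is not None:
        lo = pas - w.hi if use_end is None else max(pas - w.hi, use_end)
        hi = pas - 4  # keep the motif verbatim: no overlap with the PAS
        if lo > hi:
            return None
        out["UGUA"] = (_draw(rng, lo, hi), "TGTA")

    w_pc = model.window("PAS", "CS")
    cs_point = pas_end + _draw(rng, w_pc.lo, w_pc.hi)
    out["CS"] = (cs_point - 2, "CA")

    w_pd, w_cd = model.window("PAS", "DSE"), model.window("CS", "DSE")
    dse = None
    if w_pd is not None or w_cd is not None:
        dse_motif = ("TTTTT", "GTTGT")[_draw(rng, 0, 1)]
        if w_pd is not None:
            dse = pas_end + _draw(rng, w_pd.lo, w_pd.hi)
            if w_cd is not None and not (w_cd.lo <= dse - cs_point <= w_cd.hi):
                return None
        else:
            dse = cs_point + _draw(rng, w_cd.lo, w_cd.hi)
        out["DSE"] = (dse, dse_motif)

    w = model.window("DSE", "AuxDSE")
    if w is not None and dse is not None:
        out["AuxDSE"] = (dse + 5 + _draw(rng, w.lo, w.hi), _aux_motif(rng))

    spans = sorted((s, s + len(m)) for s, m in out.values())
    if spans[0][0] < 0 or spans[-1][1] > DGR_LEN:
        return None
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            return None
    return out


def plant_cassette(model: ModelSpec, au_frac: float = 0.80,
                   rng: np.random.Generator | None = None, *,
                   composition: dict[str, float] | None = None,
                   pas_probs: dict[str, float] | None = None,
                   max_tries: int = 500) -> tuple[str, TruthRecord]:
    """A 450-nt DGR with one full cassette planted at model distances.

    Element distances are uniform over the model windows (rejection
    sampled against joint constraints); the stop codon occupies relative
    positions -3..-1; the 40-nt window centred on the PAS is AU-enriched
    to at least ``au_frac - 0.05`` by resampling its free background.
    """
    if rng is None:
        rng = np.random.default_rng()
    composition = composition or dict(DEFAULT_BACKGROUND)
    pas_probs = pas_probs or dict(DEFAULT_PAS_PROBS)

    layout = stop = None
    for _ in range(max_tries):
        cand = _layout_cassette(model, rng, pas_probs)
        if cand is None:
            continue
        fixed = {s + k: m[k] for s, m in cand.values() for k in range(len(m))}
        cand_stop = _choose_stop(fixed, rng)
        if cand_stop is None:
            continue
        layout, stop = cand, cand_stop
        break
    if layout is None:
        raise CassetteConfigError(
            f"model {model.name!r}: no consistent cassette layout found in "
            f"{max_tries} draws (check the PAS anchor against PAS->CS/DSE windows)")

    seq = list(generate_background(DGR_LEN, composition, rng))
    fixed_idx = set()
    for start, motif in layout.values():
        for k, ch in enumerate(motif):
            seq[start + k] = ch
            fixed_idx.add(start + k)
    for p in range(3):
        seq[_STOP_LO + p] = stop[p]
        fixed_idx.add(_STOP_LO + p)

    # AU enrichment of the PAS neighbourhood
    pas_start, pas_motif = layout["PAS"]
    centre = pas_start + len(pas_motif) // 2
    lo, hi = max(0, centre - 20), min(DGR_LEN, centre + 20)
    free = [i for i in range(lo, hi) if i not in fixed_idx]
    au_comp = {"A": au_frac / 2, "T": au_frac / 2,
               "C": (1 - au_frac) / 2, "G": (1 - au_frac) / 2}
    for _ in range(50):
        for i, ch in zip(free, generate_background(len(free), au_comp, rng)):
            seq[i] = ch
        win = seq[lo:hi]
        if (win.count("A") + win.count("T")) / len(win) >= au_frac - 0.05:
            break

    truth = TruthRecord(
        genome_id="", gene_id="", strand="+", planted=True,
        element_positions={c: idx_to_rel(s) for c, (s, _) in layout.items()},
        element_sequences={c: m for c, (_, m) in layout.items()},
    )
    return "".join(seq), truth


_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in STOPS]


def coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Random open reading frame: sense codons followed by a stop."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=max(n_codons - 1, 0))
    return "".join(_SENSE_CODONS[i] for i in idx) + STOPS[_draw(rng, 0, 2)]


def generate_genome_set(params: SimParams, outdir: str | Path | None = None,
                        fmt: str = "genbank"
                        ) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Annotated synthetic genomes plus a long-format ground-truth table.

    Genes are laid out sequentially with a free 450-nt downstream block
    each, alternating strand per ``frac_minus_strand``; the whole genome
    is then rotated to a random intergenic origin so some DGRs wrap the
    circular origin.  With ``outdir`` set, one GenBank (or FASTA+GFF3)
    file per genome is written along with ``truth.tsv`` and
    ``params.json``; identical params give byte-identical files.
    """
    rng = np.random.default_rng(params.seed)
    core_names = load_core_names()
    genomes: list[GenomeRecord] = []
    rows = []
    for gi in range(params.n_genomes):
        genome_id = f"synthgenome{gi:03d}"
        L = params.genome_length
        seq = list(generate_background(L, params.background_composition, rng))
        genes: list[GeneAnnotation] = []
        pos = _draw(rng, 0, 200)
        for i in range(params.genes_per_genome):
            length = 3 * _draw(rng, *GENE_CODON_RANGE)
            strand = "-" if rng.random() < params.frac_minus_strand else "+"
            name = (core_names[(i // 2) % len(core_names)]
                    if i % 2 == 0 else f"orf{i:03d}")
            gene_id = f"g{i:03d}"
            planted = rng.random() < params.cassette_rate
            body = coding_sequence(length // 3, rng)
            if planted:
                cassette, truth = plant_cassette(
                    params.model, params.au_frac_cassette, rng,
                    composition=params.background_composition)
                oriented = body[:-DGR_UPSTREAM] + cassette[:DGR_UPSTREAM]
                downstream = cassette[DGR_UPSTREAM:]
            else:
                truth = TruthRecord(genome_id, gene_id, strand, planted=False)
                oriented, downstream = body, None
            if strand == "+":
                start = pos
                seq[start : start + length] = oriented
                if downstream:
                    seq[start + length : start + length + 350] = downstream
            else:
                start = pos + 350
                seq[start : start + length] = revcomp(oriented)
                if downstream:
                    seq[pos : pos + 350] = revcomp(downstream)
            genes.append(GeneAnnotation(gene_id, name, start, start + length, strand))
            truth.genome_id, truth.gene_id, truth.strand = genome_id, gene_id, strand
            rows.append(truth)
            pos += length + 350 + _draw(rng, 10, 120)
        if pos > L:
            raise ValueError(f"{genome_id}: gene layout overruns genome length")
        # rotate to a random intergenic origin (keeps every gene contiguous)
        for _ in range(1000):
            r = _draw(rng, 0, L - 1)
            if all(not (g.start <= r < g.end) for g in genes):
                break
        seq = seq[r:] + seq[:r]
        for g in genes:
            g.start, g.end = (g.start - r) % L, (g.start - r) % L + (g.end - g.start)
        genes.sort(key=lambda g: g.start)
        genomes.append(GenomeRecord(genome_id, "".join(seq), circular=True,
                                    genes=genes))

    truth_df = _truth_table(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rec in genomes:
            if fmt == "genbank":
                write_genbank(rec, outdir / f"{rec.id}.gb")
            elif fmt == "fasta+gff3":
                write_fasta_gff(rec, outdir / f"{rec.id}.fasta",
                                outdir / f"{rec.id}.gff3")
            else:
                raise ValueError(f"unknown output format {fmt!r}")
        truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        (outdir / "params.json").write_text(
            json.dumps(params.to_dict(), indent=2, sort_keys=True) + "\n")
    return genomes, truth_df


def _truth_table(records: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in records:
        if t.planted:
            for elem in sorted(t.element_positions):
                rows.append((t.genome_id, t.gene_id, t.strand, True, elem,
                             t.element_positions[elem], t.element_sequences[elem]))
        else:
            rows.append((t.genome_id, t.gene_id, t.strand, False, ".", pd.NA, ""))
    return pd.DataFrame(rows, columns=["genome_id", "gene_id", "strand",
                                       "planted", "element", "rel_pos", "sequence"])


# ---------------------------------------------------------------------------
# control sets and designed structural fixtures


def random_dgr_set(n: int, rng: np.random.Generator,
                   composition: dict[str, float] | None = None,
                   length: int = DGR_LEN) -> list[str]:
    """Plain random sequences (uniform by default; pass a composition for
    AU-matched controls)."""
    comp = composition or {b: 0.25 for b in "ACGT"}
    return [generate_background(length, comp, rng) for _ in range(n)]


def coding_dgr_set(n: int, rng: np.random.Generator,
                   length: int = DGR_LEN) -> list[str]:
    """Coding-like controls: concatenated sense codons, no planted signals."""
    out = []
    for _ in range(n):
        s = coding_sequence(length // 3 + 2, rng)[:length]
        out.append(s)
    return out


def design_hairpin_dgr(rng: np.random.Generator, stem_len: int = 5,
                       loop: str = "AACAA") -> dict:
    """A DGR whose cassette region folds into one designed hairpin.

    A C/G stem drawn at random is planted on the PAS side, its reverse
    complement on the DSE side, separated by an A/C loop carrying the CA
    cleavage dinucleotide.  The surrounding context is all A, so no base
    outside the stems can pair and the cleavage position is guaranteed to
    sit in the terminal loop.  Returns the sequence plus the coordinates a
    structural analysis needs (fold window, cleavage index, element spans).
    """
    stem1 = _gc_stem(rng, stem_len)
    stem2 = revcomp(stem1)
    seg = stem1 + loop + stem2
    start = DGR_UPSTREAM  # relative +1
    seq = "A" * start + seg + "A" * (DGR_LEN - start - len(seg))
    flank = 3
    fold_lo, fold_hi = start - flank, start + len(seg) + flank
    cs_idx = start + stem_len + loop.index("CA") + 2  # cleavage point
    return {
        "sequence": seq,
        "fold_window": (fold_lo, fold_hi),
        "cs_idx": cs_idx,
        "pas_span": (start, start + stem_len),
        "dse_span": (start + stem_len + len(loop), start + len(seg)),
        "stem1": stem1,
        "stem2": stem2,
    }
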