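"""IUPAC motif scanning of DGRs and positional ("hot spot") statistics.

The six cis-acting element classes of the baculovirus 3'-end processing
model are searched as degenerate IUPAC patterns (T and U interchangeable;
overlapping occurrences all reported).  The auxiliary downstream element
has no literal motif in the model -- it is defined by a G-richness rule --
so its definition uses the sentinel motif ``G-RICH``.

Hits are reported in the DGR relative coordinate convention (see
:mod:`baculopolya.coords`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .coords import DGR_UPSTREAM, idx_to_rel, rel_to_idx

#: IUPAC degenerate nucleotide codes, DNA alphabet (U folded into T).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

G_RICH_SENTINEL = "G-RICH"

ELEMENT_CLASSES = ("USE", "UGUA", "PAS", "CS", "DSE", "AuxDSE", "URichTerm")


@dataclass(frozen=True)
class ElementDef:
    """One element class and the IUPAC motifs that identify it."""

    element_class: str
    motifs: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if not self.motifs:
            raise ValueError(f"{self.element_class}: empty motif list")
        for m in self.motifs:
            if m == G_RICH_SENTINEL:
                continue
            for ch in m.upper().replace("U", "T"):
                if ch not in IUPAC:
                    raise ValueError(
                        f"{self.element_class}: invalid IUPAC symbol {ch!r} in {m!r}"
                    )


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of an element motif inside a DGR.

    ``rel_start`` is the DGR relative coordinate of the first matched base.
    """

    element_class: str
    motif: str
    rel_start: int
    length: int

    @property
    def start_idx(self) -> int:
        return rel_to_idx(self.rel_start)

    @property
    def end_idx(self) -> int:
        """0-based exclusive end index."""
        return self.start_idx + self.length


@dataclass
class PositionalDistribution:
    """Histogram of hit start positions for one element class."""

    element_class: str
    histogram: dict[int, int] = field(default_factory=dict)
    n_sequences: int = 0
    hotspot: tuple[int, int] | None = None
    hotspot_q: float = 0.75

    @property
    def n_hits(self) -> int:
        return sum(self.histogram.values())


def _normalize(s: str) -> str:
    return s.upper().replace("U", "T")


def compile_iupac(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern to a lookahead regex reporting overlaps.

    The character classes never include N, so an N in the scanned sequence
    matches no pattern symbol (conservative handling of ambiguity).
    """
    norm = _normalize(pattern)
    parts = []
    for ch in norm:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern {pattern!r}")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))")


def scan_iupac(sequence: str, pattern: str) -> list[tuple[int, str]]:
    """All occurrences of an IUPAC ``pattern`` in ``sequence``.

    Returns ``(start, matched substring)`` pairs with 0-based starts in
    scan space; overlapping matches are all reported.  T and U are
    interchangeable on both sides; the matched substring is returned as it
    appears in the input sequence.
    """
    rx = compile_iupac(pattern)
    seq_norm = _normalize(sequence)
    for ch in set(seq_norm):
        if ch not in "ACGTN":
            raise ValueError(f"invalid sequence character {ch!r}")
    n = len(pattern)
    return [(m.start(), sequence[m.start() : m.start() + n])
            for m in rx.finditer(seq_norm)]


def g_rich_windows(sequence: str, window: int = 6, min_g: int = 4,
                   region: tuple[int, int] | None = None) -> list[tuple[int, str]]:
    """Windows of length ``window`` with at least ``min_g`` G.

    ``region`` restricts starts to a 0-based half-open index interval;
    by default the downstream part of the DGR (+1..+350) is searched,
    which is where the auxiliary DSE is expected.
    """
    seq = _normalize(sequence)
    lo, hi = region if region is not None else (DGR_UPSTREAM, len(seq))
    lo = max(lo, 0)
    hi = min(hi, len(seq) - window + 1)
    out = []
    for i in range(lo, hi):
        if seq[i : i + window].count("G") >= min_g:
            out.append((i, sequence[i : i + window]))
    return out


def default_element_defs(include_urich: bool = False) -> list[ElementDef]:
    """Element definitions of the baculovirus polyadenylation model."""
    defs = [
        ElementDef("USE", ("TTTT",), "U-rich upstream sequence element"),
        ElementDef("UGUA", ("TGTA",), "CFIm recognition motif"),
        ElementDef("PAS", ("AATAAA", "ATTAAA"),
                   "polyadenylation signal, canonical and lepidopteran alternative"),
        ElementDef("CS", ("CA",),
                   "cleavage-site candidate: cleavage occurs just 3' of a CA"),
        ElementDef("DSE", ("TTTTT", "GTTGT"), "CstF-bound downstream element"),
        ElementDef("AuxDSE", (G_RICH_SENTINEL,), "G-rich auxiliary downstream element"),
    ]
    if include_urich:
        defs.append(ElementDef("URichTerm", ("TTTTTT",),
                               "late-gene U-rich terminator motif"))
    return defs


def find_elements(dgr, defs: Sequence[ElementDef] | None = None, *,
                  g_window: int = 6, g_min: int = 4) -> dict[str, list[MotifHit]]:
    """Scan one DGR for every element class.

    ``dgr`` may be a :class:`~baculopolya.genome_io.DGR` or a plain string
    (assumed to start at relative position -100).  Hits are returned in DGR
    relative coordinates, all overlaps retained; deduplication is the model
    layer's job.
    """
    seq = dgr if isinstance(dgr, str) else dgr.sequence
    if defs is None:
        defs = default_element_defs()
    hits: dict[str, list[MotifHit]] = {}
    for d in defs:
        found: list[MotifHit] = []
        for motif in d.motifs:
            if motif == G_RICH_SENTINEL:
                occ = g_rich_windows(seq, window=g_window, min_g=g_min)
                found.extend(MotifHit(d.element_class, sub, idx_to_rel(i), g_window)
                             for i, sub in occ)
            else:
                for i, sub in scan_iupac(seq, motif):
                    found.append(MotifHit(d.element_class, sub, idx_to_rel(i), len(motif)))
        found.sort(key=lambda h: (h.start_idx, h.motif))
        hits[d.element_class] = found
    return hits


def positional_distribution(hits_per_dgr: Iterable[dict[str, list[MotifHit]]],
                            element_class: str, q: float = 0.75) -> PositionalDistribution:
    """Pool hits over many DGRs into a positional histogram with a hot spot.

    The hot spot is the smallest contiguous relative-coordinate window that
    contains at least a fraction ``q`` of all hits (leftmost such window on
    width ties).  With zero hits the histogram is empty and the hot spot is
    None (flagged, not an error).
    """
    dist = PositionalDistribution(element_class, hotspot_q=q)
    positions: list[int] = []
    for hits in hits_per_dgr:
        dist.n_sequences += 1
        for h in hits.get(element_class, []):
            positions.append(h.rel_start)
            dist.histogram[h.rel_start] = dist.histogram.get(h.rel_start, 0) + 1
    if not positions:
        return dist
    dist.hotspot = _min_window(sorted(positions), q)
    return dist


def _min_window(sorted_pos: list[int], q: float) -> tuple[int, int]:
    import math

    n = len(sorted_pos)
    need = max(1, math.ceil(q * n))
    best = None
    for i in range(0, n - need + 1):
        lo, hi = sorted_pos[i], sorted_pos[i + need - 1]
        if best is None or hi - lo < best[1] - best[0]:
            best = (lo, hi)
    return best
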