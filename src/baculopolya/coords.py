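"""Relative coordinate system of downstream gene regions (DGRs).

A DGR is a 450-nt window in gene orientation anchored on the stop codon:
positions -100..-1 cover the last 100 nt of the annotated gene (so -3..-1
is the stop codon) and +1..+350 the 350 nt immediately 3' of it.  There is
no position 0.  Internally sequences are indexed 0..449; these helpers
convert between the two conventions.
"""

from __future__ import annotations

DGR_UPSTREAM = 100
DGR_DOWNSTREAM = 350
DGR_LEN = DGR_UPSTREAM + DGR_DOWNSTREAM

#: 0-based index of the first base 3' of the stop codon (relative position +1)
POST_STOP_IDX = DGR_UPSTREAM
#: indices of the stop codon inside a full-length DGR (relative -3..-1)
STOP_IDX = (DGR_UPSTREAM - 3, DGR_UPSTREAM)


def rel_to_idx(rel: int, upstream: int = DGR_UPSTREAM) -> int:
    """Map a relative DGR position (no 0) to a 0-based sequence index."""
    if rel == 0:
        raise ValueError("relative DGR coordinates have no position 0")
    return rel + upstream if rel < 0 else rel + upstream - 1


def idx_to_rel(idx: int, upstream: int = DGR_UPSTREAM) -> int:
    """Map a 0-based sequence index to a relative DGR position (no 0)."""
    if idx < 0:
        raise ValueError(f"negative index {idx}")
    return idx - upstream if idx < upstream else idx - upstream + 1
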