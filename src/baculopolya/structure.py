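"""Nested secondary structure and inter-element complementarity.

Folding is by dynamic programming over the number of base pairs: among all
nested (pseudoknot-free) structures with hairpin loops of at least
``min_loop`` unpaired bases, the one maximizing the pair count is returned
with a deterministic traceback.  This is a thermodynamics-free model of
pairing potential: the quantities interpreted downstream (whether the
cleavage site sits in a loop or a stem, which elements can pair with each
other) depend only on base complementarity, not on folding energies, and
the folding engine is pluggable behind :func:`fold_max_pairing`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "T"), ("T", "G")}


def _norm(s: str) -> str:
    return s.upper().replace("U", "T")


def can_pair(x: str, y: str, allow_gu: bool = False) -> bool:
    p = (x, y)
    return p in WC_PAIRS or (allow_gu and p in GU_PAIRS)


@dataclass(frozen=True)
class Fold:
    sequence: str
    pairs: frozenset[tuple[int, int]]  # (i, j) with i < j
    dot_bracket: str
    min_loop: int = 3

    @property
    def pair_count(self) -> int:
        return len(self.pairs)

    def paired(self, i: int) -> bool:
        return any(i in p for p in self.pairs)

    def partner(self, i: int) -> int | None:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None


def pairs_to_dot_bracket(n: int, pairs) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def parse_dot_bracket(db: str) -> frozenset[tuple[int, int]]:
    """Pair set encoded by a dot-bracket string (round-trip of the writer)."""
    stack: list[int] = []
    pairs = set()
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket string")
    return frozenset(pairs)


def fold_max_pairing(sequence: str, min_loop: int = 3,
                     allow_gu: bool = False) -> Fold:
    """Nested structure maximizing the number of base pairs.

    Watson-Crick pairs only by default (``allow_gu`` adds G.U wobbles); N
    never pairs; hairpin loops keep at least ``min_loop`` unpaired bases
    (j - i > min_loop for every pair).  The traceback is deterministic:
    position i is paired with its smallest admissible partner achieving
    the optimum, otherwise left unpaired.
    """
    seq = _norm(sequence)
    n = len(seq)
    if n > 2000:
        raise ValueError("sequence longer than 2000 nt; fold a window instead")
    if n == 0:
        return Fold(sequence, frozenset(), "", min_loop)

    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            pairable[i, j] = can_pair(seq[i], seq[j], allow_gu)

    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    # dp over closed intervals [i, j]; dp[i][j] at indices i, j (j < n)

    def cell(i, j):
        return dp[i, j] if i <= j else 0

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            ks = np.nonzero(pairable[i, i : j + 1])[0]
            if ks.size:
                ks = ks + i
                inner = np.where(ks - 1 >= i + 1, dp[i + 1, np.maximum(ks - 1, 0)], 0)
                outer = np.where(ks + 1 <= j, dp[np.minimum(ks + 1, n - 1), j], 0)
                cand = 1 + inner + outer
                best = max(best, int(cand.max()))
            dp[i, j] = best

    pairs: set[tuple[int, int]] = set()

    def trace(i: int, j: int):
        # i is left unpaired whenever that is optimal; otherwise it pairs
        # with its smallest admissible partner achieving the optimum
        while i < j:
            if dp[i, j] == cell(i + 1, j):
                i += 1
                continue
            for k in range(i + min_loop + 1, j + 1):
                if pairable[i, k] and 1 + cell(i + 1, k - 1) + cell(k + 1, j) == dp[i, j]:
                    pairs.add((i, k))
                    trace(i + 1, k - 1)
                    i = k + 1
                    break
            else:  # pragma: no cover - dp table and trace disagree
                raise AssertionError("traceback failed")

    trace(0, n - 1)
    return Fold(sequence, frozenset(pairs), pairs_to_dot_bracket(n, pairs), min_loop)


# ---------------------------------------------------------------------------
# complementarity

#: element pairs examined for mutual complementarity
COMPLEMENT_PAIRS = (("USE", "PAS"), ("USE", "CS"), ("PAS", "CS"),
                    ("PAS", "DSE"), ("CS", "DSE"))


@dataclass(frozen=True)
class ComplementMatch:
    element_pair: tuple[str, str] | None
    offsets: tuple[int, int]  # start in seq_a, start in seq_b
    length: int
    wobble_used: bool = False


def find_complementarity(seq_a: str, seq_b: str, min_len: int = 4,
                         max_len: int = 6, allow_wobble: bool = False,
                         element_pair: tuple[str, str] | None = None
                         ) -> list[ComplementMatch]:
    """Maximal antiparallel complementary stretches between two sequences.

    A stretch of length L pairs ``seq_a[i+t]`` with ``seq_b[j+L-1-t]``.
    Maximal runs shorter than ``min_len`` are dropped; longer runs are
    reported once, clipped to ``max_len`` from the run start.  Output is
    ordered by (start_a, start_b).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    a, b = _norm(seq_a), _norm(seq_b)
    la, lb = len(a), len(b)

    def ok(x, y):
        return can_pair(x, y, allow_wobble)

    out = []
    # runs go along direction (+1, -1) in the (a-index, b-index) plane
    for i0 in range(la):
        for j0 in range(lb - 1, -1, -1):
            if not ok(a[i0], b[j0]):
                continue
            if i0 > 0 and j0 + 1 < lb and ok(a[i0 - 1], b[j0 + 1]):
                continue  # not a run start
            run = 1
            while i0 + run < la and j0 - run >= 0 and ok(a[i0 + run], b[j0 - run]):
                run += 1
            if run < min_len:
                continue
            length = min(run, max_len)
            start_b = j0 - length + 1
            wob = any((a[i0 + t], b[j0 - t]) in GU_PAIRS for t in range(length))
            out.append(ComplementMatch(element_pair, (i0, start_b), length, wob))
    out.sort(key=lambda m: m.offsets)
    return out


def element_complementarity(sequence: str, chosen, flank: int = 5,
                            min_len: int = 4, max_len: int = 6,
                            allow_wobble: bool = False) -> list[ComplementMatch]:
    """Complementarity between assigned cassette elements.

    ``chosen`` maps element class to a MotifHit; each element contributes
    its span widened by ``flank`` nt on both sides (the complementary
    stretches overlap the elements rather than coinciding with them).
    Offsets are returned in DGR index space.
    """
    out = []
    for ca, cb in COMPLEMENT_PAIRS:
        if ca not in chosen or cb not in chosen:
            continue
        ha, hb = chosen[ca], chosen[cb]
        alo = max(0, ha.start_idx - flank)
        ahi = min(len(sequence), ha.end_idx + flank)
        blo = max(0, hb.start_idx - flank)
        bhi = min(len(sequence), hb.end_idx + flank)
        for m in find_complementarity(sequence[alo:ahi], sequence[blo:bhi],
                                      min_len, max_len, allow_wobble, (ca, cb)):
            out.append(ComplementMatch((ca, cb),
                                       (m.offsets[0] + alo, m.offsets[1] + blo),
                                       m.length, m.wobble_used))
    return out


# ---------------------------------------------------------------------------
# cleavage-site context


@dataclass(frozen=True)
class CsContext:
    cs_position: int
    state: str  # loop | stem | unpaired_external
    structure_class: str  # e.g. "PAS-stem/CS-loop"


def classify_cs_context(fold: Fold, cs_position: int,
                        pas_span: tuple[int, int] | None = None) -> CsContext:
    """Structural context of the cleavage position within a fold.

    stem: the position is paired; loop: unpaired but enclosed by at least
    one pair; unpaired_external: unpaired and outside every pair.  The
    class label combines the modal pairing state over the PAS span with
    the CS state.
    """
    n = len(fold.sequence)
    if not 0 <= cs_position < n:
        raise ValueError(f"cs_position {cs_position} outside fold of length {n}")
    if fold.paired(cs_position):
        cs_state = "stem"
    elif any(i < cs_position < j for i, j in fold.pairs):
        cs_state = "loop"
    else:
        cs_state = "unpaired_external"
    if pas_span is None:
        label = f"CS-{cs_state}"
    else:
        lo, hi = pas_span
        idxs = [i for i in range(max(0, lo), min(n, hi))]
        n_paired = sum(fold.paired(i) for i in idxs)
        pas_state = "stem" if idxs and n_paired * 2 >= len(idxs) else "loop"
        label = f"PAS-{pas_state}/CS-{cs_state}"
    return CsContext(cs_position, cs_state, label)
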