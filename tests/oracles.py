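"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive and share no code path with the package:
per-position set membership for IUPAC scanning, explicit recursion over
all nested structures for folding, full combination enumeration for
cassette assignment, and substring comparison against the literal reverse
complement for complementarity.
"""

from __future__ import annotations

import itertools

# independent copy of the degenerate-code table
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_RC = str.maketrans("ACGT", "TGCA")


def naive_iupac_scan(sequence: str, pattern: str) -> list[int]:
    """Start positions where every pattern symbol's base set contains the
    sequence base (T folded onto U on both sides; N in sequence matches
    nothing)."""
    seq = sequence.upper().replace("U", "T")
    pat = pattern.upper().replace("U", "T")
    out = []
    for i in range(len(seq) - len(pat) + 1):
        if all(seq[i + k] in IUPAC_SETS[pat[k]] for k in range(len(pat))):
            out.append(i)
    return out


def enum_max_pairs(sequence: str, min_loop: int = 3) -> int:
    """Maximum Watson-Crick pair count over ALL nested structures,
    found by uncached recursion over every pairing decision."""
    seq = sequence.upper().replace("U", "T")

    def rec(i: int, j: int) -> int:  # closed interval [i, j]
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _WC:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1) if seq else 0


def brute_assign(hits, model):
    """Exhaustive enumeration of all class-wise hit combinations under the
    documented total order; returns the winning class->hit dict or None."""
    from baculopolya.pas_model import assignment_key, pair_distance

    a_lo, a_hi = model.anchor_idx
    options = []
    for c in model.classes:
        opts = [h for h in hits.get(c, [])]
        if c == "PAS":
            opts = [h for h in opts if a_lo <= h.start_idx <= a_hi]
        if c not in model.required:
            opts = opts + [None]
        elif not opts:
            return None
        options.append((c, opts))

    best_key, best = None, None
    for combo in itertools.product(*(o for _, o in options)):
        chosen = {c: h for (c, _), h in zip(options, combo) if h is not None}
        if not model.required <= chosen.keys():
            continue
        ok = True
        for w in model.windows:
            if w.a in chosen and w.b in chosen:
                d = pair_distance(w, chosen[w.a], chosen[w.b])
                if not w.lo <= d <= w.hi:
                    ok = False
                    break
        if not ok:
            continue
        key = assignment_key(chosen, model)
        if best_key is None or key < best_key:
            best_key, best = key, chosen
    return best


def brute_complementarity(seq_a: str, seq_b: str, min_len: int = 4,
                          max_len: int = 6) -> list[tuple[int, int, int]]:
    """Maximal antiparallel WC-complementary runs via literal reverse
    complement matching: runs are common substrings of seq_a and
    revcomp(seq_b).  Returns (start_a, start_b, clipped length) sorted."""
    a = seq_a.upper().replace("U", "T")
    rc = seq_b.upper().replace("U", "T").translate(_RC)[::-1]
    lb = len(rc)
    out = []
    for i in range(len(a)):
        for x in range(lb):
            if a[i] != rc[x]:
                continue
            if i > 0 and x > 0 and a[i - 1] == rc[x - 1]:
                continue  # not a run start
            run = 1
            while i + run < len(a) and x + run < lb and a[i + run] == rc[x + run]:
                run += 1
            if run < min_len:
                continue
            length = min(run, max_len)
            # b-position pairing a[i] is j0 = lb-1-x; match starts at j0-length+1
            out.append((i, (lb - 1 - x) - length + 1, length))
    return sorted(out)
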