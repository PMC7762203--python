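"""Positional models of the baculovirus polyadenylation cassette.

A :class:`ModelSpec` states, for an ordered pair of element classes, the
admissible signed distance between them, plus an anchor window tying the
PAS to the stop codon.  Two presets are shipped:

``initial2003``
    the gp64-derived model: PAS 0-50 nt downstream of the stop codon and
    12-42 nt upstream of the cleavage site; CS 4-40 nt upstream of the DSE;
    USE 5-30 nt upstream of the PAS.

``improved2020``
    the family-wide refinement: PAS between 12 nt upstream and 7 nt
    downstream of the stop codon, 0-75 nt upstream of the CS; USE 5-30 nt
    upstream of the PAS; DSE 21-29 nt downstream of the PAS and 0-50 nt
    downstream of the CS; UGUA immediately upstream of / overlapping the
    PAS; G-rich auxiliary DSE downstream of the DSE.

Distance conventions (documented, since the source ranges are prose):

* ``gap`` windows measure from the upstream element's last base (exclusive
  end) to the downstream element's first base, i.e. the number of
  nucleotides strictly between them; overlaps give negative gaps.
* ``start`` windows measure start-to-start (used for UGUA-PAS, where
  overlap is explicitly allowed).
* The cleavage site's reference point is the cleavage position itself,
  immediately 3' of the CA dinucleotide, on both sides of a window.
* The anchor window constrains the PAS start in relative DGR coordinates
  ("k nt downstream of the stop codon" is written +k, with 0 meaning the
  first base after the stop).

:func:`assign_cassette` finds, among all combinations of scanned hits, the
placement that maximizes (1) the number of element classes placed
consistently, then minimizes (2) the summed deviation of each satisfied
window's distance from its window center, then (3) the PAS distance to the
stop anchor, then (4) the leftmost CS — a deterministic total order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .coords import rel_to_idx
from .motif_scan import MotifHit, default_element_defs, find_elements

log = logging.getLogger(__name__)

#: nominal motif length per class, used only for load-time feasibility checks
NOMINAL_LEN = {"USE": 4, "UGUA": 4, "PAS": 6, "CS": 2, "DSE": 5, "AuxDSE": 6,
               "URichTerm": 6}

CANONICAL_ORDER = ("PAS", "CS", "DSE", "USE", "UGUA", "AuxDSE")


class ModelConfigError(ValueError):
    """Raised at load time for contradictory or malformed model windows."""


@dataclass(frozen=True)
class PairWindow:
    a: str
    b: str
    lo: int
    hi: int
    mode: str = "gap"  # "gap" | "start"

    def __post_init__(self):
        if self.lo > self.hi:
            raise ModelConfigError(f"window {self.a}->{self.b}: min {self.lo} > max {self.hi}")
        if self.mode not in ("gap", "start"):
            raise ModelConfigError(f"window {self.a}->{self.b}: unknown mode {self.mode!r}")

    @property
    def center(self) -> float:
        return (self.lo + self.hi) / 2.0


def _ref_up(cls: str, hit: MotifHit) -> int:
    """Reference point of a hit acting as the upstream partner."""
    return cleavage_point(hit) if cls == "CS" else hit.end_idx


def _ref_down(cls: str, hit: MotifHit) -> int:
    """Reference point of a hit acting as the downstream partner."""
    return cleavage_point(hit) if cls == "CS" else hit.start_idx


def cleavage_point(cs_hit: MotifHit) -> int:
    """0-based index of the cleavage position, immediately 3' of the CA."""
    return cs_hit.start_idx + 2


def pair_distance(w: PairWindow, hit_a: MotifHit, hit_b: MotifHit) -> int:
    if w.mode == "start":
        return hit_b.start_idx - hit_a.start_idx
    return _ref_down(w.b, hit_b) - _ref_up(w.a, hit_a)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    classes: tuple[str, ...]
    required: frozenset[str]
    pas_anchor: tuple[int, int]  # relative coordinates of the PAS start
    windows: tuple[PairWindow, ...]

    def __post_init__(self):
        if not self.required >= {"PAS", "CS"}:
            raise ModelConfigError("required elements must include PAS and CS")
        for c in self.required:
            if c not in self.classes:
                raise ModelConfigError(f"required class {c} not in model classes")
        lo, hi = self.pas_anchor
        if lo > hi or lo == 0 or hi == 0:
            raise ModelConfigError(f"bad PAS anchor window {self.pas_anchor}")
        self._check_feasible()

    def window(self, a: str, b: str) -> PairWindow | None:
        for w in self.windows:
            if w.a == a and w.b == b:
                return w
        return None

    @property
    def anchor_idx(self) -> tuple[int, int]:
        """PAS-start anchor window as 0-based DGR indices."""
        return rel_to_idx(self.pas_anchor[0]), rel_to_idx(self.pas_anchor[1])

    @property
    def anchor_center_idx(self) -> float:
        lo, hi = self.anchor_idx
        return (lo + hi) / 2.0

    def _check_feasible(self):
        """Difference-constraint feasibility on start positions.

        Uses nominal motif lengths; a negative cycle means the windows are
        mutually contradictory and no cassette can ever satisfy them.
        """
        nodes = list(self.classes) + ["_STOP_"]
        inf = float("inf")
        d = {u: {v: (0 if u == v else inf) for v in nodes} for u in nodes}

        def add(u, v, hi_bound):  # x_v - x_u <= hi_bound
            d[u][v] = min(d[u][v], hi_bound)

        for w in self.windows:
            off = 0
            if w.mode == "gap":
                off = (2 if w.a == "CS" else NOMINAL_LEN[w.a]) - (2 if w.b == "CS" else 0)
            add(w.a, w.b, w.hi + off)
            add(w.b, w.a, -(w.lo + off))
        a_lo, a_hi = self.anchor_idx
        add("_STOP_", "PAS", a_hi - 100)
        add("PAS", "_STOP_", -(a_lo - 100))
        for k in nodes:
            for i in nodes:
                for j in nodes:
                    if d[i][k] + d[k][j] < d[i][j]:
                        d[i][j] = d[i][k] + d[k][j]
        for u in nodes:
            if d[u][u] < 0:
                raise ModelConfigError(
                    f"model {self.name!r}: windows are mutually contradictory")

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ModelSpec":
        windows = tuple(
            PairWindow(w["a"], w["b"], int(w["min"]), int(w["max"]),
                       w.get("mode", "gap"))
            for w in cfg["windows"]
        )
        return cls(
            name=cfg["name"],
            classes=tuple(cfg["classes"]),
            required=frozenset(cfg["required"]),
            pas_anchor=(int(cfg["pas_anchor"]["min"]), int(cfg["pas_anchor"]["max"])),
            windows=windows,
        )

    @classmethod
    def preset(cls, name: str) -> "ModelSpec":
        """Load a shipped preset (``initial2003`` or ``improved2020``)."""
        ref = resources.files("baculopolya.data") / f"{name}.yaml"
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise ModelConfigError(f"unknown model preset {name!r}") from None
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class CassetteAssignment:
    dgr_id: str
    chosen: dict[str, MotifHit]
    satisfied_windows: list[tuple[str, str, int]]  # (a, b, distance)
    score: tuple[int, float]  # (n_elements, total center deviation)
    complete: bool

    @property
    def n_elements(self) -> int:
        return len(self.chosen)


@dataclass
class SetResult:
    n_sequences: int = 0
    n_complete: int = 0
    by_element_count: dict[int, int] = field(default_factory=dict)

    @property
    def detection_fraction(self) -> float:
        return self.n_complete / self.n_sequences if self.n_sequences else 0.0


@dataclass
class ValidationReport:
    model: str
    sets: dict[str, SetResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "sets": {
                name: {
                    "n_sequences": r.n_sequences,
                    "n_complete": r.n_complete,
                    "by_element_count": dict(sorted(r.by_element_count.items())),
                    "detection_fraction": r.detection_fraction,
                }
                for name, r in self.sets.items()
            },
        }


def assignment_key(chosen: Mapping[str, MotifHit], model: ModelSpec):
    """The documented total order, as a sortable key (smaller is better).

    Shared by the production search and by brute-force enumeration in the
    test-suite so both rank candidate placements identically.
    """
    dev = 0.0
    for w in model.windows:
        if w.a in chosen and w.b in chosen:
            dev += abs(pair_distance(w, chosen[w.a], chosen[w.b]) - w.center)
    pas = chosen["PAS"]
    dev += abs(pas.start_idx - model.anchor_center_idx)
    anchor_dist = abs(pas.start_idx - 99.5)
    cs_idx = chosen["CS"].start_idx
    detail = tuple((c, chosen[c].start_idx, chosen[c].motif)
                   for c in CANONICAL_ORDER if c in chosen)
    return (-len(chosen), dev, anchor_dist, cs_idx, detail)


def _window_ok(w: PairWindow, hit_a: MotifHit, hit_b: MotifHit) -> bool:
    return w.lo <= pair_distance(w, hit_a, hit_b) <= w.hi


def assign_cassette(hits: Mapping[str, Sequence[MotifHit]], model: ModelSpec,
                    dgr_id: str = "") -> CassetteAssignment | None:
    """Best consistent placement of element hits under the model windows.

    Returns None when not even the required classes (PAS and CS) can be
    placed consistently.  The search is exact: a depth-first enumeration
    over per-class candidates with window filtering against already placed
    classes, pruned only by bounds that cannot exclude the optimum under
    the documented total order.
    """
    order = [c for c in CANONICAL_ORDER if c in model.classes]
    a_lo, a_hi = model.anchor_idx
    cand: dict[str, list[MotifHit]] = {}
    for c in order:
        hs = list(hits.get(c, []))
        if c == "PAS":
            hs = [h for h in hs if a_lo <= h.start_idx <= a_hi]
        if not hs and c in model.required:
            return None
        cand[c] = hs

    rel_windows = {c: [w for w in model.windows if c in (w.a, w.b)] for c in order}
    best: list = [None]  # best key seen

    def dfs(i: int, chosen: dict[str, MotifHit], dev: float, count: int):
        if i == len(order):
            if not model.required <= chosen.keys():
                return
            key = assignment_key(chosen, model)
            if best[0] is None or key < best[0]:
                best[0] = key
                best.append(dict(chosen))
            return
        # bound: even placing every remaining class cannot beat best count
        if best[0] is not None:
            max_count = count + (len(order) - i)
            if -max_count > best[0][0]:
                return
            if -max_count == best[0][0] and dev > best[0][1]:
                return
        c = order[i]
        for h in cand[c]:
            extra = 0.0
            ok = True
            for w in rel_windows[c]:
                other = w.b if w.a == c else w.a
                if other not in chosen:
                    continue
                ha, hb = (h, chosen[other]) if w.a == c else (chosen[other], h)
                if not _window_ok(w, ha, hb):
                    ok = False
                    break
                extra += abs(pair_distance(w, ha, hb) - w.center)
            if not ok:
                continue
            if c == "PAS":
                extra += abs(h.start_idx - model.anchor_center_idx)
            chosen[c] = h
            dfs(i + 1, chosen, dev + extra, count + 1)
            del chosen[c]
        if c not in model.required:
            dfs(i + 1, chosen, dev, count)

    dfs(0, {}, 0.0, 0)
    if best[0] is None:
        return None
    chosen = best[-1]
    satisfied = [(w.a, w.b, pair_distance(w, chosen[w.a], chosen[w.b]))
                 for w in model.windows if w.a in chosen and w.b in chosen]
    dev = best[0][1]
    return CassetteAssignment(
        dgr_id=dgr_id,
        chosen=chosen,
        satisfied_windows=satisfied,
        score=(len(chosen), dev),
        complete=len(chosen) == len(model.classes),
    )


def verify_assignment(assignment: CassetteAssignment, model: ModelSpec) -> bool:
    """Independent re-check that every window the assignment spans holds."""
    ch = assignment.chosen
    a_lo, a_hi = model.anchor_idx
    if not (a_lo <= ch["PAS"].start_idx <= a_hi):
        return False
    for w in model.windows:
        if w.a in ch and w.b in ch and not _window_ok(w, ch[w.a], ch[w.b]):
            return False
    return True


def classify_sets(sets: Mapping[str, Sequence], model: ModelSpec,
                  defs=None) -> ValidationReport:
    """Complete-cassette detection fractions over labelled sequence sets.

    Each entry of ``sets`` maps a set name (e.g. dgr_core, dgr_noncore,
    random, coding) to DGRs or plain 450-nt strings.  A sequence appearing
    in several sets is counted in each (warned).
    """
    if defs is None:
        defs = default_element_defs()
    seen: dict[int, str] = {}
    report = ValidationReport(model=model.name)
    for name, seqs in sets.items():
        if not len(seqs):
            raise ValueError(f"set {name!r} is empty")
        res = SetResult()
        for s in seqs:
            seq = s if isinstance(s, str) else s.sequence
            key = hash(seq)
            if key in seen and seen[key] != name:
                warnings.warn(
                    f"sequence shared between sets {seen[key]!r} and {name!r}; "
                    "counted in each", stacklevel=2)
            seen.setdefault(key, name)
            res.n_sequences += 1
            asg = assign_cassette(find_elements(seq, defs), model)
            n = asg.n_elements if asg else 0
            res.by_element_count[n] = res.by_element_count.get(n, 0) + 1
            if asg and asg.complete:
                res.n_complete += 1
        report.sets[name] = res
    return report


def au_content(dgr, center_rel: int, halfwidth: int = 20) -> float:
    """AU fraction of the ``2*halfwidth``-nt window centred on a position.

    The window is clipped to the DGR; an empty intersection returns NaN
    (flagged via warning) rather than raising.
    """
    seq = dgr if isinstance(dgr, str) else dgr.sequence
    c = rel_to_idx(center_rel)
    lo, hi = max(0, c - halfwidth), min(len(seq), c + halfwidth)
    if lo >= hi:
        warnings.warn("AU window does not intersect the DGR", stacklevel=2)
        return float("nan")
    win = seq[lo:hi].upper().replace("U", "T")
    return (win.count("A") + win.count("T")) / (hi - lo)
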