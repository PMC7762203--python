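"""Position frequency matrices, information content, logos, run reports."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

BASES = "ACGU"
_COL = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass
class PFM:
    """Per-column base frequencies of aligned element windows.

    Columns are (A, C, G, U) probability vectors; T counts as U.  Ns are
    excluded column-wise, so different columns may rest on different
    effective counts.
    """

    element_class: str
    columns: np.ndarray  # shape (L, 4), rows sum to 1
    n_sequences: int
    anchor: str = "element start"

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.columns.argmax(axis=1))


def build_pfm(windows: list[str], element_class: str = "",
              anchor: str = "element start") -> PFM:
    """Column frequencies of equal-length aligned windows."""
    if not windows:
        raise ValueError("no windows given")
    L = len(windows[0])
    if any(len(w) != L for w in windows):
        raise ValueError("aligned windows must all have the same length")
    counts = np.zeros((L, 4), dtype=float)
    for w in windows:
        for i, ch in enumerate(w.upper()):
            if ch == "N":
                continue
            if ch not in _COL:
                raise ValueError(f"invalid character {ch!r} in window")
            counts[i, _COL[ch]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a column has no informative (non-N) bases")
    return PFM(element_class, counts / totals, len(windows), anchor)


def information_content(pfm: PFM) -> np.ndarray:
    """Per-column information in bits: 2 minus the Shannon entropy."""
    p = pfm.columns
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=1)
    return 2.0 - h


def pfm_to_meme(pfms: list[PFM], path: str | Path) -> None:
    """MEME minimal motif format export."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("strands: +\n\nBackground letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for p in pfms:
            fh.write(f"MOTIF {p.element_class}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.length} "
                     f"nsites= {p.n_sequences}\n")
            for row in p.columns:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def pfm_to_tsv(pfm: PFM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(BASES) + "\n")
        for i, row in enumerate(pfm.columns):
            fh.write(str(i) + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def plot_logo(pfm: PFM, path: str | Path, title: str | None = None) -> None:
    """Sequence logo: stacked letters scaled by frequency x information."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}
    ic = information_content(pfm)
    fig, ax = plt.subplots(figsize=(max(3, pfm.length * 0.35), 2.4))
    fp = FontProperties(family="DejaVu Sans", weight="bold")
    for x in range(pfm.length):
        heights = sorted(zip(BASES, pfm.columns[x] * ic[x]), key=lambda t: t[1])
        y = 0.0
        for base, h in heights:
            if h <= 0:
                continue
            tp = TextPath((0, 0), base, size=1, prop=fp)
            bb = tp.get_extents()
            tr = (Affine2D().translate(-bb.x0, -bb.y0)
                  .scale(0.9 / bb.width, h / bb.height).translate(x + 0.05, y))
            ax.add_patch(PathPatch(tr.transform_path(tp), fc=colors[base], ec="none"))
            y += h
    ax.set_xlim(0, pfm.length)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xticks(np.arange(pfm.length) + 0.5)
    ax.set_xticklabels(np.arange(pfm.length))
    ax.set_title(title or pfm.element_class)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


REPORT_SECTIONS = ("hits", "distributions", "cassettes", "validation", "folds",
                   "complementarity")


def emit_report(artifacts: dict, outdir: str | Path, *, seed: int | None = None,
                config: dict | None = None) -> dict:
    """Bundle run artifacts into one JSON report (+ a TSV summary).

    ``artifacts`` may contain any of the standard sections; missing ones
    are flagged explicitly rather than dropped, so a scan-only run is
    distinguishable from an empty one.  Output is deterministic for
    identical inputs (no timestamps).
    """
    import baculopolya

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "meta": {
            "package": "baculopolya",
            "version": baculopolya.__version__,
            "seed": seed,
            "config": config or {},
        },
        "sections": {},
        "missing_sections": [],
    }
    for name in REPORT_SECTIONS:
        if name in artifacts:
            report["sections"][name] = artifacts[name]
        else:
            report["missing_sections"].append(name)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    with open(outdir / "report_summary.tsv", "w") as fh:
        fh.write("section\tpresent\n")
        for name in REPORT_SECTIONS:
            fh.write(f"{name}\t{name in artifacts}\n")
    return report
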