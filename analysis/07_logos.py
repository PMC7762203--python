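#!/usr/bin/env python
"""Sequence logos of the recovered elements and the bundled run report.

Aligns each element class on its recovered start (+- 10 nt of context),
builds position frequency matrices, renders logos, exports MEME-format
motifs, and bundles the run's artifacts into results/report.json.
"""

import argparse
import json
from pathlib import Path

from baculopolya.genome_io import read_dgr_fasta
from baculopolya.motif_scan import find_elements
from baculopolya.pas_model import ModelSpec, assign_cassette
from baculopolya.reporting import (build_pfm, emit_report, information_content,
                                   pfm_to_meme, pfm_to_tsv, plot_logo)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dgr", type=Path, default=ROOT / "results" / "dgr.fasta")
    ap.add_argument("--flank", type=int, default=10)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    model = ModelSpec.preset("improved2020")
    windows: dict[str, list[str]] = {}
    for d in read_dgr_fasta(args.dgr):
        asg = assign_cassette(find_elements(d), model, dgr_id=d.id)
        if asg is None or not asg.complete:
            continue
        for cls, h in asg.chosen.items():
            lo, hi = h.start_idx - args.flank, h.end_idx + args.flank
            if 0 <= lo and hi <= len(d.sequence):
                windows.setdefault(cls, []).append(d.sequence[lo:hi])

    logos_dir = args.out / "logos"
    logos_dir.mkdir(parents=True, exist_ok=True)
    pfms, summary = [], {}
    for cls, ws in sorted(windows.items()):
        pfm = build_pfm(ws, cls)
        pfms.append(pfm)
        plot_logo(pfm, logos_dir / f"{cls}.png")
        pfm_to_tsv(pfm, logos_dir / f"{cls}.tsv")
        core = pfm.consensus()[args.flank:-args.flank]
        summary[cls] = {"n": pfm.n_sequences, "consensus_core": core,
                        "max_ic_bits": float(information_content(pfm).max())}
        print(f"{cls:8s} n={pfm.n_sequences:4d}  consensus core: {core}")
    pfm_to_meme(pfms, logos_dir / "elements.meme")

    validation = None
    vpath = args.out / "validation.json"
    if vpath.exists():
        validation = json.loads(vpath.read_text())
    artifacts = {"cassettes": summary}
    if validation is not None:
        artifacts["validation"] = validation
    emit_report(artifacts, args.out)
    print(f"wrote logos and report -> {logos_dir}, {args.out / 'report.json'}")


if __name__ == "__main__":
    main()
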