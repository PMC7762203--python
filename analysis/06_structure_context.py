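#!/usr/bin/env python
"""Structural context of assigned cassettes: folds, CS context, complementarity.

Folds the cassette-spanning window of each complete assignment with the
maximum-base-pairing engine, classifies the cleavage position (stem /
loop / unpaired-external), combines it with the modal PAS pairing state
into a structure-class label, and searches the five element pairs for
4-6 nt complementary stretches.  Writes a per-DGR table and a frequency
table of the structure classes.
"""

import argparse
from collections import Counter
from pathlib import Path

from baculopolya.genome_io import read_dgr_fasta
from baculopolya.motif_scan import find_elements
from baculopolya.pas_model import ModelSpec, assign_cassette, cleavage_point
from baculopolya.structure import (classify_cs_context, element_complementarity,
                                   fold_max_pairing)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dgr", type=Path, default=ROOT / "results" / "dgr.fasta")
    ap.add_argument("--max-dgrs", type=int, default=87,
                    help="fold at most this many complete cassettes")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    model = ModelSpec.preset("improved2020")
    rows, classes, comp_counts = [], Counter(), Counter()
    for d in read_dgr_fasta(args.dgr):
        if len(rows) >= args.max_dgrs:
            break
        asg = assign_cassette(find_elements(d), model, dgr_id=d.id)
        if asg is None or not asg.complete:
            continue
        pas, dse = asg.chosen["PAS"], asg.chosen["DSE"]
        cs = cleavage_point(asg.chosen["CS"])
        lo = max(0, pas.start_idx - 15)
        hi = min(len(d.sequence), dse.end_idx + 40)
        fold = fold_max_pairing(d.sequence[lo:hi])
        ctx = classify_cs_context(fold, cs - lo,
                                  (pas.start_idx - lo, pas.end_idx - lo))
        matches = element_complementarity(d.sequence, asg.chosen)
        for m in matches:
            comp_counts[m.element_pair] += 1
        classes[ctx.structure_class] += 1
        rows.append((d.id, fold.pair_count, ctx.state, ctx.structure_class,
                     len(matches)))

    with open(args.out / "structure_context.tsv", "w") as fh:
        fh.write("dgr_id\tpairs\tcs_state\tstructure_class\tn_complements\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    with open(args.out / "structure_classes.tsv", "w") as fh:
        fh.write("structure_class\tcount\n")
        for cls, n in classes.most_common():
            fh.write(f"{cls}\t{n}\n")
    print(f"folded {len(rows)} complete cassettes; structure classes:")
    for cls, n in classes.most_common():
        print(f"  {cls:28s} {n}")
    print("complementary element pairs found:",
          {f"{a}-{b}": n for (a, b), n in comp_counts.most_common()})


if __name__ == "__main__":
    main()
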