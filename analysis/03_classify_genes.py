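#!/usr/bin/env python
"""Tabulate the protein evidence and the integrated gene classification.

Reads the summary produced by 02_scan_and_call.py and writes
results/gene_classification.tsv: per gene the C-terminal domain identity,
Ase-motif status, protein label, SOPE evidence and the final gene label
(proneural_ASH / ase_like / ancestral_ASH_ase_like / indeterminate).
"""

import argparse
import json
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--rundir", type=Path, default=Path("results/run"))
    ap.add_argument("--out", type=Path, default=Path("results/gene_classification.tsv"))
    args = ap.parse_args()

    summary = json.loads((args.rundir / "summary.json").read_text())
    rows = []
    for g in summary["genes"]:
        rows.append(
            {
                "gene": g["protein_id"].removesuffix("_protein"),
                "cterm_percent": g["cterm"]["percent"] if g["cterm"] else None,
                "ase_motif": "yes" if g["ase_motif_hits"] else "no",
                "protein_label": g["protein_label"],
                "sope_utr_side": g["sope"]["utr_side"] if g["sope"] else None,
                "sope_location": g["sope"]["location"] if g["sope"] else "none",
                "gene_label": g["gene_label"],
            }
        )
    frame = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, sep="\t", index=False)
    print(frame.to_string(index=False))
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
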