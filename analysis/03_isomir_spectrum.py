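#!/usr/bin/env python
"""Summarize the isomiR spectrum per stage.

Reads the per-stage spectrum tables written by the pipeline and reports the
TPM fraction of each of the 8 end-offset categories; 3' trimming (category
7) is expected to dominate at every stage.
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    pipedir = args.outdir / "pipeline"
    for path in sorted(pipedir.glob("isomir_spectrum_*.tsv")):
        stage = path.stem.replace("isomir_spectrum_", "")
        spec = pd.read_csv(path, sep="\t", index_col=0)
        top = spec["fraction"].idxmax()
        print(f"{stage}: dominant category {top} "
              f"({spec.loc[top, 'description']}), "
              f"fraction {spec.loc[top, 'fraction']:.2f}")
        print(spec[["tag_count", "tpm", "fraction"]].round(3).to_string())
        print()


if __name__ == "__main__":
    main()
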