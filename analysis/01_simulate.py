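#!/usr/bin/env python
"""Generate the synthetic developmental small-RNA dataset.

Writes reference libraries (matures, precursors, per-class decoys, genome,
SNP table) and per-stage paired-replicate read FASTAs with fully planted
ground truth under results/data/, plus the pipeline run config.
"""

import argparse
from pathlib import Path

import yaml

from smallrna_devatlas.pipeline import _write_simulated_inputs
from smallrna_devatlas.simulate import SimulationConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimulationConfig(rng_seed=args.seed)
    datadir = args.outdir / "data"
    run_config, truths = _write_simulated_inputs(cfg, datadir)
    run_config.outdir = str(args.outdir / "pipeline")
    with open(datadir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "stages": [
                    {"label": s.label, "rep1_fasta": s.rep1_fasta,
                     "rep2_fasta": s.rep2_fasta}
                    for s in run_config.stages
                ],
                "refdir": run_config.refdir,
                "outdir": run_config.outdir,
                "seed": run_config.seed,
            },
            fh,
        )
    print(f"dataset written under {datadir}")
    print(f"  stages: {cfg.labels()}  reads/replicate: {cfg.reads_per_replicate}")
    print(f"  miRNAs: {cfg.mirna_count}  planted edits: "
          f"{len(cfg.resolved_edit_plan())}  planted SNPs: "
          f"{len(cfg.resolved_snp_plan())}")
    for label, truth in truths.items():
        frac = (truth.reads.class_label == "miRNA").mean()
        print(f"  {label}: miRNA read fraction {frac:.2f}")


if __name__ == "__main__":
    main()
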