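#!/usr/bin/env python
"""Simulate the study trio: reference genome, trio call set, ground truth.

Generates the default synthetic trio — 22 short autosomes each split into a
40%-GC and a 60%-GC half, 2000 inherited SNVs, 300 planted de novo SNVs
(transition fraction 2/3), ~30x depth with 1% read error, and 10% of
candidate de novo sites being spurious genotyping errors — and writes the
reference FASTA, the trio VCF and the truth table under results/sim/.

Run from the repository root:  python analysis/01_simulate.py [--seed N]
"""

import argparse
from pathlib import Path

from dnsnvkit.synthetic_trio import (
    SyntheticTrioConfig,
    generate_reference,
    generate_trio,
)

OUTDIR = Path("results/sim")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    OUTDIR.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticTrioConfig(seed=args.seed)
    ref = generate_reference(cfg, fasta_path=OUTDIR / "reference.fa")
    callset, truth = generate_trio(
        cfg, ref, vcf_path=OUTDIR / "trio.vcf", truth_path=OUTDIR / "truth.tsv"
    )
    origins = {o: len(truth.keys(o)) for o in ("inherited", "denovo", "spurious")}
    print(f"simulated {len(callset)} trio records on {cfg.n_chrom} autosomes "
          f"({cfg.n_chrom * cfg.chrom_length / 1e6:.1f} Mb reference)")
    print(f"  planted: {origins['inherited']} inherited, {origins['denovo']} de novo, "
          f"{origins['spurious']} spurious candidates")
    print(f"  wrote reference.fa, trio.vcf, truth.tsv under {OUTDIR}/")


if __name__ == "__main__":
    main()
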