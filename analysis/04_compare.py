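#!/usr/bin/env python
"""Compare filtered call sets across three emulated pipelines.

Real calling pipelines share a substrate of detectable variants but differ
in sensitivity, so this driver derives three pipeline-like call sets from
the simulated trio by seeded subsampling (keep fractions 0.95 / 0.65 /
0.75), filters each at cutoff 0, and reports the three-way overlap
structure, per-chromosome counts, and GQ summaries before/after filtering.
It also tallies the packaged 22-variant consensus fixture for reference.
Outputs land in results/compare/.

Run from the repository root:  python analysis/04_compare.py
"""

from pathlib import Path

from dnsnvkit.callset_comparison import chromosomal_distribution, load_table1
from dnsnvkit.core_model import (
    DEFAULT_ROLE_MAP,
    extract_candidate_dnsnvs,
    read_trio_vcf,
    write_callset_vcf,
)
from dnsnvkit.pipeline import PipelineConfig, TrioInput, run_filter_and_compare
from dnsnvkit.synthetic_trio import subsample_callset

SIM = Path("results/sim")
OUT = Path("results/compare")
FRACTIONS = {"alpha": 0.95, "beta": 0.65, "gamma": 0.75}


def main() -> None:
    if not (SIM / "trio.vcf").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    callset = read_trio_vcf(SIM / "trio.vcf", DEFAULT_ROLE_MAP, name="trio")
    cands = extract_candidate_dnsnvs(callset)

    inputs = []
    for i, (name, frac) in enumerate(FRACTIONS.items()):
        sub = subsample_callset(cands, frac, seed=500 + i, name=name)
        path = OUT / f"{name}.vcf"
        write_callset_vcf(sub, path)
        inputs.append(TrioInput(path=str(path), role_map=DEFAULT_ROLE_MAP, name=name))
        print(f"pipeline {name}: {len(sub)} candidates (keep fraction {frac})")

    cfg = PipelineConfig(inputs=tuple(inputs), outdir=str(OUT))
    bundle = run_filter_and_compare(cfg)
    cmp = bundle["comparison"]
    kept = {n: bundle["sets"][n]["n_kept"] for n in FRACTIONS}
    print(f"filtered at cutoff 0: {kept}")
    print(f"common to all three: {cmp['common_count']} of a union of {cmp['union_size']}")
    for pair, n in cmp["pairwise_overlaps"].items():
        a = pair.split("&")[0]
        print(f"  {pair}: {n} shared ({round(100 * n / cmp['sizes'][a])}% of {a})")

    t1 = load_table1()
    busiest = sorted(chromosomal_distribution(t1).items(),
                     key=lambda kv: -kv[1])[:3]
    print(f"consensus fixture: {len(t1)} variants; busiest chromosomes "
          + ", ".join(f"chr{c} ({n})" for c, n in busiest))
    print(f"report written to {OUT}/filter_compare.json")


if __name__ == "__main__":
    main()
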