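"""Synthetic reference and trio call-set generator with ground truth.

The generator emulates the downstream products of exome trio calling on a
father–mother–child trio: a reference with controllable GC structure and a
multi-sample VCF of biallelic autosomal SNVs carrying GT, AD and GQ, plus a
truth table recording every planted variant's origin.  It uses the standard
sequencing toy model:

* reference bases drawn i.i.d. per segment with P(G or C) = the segment's
  target GC fraction;
* inherited SNVs assigned to a random parent (het with probability 2/3,
  hom-alt otherwise) and transmitted Mendelianly to the child;
* de novo SNVs planted with parents 0/0 and child 0/1;
* spurious candidates planted as sites whose true genotypes are all 0/0
  but whose *called* child genotype is 0/1 — a genotyping error;
* per-site per-sample depth ~ Poisson(mean_depth); alt reads ~
  Binomial(depth, vaf) with vaf = seq_error for genotype 0/0, 0.5 for 0/1
  and 1 − seq_error for 1/1;
* GQ drawn uniformly from a high band for true variants and from the same
  band shifted down by ``gq_margin`` for spurious candidates (GQ is
  synthesised, not derived from likelihoods).

The substitution of each planted variant is a transition with probability
``ti_fraction`` and otherwise uniform over the two transversions of its
reference base, so the planted Ti/Tv ratio is ti_fraction/(1−ti_fraction)
in expectation.  All randomness flows from the single config seed; a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    CallSet,
    ReferenceSequence,
    SampleCall,
    VariantKey,
    VariantRecord,
    write_callset_vcf,
)
from .context_metrics import classify_substitution

ORIGIN_DENOVO = "denovo"
ORIGIN_INHERITED = "inherited"
ORIGIN_SPURIOUS = "spurious"

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# Planted variants stay this many bases clear of contig ends so that the
# 100-base context window is always defined for them.
_EDGE_MARGIN = 50


@dataclass(frozen=True)
class SyntheticTrioConfig:
    """Study conditions for one simulated trio.

    Defaults emulate an exome-scale trio experiment: a genome of 22 short
    autosomes, each split into a low-GC (40%) and a high-GC (60%) half —
    the two GC regimes in which calling behaviour is compared — roughly
    30× coverage, a 1% per-read error rate, about two thousand inherited
    variants, 300 planted de novo SNVs with a transition fraction of 2/3
    (planted Ti/Tv = 2, the expectation for genuine variation), and 10% of
    candidate de novo sites being spurious genotyping errors.
    """

    n_chrom: int = 22
    chrom_length: int = 200_000
    gc_segments: tuple[tuple[int, float], ...] = ((100_000, 0.4), (100_000, 0.6))
    n_inherited: int = 2000
    n_denovo: int = 300
    ti_fraction: float = 2 / 3
    mean_depth: float = 30.0
    seq_error: float = 0.01
    spurious_rate: float = 0.10
    gq_true_min: int = 60
    gq_true_max: int = 99
    gq_margin: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.n_chrom > 22:
            raise ValueError(f"n_chrom must be in 1..22, got {self.n_chrom}")
        if sum(l for l, _ in self.gc_segments) != self.chrom_length:
            raise ValueError(
                "gc_segments lengths must sum to chrom_length "
                f"({sum(l for l, _ in self.gc_segments)} != {self.chrom_length})"
            )
        for length, gc in self.gc_segments:
            if length <= 0 or not 0.0 <= gc <= 1.0:
                raise ValueError(f"bad segment ({length}, {gc})")
        for name in ("ti_fraction", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.spurious_rate < 1.0:
            raise ValueError(f"spurious_rate must be in [0, 1), got {self.spurious_rate}")
        if min(self.n_inherited, self.n_denovo) < 0 or self.mean_depth <= 0:
            raise ValueError("counts must be >= 0 and mean_depth > 0")

    @property
    def n_spurious(self) -> int:
        """Spurious candidates such that they form ``spurious_rate`` of all
        candidate de novo sites (planted de novo + spurious)."""
        if self.spurious_rate == 0.0:
            return 0
        return round(self.spurious_rate * self.n_denovo / (1.0 - self.spurious_rate))

    def segment_gc_at(self, pos: int) -> float:
        """Target GC fraction of the segment containing a 1-based position."""
        offset = 0
        for length, gc in self.gc_segments:
            offset += length
            if pos <= offset:
                return gc
        raise ValueError(f"position {pos} beyond chrom_length {self.chrom_length}")


@dataclass(frozen=True)
class TruthRecord:
    key: VariantKey
    origin: str
    true_genotypes: dict[str, tuple[int, int]]
    segment_gc: float
    substitution_class: str


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keys(self, origin: Optional[str] = None) -> set[VariantKey]:
        return {t.key for t in self.records if origin is None or t.origin == origin}

    def by_key(self) -> dict[VariantKey, TruthRecord]:
        return {t.key: t for t in self.records}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                ["chrom", "pos", "ref", "alt", "origin", "gt_father", "gt_mother",
                 "gt_child", "segment_gc", "substitution_class"]
            )
            for t in self.records:
                c, p, ref, alt = t.key
                fmt = lambda g: "/".join(str(a) for a in g)
                w.writerow(
                    [c, p, ref, alt, t.origin,
                     fmt(t.true_genotypes["father"]),
                     fmt(t.true_genotypes["mother"]),
                     fmt(t.true_genotypes["child"]),
                     f"{t.segment_gc:.4f}", t.substitution_class]
                )


def generate_reference(
    config: SyntheticTrioConfig, fasta_path: Optional[str | Path] = None
) -> ReferenceSequence:
    """Draw a reference whose segments hit their target GC in expectation.

    Each chromosome is built from the same segment profile; within a
    segment each base is G or C with the target probability (split evenly
    between the two), else A or T.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    seqs: dict[str, str] = {}
    bases = np.frombuffer(b"ATGC", dtype="S1")
    for i in range(1, config.n_chrom + 1):
        parts = []
        for length, gc in config.gc_segments:
            is_gc = rng.random(length) < gc
            which = rng.integers(0, 2, size=length)  # A vs T, G vs C
            idx = is_gc.astype(np.int8) * 2 + which
            parts.append(bases[idx].tobytes().decode("ascii"))
        seqs[str(i)] = "".join(parts)
    ref = ReferenceSequence(seqs)
    if fasta_path is not None:
        ref.write_fasta(fasta_path)
    return ref


def _draw_alt(rng: np.random.Generator, ref_base: str, ti_fraction: float) -> str:
    if rng.random() < ti_fraction:
        return _TRANSITION_OF[ref_base]
    return _TRANSVERSIONS_OF[ref_base][rng.integers(0, 2)]


def _depths(
    rng: np.random.Generator, genotype: tuple[int, int], config: SyntheticTrioConfig
) -> tuple[int, int]:
    vaf = {
        (0, 0): config.seq_error,
        (0, 1): 0.5,
        (1, 1): 1.0 - config.seq_error,
    }[genotype]
    depth = int(rng.poisson(config.mean_depth))
    alt = int(rng.binomial(depth, vaf)) if depth > 0 else 0
    return depth - alt, alt


def generate_trio(
    config: SyntheticTrioConfig,
    reference: ReferenceSequence,
    vcf_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
    name: str = "synthetic",
) -> tuple[CallSet, TruthTable]:
    """Plant inherited, de novo and spurious SNVs and emit calls with depths.

    Positions are drawn without replacement, at least 50 bp from contig
    ends so every planted variant has a defined 100-base context window.
    The emitted call set carries the *called* genotypes (which differ from
    truth only at spurious sites); the truth table carries the true ones.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_total = config.n_inherited + config.n_denovo + config.n_spurious
    usable = config.chrom_length - 2 * _EDGE_MARGIN
    if usable <= 0 or n_total > config.n_chrom * usable:
        raise ValueError(
            f"cannot place {n_total} variants on {config.n_chrom} chromosomes "
            f"of usable length {max(usable, 0)}"
        )
    flat = rng.choice(config.n_chrom * usable, size=n_total, replace=False)
    sites = [
        (str(1 + f // usable), _EDGE_MARGIN + 1 + int(f % usable)) for f in flat
    ]

    origins = (
        [ORIGIN_INHERITED] * config.n_inherited
        + [ORIGIN_DENOVO] * config.n_denovo
        + [ORIGIN_SPURIOUS] * config.n_spurious
    )
    records: list[VariantRecord] = []
    truth = TruthTable()
    for (chrom, pos), origin in zip(sites, origins):
        ref_base = reference.base(chrom, pos)
        alt_base = _draw_alt(rng, ref_base, config.ti_fraction)

        if origin == ORIGIN_INHERITED:
            carrier = "father" if rng.random() < 0.5 else "mother"
            carrier_gt = (0, 1) if rng.random() < 2 / 3 else (1, 1)
            transmitted = 1 if carrier_gt == (1, 1) or rng.random() < 0.5 else 0
            true_gts = {
                "father": carrier_gt if carrier == "father" else (0, 0),
                "mother": carrier_gt if carrier == "mother" else (0, 0),
                "child": tuple(sorted((0, transmitted))),
            }
            called_child = true_gts["child"]
        elif origin == ORIGIN_DENOVO:
            true_gts = {"father": (0, 0), "mother": (0, 0), "child": (0, 1)}
            called_child = (0, 1)
        else:  # spurious: truly hom-ref everywhere, child miscalled het
            true_gts = {"father": (0, 0), "mother": (0, 0), "child": (0, 0)}
            called_child = (0, 1)

        calls: dict[str, SampleCall] = {}
        spurious = origin == ORIGIN_SPURIOUS
        for role in ("father", "mother", "child"):
            ref_d, alt_d = _depths(rng, true_gts[role], config)
            gq = int(rng.integers(config.gq_true_min, config.gq_true_max + 1))
            if spurious:
                gq = max(0, gq - config.gq_margin)
            called = called_child if role == "child" else true_gts[role]
            calls[role] = SampleCall(
                genotype=called, ref_depth=ref_d, alt_depth=alt_d, gq=gq
            )
        records.append(
            VariantRecord(chrom=chrom, pos=pos, ref=ref_base, alt=alt_base, **calls)
        )
        truth.records.append(
            TruthRecord(
                key=(chrom, pos, ref_base, alt_base),
                origin=origin,
                true_genotypes=true_gts,
                segment_gc=config.segment_gc_at(pos),
                substitution_class=classify_substitution(ref_base, alt_base),
            )
        )

    callset = CallSet(name=name, records=records)
    truth.records.sort(key=lambda t: ((int(t.key[0]), t.key[1], t.key[2], t.key[3])))
    if vcf_path is not None:
        write_callset_vcf(callset, vcf_path, reference=reference)
    if truth_path is not None:
        truth.write_tsv(truth_path)
    return callset, truth


def subsample_callset(
    callset: CallSet,
    keep_fraction: float,
    seed: int,
    name: Optional[str] = None,
) -> CallSet:
    """Independently keep each record with the given probability.

    Emulates a pipeline of imperfect sensitivity drawing from a common pool
    of detectable variants, so that call sets derived from the same trio
    have realistic partial overlaps.
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in [0, 1], got {keep_fraction}")
    rng = np.random.default_rng(seed)
    kept = [r for r in callset if rng.random() < keep_fraction]
    return CallSet(name=name or callset.name, records=kept, provenance=callset.provenance)
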