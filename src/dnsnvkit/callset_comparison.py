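"""Comparison of DNSNV call sets across pipelines.

Different trio callers nominate overlapping but far from identical de novo
candidate sets.  This module computes the quantities used to compare them:
Venn-region and pairwise overlap counts over the exact variant key
(chrom, pos, ref, alt), the overlap rate of a call set against a
known-variant catalog (a dbSNP-like VCF), per-autosome counts, and
per-role genotype-quality (GQ) summaries.

Matching is allele-aware on purpose: two pipelines calling different
alleles at the same position are not counted as agreeing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

from .core_model import (
    AUTOSOMES,
    BASES,
    CallSet,
    ROLES,
    VariantKey,
    is_autosome,
    normalize_chrom,
)


@dataclass(frozen=True)
class ComparisonReport:
    """Overlap structure of 2–3 call sets matched on (chrom, pos, ref, alt).

    ``exclusive_counts`` is keyed by the exact membership combination,
    rendered as names joined with ``&`` (e.g. ``"GATK"``, ``"GATK&RTG"``);
    the counts over all regions sum to the union size.
    """

    set_names: tuple[str, ...]
    sizes: dict[str, int]
    exclusive_counts: dict[str, int]
    pairwise_overlaps: dict[str, int]
    common_count: int
    union_size: int

    def to_dict(self) -> dict:
        return {
            "set_names": list(self.set_names),
            "sizes": dict(self.sizes),
            "exclusive_counts": dict(self.exclusive_counts),
            "pairwise_overlaps": dict(self.pairwise_overlaps),
            "common_count": self.common_count,
            "union_size": self.union_size,
        }


def intersect_callsets(callsets: Sequence[CallSet]) -> ComparisonReport:
    """Venn-region, pairwise and common counts over 2–3 call sets."""
    if not 2 <= len(callsets) <= 3:
        raise ValueError(f"need 2 or 3 call sets, got {len(callsets)}")
    names = tuple(cs.name for cs in callsets)
    if len(set(names)) != len(names):
        raise ValueError(f"call set names must be distinct: {names}")
    keysets = {cs.name: cs.keys() for cs in callsets}
    union: set[VariantKey] = set().union(*keysets.values())

    exclusive: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            exclusive["&".join(combo)] = 0
    for k in union:
        members = tuple(n for n in names if k in keysets[n])
        exclusive["&".join(members)] += 1

    pairwise = {
        "&".join(pair): len(keysets[pair[0]] & keysets[pair[1]])
        for pair in combinations(names, 2)
    }
    common = len(set.intersection(*keysets.values()))
    return ComparisonReport(
        set_names=names,
        sizes={n: len(keysets[n]) for n in names},
        exclusive_counts=exclusive,
        pairwise_overlaps=pairwise,
        common_count=common,
        union_size=len(union),
    )


def overlap_rate(callset: CallSet, catalog: set[VariantKey]) -> float:
    """Percentage of a call set's records found in a known-variant catalog.

    100 × |records with key in catalog| / |records|.  Full precision is
    returned; round for display.  An empty call set has no defined rate.
    """
    if len(callset) == 0:
        raise ValueError(f"overlap rate undefined for empty call set {callset.name!r}")
    hits = sum(1 for k in callset.keys() if k in catalog)
    return 100.0 * hits / len(callset)


def read_catalog_vcf(path: str | Path) -> set[VariantKey]:
    """Variant keys of all biallelic autosomal SNVs in a catalog VCF."""
    keys: set[VariantKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or rec.ref is None or not is_autosome(rec.chrom):
                continue
            if len(rec.ref) != 1 or rec.ref not in BASES:
                continue
            for alt in rec.alts:
                if len(alt) == 1 and alt in BASES:
                    keys.add((normalize_chrom(rec.chrom), rec.pos, rec.ref, alt))
    return keys


def chromosomal_distribution(callset: CallSet) -> dict[str, int]:
    """Record count per autosome, zeros included; counts sum to |callset|."""
    counts = {c: 0 for c in AUTOSOMES}
    for r in callset:
        counts[r.chrom] = counts.get(r.chrom, 0) + 1
    return counts


@dataclass(frozen=True)
class GQSummary:
    """Order statistics and mean of GQ values for one trio role."""

    n: int
    n_missing: int
    min: Optional[float] = None
    q25: Optional[float] = None
    median: Optional[float] = None
    q75: Optional[float] = None
    max: Optional[float] = None
    mean: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_missing": self.n_missing,
            "min": self.min,
            "q25": self.q25,
            "median": self.median,
            "q75": self.q75,
            "max": self.max,
            "mean": self.mean,
        }


def gq_summary(callset: CallSet) -> dict[str, GQSummary]:
    """Per-role GQ quantiles and mean over records with a non-missing GQ."""
    out: dict[str, GQSummary] = {}
    for role in ROLES:
        vals = [r.sample(role).gq for r in callset]
        present = np.array([v for v in vals if v is not None], dtype=float)
        n_missing = len(vals) - len(present)
        if len(present) == 0:
            out[role] = GQSummary(n=0, n_missing=n_missing)
            continue
        q25, med, q75 = np.percentile(present, [25, 50, 75])
        out[role] = GQSummary(
            n=len(present),
            n_missing=n_missing,
            min=float(present.min()),
            q25=float(q25),
            median=float(med),
            q75=float(q75),
            max=float(present.max()),
            mean=float(present.mean()),
        )
    return out


_TABLE1_RESOURCE = "data/table1_fixture.vcf"


def table1_path() -> Path:
    """Filesystem path of the packaged consensus-DNSNV fixture VCF."""
    return Path(str(files("dnsnvkit").joinpath(_TABLE1_RESOURCE)))


def load_table1() -> CallSet:
    """The packaged 22-variant consensus call set as a trio CallSet.

    These are the candidates nominated by all three reference pipelines on
    the GIAB Ashkenazi trio exomes; the fixture encodes chromosome,
    position and substitution (the published values, in their published
    order) with canonical de novo genotypes and no depths.
    """
    from .core_model import DEFAULT_ROLE_MAP, read_trio_vcf

    return read_trio_vcf(table1_path(), DEFAULT_ROLE_MAP, name="consensus22")


def load_table1_metadata() -> dict[VariantKey, dict[str, Optional[str]]]:
    """Gene symbol and phenotype annotations carried as opaque metadata."""
    meta: dict[VariantKey, dict[str, Optional[str]]] = {}
    with pysam.VariantFile(str(table1_path())) as vcf:
        for rec in vcf:
            key = (normalize_chrom(rec.chrom), rec.pos, rec.ref, rec.alts[0])
            gene = rec.info.get("GENE")
            pheno = rec.info.get("PHENO")
            meta[key] = {
                "gene": None if gene is None else str(gene).replace("_", " "),
                "phenotype": None if pheno is None else str(pheno).replace("_", " "),
            }
    return meta
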