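"""Read-coverage score for refining candidate de novo SNVs.

For a true de novo variant one expects the parents' reads to support the
reference allele almost exclusively, while the child's reads split between
the two alleles.  The score condenses the six allele depths at a site —
father (F_ref, F_alt), mother (M_ref, M_alt), child (S_ref, S_alt) — into a
single log10 quantity built from the per-sample depth *separations*
|ref − alt|:

    product form (default):
        score = log10( ((|F_ref−F_alt| + |M_ref−M_alt|) / 2) × |S_alt−S_ref| )

    ratio form:
        score = log10( (|F_ref−F_alt| + |M_ref−M_alt|) / (2 × |S_alt−S_ref|) )

The product form grows whenever the parental support is cleanly reference
and the child's depths are separated at all; the ratio form rewards clean
parents *relative* to the child's separation, which penalises candidates
whose child depths look homozygous (a hallmark of miscalled sites under a
simple error model).  Both forms are undefined when the child separation
is zero or the mean parental separation is zero, or when any depth is
missing; undefined scores never pass any finite cutoff.

Candidates are ranked by descending score, and filtered at a cutoff with a
strict inequality — a non-stringent cutoff of 0 (the unit point of the
log) is the conventional default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .core_model import CallSet, VariantKey, VariantRecord

PRODUCT = "product"
RATIO = "ratio"
_VARIANTS = (PRODUCT, RATIO)

REASON_MISSING_DEPTH = "missing-depth"
REASON_ZERO_CHILD = "zero-child-separation"
REASON_ZERO_PARENTAL = "zero-parental-separation"
REASON_BELOW_CUTOFF = "below-cutoff"


@dataclass(frozen=True)
class FilterScore:
    """A log10 coverage score, or the reason it is undefined."""

    value: Optional[float]
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def passes(self, cutoff: float) -> bool:
        return self.value is not None and self.value > cutoff


def score_dnsnv(record: VariantRecord, variant: str = PRODUCT) -> FilterScore:
    """Score one candidate from its six allele depths.

    ``variant`` selects the product (default) or ratio grouping; see the
    module docstring.  Missing depths in any role give an undefined score
    with reason ``missing-depth``; a zero child separation or zero mean
    parental separation gives the corresponding zero-factor reason.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown score variant {variant!r}; expected {_VARIANTS}")
    calls = (record.father, record.mother, record.child)
    if any(not c.has_depths for c in calls):
        return FilterScore(value=None, reason=REASON_MISSING_DEPTH)
    f = abs(record.father.ref_depth - record.father.alt_depth)
    m = abs(record.mother.ref_depth - record.mother.alt_depth)
    s = abs(record.child.alt_depth - record.child.ref_depth)
    if s == 0:
        return FilterScore(value=None, reason=REASON_ZERO_CHILD)
    parental = (f + m) / 2.0
    if parental == 0:
        return FilterScore(value=None, reason=REASON_ZERO_PARENTAL)
    x = parental * s if variant == PRODUCT else parental / s
    return FilterScore(value=math.log10(x))


def score_callset(
    callset: CallSet, variant: str = PRODUCT
) -> dict[VariantKey, FilterScore]:
    return {r.key: score_dnsnv(r, variant) for r in callset}


def apply_filter(
    callset: CallSet, cutoff: float = 0.0, variant: str = PRODUCT
) -> CallSet:
    """Records whose score is defined and strictly greater than the cutoff.

    Unscorable records (missing depths, zero separations) are removed at
    every cutoff.  The result preserves order and is a subset of the input.
    """
    kept, _ = filter_with_reasons(callset, cutoff, variant)
    return kept


def filter_with_reasons(
    callset: CallSet, cutoff: float = 0.0, variant: str = PRODUCT
) -> tuple[CallSet, dict[VariantKey, str]]:
    """Like :func:`apply_filter` but also report why each record was removed."""
    if not math.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    kept: list[VariantRecord] = []
    rejected: dict[VariantKey, str] = {}
    for r in callset:
        sc = score_dnsnv(r, variant)
        if sc.passes(cutoff):
            kept.append(r)
        else:
            rejected[r.key] = sc.reason if sc.reason is not None else REASON_BELOW_CUTOFF
    return (
        CallSet(name=callset.name, records=kept, provenance=callset.provenance),
        rejected,
    )


@dataclass(frozen=True)
class CutoffSweep:
    """Number of records kept at each cutoff of an ascending sweep."""

    cutoffs: tuple[float, ...]
    kept_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.cutoffs) != len(self.kept_counts):
            raise ValueError("cutoffs and kept_counts must align")


def cutoff_sweep(
    callset: CallSet, cutoffs: Sequence[float], variant: str = PRODUCT
) -> CutoffSweep:
    """Kept counts over an ascending list of cutoffs (duplicates allowed).

    Counts are non-increasing because filtering at a larger cutoff keeps a
    subset of the records kept at a smaller one.
    """
    cs = list(cutoffs)
    if any(b < a for a, b in zip(cs, cs[1:])):
        raise ValueError(f"cutoffs must be sorted ascending: {cs}")
    scores = [score_dnsnv(r, variant) for r in callset]
    counts = tuple(sum(1 for sc in scores if sc.passes(c)) for c in cs)
    return CutoffSweep(cutoffs=tuple(cs), kept_counts=counts)


def rank_by_score(
    callset: CallSet, variant: str = PRODUCT
) -> list[tuple[VariantRecord, FilterScore]]:
    """Records ordered by descending score; undefined scores last.

    Ties (including among undefined scores) break by genomic position so
    the ranking is deterministic.
    """
    scored = [(r, score_dnsnv(r, variant)) for r in callset]
    return sorted(
        scored,
        key=lambda rs: (
            rs[1].value is None,
            -(rs[1].value if rs[1].value is not None else 0.0),
            rs[0].sort_key,
        ),
    )
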