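"""Per-variant sequence-context metrics.

Three context metrics characterise a candidate de novo SNV:

* **GC content** — the percentage of G and C bases in the 100-base reference
  window centred on the variant.  High-GC regions amplify poorly during PCR
  and accumulate calling errors, so call sets can be stratified by GC.
* **SNV density** — the number of called SNVs (as a percentage of the
  window length) in the same 100-base window; dense clusters of calls are
  enriched for alignment artefacts.
* **Substitution class** — transition (purine↔purine A↔G, or
  pyrimidine↔pyrimidine C↔T) versus transversion (purine↔pyrimidine).
  The transition/transversion ratio (Ti/Tv) of a call set is a standard
  quality proxy: random errors push it towards the uniform expectation of
  0.5, real variation well above it.

Window geometry: a window of even length ``w`` centred on position ``p`` is
the 1-based inclusive interval ``[p - w/2, p + w/2 - 1]``, which contains
the variant base itself.  Windows that overrun a contig end, or contain an
N, yield a missing GC content rather than a rescaled one — the denominator
is fixed at the window length by construction.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core_model import (
    BASES,
    CallSet,
    ReferenceSequence,
    VariantKey,
    normalize_chrom,
)

TRANSITION = "transition"
TRANSVERSION = "transversion"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

DEFAULT_WINDOW = 100
DEFAULT_GC_THRESHOLD = 50.0


@dataclass(frozen=True)
class ContextAnnotation:
    """GC content, SNV density and substitution class for one variant.

    Percentages are on [0, 100]; with the default window of 100 they are
    integer-valued because they are counts over a 100-base window.  Either
    may be missing (``None``) when the window is undefined.
    """

    gc_content: Optional[float]
    snv_density: Optional[float]
    substitution_class: str

    def __post_init__(self) -> None:
        for name in ("gc_content", "snv_density"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.substitution_class not in (TRANSITION, TRANSVERSION):
            raise ValueError(f"bad substitution class {self.substitution_class!r}")

    @property
    def gc_class(self) -> Optional[str]:
        """``high`` iff gc_content >= 50, ``low`` below, None when missing."""
        if self.gc_content is None:
            return None
        return "high" if self.gc_content >= DEFAULT_GC_THRESHOLD else "low"


@dataclass(frozen=True)
class TiTvSummary:
    n_transitions: int
    n_transversions: int

    @property
    def ratio(self) -> Optional[float]:
        if self.n_transversions == 0:
            return None
        return self.n_transitions / self.n_transversions

    @property
    def ratio_str(self) -> str:
        """Ratio rendered at the conventional 2-decimal reporting precision."""
        r = self.ratio
        return "NA" if r is None else f"{r:.2f}"

    @property
    def n_classified(self) -> int:
        return self.n_transitions + self.n_transversions


def window_bounds(pos: int, window: int = DEFAULT_WINDOW) -> tuple[int, int]:
    """Inclusive 1-based bounds of the even-length window centred on pos."""
    if window <= 0 or window % 2:
        raise ValueError(f"window length must be positive and even, got {window}")
    half = window // 2
    return pos - half, pos + half - 1


def gc_content(
    reference: ReferenceSequence,
    chrom: str,
    pos: int,
    window: int = DEFAULT_WINDOW,
) -> Optional[float]:
    """GC percentage of the window centred on (chrom, pos).

    Returns ``None`` when the window overruns the contig or contains N.
    An invalid chromosome or position raises.
    """
    reference.base(chrom, pos)  # validates (chrom, pos)
    start, end = window_bounds(pos, window)
    if not reference.in_range(chrom, start, end):
        return None
    seq = reference.window(chrom, start, end)
    if "N" in seq:
        return None
    return (seq.count("G") + seq.count("C")) * 100.0 / window


def snv_density(
    snv_positions: Iterable[tuple[str, int]],
    chrom: str,
    pos: int,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Percentage of window positions holding a called SNV.

    ``snv_positions`` should be the full SNV call set of the same sample and
    pipeline (de novo plus inherited); the focal variant, if present in the
    set, counts itself.
    """
    start, end = window_bounds(pos, window)
    c = normalize_chrom(chrom)
    n = sum(
        1
        for (pc, pp) in snv_positions
        if normalize_chrom(pc) == c and start <= pp <= end
    )
    return n * 100.0 / window


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a substitution as transition or transversion.

    Transitions keep the base family (A↔G within purines, C↔T within
    pyrimidines); everything else crosses families and is a transversion.
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"ref/alt must be in ACGT: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    pair = {ref, alt}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return TRANSITION
    return TRANSVERSION


def titv_summary(callset: CallSet) -> TiTvSummary:
    """Transition/transversion counts and ratio over a call set."""
    ti = sum(1 for r in callset if classify_substitution(r.ref, r.alt) == TRANSITION)
    return TiTvSummary(n_transitions=ti, n_transversions=len(callset) - ti)


@dataclass(frozen=True)
class GCStrata:
    """Call set partitioned at a GC-content threshold, with Ti/Tv per stratum."""

    high: CallSet
    low: CallSet
    missing: CallSet
    high_titv: TiTvSummary
    low_titv: TiTvSummary
    threshold: float


def stratify_by_gc(
    callset: CallSet,
    annotations: Mapping[VariantKey, ContextAnnotation],
    threshold: float = DEFAULT_GC_THRESHOLD,
) -> GCStrata:
    """Partition records into GC >= threshold and GC < threshold strata.

    Records whose GC content is missing (window undefined) go to neither
    stratum and are reported separately.
    """
    high, low, missing = [], [], []
    for r in callset:
        ann = annotations[r.key]
        if ann.gc_content is None:
            missing.append(r)
        elif ann.gc_content >= threshold:
            high.append(r)
        else:
            low.append(r)
    mk = lambda recs, tag: CallSet(name=f"{callset.name}:{tag}", records=recs)
    high_cs, low_cs = mk(high, "gc_high"), mk(low, "gc_low")
    return GCStrata(
        high=high_cs,
        low=low_cs,
        missing=mk(missing, "gc_missing"),
        high_titv=titv_summary(high_cs),
        low_titv=titv_summary(low_cs),
        threshold=threshold,
    )


def density_cumulative(
    densities: Sequence[Optional[float]],
    bin_edges: Sequence[float],
) -> list[float]:
    """Cumulative fraction of records with SNV density strictly below each edge.

    Edges must be strictly increasing.  Missing densities count in the
    denominator but never in a numerator, so the final fraction can be < 1.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must be strictly increasing: {edges}")
    vals = list(densities)
    if not vals:
        raise ValueError("cannot compute a cumulative distribution of zero records")
    n = len(vals)
    return [sum(1 for v in vals if v is not None and v < e) / n for e in edges]


def annotate_callset(
    callset: CallSet,
    reference: Optional[ReferenceSequence] = None,
    snv_positions: Optional[set[tuple[str, int]]] = None,
    window: int = DEFAULT_WINDOW,
) -> dict[VariantKey, ContextAnnotation]:
    """Compute context annotations for every record of a call set.

    GC content requires ``reference``; SNV density requires
    ``snv_positions`` (the full per-pipeline SNV set, positions as
    (chrom, pos)).  Omitted inputs yield missing values.
    """
    by_chrom: dict[str, list[int]] = {}
    if snv_positions is not None:
        for (c, p) in snv_positions:
            by_chrom.setdefault(normalize_chrom(c), []).append(p)
        for ps in by_chrom.values():
            ps.sort()
    out: dict[VariantKey, ContextAnnotation] = {}
    for r in callset:
        gc = gc_content(reference, r.chrom, r.pos, window) if reference is not None else None
        dens = None
        if snv_positions is not None:
            start, end = window_bounds(r.pos, window)
            ps = by_chrom.get(r.chrom, [])
            dens = (bisect.bisect_right(ps, end) - bisect.bisect_left(ps, start)) * 100.0 / window
        out[r.key] = ContextAnnotation(
            gc_content=gc,
            snv_density=dens,
            substitution_class=classify_substitution(r.ref, r.alt),
        )
    return out
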