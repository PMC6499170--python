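"""Trio call-set data model, VCF/FASTA ingestion, and candidate extraction.

A de novo single-nucleotide variant (DNSNV) is a single-base substitution
carried by a child but absent from both parental germlines.  This module
holds the in-memory model shared by the whole package: a biallelic SNV
record with per-role (father / mother / child) genotype, allele depths and
genotype quality; an ordered, deduplicated call set attributed to one
calling pipeline; and a random-access reference sequence.  Ingestion is
deliberately strict — only biallelic SNVs on the 22 autosomes are modelled,
matching the scope of the downstream metrics.

All public coordinates are 1-based (VCF convention).  Chromosome labels are
accepted in both ``chr1`` and ``1`` dialects and normalised to the
unprefixed form; sort order is numeric 1–22.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import pysam
from pyfaidx import Fasta

log = logging.getLogger(__name__)

BASES = frozenset("ACGT")
ROLES = ("father", "mother", "child")
AUTOSOMES = tuple(str(i) for i in range(1, 23))
_AUTOSOME_SET = frozenset(AUTOSOMES)

Genotype = tuple[int, int]
VariantKey = tuple[str, int, str, str]


class ConfigurationError(ValueError):
    """A configuration (sample names, role map, paths) is unusable."""


class ReferenceError_(ValueError):
    """A reference sequence is malformed or a lookup is out of range."""


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix from a chromosome label."""
    s = str(label)
    return s[3:] if s[:3].lower() == "chr" else s


def is_autosome(label: str) -> bool:
    return normalize_chrom(label) in _AUTOSOME_SET


def chrom_sort_key(label: str) -> tuple[int, str]:
    """Numeric sort key for autosomes; non-numeric labels sort after them."""
    c = normalize_chrom(label)
    return (int(c), "") if c.isdigit() else (10**6, c)


@dataclass(frozen=True)
class SampleCall:
    """Genotype, allele depths and GQ for one trio member at one site.

    ``genotype`` is the unordered pair of allele indices (0 = ref, 1 = alt),
    stored sorted; ``None`` means the genotype was not called.  Depths are
    read counts supporting the reference and alternate allele (VCF ``AD``);
    both are ``None`` when AD was absent, which makes the record unscorable
    by the coverage filter but keeps it in the call set.
    """

    genotype: Optional[Genotype] = None
    ref_depth: Optional[int] = None
    alt_depth: Optional[int] = None
    gq: Optional[int] = None

    def __post_init__(self) -> None:
        if self.genotype is not None:
            g = tuple(sorted(int(a) for a in self.genotype))
            if not all(a in (0, 1) for a in g) or len(g) != 2:
                raise ValueError(f"genotype alleles must be in {{0,1}}: {self.genotype}")
            object.__setattr__(self, "genotype", g)
        for name in ("ref_depth", "alt_depth"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if (self.ref_depth is None) != (self.alt_depth is None):
            raise ValueError("ref_depth and alt_depth must be both present or both missing")

    @property
    def has_depths(self) -> bool:
        return self.ref_depth is not None and self.alt_depth is not None

    @property
    def carries_alt(self) -> bool:
        return self.genotype is not None and 1 in self.genotype


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV with calls for father, mother and child."""

    chrom: str
    pos: int
    ref: str
    alt: str
    father: SampleCall
    mother: SampleCall
    child: SampleCall

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def sample(self, role: str) -> SampleCall:
        if role not in ROLES:
            raise KeyError(f"unknown role {role!r}; expected one of {ROLES}")
        return getattr(self, role)

    @property
    def sort_key(self) -> tuple[tuple[int, str], int, str, str]:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def is_candidate_denovo(self) -> bool:
        """Mendelian-violation pattern: both parents 0/0, child carries alt."""
        return (
            self.father.genotype == (0, 0)
            and self.mother.genotype == (0, 0)
            and self.child.carries_alt
        )


@dataclass
class SkipLog:
    """Counts of records excluded during VCF ingestion, by reason."""

    non_snv: int = 0
    multiallelic: int = 0
    non_autosome: int = 0
    missing_genotype: int = 0

    @property
    def total(self) -> int:
        return self.non_snv + self.multiallelic + self.non_autosome + self.missing_genotype


@dataclass
class CallSet:
    """A named, ordered, deduplicated collection of variant records.

    Records are kept sorted by (numeric chromosome, position, ref, alt);
    duplicate (chrom, pos, ref, alt) keys are rejected.
    """

    name: str
    records: list[VariantRecord] = field(default_factory=list)
    provenance: Optional[str] = None
    skip_log: Optional[SkipLog] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.sort_key)
        seen: set[VariantKey] = set()
        for r in self.records:
            if r.key in seen:
                raise ValueError(f"duplicate record {r.key} in call set {self.name!r}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def keys(self) -> set[VariantKey]:
        return {r.key for r in self.records}

    def by_key(self) -> dict[VariantKey, VariantRecord]:
        return {r.key: r for r in self.records}

    def subset(self, keys: set[VariantKey], name: Optional[str] = None) -> "CallSet":
        return CallSet(
            name=name or self.name,
            records=[r for r in self.records if r.key in keys],
            provenance=self.provenance,
        )


class ReferenceSequence:
    """Random-access reference with 1-based lookups over {A,C,G,T,N}."""

    _VALID = re.compile(r"[^ACGTN]")

    def __init__(self, sequences: Mapping[str, str]):
        self._seq: dict[str, str] = {}
        for name, seq in sequences.items():
            norm = normalize_chrom(name)
            if norm in self._seq:
                raise ReferenceError_(f"duplicate sequence name {name!r}")
            s = seq.upper()
            m = self._VALID.search(s)
            if m:
                raise ReferenceError_(
                    f"invalid base {m.group()!r} in {name} at position {m.start() + 1}"
                )
            self._seq[norm] = s

    @property
    def names(self) -> list[str]:
        return list(self._seq)

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seq.items()}

    def length(self, chrom: str) -> int:
        return len(self._get(chrom))

    def _get(self, chrom: str) -> str:
        norm = normalize_chrom(chrom)
        if norm not in self._seq:
            raise ReferenceError_(f"unknown sequence {chrom!r}")
        return self._seq[norm]

    def base(self, chrom: str, pos: int) -> str:
        seq = self._get(chrom)
        if not 1 <= pos <= len(seq):
            raise ReferenceError_(f"position {pos} out of range for {chrom} (1..{len(seq)})")
        return seq[pos - 1]

    def window(self, chrom: str, start: int, end: int) -> str:
        """Inclusive 1-based slice; errors if any part is out of range."""
        seq = self._get(chrom)
        if start < 1 or end > len(seq) or start > end:
            raise ReferenceError_(
                f"window {start}-{end} out of range for {chrom} (1..{len(seq)})"
            )
        return seq[start - 1 : end]

    def in_range(self, chrom: str, start: int, end: int) -> bool:
        seq = self._get(chrom)
        return start >= 1 and end <= len(seq) and start <= end

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seq.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_reference(path: str | Path) -> ReferenceSequence:
    """Load a FASTA into an in-memory :class:`ReferenceSequence`.

    Duplicate sequence names and non-ACGTN characters are errors.
    """
    try:
        fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    except ValueError as exc:
        raise ReferenceError_(f"cannot index {path}: {exc}") from exc
    try:
        return ReferenceSequence({name: str(fasta[name][:]) for name in fasta.keys()})
    finally:
        fasta.close()


def _sample_call_from_vcf(vcf_sample) -> tuple[Optional[SampleCall], bool]:
    """Build a SampleCall from a pysam sample; second value is True when GT
    was missing (caller skips the record)."""
    gt = vcf_sample.get("GT")
    if gt is None or any(a is None for a in gt) or len(gt) != 2:
        return None, True
    ad = vcf_sample.get("AD")
    ref_d = alt_d = None
    if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
        ref_d, alt_d = int(ad[0]), int(ad[1])
    gq = vcf_sample.get("GQ")
    return (
        SampleCall(
            genotype=tuple(gt),  # type: ignore[arg-type]
            ref_depth=ref_d,
            alt_depth=alt_d,
            gq=None if gq is None else int(gq),
        ),
        False,
    )


def read_trio_vcf(
    path: str | Path,
    role_map: Mapping[str, str],
    name: Optional[str] = None,
) -> CallSet:
    """Read a multi-sample VCF into a trio :class:`CallSet`.

    ``role_map`` maps VCF sample names to the roles ``father``, ``mother``
    and ``child``; all three roles must be covered by samples present in the
    header.  Only biallelic SNVs on autosomes are kept; everything else is
    counted in the returned call set's ``skip_log``.  Records lacking a
    called genotype in any role are skipped; records lacking AD are kept
    with missing depths.
    """
    roles_covered = set(role_map.values())
    if roles_covered != set(ROLES):
        raise ConfigurationError(
            f"role_map must cover exactly {ROLES}, got {sorted(roles_covered)}"
        )
    vcf = pysam.VariantFile(str(path))
    header_samples = set(vcf.header.samples)
    missing = [s for s in role_map if s not in header_samples]
    if missing:
        raise ConfigurationError(f"sample(s) {missing} not in VCF header of {path}")
    role_to_sample = {role: sample for sample, role in role_map.items()}

    skip = SkipLog()
    records: list[VariantRecord] = []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            skip.multiallelic += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if ref is None or len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            skip.non_snv += 1
            continue
        if not is_autosome(rec.chrom):
            skip.non_autosome += 1
            continue
        calls: dict[str, SampleCall] = {}
        missing_gt = False
        for role in ROLES:
            call, gt_missing = _sample_call_from_vcf(rec.samples[role_to_sample[role]])
            if gt_missing:
                missing_gt = True
                break
            calls[role] = call  # type: ignore[assignment]
        if missing_gt:
            skip.missing_genotype += 1
            log.debug("skipping %s:%s (missing genotype)", rec.chrom, rec.pos)
            continue
        records.append(
            VariantRecord(chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt, **calls)
        )
    vcf.close()
    cs = CallSet(
        name=name or Path(path).stem,
        records=records,
        provenance=str(path),
        skip_log=skip,
    )
    log.info(
        "read %d records from %s (%d skipped: %s)", len(cs), path, skip.total, skip
    )
    return cs


def extract_candidate_dnsnvs(callset: CallSet) -> CallSet:
    """Subset of records matching the de novo genotype pattern.

    Both parents homozygous reference (0/0) and the child carrying at least
    one alternate allele.  Child 1/1 calls are admitted (and flagged on VCF
    output) because a pipeline may emit them; records with a missing
    genotype in any role are excluded and counted.
    """
    skip = SkipLog()
    kept = []
    for r in callset:
        if any(r.sample(role).genotype is None for role in ROLES):
            skip.missing_genotype += 1
            continue
        if r.is_candidate_denovo():
            kept.append(r)
    return CallSet(
        name=callset.name, records=kept, provenance=callset.provenance, skip_log=skip
    )


_INFO_DEFS = [
    ("GCC", "1", "Float", "GC content (%) of the 100-base window centered on the variant"),
    ("SNVD", "1", "Float", "SNV density (%) in the 100-base window centered on the variant"),
    ("TITV_CLASS", "1", "String", "Substitution class: ti (transition) or tv (transversion)"),
    ("DNSCORE", "1", "Float", "Read-coverage de novo filter score (log10 scale)"),
]


def write_callset_vcf(
    callset: CallSet,
    path: str | Path,
    reference: Optional[ReferenceSequence] = None,
    annotations: Optional[Mapping[VariantKey, Mapping[str, object]]] = None,
    fail_keys: Optional[set[VariantKey]] = None,
    sample_names: Sequence[str] = ("FATHER", "MOTHER", "CHILD"),
) -> None:
    """Write a call set as an uncompressed VCF with GT, AD, GQ per sample.

    ``annotations`` maps variant keys to INFO values for the keys GCC, SNVD,
    TITV_CLASS and DNSCORE.  Records in ``fail_keys`` get the FILTER value
    ``DNSNV_FAIL``; others PASS.  Child homozygous-alt candidates carry the
    ``HOMALT_CHILD`` flag so users can exclude them.  ``read_trio_vcf`` on
    the output reproduces the call set's modelled fields.
    """
    header = pysam.VariantHeader()
    max_pos: dict[str, int] = {}
    for r in callset:
        max_pos[r.chrom] = max(max_pos.get(r.chrom, 0), r.pos)
    contigs = list(AUTOSOMES) if not max_pos or set(max_pos) <= _AUTOSOME_SET else sorted(
        max_pos, key=chrom_sort_key
    )
    for c in contigs:
        if reference is not None and c in {normalize_chrom(n) for n in reference.names}:
            length = reference.length(c)
        else:
            length = max(max_pos.get(c, 0) + 1000, 1000)
        header.contigs.add(c, length=length)
    for key, number, typ, desc in _INFO_DEFS:
        header.info.add(key, number, typ, desc)
    header.info.add("HOMALT_CHILD", 0, "Flag", "Child genotype is 1/1 for this candidate")
    header.filters.add("DNSNV_FAIL", None, None, "Rejected by the read-coverage de novo filter")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Read depths for ref and alt alleles")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in sample_names:
        header.add_sample(s)

    role_for_sample = dict(zip(sample_names, ROLES))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in callset:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos, alleles=(r.ref, r.alt)
            )
            if fail_keys is not None:
                rec.filter.add("DNSNV_FAIL" if r.key in fail_keys else "PASS")
            else:
                rec.filter.add("PASS")
            if annotations is not None and r.key in annotations:
                for k, v in annotations[r.key].items():
                    if v is not None:
                        rec.info[k] = v
            if r.child.genotype == (1, 1) and r.is_candidate_denovo():
                rec.info["HOMALT_CHILD"] = True
            for sname in sample_names:
                call = r.sample(role_for_sample[sname])
                rec.samples[sname]["GT"] = call.genotype if call.genotype else (None, None)
                rec.samples[sname].phased = False
                if call.has_depths:
                    rec.samples[sname]["AD"] = (call.ref_depth, call.alt_depth)
                if call.gq is not None:
                    rec.samples[sname]["GQ"] = call.gq
            out.write(rec)


DEFAULT_ROLE_MAP = {"FATHER": "father", "MOTHER": "mother", "CHILD": "child"}
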