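"""Shared fixtures: record factories, a tiny reference, and a simulated trio."""

from __future__ import annotations

import pytest

from dnsnvkit.core_model import CallSet, ReferenceSequence, SampleCall, VariantRecord
from dnsnvkit.synthetic_trio import (
    SyntheticTrioConfig,
    generate_reference,
    generate_trio,
)


def make_record(
    chrom="1",
    pos=100,
    ref="A",
    alt="G",
    father=(0, 0),
    mother=(0, 0),
    child=(0, 1),
    depths=None,
    gqs=None,
):
    """Build a VariantRecord with sensible defaults for tests.

    ``depths`` maps role -> (ref_depth, alt_depth); ``gqs`` maps role -> GQ.
    Default depths are clean: parents 20/0, child 10/10.
    """
    depths = depths or {"father": (20, 0), "mother": (20, 0), "child": (10, 10)}
    gqs = gqs or {}
    calls = {}
    for role, gt in (("father", father), ("mother", mother), ("child", child)):
        d = depths.get(role)
        calls[role] = SampleCall(
            genotype=gt,
            ref_depth=None if d is None else d[0],
            alt_depth=None if d is None else d[1],
            gq=gqs.get(role),
        )
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **calls)


def make_callset(records, name="test"):
    return CallSet(name=name, records=list(records))


# Cycle of substitutions so consecutive positions get valid distinct alleles.
_TI = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
_TV = [("A", "T"), ("A", "C"), ("G", "T"), ("G", "C"), ("C", "A"), ("C", "G"), ("T", "A"), ("T", "G")]


def build_titv_callset(n_ti, n_tv, name="titv", chrom="1", start=1000):
    """A call set with exactly the requested transition/transversion counts."""
    records = []
    pos = start
    for i in range(n_ti):
        ref, alt = _TI[i % len(_TI)]
        records.append(make_record(chrom=chrom, pos=pos, ref=ref, alt=alt))
        pos += 1
    for i in range(n_tv):
        ref, alt = _TV[i % len(_TV)]
        records.append(make_record(chrom=chrom, pos=pos, ref=ref, alt=alt))
        pos += 1
    return make_callset(records, name=name)


SMALL_CONFIG = SyntheticTrioConfig(
    n_chrom=4,
    chrom_length=20_000,
    gc_segments=((10_000, 0.4), (10_000, 0.6)),
    n_inherited=300,
    n_denovo=80,
    spurious_rate=0.10,
    seed=11,
)


RECOVERY_CONFIG = SyntheticTrioConfig(
    n_chrom=4,
    chrom_length=20_000,
    gc_segments=((10_000, 0.4), (10_000, 0.6)),
    n_inherited=300,
    n_denovo=300,
    spurious_rate=0.10,
    seed=17,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated trio with ground truth."""
    ref = generate_reference(SMALL_CONFIG)
    callset, truth = generate_trio(SMALL_CONFIG, ref)
    return SMALL_CONFIG, ref, callset, truth


@pytest.fixture(scope="session")
def recovery_sim():
    """A trio sized for parameter-recovery assertions (300 planted de novo)."""
    ref = generate_reference(RECOVERY_CONFIG)
    callset, truth = generate_trio(RECOVERY_CONFIG, ref)
    return RECOVERY_CONFIG, ref, callset, truth


@pytest.fixture(scope="session")
def toy_reference():
    return ReferenceSequence(
        {
            "1": "A" * 300,
            "2": "G" * 150 + "C" * 150,
            "3": "ACGT" * 100,
        }
    )
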