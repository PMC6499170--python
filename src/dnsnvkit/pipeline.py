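"""End-to-end reporting pipeline: landscape, filter and comparison bundles.

The two entry points mirror how a trio call-set evaluation is actually
run: :func:`run_landscape` characterises each input call set (candidate
counts, Ti/Tv, GC stratification, SNV-density distribution, catalog
overlap), and :func:`run_filter_and_compare` applies the read-coverage
filter, sweeps cutoffs, and compares the filtered sets across pipelines.
Every number in the emitted JSON bundles is produced by the underlying
module operations — this layer only orchestrates and serialises.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import callset_comparison as cmp
from . import context_metrics as ctx
from . import denovo_filter as flt
from .core_model import (
    CallSet,
    ReferenceSequence,
    VariantKey,
    extract_candidate_dnsnvs,
    read_reference,
    read_trio_vcf,
)

log = logging.getLogger(__name__)

try:
    __version__ = version("dnsnvkit")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


@dataclass(frozen=True)
class TrioInput:
    """One pipeline's trio VCF plus its sample-name → role mapping."""

    path: str
    role_map: Mapping[str, str]
    name: str


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the evaluation pipeline.

    The fixed constants of the method live here with their conventional
    defaults: a 100-base context window, a GC split at 50%, a score cutoff
    of 0 (the non-stringent log-unit boundary) and a cutoff sweep from −3
    to 3.
    """

    inputs: tuple[TrioInput, ...]
    reference_path: Optional[str] = None
    catalog_path: Optional[str] = None
    cutoff: float = 0.0
    gc_threshold: float = 50.0
    window: int = 100
    sweep_from: float = -3.0
    sweep_to: float = 3.0
    sweep_step: float = 0.5
    score_variant: str = flt.PRODUCT
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2:
            raise ValueError(f"window must be even and positive, got {self.window}")
        if not math.isfinite(self.cutoff):
            raise ValueError(f"cutoff must be finite, got {self.cutoff}")
        if self.sweep_step <= 0 or self.sweep_to < self.sweep_from:
            raise ValueError("sweep range must be ascending with positive step")

    def sweep_cutoffs(self) -> list[float]:
        n = int(round((self.sweep_to - self.sweep_from) / self.sweep_step)) + 1
        return [round(self.sweep_from + i * self.sweep_step, 10) for i in range(n)]

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "inputs": [[i.path, dict(i.role_map), i.name] for i in self.inputs],
                "reference": self.reference_path,
                "catalog": self.catalog_path,
                "cutoff": self.cutoff,
                "gc_threshold": self.gc_threshold,
                "window": self.window,
                "sweep": [self.sweep_from, self.sweep_to, self.sweep_step],
                "score_variant": self.score_variant,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig) -> list[CallSet]:
    callsets = []
    for inp in config.inputs:
        if not Path(inp.path).exists():
            raise FileNotFoundError(f"input VCF not found: {inp.path}")
        cs = read_trio_vcf(inp.path, inp.role_map, name=inp.name)
        log.info("loaded %s: %d records (skipped %d)", inp.name, len(cs),
                 cs.skip_log.total if cs.skip_log else 0)
        callsets.append(cs)
    return callsets


def _child_snv_positions(callset: CallSet) -> set[tuple[str, int]]:
    """Positions of all SNVs carried by the child in this pipeline's VCF —
    the density source set (de novo plus inherited)."""
    return {(r.chrom, r.pos) for r in callset if r.child.carries_alt}


def _titv_dict(s: ctx.TiTvSummary) -> dict:
    return {
        "n_transitions": s.n_transitions,
        "n_transversions": s.n_transversions,
        "ratio": s.ratio,
        "ratio_str": s.ratio_str,
    }


def _annotation_frame(
    callset: CallSet,
    annotations: Mapping[VariantKey, ctx.ContextAnnotation],
    scores: Optional[Mapping[VariantKey, flt.FilterScore]] = None,
) -> pd.DataFrame:
    rows = []
    for r in callset:
        a = annotations[r.key]
        row = {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gc_content": a.gc_content,
            "snv_density": a.snv_density,
            "class": "ti" if a.substitution_class == ctx.TRANSITION else "tv",
        }
        if scores is not None:
            row["score"] = scores[r.key].value
        rows.append(row)
    cols = ["chrom", "pos", "ref", "alt", "gc_content", "snv_density", "class"]
    if scores is not None:
        cols.append("score")
    return pd.DataFrame(rows, columns=cols)


DENSITY_EDGES = tuple(float(e) for e in range(1, 21))


def run_landscape(config: PipelineConfig) -> dict:
    """Characterise each input call set; write TSV tables and a JSON bundle.

    Per set: candidate DNSNV count, Ti/Tv, GC stratification at the
    configured threshold, the cumulative SNV-density distribution, and —
    when a catalog is configured — the overlap rate.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("dnsnvkit %s landscape, config %s", __version__, config.config_hash())

    reference = read_reference(config.reference_path) if config.reference_path else None
    catalog = (
        cmp.read_catalog_vcf(config.catalog_path) if config.catalog_path else None
    )
    bundle: dict = {"tool_version": __version__, "config_hash": config.config_hash(),
                    "sets": {}}
    for cs in _load_inputs(config):
        candidates = extract_candidate_dnsnvs(cs)
        density_set = _child_snv_positions(cs)
        ann = ctx.annotate_callset(
            candidates, reference=reference, snv_positions=density_set,
            window=config.window,
        )
        titv = ctx.titv_summary(candidates)
        entry: dict = {
            "n_input_records": len(cs),
            "n_candidates": len(candidates),
            "titv": _titv_dict(titv),
        }
        if reference is not None:
            strata = ctx.stratify_by_gc(candidates, ann, config.gc_threshold)
            entry["gc_strata"] = {
                "threshold": strata.threshold,
                "n_high": len(strata.high),
                "n_low": len(strata.low),
                "n_missing": len(strata.missing),
                "titv_high": _titv_dict(strata.high_titv),
                "titv_low": _titv_dict(strata.low_titv),
            }
        if len(candidates) > 0:
            densities = [ann[r.key].snv_density for r in candidates]
            fracs = ctx.density_cumulative(densities, DENSITY_EDGES)
            entry["density_cumulative"] = {
                "edges": list(DENSITY_EDGES),
                "fractions": fracs,
            }
        if catalog is not None and len(candidates) > 0:
            entry["catalog_overlap_pct"] = cmp.overlap_rate(candidates, catalog)
        frame = _annotation_frame(candidates, ann)
        frame.to_csv(outdir / f"{cs.name}_annotations.tsv", sep="\t", index=False)
        bundle["sets"][cs.name] = entry
        log.info("%s: %d candidates of %d records", cs.name, len(candidates), len(cs))

    _write_json(bundle, outdir / "landscape.json")
    return bundle


def run_filter_and_compare(config: PipelineConfig) -> dict:
    """Filter each candidate set at the configured cutoff and compare sets.

    Per set: pre/post-filter counts and Ti/Tv, the cutoff-sweep table and
    pre/post GQ summaries.  With ≥2 inputs, an overlap report over the
    filtered sets; with a catalog, pre/post overlap rates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("dnsnvkit %s filter+compare, config %s", __version__, config.config_hash())

    catalog = (
        cmp.read_catalog_vcf(config.catalog_path) if config.catalog_path else None
    )
    cutoffs = config.sweep_cutoffs()
    bundle: dict = {"tool_version": __version__, "config_hash": config.config_hash(),
                    "cutoff": config.cutoff, "score_variant": config.score_variant,
                    "sets": {}}
    filtered_sets: list[CallSet] = []
    sweep_rows = []
    for cs in _load_inputs(config):
        candidates = extract_candidate_dnsnvs(cs)
        kept, reasons = flt.filter_with_reasons(
            candidates, config.cutoff, config.score_variant
        )
        sweep = flt.cutoff_sweep(candidates, cutoffs, config.score_variant)
        entry = {
            "n_candidates": len(candidates),
            "n_kept": len(kept),
            "n_removed": len(candidates) - len(kept),
            "titv_before": _titv_dict(ctx.titv_summary(candidates)),
            "titv_after": _titv_dict(ctx.titv_summary(kept)),
            "sweep": {"cutoffs": list(sweep.cutoffs),
                      "kept_counts": list(sweep.kept_counts)},
            "gq_before": {role: s.to_dict() for role, s in cmp.gq_summary(candidates).items()},
            "gq_after": {role: s.to_dict() for role, s in cmp.gq_summary(kept).items()},
            "rejection_reasons": _reason_counts(reasons),
        }
        if catalog is not None and len(candidates) > 0 and len(kept) > 0:
            entry["catalog_overlap_pct_before"] = cmp.overlap_rate(candidates, catalog)
            entry["catalog_overlap_pct_after"] = cmp.overlap_rate(kept, catalog)
        bundle["sets"][cs.name] = entry
        filtered_sets.append(kept)
        for c, n in zip(sweep.cutoffs, sweep.kept_counts):
            sweep_rows.append({"set": cs.name, "cutoff": c, "kept": n})
        log.info("%s: kept %d of %d at cutoff %g", cs.name, len(kept),
                 len(candidates), config.cutoff)

    if len(filtered_sets) >= 2:
        report = cmp.intersect_callsets(filtered_sets)
        bundle["comparison"] = report.to_dict()
        bundle["per_chrom_counts"] = {
            cs.name: cmp.chromosomal_distribution(cs) for cs in filtered_sets
        }
    pd.DataFrame(sweep_rows, columns=["set", "cutoff", "kept"]).to_csv(
        outdir / "cutoff_sweep.tsv", sep="\t", index=False
    )
    _write_json(bundle, outdir / "filter_compare.json")
    return bundle


def _reason_counts(reasons: Mapping[VariantKey, str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for reason in reasons.values():
        out[reason] = out.get(reason, 0) + 1
    return dict(sorted(out.items()))


def _write_json(bundle: dict, path: Path) -> None:
    path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
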