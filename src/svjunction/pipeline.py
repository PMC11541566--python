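"""End-to-end pipeline orchestration and report assembly.

Stage order mirrors the analysis: filter -> coverage -> characterize ->
templates -> statistics. Output is a pure function of (input files, config,
seed); rerunning with the same configuration produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as svio
from .filtering import (
    FilterConfig,
    breakpoint_density,
    compute_coverage,
    filter_svs,
    sv_frequency,
)
from .junctions import SvCall, canonicalize_call, characterize_junction, molecule_order, orient_to_transcription
from .stats import compare_frequency, enrichment_by_size, junction_profile
from .templates import (
    build_query,
    classify_template,
    scan_templates,
    template_position_pileup,
    TemplateDataError,
)

logger = logging.getLogger("svjunction")

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, record: str, message: str):
        super().__init__(f"stage {stage}: record {record}: {message}")
        self.stage = stage
        self.record = record


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run; echoed verbatim into the
    output directory."""

    reference: str
    targets: str
    molecules: str
    calls: str
    manifest: str
    out_dir: str
    seed: int = 0
    window: int = 500
    contrasts: list = field(default_factory=list)   # [(group_ref, group_alt), ...]
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("reference", "targets", "molecules", "calls", "manifest"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["filter_config"] = dataclasses.asdict(self.filter_config)
        return json.dumps(d, indent=2, sort_keys=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle.

    Emits kept/rejected calls, coverage and density tracks, the per-SV
    template table and pileup, per-size enrichment, per-sample junction
    profiles, intergroup frequency comparisons, and a machine-readable run
    summary with per-stage record counts and a config hash.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(cfg.to_json() + "\n")
    config_hash = hashlib.sha256(cfg.to_json().encode()).hexdigest()[:16]

    reference_by_chrom = svio.read_fasta(cfg.reference)
    targets = svio.read_targets_bed(cfg.targets, default_pad=cfg.filter_config.pad)
    molecules = svio.read_molecules(cfg.molecules)
    calls = svio.read_calls(cfg.calls)
    samples = svio.read_manifest(cfg.manifest)
    summary: dict = {
        "config_hash": config_hash,
        "seed": cfg.seed,
        "counts": {
            "input_calls": len(calls),
            "input_molecules": len(molecules),
            "samples": len(samples),
        },
        "warnings": [],
    }
    logger.info("inputs: %d calls, %d molecules, %d samples",
                len(calls), len(molecules), len(samples))

    def ref_for(call: SvCall) -> str:
        try:
            return reference_by_chrom[call.bp1.chrom]
        except KeyError:
            raise StageError("characterize", call.id,
                             f"chromosome {call.bp1.chrom} absent from reference")

    # characterize: recompute offsets from molecule coordinates where
    # available, then canonicalize to maximal microhomology
    have_seq = all(c.molecule_seq for c in calls) and bool(calls)
    canon_calls: list[SvCall] = []
    for call in calls:
        if call.molecule_seq:
            first, second, _ = molecule_order(call)
            offset, inserted = characterize_junction(call.molecule_seq, first, second)
            if offset != call.offset:
                logger.warning("call %s: stated offset %d recomputed as %d",
                               call.id, call.offset, offset)
            call = dataclasses.replace(call, offset=offset, inserted_bases=inserted)
            call = canonicalize_call(call, ref_for(call))
        canon_calls.append(call)

    # filter
    kept, rejections = filter_svs(
        canon_calls, molecules, samples, targets, cfg.filter_config,
    )
    svio.write_tsv(out / "kept_calls.tsv", svio.calls_to_frame(kept))
    svio.write_tsv(out / "rejections.tsv", rejections)
    summary["counts"]["kept_calls"] = len(kept)
    summary["counts"]["rejected_calls"] = len(rejections)
    logger.info("filter: kept %d / rejected %d (conservation: %s)",
                len(kept), len(rejections),
                len(kept) + len(rejections) == len(calls))

    # coverage & frequency & density
    track = compute_coverage(molecules, targets, cfg.filter_config)
    svio.write_tsv(out / "coverage_bins.tsv", track.bins100)
    freq_rows = []
    for s in samples:
        sample_mols = [m for m in molecules if m.sample_id == s.sample_id]
        sample_track = compute_coverage(sample_mols, targets, cfg.filter_config)
        sample_kept = [c for c in kept if c.sample_id == s.sample_id]
        freq = (
            sv_frequency(sample_kept, sample_track).frequency
            if sample_track.fold > 0 else float("nan")
        )
        freq_rows.append(
            (s.sample_id, s.group, s.batch, len(sample_kept), sample_track.fold, freq)
        )
    freq_df = pd.DataFrame(
        freq_rows, columns=["sample", "group", "batch", "nSvs", "coverage", "frequency"]
    )
    svio.write_tsv(out / "sv_frequency.tsv", freq_df)
    density = breakpoint_density(kept, track)
    svio.write_tsv(out / "breakpoint_density.tsv", density)
    summary["counts"]["target_coverage_fold"] = track.fold

    # orientation to transcription for reporting
    oriented = []
    for c in kept:
        t = next((t for t in targets if t.padded_contains(c.bp1.chrom, c.bp1.ref_pos)
                  or t.padded_contains(c.bp2.chrom, c.bp2.ref_pos)), None)
        oriented.append(orient_to_transcription(c, t) if t is not None else c)

    # template discovery on insertion junctions
    template_rows = []
    hits, hit_calls = [], []
    ins_calls = [c for c in oriented if c.offset >= 1]
    if have_seq:
        for call in ins_calls:
            try:
                query = build_query(call)
            except TemplateDataError as exc:
                summary["warnings"].append(str(exc))
                continue
            result = scan_templates(query, ref_for(call), call, window=cfg.window)
            sel = result.selected_hit
            if sel is not None:
                classify_template(sel, call)
                hits.append(sel)
                hit_calls.append(call)
            template_rows.append(
                (call.id, call.offset, query.n_template_bases, result.n_candidates,
                 sel.breakpoint_index if sel else "",
                 sel.strand if sel else "",
                 sel.ref_start if sel else "", sel.ref_end if sel else "",
                 sel.distance_to_junction if sel else "",
                 sel.priming_mh if sel else "", sel.resolving_mh if sel else "",
                 sel.total_span if sel else "",
                 sel.template_class if sel else "")
            )
        template_df = pd.DataFrame(
            template_rows,
            columns=["svId", "insertSize", "nTemplateBases", "nCandidates",
                     "breakpoint", "strand", "refStart", "refEnd", "distance",
                     "primingMh", "resolvingMh", "totalSpan", "class"],
        )
        svio.write_tsv(out / "templates.tsv", template_df)
        pileup = template_position_pileup(hits, hit_calls)
        svio.write_tsv(out / "template_pileup.tsv", pileup)
        summary["counts"]["insertion_calls_searched"] = len(template_rows)
        summary["counts"]["templates_found"] = len(hits)

        # enrichment per insertion size
        if template_rows:
            enrich = enrichment_by_size(
                insert_sizes=template_df["insertSize"],
                found=template_df["class"] != "",
                n_template_bases=template_df["nTemplateBases"],
                search_space=4 * cfg.window * 2,
            )
            svio.write_tsv(out / "enrichment.tsv", enrich)
    else:
        msg = "moleculeSeq unavailable: template discovery and enrichment skipped"
        logger.warning(msg)
        summary["warnings"].append(msg)

    # per-sample junction profiles
    prof_rows = []
    for s in samples:
        offs = [c.offset for c in kept if c.sample_id == s.sample_id]
        prof = junction_profile(offs)
        prof_rows.append(
            (s.sample_id, s.group, prof.n_junctions,
             prof.mean_mh_no_insertion, prof.frac_insertion_2to15)
        )
    prof_df = pd.DataFrame(
        prof_rows,
        columns=["sample", "group", "nJunctions", "meanMhNoInsertion",
                 "fracInsertion2to15"],
    )
    svio.write_tsv(out / "junction_profiles.tsv", prof_df)

    # intergroup frequency comparisons
    contrasts = list(cfg.contrasts)
    if not contrasts:
        groups = sorted({s.group for s in samples})
        if len(groups) == 2:
            contrasts = [(groups[0], groups[1])]
    comp_rows = []
    for ref_g, alt_g in contrasts:
        sub = freq_df[freq_df["group"].isin([ref_g, alt_g])]
        comp = compare_frequency(
            sub["nSvs"], sub["coverage"], sub["group"], sub["batch"],
            group_ref=ref_g, group_alt=alt_g,
        )
        comp_rows.append(
            (ref_g, alt_g, comp.log_rate_ratio, comp.std_err, comp.rate_ratio,
             comp.p_value, comp.model_used, comp.dispersion,
             int(comp.batch_dropped), int(comp.zero_count_group))
        )
    comp_df = pd.DataFrame(
        comp_rows,
        columns=["groupRef", "groupAlt", "logRateRatio", "stdErr", "rateRatio",
                 "pValue", "modelUsed", "dispersion", "batchDropped",
                 "zeroCountGroup"],
    )
    svio.write_tsv(out / "frequency_comparisons.tsv", comp_df)
    summary["counts"]["contrasts"] = len(comp_rows)

    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
    )
    return summary
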