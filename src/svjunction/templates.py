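"""Insertion-template discovery and classification near SV breakpoints.

De novo insertions at end-joining junctions are often copied from reference
sequence near the breakpoints (the theta-mediated end-joining signature). The
search takes the inserted bases plus flanking microhomology as an exact-match
query, scans 500 bp on each side of both breakpoints on both strands (4 kb of
sequence), maximally extends the flanking microhomologies of every match, and
classifies the selected template by strand and retained/lost placement:

* foldback / palindrome — bottom strand, fully retained sequence;
* cross-junction       — top strand, fully retained;
* strand-switching     — bottom strand, at least partly in lost sequence;
* expansion            — top strand, crossing from retained into lost.

"Top" strand means the template reads the same as the junction molecule on
the reference forward strand; "bottom" means it matches the reverse
complement. Retained/lost is defined relative to alignment breakpoints: for a
deletion, retained sequence lies outside the deleted interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .junctions import SvCall, molecule_order, revcomp, comp

__all__ = [
    "TemplateQuery",
    "TemplateHit",
    "TemplateSearchResult",
    "NotAnInsertionError",
    "TemplateDataError",
    "build_query",
    "scan_templates",
    "select_template",
    "classify_template",
    "template_position_pileup",
    "modal_distance_by_class",
    "flank_per_side",
]

TEMPLATE_CLASSES = (
    "foldback", "palindrome", "cross_junction",
    "strand_switching", "expansion", "unclassified",
)


class NotAnInsertionError(ValueError):
    """Template queries are defined only for insertion junctions (offset >= 1)."""


class TemplateDataError(ValueError):
    """Molecule sequence missing or too short to build the query."""


def flank_per_side(insert_size: int) -> int:
    """Initial flanking-microhomology bases required per side.

    The query must total at least seven bases with at least one base of
    flanking homology per side: a 1 bp insertion uses 3 bp flanks, a 4 bp
    insertion 2 bp, and insertions >= 5 bp a single base. Odd shortfalls are
    split by ceiling on both sides.
    """
    return max(1, math.ceil((7 - insert_size) / 2))


@dataclass(frozen=True)
class TemplateQuery:
    """Exact-match template query for one insertion junction.

    ``query_seq`` is the last ``flank_per_side`` retained bases upstream of
    the insertion, the inserted bases, and the first ``flank_per_side``
    retained bases downstream, as they appear in the molecule. The molecule
    context beyond the flanks drives maximal extension of matches.
    """

    insert_size: int
    flank_per_side: int
    query_seq: str
    up_context: str    # molecule bases upstream of the query, junction-proximal last
    down_context: str  # molecule bases downstream of the query

    @property
    def n_template_bases(self) -> int:
        return len(self.query_seq)


@dataclass
class TemplateHit:
    """One candidate insertion template, maximally extended.

    ``distance_to_junction`` is the signed distance of the template base
    nearest its breakpoint: negative into retained sequence, positive into
    lost, 0 when the template crosses the breakpoint. ``priming_mh`` /
    ``resolving_mh`` are the flanking microhomology lengths after maximal
    extension (``>= flank_per_side`` by construction).
    """

    breakpoint_index: int           # 1 or 2
    strand: str                     # "top" | "bottom"
    ref_start: int
    ref_end: int
    distance_to_junction: int
    priming_mh: int
    resolving_mh: int
    total_span: int
    n_retained: int
    n_lost: int
    template_seq: str
    template_class: str = "unclassified"
    low_confidence: bool = False
    priming_capped: bool = False    # extension stopped at a context/window boundary
    resolving_capped: bool = False


@dataclass
class TemplateSearchResult:
    all_hits: list[TemplateHit] = field(default_factory=list)
    selected_hit: Optional[TemplateHit] = None
    search_space: int = 4000
    truncated: bool = False  # a window was clipped by a contig edge

    @property
    def n_candidates(self) -> int:
        return len(self.all_hits)


def build_query(call: SvCall) -> TemplateQuery:
    """Build the template query for an insertion junction from its molecule
    sequence (errors if the call is not an insertion or lacks sequence)."""
    if call.offset < 1:
        raise NotAnInsertionError(f"call {call.id} has offset {call.offset}")
    if not call.molecule_seq:
        raise TemplateDataError(f"call {call.id} lacks a molecule sequence")
    first, second, _ = molecule_order(call)
    a, b = first.molecule_pos, second.molecule_pos
    s = call.offset
    f = flank_per_side(s)
    mol = call.molecule_seq
    if a - f < 0 or b - 1 + f > len(mol):
        raise TemplateDataError(
            f"call {call.id}: molecule too short for {f} bp flanks"
        )
    query = mol[a - f : b - 1 + f]
    return TemplateQuery(
        insert_size=s,
        flank_per_side=f,
        query_seq=query,
        up_context=mol[: a - f],
        down_context=mol[b - 1 + f :],
    )


# Direction in which retained sequence lies from each breakpoint, by SV type:
# -1 means retained positions are <= the breakpoint, +1 means >=.
_RETAINED_DIR = {
    "DEL": {1: -1, 2: +1},
    "DUP": {1: +1, 2: -1},
    "INV": {1: -1, 2: -1},
}


def _signed_distance(pos: int, center: int, retained_dir: int) -> int:
    """Signed distance of one reference base from a breakpoint: <= 0 in
    retained sequence, > 0 in lost."""
    return (pos - center) if retained_dir == -1 else (center - pos)


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_templates(
    query: TemplateQuery,
    reference: str,
    call: SvCall,
    window: int = 500,
) -> TemplateSearchResult:
    """Find and maximally extend every exact match of the query within
    ``window`` bp of both breakpoints on both strands.

    Each match's flanking microhomologies are extended base by base, stopping
    just before the first mismatch between the junction molecule and the
    template neighborhood (or at a window/context boundary, flagged on the
    hit). Distinct maximal hits are deduplicated on (breakpoint, strand,
    extended span).
    """
    n = query.n_template_bases
    f = query.flank_per_side
    q = query.query_seq
    qrc = revcomp(q)
    up, down = query.up_context, query.down_context
    L = len(reference)
    sv_dirs = _RETAINED_DIR.get(call.sv_type, _RETAINED_DIR["DEL"])

    result = TemplateSearchResult(search_space=4 * window * 2)
    seen: set[tuple] = set()

    for bp_index, bp in ((1, call.bp1), (2, call.bp2)):
        center = bp.ref_pos
        lo = max(1, center - window)
        hi = min(L, center + window)
        if lo > center - window or hi < center + window:
            result.truncated = True
        region = reference[lo - 1 : hi]
        rdir = sv_dirs[bp_index]

        for strand, needle in (("top", q), ("bottom", qrc)):
            for i in _find_all(region, needle):
                t = lo + i            # 1-based ref start of the raw match
                t_end = t + n - 1
                if strand == "top":
                    # priming extension: molecule upstream vs ref before match
                    e_up = 0
                    while e_up < window:
                        j = e_up + 1
                        if j > len(up) or t - j < 1:
                            break
                        mb = up[-j]
                        rb = reference[t - j - 1]
                        if rb not in "ACGT" or mb != rb:
                            break
                        e_up += 1
                    up_capped = e_up < window and (e_up + 1 > len(up) or t - e_up - 1 < 1)
                    e_dn = 0
                    while e_dn < window:
                        j = e_dn + 1
                        if j > len(down) or t_end + j > L:
                            break
                        mb = down[j - 1]
                        rb = reference[t_end + j - 1]
                        if rb not in "ACGT" or mb != rb:
                            break
                        e_dn += 1
                    dn_capped = e_dn < window and (e_dn + 1 > len(down) or t_end + e_dn + 1 > L)
                    ref_start, ref_end = t - e_up, t_end + e_dn
                else:
                    # bottom strand: the template reads right-to-left on the
                    # reference; upstream molecule context extends past the
                    # match's right edge, downstream past its left edge.
                    e_up = 0
                    while e_up < window:
                        j = e_up + 1
                        if j > len(up) or t_end + j > L:
                            break
                        mb = up[-j]
                        rb = reference[t_end + j - 1]
                        if rb not in "ACGT" or mb != comp(rb):
                            break
                        e_up += 1
                    up_capped = e_up < window and (e_up + 1 > len(up) or t_end + e_up + 1 > L)
                    e_dn = 0
                    while e_dn < window:
                        j = e_dn + 1
                        if j > len(down) or t - j < 1:
                            break
                        mb = down[j - 1]
                        rb = reference[t - j - 1]
                        if rb not in "ACGT" or mb != comp(rb):
                            break
                        e_dn += 1
                    dn_capped = e_dn < window and (e_dn + 1 > len(down) or t - e_dn - 1 < 1)
                    ref_start, ref_end = t - e_dn, t_end + e_up

                key = (bp_index, strand, ref_start, ref_end)
                if key in seen:
                    continue
                seen.add(key)

                d_start = _signed_distance(ref_start, center, rdir)
                d_end = _signed_distance(ref_end, center, rdir)
                d_lo, d_hi = min(d_start, d_end), max(d_start, d_end)
                span_len = ref_end - ref_start + 1
                if d_lo <= 0 <= d_hi and d_lo < 0 < d_hi:
                    distance = 0
                elif d_hi <= 0:
                    distance = d_hi
                else:
                    distance = d_lo if d_lo > 0 else 0
                n_retained = sum(
                    1 for x in range(ref_start, ref_end + 1)
                    if _signed_distance(x, center, rdir) <= 0
                )
                tmpl = reference[ref_start - 1 : ref_end]
                if strand == "bottom":
                    tmpl = revcomp(tmpl)
                result.all_hits.append(
                    TemplateHit(
                        breakpoint_index=bp_index,
                        strand=strand,
                        ref_start=ref_start,
                        ref_end=ref_end,
                        distance_to_junction=distance,
                        priming_mh=f + e_up,
                        resolving_mh=f + e_dn,
                        total_span=span_len,
                        n_retained=n_retained,
                        n_lost=span_len - n_retained,
                        template_seq=tmpl,
                        priming_capped=up_capped,
                        resolving_capped=dn_capped,
                    )
                )

    result.selected_hit = select_template(result)
    return result


def select_template(result: TemplateSearchResult) -> Optional[TemplateHit]:
    """Select the preferred template: longest total span (including flanking
    microhomologies), then closest to the junction, then a deterministic
    fallback (breakpoint 1 before 2, top before bottom, leftmost start)."""
    if not result.all_hits:
        return None
    return min(
        result.all_hits,
        key=lambda h: (
            -h.total_span,
            abs(h.distance_to_junction),
            h.breakpoint_index,
            0 if h.strand == "top" else 1,
            h.ref_start,
        ),
    )


def classify_template(hit: TemplateHit, call: SvCall) -> str:
    """Assign the template class from strand and retained/lost placement and
    record it on the hit.

    A foldback whose extended template equals its own reverse complement is
    subclassified palindrome. Top-strand hits fully within lost sequence are
    left unclassified (flagged low confidence). For non-deletion SV types the
    retained/lost geometry is an extrapolation of the deletion diagram, so
    classes other than cross_junction carry a low-confidence flag.
    """
    if hit.strand == "bottom":
        if hit.n_lost == 0:
            cls = "foldback"
            if hit.template_seq == revcomp(hit.template_seq):
                cls = "palindrome"
        else:
            cls = "strand_switching"
    else:
        if hit.n_lost == 0:
            cls = "cross_junction"
        elif hit.n_retained > 0:
            cls = "expansion"
        else:
            cls = "unclassified"
    hit.template_class = cls
    if call.sv_type != "DEL" and cls != "cross_junction":
        hit.low_confidence = True
    if cls == "unclassified":
        hit.low_confidence = True
    return cls


def _oriented_side(hit: TemplateHit, call: SvCall) -> str:
    """Breakpoint side label ('left'/'right') in the reporting frame; flipped
    when the call is viewed in '-' transcription orientation."""
    idx = hit.breakpoint_index
    if call.oriented:
        idx = 3 - idx
    return "left" if idx == 1 else "right"


def template_position_pileup(
    hits: Sequence[TemplateHit],
    calls: Sequence[SvCall],
) -> pd.DataFrame:
    """Per-base histogram of template-contributing positions by class and
    breakpoint side, in signed distances from the breakpoint (negative into
    retained sequence)."""
    rows: dict[tuple, int] = {}
    for hit, call in zip(hits, calls):
        center = (call.bp1 if hit.breakpoint_index == 1 else call.bp2).ref_pos
        rdir = _RETAINED_DIR.get(call.sv_type, _RETAINED_DIR["DEL"])[hit.breakpoint_index]
        side = _oriented_side(hit, call)
        for x in range(hit.ref_start, hit.ref_end + 1):
            d = _signed_distance(x, center, rdir)
            key = (hit.template_class, side, d)
            rows[key] = rows.get(key, 0) + 1
    if not rows:
        return pd.DataFrame(columns=["template_class", "side", "distance", "count"])
    df = pd.DataFrame(
        [(c, s, d, n) for (c, s, d), n in rows.items()],
        columns=["template_class", "side", "distance", "count"],
    )
    return df.sort_values(["template_class", "side", "distance"]).reset_index(drop=True)


def modal_distance_by_class(pileup: pd.DataFrame) -> dict[str, int]:
    """Modal template-base distance per class (ties broken toward the
    junction); supports the foldback-vs-cross-junction offset statistic."""
    out: dict[str, int] = {}
    for cls, sub in pileup.groupby("template_class"):
        agg = sub.groupby("distance")["count"].sum()
        best = agg[agg == agg.max()]
        out[str(cls)] = int(min(best.index, key=abs))
    return out
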