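"""Synthetic SV-junction cohort generator with known mechanism truth.

The generator emulates the output schema of a single-molecule capture
sequencing pipeline — on-target source molecules with read-pair counts and
mapping qualities, plus de novo SV calls with dual-coordinate breakpoints —
so every downstream stage (filtering, coverage, junction characterization,
template discovery, statistics) can be verified against planted truth without
sequencing data.

Junction mechanisms are planted by *editing* the reference so that declared
microhomologies and insertion templates genuinely exist and are maximal (the
base beyond each planted homology mismatches by construction). Per-sample SV
counts are overdispersed (negative binomial around rate x coverage), molecule
read-pair support and mapping qualities include a configurable failing
fraction so the filters are exercised, and all randomness flows from a single
seed (outputs are byte-identical per configuration).

Three mechanism presets mirror distinct repair regimes: ``TMEJ`` (modal 2 bp
microhomology, ~25% insertions, locally templated inserts), ``NHEJ_like``
(blunt-heavy, short microhomology, few insertions), and ``POLQ_KO`` (modal
1 bp microhomology, near absence of insertions >= 3 bp).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .junctions import (
    Breakpoint,
    Sample,
    SourceMolecule,
    SvCall,
    TargetRegion,
    characterize_junction,
    canonicalize_offset,
    comp,
    molecule_order,
    revcomp,
)
from .templates import flank_per_side

__all__ = [
    "SimConfig",
    "JunctionPlan",
    "PlantedJunction",
    "CohortData",
    "SizingError",
    "PlantError",
    "make_reference",
    "plant_junction",
    "simulate_cohort",
    "simulate_junction_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MECHANISMS = ("microhomology", "blunt", "insertion")
TEMPLATE_PLANT_CLASSES = ("foldback", "cross_junction", "strand_switching", "expansion")


class SizingError(ValueError):
    """Genome too small for the maximum SV size plus search windows."""


class PlantError(RuntimeError):
    """A junction could not be planted consistently within bounded retries."""


def _norm(d: dict) -> dict:
    total = float(sum(d.values()))
    return {k: v / total for k, v in d.items()}


@dataclass
class SimConfig:
    """Full description of a simulated cohort; the seed determines every
    output byte.

    Probability vectors must sum to 1 within 1e-9. ``sv_rate_per_haplotype``
    maps group label -> expected de novo SVs per covered target haplotype;
    per-sample counts are NB(rate x coverage, theta). Mechanism and length
    distributions default to the TMEJ regime (microhomology peak at 2 bp,
    ~25% insertions, templates within ~20 bp of breakpoints, priming and
    resolving microhomologies peaking at 2–3 bp).
    """

    seed: int = 0
    genome_length: int = 4_000_000
    target: tuple[int, int] = (1_925_001, 2_075_000)   # 1-based inclusive
    n_samples_per_group: int = 6
    groups: tuple[str, ...] = ("A", "B")
    batches: tuple[str, ...] = ("b1", "b2")
    mean_coverage: float = 60.0
    sv_rate_per_haplotype: dict = field(default_factory=lambda: {"A": 0.1, "B": 0.5})
    dispersion_theta: float = 10.0
    mechanism_mix: dict = field(
        default_factory=lambda: {"microhomology": 0.62, "blunt": 0.13, "insertion": 0.25}
    )
    mh_length_dist: dict = field(
        default_factory=lambda: {
            1: 0.22, 2: 0.34, 3: 0.18, 4: 0.10, 5: 0.06,
            6: 0.04, 7: 0.025, 8: 0.015, 9: 0.01, 10: 0.01,
        }
    )
    insertion_size_dist: dict = field(
        default_factory=lambda: _norm({k: 0.75 ** k for k in range(1, 21)})
    )
    templated_fraction: float = 0.36
    template_class_mix: dict = field(
        default_factory=lambda: {
            "foldback": 0.45, "cross_junction": 0.40,
            "strand_switching": 0.05, "expansion": 0.10,
        }
    )
    template_distance_dist: dict = field(
        default_factory=lambda: _norm({k: math.exp(-k / 9.0) for k in range(0, 51)})
    )
    priming_resolving_mh_dist: dict = field(
        default_factory=lambda: {1: 0.15, 2: 0.30, 3: 0.30, 4: 0.15, 5: 0.10}
    )
    sv_size_median: float = 200_000.0
    sv_size_log_sigma: float = 0.8
    sv_size_range: tuple[int, int] = (10_000, 1_200_000)
    sv_type_mix: dict = field(
        default_factory=lambda: {"DEL": 0.90, "DUP": 0.05, "INV": 0.05}
    )
    mode: str = "TMEJ"
    pad: int = 800_000
    molecule_length_range: tuple[int, int] = (300, 600)
    frac_low_support: float = 0.04    # molecules with < 3 read pairs
    frac_low_mapq: float = 0.03
    transcription_strand: str = "+"

    def __post_init__(self) -> None:
        for name in (
            "mechanism_mix", "mh_length_dist", "insertion_size_dist",
            "template_class_mix", "template_distance_dist",
            "priming_resolving_mh_dist", "sv_type_mix",
        ):
            d = getattr(self, name)
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        lo, hi = self.target
        max_size = self.sv_size_range[1]
        if self.genome_length < 2 * (max_size + 500) + (hi - lo + 1):
            raise SizingError(
                "genome too small for the maximum SV size plus search windows"
            )
        if self.n_samples_per_group < 1 or not self.groups:
            raise ValueError("need at least one sample in at least one group")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "SimConfig":
        """Preset mechanism mixes for the three repair regimes."""
        if mode == "TMEJ":
            return cls(mode="TMEJ", **overrides)
        if mode == "NHEJ_like":
            return cls(
                mode="NHEJ_like",
                mechanism_mix={"microhomology": 0.50, "blunt": 0.44, "insertion": 0.06},
                mh_length_dist=_norm({1: 0.50, 2: 0.26, 3: 0.13, 4: 0.07, 5: 0.04}),
                insertion_size_dist=_norm({1: 0.70, 2: 0.20, 3: 0.07, 4: 0.03}),
                templated_fraction=0.05,
                **overrides,
            )
        if mode == "POLQ_KO":
            return cls(
                mode="POLQ_KO",
                mechanism_mix={"microhomology": 0.74, "blunt": 0.23, "insertion": 0.03},
                mh_length_dist=_norm({1: 0.48, 2: 0.26, 3: 0.13, 4: 0.07, 5: 0.04, 6: 0.02}),
                insertion_size_dist=_norm({1: 0.80, 2: 0.15, 3: 0.05}),
                templated_fraction=0.0,
                **overrides,
            )
        raise ValueError(f"unknown mode {mode!r}")

    def target_region(self, chrom: str = "chr1") -> TargetRegion:
        return TargetRegion(
            name="target1",
            chrom=chrom,
            capture_start=self.target[0],
            capture_end=self.target[1],
            pad=self.pad,
            transcription_strand=self.transcription_strand,
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def make_reference(seed: int, genome_length: int = 4_000_000) -> str:
    """Uniform-random uppercase A/C/G/T reference; deterministic per seed."""
    if genome_length < 2 * (1_200_000 + 500):
        raise SizingError(
            "genome too small for the maximum SV size plus search windows"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=genome_length)
    return _BASES[idx].tobytes().decode("ascii")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


@dataclass
class JunctionPlan:
    """Mechanism parameters for one planted junction."""

    sv_id: str
    sample_id: str
    sv_type: str
    p1: int
    size: int
    mechanism: str
    mh_len: int = 0
    insert_size: int = 0
    templated: bool = False
    template_class: Optional[str] = None
    template_side: int = 1
    template_distance: int = 5
    priming_mh: int = 2
    resolving_mh: int = 2
    mol_left: int = 220
    mol_right: int = 220
    read_pair_count: int = 5
    mapq1: int = 60
    mapq2: int = 60


@dataclass
class PlantedJunction:
    call: SvCall
    molecule: SourceMolecule
    truth: dict
    reference: Optional[str] = None  # set by simulate_junction_set


class _Ref:
    """1-based mutable reference with edit tracking."""

    def __init__(self, seq: bytearray):
        self.seq = seq
        self.edits: set[int] = set()

    def get(self, pos: int) -> str:
        return chr(self.seq[pos - 1])

    def set(self, pos: int, base: str) -> None:
        self.seq[pos - 1] = ord(base)
        self.edits.add(pos)

    def slice(self, start: int, end: int) -> str:
        return self.seq[start - 1 : end].decode("ascii")

    def set_slice(self, start: int, s: str) -> None:
        self.seq[start - 1 : start - 1 + len(s)] = s.encode("ascii")
        self.edits.update(range(start, start + len(s)))


def plant_junction(
    ref: _Ref | bytearray, plan: JunctionPlan, rng: np.random.Generator,
    chrom: str = "chr1",
) -> PlantedJunction:
    """Edit the reference so the planned junction genuinely exists, then emit
    the SV call, its source molecule, and the truth record.

    For microhomology junctions the second breakpoint flank is rewritten to
    match the first so the planted overlap is real and MAXIMAL (the next base
    on each side is forced to mismatch). Templated insertions copy the insert
    plus planted priming/resolving microhomologies into the reference at the
    planned class geometry (reverse complement for bottom-strand classes).
    Expansion insertions are planted as perfect two-unit direct repeats
    crossing the breakpoint, gaining a third unit in the junction. An internal
    consistency check re-characterizes the emitted molecule against the
    planted offset.
    """
    if isinstance(ref, bytearray):
        ref = _Ref(ref)
    p1 = plan.p1
    p2 = p1 + plan.size
    sv_type = plan.sv_type
    if sv_type == "DUP":
        pf, ps = p2, p1
    else:
        pf, ps = p1, p2
    inv = sv_type == "INV"

    def mol_first(k: int) -> str:
        return ref.get(pf - k)

    def mol_second(k: int) -> str:
        return comp(ref.get(ps - k)) if inv else ref.get(ps + k)

    def set_second(k: int, c: str) -> None:
        if inv:
            ref.set(ps - k, comp(c))
        else:
            ref.set(ps + k, c)

    def ext2(j: int) -> str:
        return comp(ref.get(ps + j)) if inv else ref.get(ps - j)

    def set_ext2(j: int, c: str) -> None:
        if inv:
            ref.set(ps + j, comp(c))
        else:
            ref.set(ps - j, c)

    mech = plan.mechanism
    m = plan.mh_len if mech == "microhomology" else 0
    s = plan.insert_size if mech == "insertion" else 0
    insert = ""
    truth: dict = {
        "sv_id": plan.sv_id,
        "sample": plan.sample_id,
        "sv_type": sv_type,
        "mechanism": mech,
        "mh_len": m,
        "insert_size": s,
        "inserted_bases": "",
        "offset": (-m if mech == "microhomology" else s),
        "templated": False,
        "template_class": "",
        "template_side": 0,
        "template_strand": "",
        "template_ref_start": 0,
        "template_ref_end": 0,
        "priming_mh": 0,
        "resolving_mh": 0,
        "template_distance": 0,
    }

    if mech == "blunt":
        if ext2(1) == mol_first(0):
            set_ext2(1, _other_base(rng, mol_first(0)))
        if ref.get(pf + 1) == mol_second(0):
            ref.set(pf + 1, _other_base(rng, mol_second(0)))
    elif mech == "microhomology":
        if m < 1:
            raise PlantError("microhomology junction needs mh_len >= 1")
        for k in range(m):
            set_second(k, mol_first(m - 1 - k))
        if ext2(1) == mol_first(m):
            set_ext2(1, _other_base(rng, mol_first(m)))
        if ref.get(pf + 1) == mol_second(m):
            ref.set(pf + 1, _other_base(rng, mol_second(m)))
    elif mech == "insertion":
        if s < 1:
            raise PlantError("insertion junction needs insert_size >= 1")
        if plan.templated and plan.template_class == "expansion" and sv_type == "DEL":
            insert = _plant_expansion(ref, plan, p1, p2, rng, truth)
        else:
            insert = _draw_insert(ref, rng, s, pf, ext2)
            if plan.templated and sv_type == "DEL":
                _plant_template(ref, plan, p1, p2, insert, rng, truth, mol_first, mol_second)
        truth["inserted_bases"] = insert
    else:
        raise PlantError(f"unknown mechanism {mech!r}")

    # emit the source molecule carrying the junction
    l1, l2 = plan.mol_left, plan.mol_right
    first_part = ref.slice(pf - l1 + 1, pf)
    if inv:
        tail = revcomp(ref.slice(ps - l2 + 1, ps - m))
    else:
        tail = ref.slice(ps + m, ps + l2 - 1)
    mol_seq = first_part + insert + tail
    a = l1
    b = l1 - m + 1 if mech == "microhomology" else (l1 + s + 1)
    offset = b - a - 1

    first_bp = Breakpoint(chrom, pf, a, "left" if pf == p1 else "right")
    second_bp = Breakpoint(chrom, ps, b, "left" if ps == p1 else "right")
    bp1, bp2 = (second_bp, first_bp) if sv_type == "DUP" else (first_bp, second_bp)

    if sv_type == "DUP":
        outer_start, outer_end = p1, p2
    elif inv:
        outer_start, outer_end = p1 - l1 + 1, p2
    else:
        outer_start, outer_end = p1 - l1 + 1, p2 + l2 - 1

    molecule = SourceMolecule(
        molecule_id=f"m_{plan.sv_id}",
        sample_id=plan.sample_id,
        chrom=chrom,
        outer_start=outer_start,
        outer_end=outer_end,
        read_pair_count=plan.read_pair_count,
        mapq1=plan.mapq1,
        mapq2=plan.mapq2,
        carries_sv=True,
    )
    call = SvCall(
        id=plan.sv_id,
        sample_id=plan.sample_id,
        sv_type=sv_type,
        bp1=bp1,
        bp2=bp2,
        offset=offset,
        inserted_bases=insert,
        molecule_id=molecule.molecule_id,
        molecule_seq=mol_seq,
    )

    # internal consistency checks: round-trip offset and maximality
    fst, snd, _ = molecule_order(call)
    got_offset, got_ins = characterize_junction(mol_seq, fst, snd)
    if got_offset != truth["offset"] or got_ins != insert:
        raise PlantError(
            f"{plan.sv_id}: planted offset {truth['offset']} not recovered "
            f"(got {got_offset})"
        )
    if offset <= 0:
        ref_str = ref.slice(1, len(ref.seq))
        canon_off, _, _, _ = canonicalize_offset(
            mol_seq, ref_str, bp1, bp2, sv_type
        )
        if canon_off != offset:
            raise PlantError(
                f"{plan.sv_id}: planted homology not maximal "
                f"({offset} canonicalizes to {canon_off})"
            )
    return PlantedJunction(call=call, molecule=molecule, truth=truth)


def _draw_insert(ref: _Ref, rng: np.random.Generator, s: int, pf: int, ext2) -> str:
    """Random inserted bases whose seam bases cannot extend either alignment
    (first base differs from the next reference base of segment 1, last base
    from the previous reference base of segment 2)."""
    left_block = ref.get(pf + 1)
    right_block = ext2(1)
    insert = list(_random_seq(rng, s))
    if s == 1:
        insert[0] = _other_base(rng, left_block, right_block)
    else:
        if insert[0] == left_block:
            insert[0] = _other_base(rng, left_block)
        if insert[-1] == right_block:
            insert[-1] = _other_base(rng, right_block)
    return "".join(insert)


def _plant_template(
    ref: _Ref,
    plan: JunctionPlan,
    p1: int,
    p2: int,
    insert: str,
    rng: np.random.Generator,
    truth: dict,
    mol_first,
    mol_second,
) -> None:
    """Copy the template (priming flank + insert + resolving flank, reverse
    complemented for bottom-strand classes) into the reference at the planned
    geometry, then force a mismatch just beyond each flank so the planted
    microhomologies are maximal."""
    s = len(insert)
    f = flank_per_side(s)
    # planted flank homologies must reach the initial query flank or the
    # template would be undiscoverable by construction
    p = max(plan.priming_mh, f)
    q = max(plan.resolving_mh, f)
    # keep the template span and its mismatch-breaker bases clear of the
    # flank source regions at the breakpoints
    d = max(plan.template_distance, max(p, q) + 2)
    cls = plan.template_class
    side = plan.template_side
    c = p1 if side == 1 else p2

    u_p = "".join(mol_first(k) for k in range(p - 1, -1, -1))   # ref[pf-p+1..pf]
    d_q = "".join(mol_second(k) for k in range(q))
    tmpl = u_p + insert + d_q
    n_t = len(tmpl)

    if cls in ("foldback", "cross_junction"):
        # fully retained sequence
        if side == 1:
            x2 = c - d
            x1 = x2 - n_t + 1
        else:
            x1 = c + d
            x2 = x1 + n_t - 1
    elif cls == "strand_switching":
        # fully within lost sequence (deleted interval); keep the breaker
        # base clear of the junction seam
        dd = max(3, plan.template_distance)
        d = dd
        if side == 1:
            x1 = c + dd
            x2 = x1 + n_t - 1
        else:
            x2 = c - dd
            x1 = x2 - n_t + 1
    else:
        raise PlantError(f"unsupported template class {cls!r}")

    strand = "bottom" if cls in ("foldback", "strand_switching") else "top"
    content = revcomp(tmpl) if strand == "bottom" else tmpl
    ref.set_slice(x1, content)

    # maximality breakers: the molecule base just beyond each planted flank
    # must mismatch the adjacent reference base
    beyond_up = mol_first(p)       # molecule context beyond the priming flank
    beyond_dn = mol_second(q)      # beyond the resolving flank
    if strand == "top":
        if ref.get(x1 - 1) == beyond_up:
            ref.set(x1 - 1, _other_base(rng, beyond_up))
        if ref.get(x2 + 1) == beyond_dn:
            ref.set(x2 + 1, _other_base(rng, beyond_dn))
    else:
        if comp(ref.get(x2 + 1)) == beyond_up:
            ref.set(x2 + 1, _other_base(rng, comp(beyond_up)))
        if comp(ref.get(x1 - 1)) == beyond_dn:
            ref.set(x1 - 1, _other_base(rng, comp(beyond_dn)))

    truth.update(
        templated=True,
        template_class=cls,
        template_side=side,
        template_strand=strand,
        template_ref_start=x1,
        template_ref_end=x2,
        priming_mh=p,
        resolving_mh=q,
        template_distance=d,
    )


def _plant_expansion(
    ref: _Ref,
    plan: JunctionPlan,
    p1: int,
    p2: int,
    rng: np.random.Generator,
    truth: dict,
) -> str:
    """Plant an expansion insertion: a perfect direct repeat crossing the
    breakpoint is expanded from two to three units in the junction (the
    insert is one repeat unit; the found template crosses retained into lost
    sequence on the top strand)."""
    s = plan.insert_size
    f = flank_per_side(s)
    q = max(plan.resolving_mh, f)
    side = plan.template_side
    unit = _random_seq(rng, s)

    if side == 1:
        # retained unit ends at p1, lost copy just past it, then the
        # resolving flank copied so extension reaches q before mismatching
        ref.set_slice(p1 - s + 1, unit)
        ref.set_slice(p1 + 1, unit)
        d_q = ref.slice(p2, p2 + q - 1)
        ref.set_slice(p1 + s + 1, d_q)
        beyond = ref.get(p2 + q)
        if ref.get(p1 + s + q + 1) == beyond:
            ref.set(p1 + s + q + 1, _other_base(rng, beyond))
        x1, x2 = p1 - s + 1, p1 + s
    else:
        p = max(plan.priming_mh, f)
        ref.set_slice(p2, unit)
        ref.set_slice(p2 - s, unit)
        u_p = ref.slice(p1 - p + 1, p1)
        ref.set_slice(p2 - s - p, u_p)
        beyond = ref.get(p1 - p)
        if ref.get(p2 - s - p - 1) == beyond:
            ref.set(p2 - s - p - 1, _other_base(rng, beyond))
        x1, x2 = p2 - s, p2 + s - 1

    truth.update(
        templated=True,
        template_class="expansion",
        template_side=side,
        template_strand="top",
        template_ref_start=x1,
        template_ref_end=x2,
        priming_mh=0 if side == 1 else max(plan.priming_mh, f),
        resolving_mh=q if side == 1 else 0,
        template_distance=0,
    )
    return unit


def _draw_categorical(rng: np.random.Generator, dist: dict):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _draw_plan_mechanism(cfg: SimConfig, rng: np.random.Generator, plan: JunctionPlan) -> None:
    """Fill mechanism fields of a plan from the configured distributions."""
    plan.mechanism = _draw_categorical(rng, cfg.mechanism_mix)
    if plan.mechanism == "microhomology":
        plan.mh_len = int(_draw_categorical(rng, cfg.mh_length_dist))
    elif plan.mechanism == "insertion":
        plan.insert_size = int(_draw_categorical(rng, cfg.insertion_size_dist))
        plan.templated = bool(rng.random() < cfg.templated_fraction)
        if plan.templated and plan.sv_type == "DEL":
            plan.template_class = _draw_categorical(rng, cfg.template_class_mix)
            plan.template_side = int(rng.integers(1, 3))
            plan.template_distance = int(_draw_categorical(rng, cfg.template_distance_dist))
            plan.priming_mh = int(_draw_categorical(rng, cfg.priming_resolving_mh_dist))
            plan.resolving_mh = int(_draw_categorical(rng, cfg.priming_resolving_mh_dist))
        else:
            plan.templated = False


def _draw_molecule_support(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[int, int, int]:
    """(read_pair_count, mapq1, mapq2) with configurable failing fractions."""
    if rng.random() < cfg.frac_low_support:
        rpc = int(rng.integers(1, 3))
    else:
        rpc = 2 + int(rng.geometric(0.5))
    if rng.random() < cfg.frac_low_mapq:
        mq1, mq2 = [(25, 25), (60, 15), (10, 60)][int(rng.integers(0, 3))]
    else:
        mq1, mq2 = 60, 60
    return rpc, mq1, mq2


@dataclass
class CohortData:
    """In-memory simulated cohort plus writers for the on-disk interchange
    files (FASTA reference, BED targets, TSV tables, JSON config echo)."""

    config: SimConfig
    reference: str
    chrom: str
    targets: list[TargetRegion]
    samples: list[Sample]
    molecules: list[SourceMolecule]
    calls: list[SvCall]
    truth: pd.DataFrame

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.group, s.batch) for s in self.samples],
            columns=["sample", "group", "batch"],
        )

    def molecules_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.molecule_id, m.sample_id, m.chrom, m.outer_start, m.outer_end,
                 m.read_pair_count, m.mapq1, m.mapq2, int(m.carries_sv))
                for m in self.molecules
            ],
            columns=["moleculeId", "sample", "chrom", "outerStart", "outerEnd",
                     "readPairCount", "mapq1", "mapq2", "carriesSv"],
        )

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.id, c.sample_id, c.sv_type,
                 c.bp1.chrom, c.bp1.ref_pos, c.bp2.chrom, c.bp2.ref_pos,
                 c.offset, c.inserted_bases, c.size,
                 c.molecule_id, c.molecule_seq or "",
                 c.bp1.molecule_pos, c.bp2.molecule_pos)
                for c in self.calls
            ],
            columns=["id", "sample", "type", "chrom1", "pos1", "chrom2", "pos2",
                     "offset", "insertedBases", "size", "moleculeId",
                     "moleculeSeq", "molPos1", "molPos2"],
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from . import io as svio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": out / "reference.fa",
            "targets": out / "targets.bed",
            "molecules": out / "molecules.tsv",
            "svcalls": out / "svcalls.tsv",
            "manifest": out / "manifest.tsv",
            "truth": out / "truth.tsv",
            "config": out / "config.json",
        }
        svio.write_fasta(paths["reference"], {self.chrom: self.reference})
        svio.write_targets_bed(paths["targets"], self.targets)
        svio.write_tsv(paths["molecules"], self.molecules_frame())
        svio.write_tsv(paths["svcalls"], self.calls_frame())
        svio.write_tsv(paths["manifest"], self.manifest_frame())
        svio.write_tsv(paths["truth"], self.truth)
        paths["config"].write_text(self.config.to_json() + "\n")
        return paths


class _Reservations:
    """Disjoint reserved intervals guarding planted junction neighborhoods."""

    def __init__(self) -> None:
        self.intervals: list[tuple[int, int]] = []

    def conflicts(self, lo: int, hi: int) -> bool:
        return any(lo <= b and a <= hi for a, b in self.intervals)

    def add(self, lo: int, hi: int) -> None:
        self.intervals.append((lo, hi))


def _plan_positions(
    cfg: SimConfig,
    rng: np.random.Generator,
    reserved: _Reservations,
    target: TargetRegion,
    margin: int = 120,
) -> tuple[int, int]:
    """Draw (p1, size) with the target-side breakpoint in the capture target,
    both breakpoints in the padded span, and junction neighborhoods disjoint
    from previously planted SVs."""
    lo_pad = max(701, target.padded_start)
    hi_pad = min(cfg.genome_length - 700, target.padded_end)
    for _ in range(500):
        size = int(
            np.clip(
                cfg.sv_size_median * math.exp(cfg.sv_size_log_sigma * rng.standard_normal()),
                *cfg.sv_size_range,
            )
        )
        anchor = int(rng.integers(target.capture_start, target.capture_end + 1))
        direction = 1 if rng.random() < 0.5 else -1
        p1 = anchor if direction == 1 else anchor - size
        p2 = p1 + size
        if p1 < lo_pad or p2 > hi_pad:
            continue
        if reserved.conflicts(p1 - margin, p1 + margin) or reserved.conflicts(
            p2 - margin, p2 + margin
        ):
            continue
        reserved.add(p1 - margin, p1 + margin)
        reserved.add(p2 - margin, p2 + margin)
        return p1, size
    raise PlantError("could not place SV without neighborhood conflicts")


def simulate_cohort(config: SimConfig, out_dir: Optional[str | Path] = None) -> CohortData:
    """Generate a full cohort: reference, samples, planted SV calls with
    truth, and non-SV source molecules reaching the configured coverage.

    Per-sample SV counts are NB(rate_group x coverage_sample, theta); non-SV
    molecule lengths are uniform over ``molecule_length_range`` and >= 95% of
    molecules carry >= 3 read pairs at the default failing fractions. All
    output files cross-reference by ids and are byte-identical per config.
    """
    cfg = config
    chrom = "chr1"
    rng = np.random.default_rng(cfg.seed)
    ref_seed = int(rng.integers(0, 2**31 - 1))
    ref = _Ref(bytearray(make_reference(ref_seed, cfg.genome_length).encode("ascii")))
    target = cfg.target_region(chrom)

    samples: list[Sample] = []
    for g in cfg.groups:
        for i in range(cfg.n_samples_per_group):
            samples.append(
                Sample(
                    sample_id=f"{g}{i + 1}",
                    group=g,
                    batch=cfg.batches[i % len(cfg.batches)],
                )
            )

    rates = cfg.sv_rate_per_haplotype
    if not isinstance(rates, dict):
        rates = {g: float(rates) for g in cfg.groups}
    theta = cfg.dispersion_theta

    coverage_by_sample: dict[str, float] = {}
    n_svs_by_sample: dict[str, int] = {}
    for smp in samples:
        cov = float(cfg.mean_coverage * math.exp(0.1 * rng.standard_normal()))
        coverage_by_sample[smp.sample_id] = cov
        mean = rates[smp.group] * cov
        p_nb = theta / (theta + mean)
        n_svs_by_sample[smp.sample_id] = int(rng.negative_binomial(theta, p_nb))

    reserved = _Reservations()
    calls: list[SvCall] = []
    molecules: list[SourceMolecule] = []
    truth_rows: list[dict] = []
    sv_counter = 0
    mol_lo, mol_hi = cfg.molecule_length_range
    for smp in samples:
        for _ in range(n_svs_by_sample[smp.sample_id]):
            sv_counter += 1
            p1, size = _plan_positions(cfg, rng, reserved, target)
            rpc, mq1, mq2 = _draw_molecule_support(cfg, rng)
            plan = JunctionPlan(
                sv_id=f"sv{sv_counter:05d}",
                sample_id=smp.sample_id,
                sv_type=_draw_categorical(rng, cfg.sv_type_mix),
                p1=p1,
                size=size,
                mechanism="blunt",
                mol_left=int(rng.integers(150, 281)),
                mol_right=int(rng.integers(150, 281)),
                read_pair_count=rpc,
                mapq1=mq1,
                mapq2=mq2,
            )
            _draw_plan_mechanism(cfg, rng, plan)
            planted = plant_junction(ref, plan, rng, chrom)
            calls.append(planted.call)
            molecules.append(planted.molecule)
            truth_rows.append(planted.truth)

    # non-SV molecules to reach the configured coverage
    mean_adj = (mol_lo + mol_hi) / 2 - 40
    mol_counter = 0
    for smp in samples:
        n_mol = int(round(coverage_by_sample[smp.sample_id] * target.length / mean_adj))
        lengths = rng.integers(mol_lo, mol_hi + 1, size=n_mol)
        starts = rng.integers(
            target.capture_start - lengths + 1, target.capture_end + 1
        )
        u_sup = rng.random(n_mol)
        geo = rng.geometric(0.5, size=n_mol)
        low = rng.integers(1, 3, size=n_mol)
        rpcs = np.where(u_sup < cfg.frac_low_support, low, 2 + geo)
        u_mapq = rng.random(n_mol)
        mq_pick = rng.integers(0, 3, size=n_mol)
        mq_fail = np.array([(25, 25), (60, 15), (10, 60)])
        for i in range(n_mol):
            mol_counter += 1
            if u_mapq[i] < cfg.frac_low_mapq:
                mq1, mq2 = (int(x) for x in mq_fail[mq_pick[i]])
            else:
                mq1, mq2 = 60, 60
            molecules.append(
                SourceMolecule(
                    molecule_id=f"mol{mol_counter:07d}",
                    sample_id=smp.sample_id,
                    chrom=chrom,
                    outer_start=int(starts[i]),
                    outer_end=int(starts[i] + lengths[i] - 1),
                    read_pair_count=int(rpcs[i]),
                    mapq1=mq1,
                    mapq2=mq2,
                    carries_sv=False,
                )
            )

    cohort = CohortData(
        config=cfg,
        reference=ref.slice(1, cfg.genome_length),
        chrom=chrom,
        targets=[target],
        samples=samples,
        molecules=molecules,
        calls=calls,
        truth=pd.DataFrame(truth_rows) if truth_rows else pd.DataFrame(),
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def simulate_junction_set(
    n: int,
    config: Optional[SimConfig] = None,
    seed: int = 0,
    sv_size: int = 2_400,
) -> list[PlantedJunction]:
    """Plant ``n`` independent junctions, each on its own small random
    reference, for junction-level analyses (profiles, template search) where
    cohort structure and coverage are irrelevant.

    Each record carries its private reference so template windows never
    interact between junctions. Deterministic per seed.
    """
    cfg = config if config is not None else SimConfig()
    rng = np.random.default_rng(seed)
    margin = 700
    ref_len = margin + sv_size + margin
    out: list[PlantedJunction] = []
    for i in range(n):
        ref_seed = int(rng.integers(0, 2**31 - 1))
        ref = _Ref(_small_reference(ref_seed, ref_len))
        plan = JunctionPlan(
            sv_id=f"j{i:05d}",
            sample_id="S1",
            sv_type="DEL",
            p1=margin,
            size=sv_size,
            mechanism="blunt",
            mol_left=int(rng.integers(150, 281)),
            mol_right=int(rng.integers(150, 281)),
        )
        _draw_plan_mechanism(cfg, rng, plan)
        planted = plant_junction(ref, plan, rng)
        planted.reference = ref.slice(1, ref_len)
        out.append(planted)
    return out


def _small_reference(seed: int, length: int) -> bytearray:
    rng = np.random.default_rng(seed)
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())
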