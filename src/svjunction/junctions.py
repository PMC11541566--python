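"""Core SV junction data model and breakpoint-offset characterization.

An SV junction is described in two coordinate systems at once: the reference
genome and the sequenced source molecule that carries the junction. On each
side of the junction the *breakpoint* is the last aligned base nearest the
junction. The signed breakpoint offset in molecule coordinates classifies the
junction chemistry:

* ``offset < 0`` — microhomology: ``-offset`` molecule bases align to both
  reference flanks;
* ``offset == 0`` — blunt joint: the two alignments abut;
* ``offset > 0`` — de novo insertion: ``offset`` molecule bases align to
  neither flank (stored as ``inserted_bases``).

Reference positions are 1-based inclusive throughout; BED input/output
converts from 0-based half-open at the boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Breakpoint",
    "SvCall",
    "SourceMolecule",
    "Sample",
    "TargetRegion",
    "MalformedCallError",
    "OrientationError",
    "WindowError",
    "revcomp",
    "comp",
    "characterize_junction",
    "canonicalize_offset",
    "canonicalize_call",
    "orient_to_transcription",
    "molecule_order",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SV_TYPES = ("DEL", "DUP", "INV", "TRA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def comp(base: str) -> str:
    """Complement of a single base."""
    return base.translate(_COMP)


class MalformedCallError(ValueError):
    """Raised when breakpoint molecule coordinates are inconsistent."""


class OrientationError(ValueError):
    """Raised when a call cannot be oriented to a target region."""


class WindowError(ValueError):
    """Raised when a required reference window is unavailable."""


@dataclass(frozen=True)
class Breakpoint:
    """One side of an SV junction.

    ``ref_pos`` is the 1-based reference position of the last aligned base
    nearest the junction on this side; ``molecule_pos`` is the 1-based index
    of that same base in the SV source molecule. ``flank_side`` labels the
    breakpoint 'left' or 'right' by reference order.
    """

    chrom: str
    ref_pos: int
    molecule_pos: int
    flank_side: str = "left"

    def __post_init__(self) -> None:
        if self.ref_pos < 1:
            raise ValueError(f"ref_pos must be >= 1, got {self.ref_pos}")
        if self.molecule_pos < 1:
            raise ValueError(f"molecule_pos must be >= 1, got {self.molecule_pos}")
        if self.flank_side not in ("left", "right"):
            raise ValueError(f"flank_side must be left/right, got {self.flank_side!r}")

    def shifted(self, ref_delta: int, mol_delta: int) -> "Breakpoint":
        return dataclasses.replace(
            self,
            ref_pos=self.ref_pos + ref_delta,
            molecule_pos=self.molecule_pos + mol_delta,
        )


@dataclass
class SvCall:
    """One de novo SV junction with dual-coordinate breakpoints.

    For intrachromosomal calls ``bp1.ref_pos <= bp2.ref_pos`` (reference
    order); molecule order depends on ``sv_type`` (see
    :func:`molecule_order`). ``oriented`` flags whether the call is currently
    viewed in the transcription frame of its target region (a pure reporting
    flip; coordinates are never rewritten).
    """

    id: str
    sample_id: str
    sv_type: str
    bp1: Breakpoint
    bp2: Breakpoint
    offset: int
    inserted_bases: str = ""
    molecule_id: str = ""
    molecule_seq: Optional[str] = None
    oriented: bool = False

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if len(self.inserted_bases) != max(self.offset, 0):
            raise ValueError(
                "inserted_bases length must equal max(offset, 0): "
                f"offset={self.offset}, inserted={self.inserted_bases!r}"
            )
        if self.intrachromosomal and self.bp1.ref_pos > self.bp2.ref_pos:
            raise ValueError("bp1.ref_pos must be <= bp2.ref_pos for intrachromosomal calls")

    @property
    def intrachromosomal(self) -> bool:
        return self.sv_type != "TRA" and self.bp1.chrom == self.bp2.chrom

    @property
    def size(self) -> Optional[int]:
        """SV size: distance between breakpoints in the reference (None for TRA)."""
        if not self.intrachromosomal:
            return None
        return abs(self.bp2.ref_pos - self.bp1.ref_pos)

    @property
    def microhomology_length(self) -> int:
        return -self.offset if self.offset < 0 else 0


@dataclass(frozen=True)
class SourceMolecule:
    """One unique sequenced DNA fragment (read group).

    ``outer_start``/``outer_end`` are 1-based inclusive reference coordinates
    of the molecule's outer endpoints; ``read_pair_count`` is the number of
    redundant read pairs supporting it.
    """

    molecule_id: str
    sample_id: str
    chrom: str
    outer_start: int
    outer_end: int
    read_pair_count: int
    mapq1: int
    mapq2: int
    carries_sv: bool = False

    def __post_init__(self) -> None:
        if self.outer_end < self.outer_start:
            raise ValueError("outer_end must be >= outer_start")
        if self.read_pair_count < 1:
            raise ValueError("read_pair_count must be >= 1")

    @property
    def length(self) -> int:
        return self.outer_end - self.outer_start + 1


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: str
    batch: str
    cell_line: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.group or not self.batch:
            raise ValueError("group and batch must be non-empty")


@dataclass(frozen=True)
class TargetRegion:
    """A capture target. ``capture_start``/``capture_end`` are 1-based
    inclusive; the padded interrogation span extends ``pad`` bp on each side
    and bounds allowable SV breakpoints."""

    name: str
    chrom: str
    capture_start: int
    capture_end: int
    pad: int = 800_000
    transcription_strand: str = "+"

    def __post_init__(self) -> None:
        if self.capture_end <= self.capture_start:
            raise ValueError("capture_end must be > capture_start")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")
        if self.transcription_strand not in ("+", "-"):
            raise ValueError("transcription_strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.capture_end - self.capture_start + 1

    @property
    def padded_start(self) -> int:
        return max(1, self.capture_start - self.pad)

    @property
    def padded_end(self) -> int:
        return self.capture_end + self.pad

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.capture_start <= pos <= self.capture_end

    def padded_contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.padded_start <= pos <= self.padded_end


def molecule_order(call: SvCall) -> tuple[Breakpoint, Breakpoint, bool]:
    """Return (first, second, second_is_reverse) breakpoints in molecule order.

    For deletions both aligned segments run forward and reference order equals
    molecule order. For tandem duplications the molecule reads the end of the
    duplicated unit (bp2) before its start (bp1). For inversions the second
    segment aligns to the reverse strand, starting at bp2 and descending.
    """
    if call.sv_type == "DUP":
        return call.bp2, call.bp1, False
    if call.sv_type == "INV":
        return call.bp1, call.bp2, True
    return call.bp1, call.bp2, False


def characterize_junction(
    molecule_seq: str, bp1: Breakpoint, bp2: Breakpoint
) -> tuple[int, str]:
    """Compute the signed breakpoint offset and inserted bases of a junction.

    ``bp1`` must be the junction-proximal end of the first aligned segment in
    molecule order and ``bp2`` of the second. With ``a`` the molecule index of
    bp1's last aligned base and ``b`` that of bp2's first aligned base, the
    offset is ``b - a - 1``; positive offsets carry the intervening molecule
    bases as the de novo insertion, negative offsets mean ``-offset`` bases
    aligned to both reference flanks (microhomology).
    """
    a = bp1.molecule_pos
    b = bp2.molecule_pos
    if b < 1 or a > len(molecule_seq):
        raise MalformedCallError(
            f"breakpoint molecule positions outside molecule: a={a}, b={b}, "
            f"len={len(molecule_seq)}"
        )
    offset = b - a - 1
    inserted = molecule_seq[a : b - 1] if offset > 0 else ""
    return offset, inserted


def _ref_base(reference: str, pos: int) -> Optional[str]:
    """1-based reference base; None when out of range or not an unambiguous
    uppercase base (N/lowercase are treated as universal mismatches)."""
    if 1 <= pos <= len(reference):
        c = reference[pos - 1]
        if c in "ACGT":
            return c
    return None


def canonicalize_offset(
    molecule_seq: Optional[str],
    reference: str,
    bp1: Breakpoint,
    bp2: Breakpoint,
    sv_type: str = "DEL",
    window: int = 50,
) -> tuple[int, str, Breakpoint, Breakpoint]:
    """Extend microhomology to its maximal extent and shift breakpoints.

    Upstream aligners place shiftable junctions arbitrarily; this makes the
    reported microhomology the MAXIMAL number of bases identical between the
    two reference flanks across the junction, with the breakpoints at the
    rightmost placement in first-segment orientation. The operation is
    idempotent, never decreases microhomology, and leaves insertion junctions
    (offset > 0) unchanged. ``bp1``/``bp2`` are in reference order; molecule
    order is derived from ``sv_type``.

    Returns ``(offset, inserted_bases, bp1', bp2')``.
    """
    first, second, second_rev = (
        (bp2, bp1, False) if sv_type == "DUP"
        else (bp1, bp2, True) if sv_type == "INV"
        else (bp1, bp2, False)
    )
    a = first.molecule_pos
    b = second.molecule_pos
    offset = b - a - 1
    if offset > 0:
        if molecule_seq is None:
            raise MalformedCallError("molecule_seq required for insertion junctions")
        return offset, molecule_seq[a : b - 1], bp1, bp2

    pf = first.ref_pos
    ps = second.ref_pos
    m0 = -offset

    def al1(i: int) -> Optional[str]:
        return _ref_base(reference, pf - i)

    def ext1(j: int) -> Optional[str]:
        return _ref_base(reference, pf + j)

    if second_rev:
        def al2(j: int) -> Optional[str]:
            x = _ref_base(reference, ps - j)
            return comp(x) if x else None

        def ext2(j: int) -> Optional[str]:
            x = _ref_base(reference, ps + j)
            return comp(x) if x else None
    else:
        def al2(j: int) -> Optional[str]:
            return _ref_base(reference, ps + j)

        def ext2(j: int) -> Optional[str]:
            return _ref_base(reference, ps - j)

    # Extend homology rightward: segment 1 claims molecule base a+1+k, which
    # the second segment aligns as al2(m0+k); claimable iff ext1(k+1) matches.
    ext_r = 0
    while ext_r < window:
        x, y = ext1(ext_r + 1), al2(m0 + ext_r)
        if x is None or y is None or x != y:
            break
        ext_r += 1
    # Extend leftward: segment 2 claims molecule base b-1-j = al1(m0+j);
    # claimable iff ext2(j+1) matches.
    ext_l = 0
    while ext_l < window:
        x, y = ext2(ext_l + 1), al1(m0 + ext_l)
        if x is None or y is None or x != y:
            break
        ext_l += 1

    m_new = m0 + ext_l + ext_r
    new_offset = -m_new
    first_new = first.shifted(ext_r, ext_r)
    second_new = second.shifted(
        ext_l if second_rev else -ext_l, -ext_l
    )
    if sv_type == "DUP":
        new_bp1, new_bp2 = second_new, first_new
    else:
        new_bp1, new_bp2 = first_new, second_new
    return new_offset, "", new_bp1, new_bp2


def bp_offset(bp1: Breakpoint, bp2: Breakpoint, sv_type: str) -> int:
    """Offset implied by the molecule coordinates of two reference-ordered
    breakpoints."""
    if sv_type == "DUP":
        first, second = bp2, bp1
    else:
        first, second = bp1, bp2
    return second.molecule_pos - first.molecule_pos - 1


def canonicalize_call(call: SvCall, reference: str, window: int = 50) -> SvCall:
    """Return a copy of ``call`` with maximal microhomology and shifted
    breakpoints (see :func:`canonicalize_offset`)."""
    if call.sv_type == "TRA" or not call.intrachromosomal:
        return call
    offset, inserted, bp1, bp2 = canonicalize_offset(
        call.molecule_seq, reference, call.bp1, call.bp2, call.sv_type, window
    )
    return dataclasses.replace(
        call, offset=offset, inserted_bases=inserted, bp1=bp1, bp2=bp2
    )


def orient_to_transcription(call: SvCall, target: TargetRegion) -> SvCall:
    """View a call in the transcription orientation of its target region.

    For '+' targets this is the identity. For '-' targets the reporting frame
    is mirrored: breakpoint roles (left/right, index 1/2) swap while strand
    labels of template hits are preserved (top/bottom means same/opposite
    strand as the junction molecule, which is frame-invariant). Applying the
    operation twice returns the original call. Storage coordinates are never
    rewritten; downstream classification and pileups consult ``oriented``.
    """
    if not call.intrachromosomal:
        raise OrientationError(f"call {call.id} is not intrachromosomal")
    lo, hi = call.bp1.ref_pos, call.bp2.ref_pos
    if hi < target.padded_start or lo > target.padded_end or call.bp1.chrom != target.chrom:
        raise OrientationError(
            f"call {call.id} is outside the interrogation span of target {target.name}"
        )
    if target.transcription_strand == "+":
        return call
    return dataclasses.replace(call, oriented=not call.oriented)
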