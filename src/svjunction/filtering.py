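"""Single-molecule SV filtering, adjusted target coverage, SV frequency, and
breakpoint density tracks.

Filtering aims to count only de novo SVs that arose during the experimental
window: a junction must be found in a single source molecule in a single
sample, be supported by >=3 redundant read pairs (late-PCR chimeras typically
have one), pass the mapping-quality rule (>=30 on one flank AND >=20 on both),
fall on target (>=1 breakpoint in an unpadded capture target, both within the
padded span), and lie in the type-specific size window.

Coverage counts only bases that could have reported an SV junction: non-SV
molecules with >=3 read pairs, each adjusted by subtracting 2 x 20 bp of
terminal dead zone, summed over on-target molecules and divided by the
unpadded target length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .junctions import SourceMolecule, SvCall, TargetRegion, canonicalize_call

__all__ = [
    "FilterConfig",
    "CoverageTrack",
    "SvFrequency",
    "IntegrityError",
    "ConfigError",
    "filter_svs",
    "compute_coverage",
    "sv_frequency",
    "breakpoint_density",
]

REJECTION_REASONS = ("duplicate", "read_pairs", "mapq", "location", "size")


class IntegrityError(ValueError):
    """A call references a molecule that does not exist."""


class ConfigError(ValueError):
    """Invalid filter/coverage configuration or empty required input."""


@dataclass(frozen=True)
class FilterConfig:
    """SV filter thresholds (defaults match the analysis conventions)."""

    min_read_pairs: int = 3
    mapq_both: int = 20
    mapq_one: int = 30
    min_size_del_dup: int = 10_000
    max_size: int = 1_200_000
    min_size_inv: int = 50_000
    pad: int = 800_000
    terminal_dead_zone: int = 20

    def __post_init__(self) -> None:
        for name in (
            "min_read_pairs", "mapq_both", "mapq_one", "min_size_del_dup",
            "max_size", "min_size_inv", "pad", "terminal_dead_zone",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.max_size <= self.min_size_del_dup:
            raise ConfigError("max_size must exceed min_size_del_dup")


@dataclass
class CoverageTrack:
    """Adjusted target coverage: scalar fold-coverage plus binned tracks.

    ``fold`` = sum of adjusted on-target molecule lengths / unpadded target
    length. ``bins100`` is a 100 bp binned mean base-coverage table over the
    unpadded targets. Per-target base-level coverage over the padded span is
    retained for density masking.
    """

    fold: float
    bins100: pd.DataFrame
    targets: Sequence[TargetRegion]
    _base_cov: dict = field(default_factory=dict, repr=False)

    def base_coverage(self, target_name: str) -> tuple[int, np.ndarray]:
        """(padded_start, per-base coverage array) for one target."""
        return self._base_cov[target_name]

    def binned(self, target: TargetRegion, width: int, padded: bool = False) -> pd.DataFrame:
        """Mean base coverage in ``width`` bp bins anchored at the capture (or
        padded) start; partial terminal bins are length-weighted."""
        start0, cov = self._base_cov[target.name]
        if padded:
            lo, hi = target.padded_start, target.padded_end
        else:
            lo, hi = target.capture_start, target.capture_end
        rows = []
        pos = lo
        while pos <= hi:
            end = min(pos + width - 1, hi)
            seg = cov[pos - start0 : end - start0 + 1]
            rows.append((target.chrom, pos, end, float(seg.mean()) if len(seg) else 0.0))
            pos = end + 1
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "coverage"])


@dataclass(frozen=True)
class SvFrequency:
    """Observed junction count divided by target fold-coverage; approximates
    the fraction of sequenced target haplotypes carrying a de novo SV."""

    n_svs: int
    coverage: float
    frequency: float


def _molecule_key(mol: SourceMolecule) -> tuple:
    return (mol.sample_id, mol.chrom, mol.outer_start, mol.outer_end)


def _junction_key(call: SvCall) -> tuple:
    return (
        call.sv_type,
        call.bp1.chrom, call.bp1.ref_pos,
        call.bp2.chrom, call.bp2.ref_pos,
    )


def filter_svs(
    calls: Sequence[SvCall],
    molecules: Sequence[SourceMolecule],
    samples=None,
    targets: Sequence[TargetRegion] = (),
    config: FilterConfig = FilterConfig(),
    reference: Optional[str] = None,
) -> tuple[list[SvCall], pd.DataFrame]:
    """Apply the SV filters and return (kept calls, rejection table).

    Rules are evaluated in a fixed order so the FIRST failing rule per call is
    reproducible: (1) single-molecule/single-sample uniqueness of the junction
    key (sv_type + canonical breakpoint pair), (2) read-pair support, (3)
    mapping quality, (4) on-target location, (5) type-specific size window.
    When ``reference`` is given, junction keys use canonicalized breakpoints.
    """
    mol_by_id = {m.molecule_id: m for m in molecules}
    for call in calls:
        if call.molecule_id not in mol_by_id:
            raise IntegrityError(
                f"call {call.id} references unknown molecule {call.molecule_id!r}"
            )

    canon = (
        [canonicalize_call(c, reference) for c in calls]
        if reference is not None
        else list(calls)
    )

    # Uniqueness: junction key must occur in exactly one molecule identity
    # (sample + outer endpoints) and one sample across the whole batch.
    key_mols: dict[tuple, set] = {}
    key_samples: dict[tuple, set] = {}
    for call, ccall in zip(calls, canon):
        k = _junction_key(ccall)
        mol = mol_by_id[call.molecule_id]
        key_mols.setdefault(k, set()).add(_molecule_key(mol))
        key_samples.setdefault(k, set()).add(call.sample_id)

    kept: list[SvCall] = []
    rejected: list[tuple[str, str]] = []
    for call, ccall in zip(calls, canon):
        mol = mol_by_id[call.molecule_id]
        k = _junction_key(ccall)
        if len(key_mols[k]) != 1 or len(key_samples[k]) != 1:
            rejected.append((call.id, "duplicate"))
            continue
        if mol.read_pair_count < config.min_read_pairs:
            rejected.append((call.id, "read_pairs"))
            continue
        if not (
            max(mol.mapq1, mol.mapq2) >= config.mapq_one
            and min(mol.mapq1, mol.mapq2) >= config.mapq_both
        ):
            rejected.append((call.id, "mapq"))
            continue
        bps = (call.bp1, call.bp2)
        on_target = any(t.contains(bp.chrom, bp.ref_pos) for t in targets for bp in bps)
        in_padded = all(
            any(t.padded_contains(bp.chrom, bp.ref_pos) for t in targets) for bp in bps
        )
        if not (on_target and in_padded):
            rejected.append((call.id, "location"))
            continue
        size = call.size
        if size is not None:
            if call.sv_type in ("DEL", "DUP") and not (
                config.min_size_del_dup <= size <= config.max_size
            ):
                rejected.append((call.id, "size"))
                continue
            if call.sv_type == "INV" and not (
                config.min_size_inv <= size <= config.max_size
            ):
                rejected.append((call.id, "size"))
                continue
        kept.append(call)

    rejections = pd.DataFrame(rejected, columns=["id", "reason"])
    return kept, rejections


def compute_coverage(
    molecules: Sequence[SourceMolecule],
    targets: Sequence[TargetRegion],
    config: FilterConfig = FilterConfig(),
) -> CoverageTrack:
    """Adjusted fold-coverage of the capture targets.

    Molecules with fewer than ``min_read_pairs`` read pairs and SV-carrying
    molecules are excluded; remaining on-target molecule lengths are adjusted
    by subtracting 2 x terminal_dead_zone bp (floored at 0), summed, and
    divided by the summed unpadded target length. The binned track averages
    base-level coverage of the molecule interiors over 100 bp bins.
    """
    if not targets:
        raise ConfigError("empty target set")
    dz = config.terminal_dead_zone
    total_target_len = sum(t.length for t in targets)

    adjusted_sum = 0.0
    base_cov: dict[str, tuple[int, np.ndarray]] = {}
    diffs = {
        t.name: np.zeros(t.padded_end - t.padded_start + 2, dtype=np.int64)
        for t in targets
    }
    for mol in molecules:
        if mol.read_pair_count < config.min_read_pairs or mol.carries_sv:
            continue
        on_target = any(
            t.chrom == mol.chrom
            and mol.outer_start <= t.capture_end
            and mol.outer_end >= t.capture_start
            for t in targets
        )
        if on_target:
            adjusted_sum += max(mol.length - 2 * dz, 0)
        # interior bases contribute to the base-level track of any padded span
        istart, iend = mol.outer_start + dz, mol.outer_end - dz
        if iend < istart:
            continue
        for t in targets:
            if t.chrom != mol.chrom:
                continue
            lo = max(istart, t.padded_start)
            hi = min(iend, t.padded_end)
            if hi >= lo:
                d = diffs[t.name]
                d[lo - t.padded_start] += 1
                d[hi - t.padded_start + 1] -= 1

    bins_frames = []
    for t in targets:
        cov = np.cumsum(diffs[t.name][:-1])
        base_cov[t.name] = (t.padded_start, cov)

    fold = adjusted_sum / total_target_len
    track = CoverageTrack(fold=fold, bins100=pd.DataFrame(), targets=list(targets), _base_cov=base_cov)
    for t in targets:
        bins_frames.append(track.binned(t, 100))
    track.bins100 = (
        pd.concat(bins_frames, ignore_index=True) if bins_frames else pd.DataFrame()
    )
    return track


def sv_frequency(kept_calls: Sequence[SvCall], coverage: CoverageTrack | float) -> SvFrequency:
    """SV frequency = junction count / target fold-coverage."""
    fold = coverage.fold if isinstance(coverage, CoverageTrack) else float(coverage)
    n = len(kept_calls)
    if fold <= 0:
        raise ConfigError("SV frequency undefined at zero coverage")
    return SvFrequency(n_svs=n, coverage=fold, frequency=n / fold)


def breakpoint_density(
    kept_calls: Sequence[SvCall],
    track: CoverageTrack,
    bin_width: int = 5_000,
    min_coverage: float = 500.0,
) -> pd.DataFrame:
    """Breakpoint counts in 5 kb bins over the padded target spans, with
    coverage-normalized density defined only on bins whose mean adjusted
    coverage is >= ``min_coverage`` (masked bins carry NaN, never zero)."""
    frames = []
    for t in track.targets:
        bins = track.binned(t, bin_width, padded=True)
        counts = np.zeros(len(bins), dtype=np.int64)
        starts = bins["start"].to_numpy()
        for call in kept_calls:
            for bp in (call.bp1, call.bp2):
                if bp.chrom != t.chrom:
                    continue
                if t.padded_start <= bp.ref_pos <= t.padded_end:
                    idx = np.searchsorted(starts, bp.ref_pos, side="right") - 1
                    if 0 <= idx < len(counts):
                        counts[idx] += 1
        bins = bins.assign(target=t.name, count=counts)
        density = np.where(
            bins["coverage"].to_numpy() >= min_coverage,
            counts / np.maximum(bins["coverage"].to_numpy(), 1e-300),
            np.nan,
        )
        bins["density"] = density
        frames.append(bins)
    return pd.concat(frames, ignore_index=True)
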