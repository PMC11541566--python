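"""Readers and writers for the interchange formats.

Tables travel as TSV with header lines; targets as BED (0-based half-open on
disk, converted to the package's 1-based inclusive coordinates at the
boundary); the reference as FASTA. All writers are deterministic so pipeline
reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .junctions import Breakpoint, Sample, SourceMolecule, SvCall, TargetRegion

__all__ = [
    "read_fasta", "write_fasta",
    "read_targets_bed", "write_targets_bed",
    "read_tsv", "write_tsv",
    "read_molecules", "read_calls", "read_manifest",
    "calls_to_frame", "load_config",
]


class SchemaError(ValueError):
    """A table is missing required columns."""


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_targets_bed(path: str | Path, default_pad: int = 800_000) -> list[TargetRegion]:
    """BED targets: chrom, start (0-based), end (half-open), [name, score,
    strand]. Strand column carries the transcription strand."""
    targets = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{i + 1}: BED needs >= 3 columns")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"target{len(targets) + 1}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            targets.append(
                TargetRegion(
                    name=name, chrom=chrom,
                    capture_start=start0 + 1, capture_end=end,
                    pad=default_pad, transcription_strand=strand,
                )
            )
    return targets


def write_targets_bed(path: str | Path, targets: list[TargetRegion]) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(
                f"{t.chrom}\t{t.capture_start - 1}\t{t.capture_end}\t{t.name}\t0\t"
                f"{t.transcription_strand}\n"
            )


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"insertedBases": str, "moleculeSeq": str},
                       keep_default_na=False, na_values=[])


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns: {', '.join(missing)}")


def read_molecules(path: str | Path) -> list[SourceMolecule]:
    df = read_tsv(path)
    _require(
        df,
        ["moleculeId", "sample", "chrom", "outerStart", "outerEnd",
         "readPairCount", "mapq1", "mapq2"],
        "molecule",
    )
    carries = df["carriesSv"] if "carriesSv" in df.columns else 0
    return [
        SourceMolecule(
            molecule_id=str(r.moleculeId), sample_id=str(r.sample), chrom=str(r.chrom),
            outer_start=int(r.outerStart), outer_end=int(r.outerEnd),
            read_pair_count=int(r.readPairCount),
            mapq1=int(r.mapq1), mapq2=int(r.mapq2),
            carries_sv=bool(int(c)),
        )
        for r, c in zip(df.itertuples(index=False), pd.Series(carries, index=df.index))
    ]


def read_calls(path: str | Path) -> list[SvCall]:
    """Read the SV-call table. ``molPos1``/``molPos2`` (1-based molecule
    coordinates of the breakpoints) are optional; without them molecule
    positions are reconstructed as 1 and a placeholder consistent with the
    stated offset, and sequence-level operations are unavailable."""
    df = read_tsv(path)
    _require(
        df,
        ["id", "sample", "type", "chrom1", "pos1", "chrom2", "pos2", "offset"],
        "SV call",
    )
    has_molpos = "molPos1" in df.columns and "molPos2" in df.columns
    calls = []
    for i, r in enumerate(df.itertuples(index=False)):
        offset = int(r.offset)
        if has_molpos:
            mp1, mp2 = int(r.molPos1), int(r.molPos2)
        else:
            first = 200
            second = first + offset + 1
            if str(r.type) == "DUP":
                mp2, mp1 = first, second
            else:
                mp1, mp2 = first, second
        inserted = str(getattr(r, "insertedBases", "") or "")
        mol_seq = str(getattr(r, "moleculeSeq", "") or "") or None
        try:
            calls.append(
                SvCall(
                    id=str(r.id), sample_id=str(r.sample), sv_type=str(r.type),
                    bp1=Breakpoint(str(r.chrom1), int(r.pos1), mp1, "left"),
                    bp2=Breakpoint(str(r.chrom2), int(r.pos2), mp2, "right"),
                    offset=offset, inserted_bases=inserted,
                    molecule_id=str(getattr(r, "moleculeId", "")),
                    molecule_seq=mol_seq,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from exc
    return calls


def read_manifest(path: str | Path) -> list[Sample]:
    df = read_tsv(path)
    _require(df, ["sample", "group", "batch"], "manifest")
    return [
        Sample(sample_id=str(r.sample), group=str(r.group), batch=str(r.batch))
        for r in df.itertuples(index=False)
    ]


def calls_to_frame(calls: list[SvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.id, c.sample_id, c.sv_type,
             c.bp1.chrom, c.bp1.ref_pos, c.bp2.chrom, c.bp2.ref_pos,
             c.offset, c.inserted_bases, c.size,
             c.molecule_id, c.molecule_seq or "",
             c.bp1.molecule_pos, c.bp2.molecule_pos)
            for c in calls
        ],
        columns=["id", "sample", "type", "chrom1", "pos1", "chrom2", "pos2",
                 "offset", "insertedBases", "size", "moleculeId", "moleculeSeq",
                 "molPos1", "molPos2"],
    )


def load_config(path: str | Path) -> dict:
    """YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
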