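"""Shared fixtures: small deterministic references and reusable simulated
junction sets (session-scoped so expensive generation runs once)."""

from __future__ import annotations

import numpy as np
import pytest

from svjunction.junctions import Breakpoint, SourceMolecule, SvCall, TargetRegion
from svjunction.simulate import SimConfig, simulate_junction_set


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_reference():
    """10 kb random reference string."""
    from svjunction.simulate import _small_reference

    return _small_reference(42, 10_000).decode("ascii")


@pytest.fixture
def toy_target():
    return TargetRegion(
        name="t1", chrom="chr1", capture_start=1_000, capture_end=2_000, pad=5_000
    )


def make_del_call(
    p1: int = 700,
    p2: int = 3_100,
    offset: int = 0,
    inserted: str = "",
    molecule_seq=None,
    mol_a: int = 200,
    sample: str = "S1",
    call_id: str = "sv1",
    molecule_id: str = "m1",
    sv_type: str = "DEL",
):
    """Hand-built deletion call with molecule positions consistent with the
    requested offset."""
    b = mol_a + offset + 1
    return SvCall(
        id=call_id,
        sample_id=sample,
        sv_type=sv_type,
        bp1=Breakpoint("chr1", p1, mol_a, "left"),
        bp2=Breakpoint("chr1", p2, b, "right"),
        offset=offset,
        inserted_bases=inserted,
        molecule_id=molecule_id,
        molecule_seq=molecule_seq,
    )


def make_molecule(
    molecule_id: str = "m1",
    sample: str = "S1",
    start: int = 500,
    end: int = 950,
    rpc: int = 5,
    mapq1: int = 60,
    mapq2: int = 60,
    carries_sv: bool = False,
):
    return SourceMolecule(
        molecule_id=molecule_id,
        sample_id=sample,
        chrom="chr1",
        outer_start=start,
        outer_end=end,
        read_pair_count=rpc,
        mapq1=mapq1,
        mapq2=mapq2,
        carries_sv=carries_sv,
    )


@pytest.fixture(scope="session")
def tmej_junctions():
    """2000 TMEJ-mode junctions with truth, each on its own reference."""
    return simulate_junction_set(2000, SimConfig(), seed=101)


@pytest.fixture(scope="session")
def polq_ko_junctions():
    """1500 POLQ-knockout-mode junctions."""
    return simulate_junction_set(1500, SimConfig.for_mode("POLQ_KO"), seed=202)


@pytest.fixture(scope="session")
def insertion_junctions():
    """600 insertion-only junctions (mixed templated/untemplated) for
    template-search tests."""
    cfg = SimConfig(
        mechanism_mix={"microhomology": 0.0, "blunt": 0.0, "insertion": 1.0}
    )
    return simulate_junction_set(600, cfg, seed=303)
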