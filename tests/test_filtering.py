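"""SV filtering rules, adjusted coverage arithmetic, SV frequency, and
breakpoint density masking."""

import numpy as np
import pytest

from svjunction.filtering import (
    ConfigError,
    FilterConfig,
    IntegrityError,
    breakpoint_density,
    compute_coverage,
    filter_svs,
    sv_frequency,
)
from svjunction.junctions import TargetRegion

from conftest import make_del_call, make_molecule


@pytest.fixture
def target():
    # 1 kb unpadded target with a wide padded interrogation span
    return TargetRegion(
        name="t1", chrom="chr1", capture_start=1_000_001, capture_end=1_001_000,
        pad=800_000,
    )


def _call_and_mol(call_id, p1, p2, sample="S1", rpc=5, mapq=(60, 60),
                  sv_type="DEL", mol_id=None, mol_span=None):
    mol_id = mol_id or f"m_{call_id}"
    start, end = mol_span or (p1 - 200, p1 + 250)
    call = make_del_call(
        p1=p1, p2=p2, call_id=call_id, molecule_id=mol_id, sample=sample,
        sv_type=sv_type,
    )
    mol = make_molecule(
        molecule_id=mol_id, sample=sample, start=start, end=end, rpc=rpc,
        mapq1=mapq[0], mapq2=mapq[1], carries_sv=True,
    )
    return call, mol


class TestFilterRules:
    def test_small_deletion_rejected_for_size(self, target):
        call, mol = _call_and_mol("c1", 1_000_100, 1_005_100)  # 5 kb DEL
        kept, rej = filter_svs([call], [mol], None, [target])
        assert kept == []
        assert rej.iloc[0]["reason"] == "size"

    def test_small_inversion_rejected_for_size(self, target):
        call, mol = _call_and_mol("c1", 1_000_100, 1_030_100, sv_type="INV")  # 30 kb
        kept, rej = filter_svs([call], [mol], None, [target])
        assert rej.iloc[0]["reason"] == "size"

    def test_passing_deletion_kept(self, target):
        # 500 kb DEL, 3 read pairs, mapq 35/25, on-target, unique
        call, mol = _call_and_mol("c1", 1_000_100, 1_500_100, rpc=3, mapq=(35, 25))
        kept, rej = filter_svs([call], [mol], None, [target])
        assert [c.id for c in kept] == ["c1"]
        assert len(rej) == 0

    def test_inversion_above_floor_kept(self, target):
        call, mol = _call_and_mol("c1", 1_000_100, 1_060_100, sv_type="INV")  # 60 kb
        kept, _ = filter_svs([call], [mol], None, [target])
        assert len(kept) == 1

    def test_low_support_rejected(self, target):
        call, mol = _call_and_mol("c1", 1_000_100, 1_500_100, rpc=2)
        _, rej = filter_svs([call], [mol], None, [target])
        assert rej.iloc[0]["reason"] == "read_pairs"

    @pytest.mark.parametrize("mapq", [(25, 25), (60, 15), (10, 60)])
    def test_mapq_rule(self, target, mapq):
        call, mol = _call_and_mol("c1", 1_000_100, 1_500_100, mapq=mapq)
        _, rej = filter_svs([call], [mol], None, [target])
        assert rej.iloc[0]["reason"] == "mapq"

    def test_off_target_rejected(self, target):
        # both breakpoints in the padded span but neither in the target
        call, mol = _call_and_mol("c1", 1_100_000, 1_600_000)
        _, rej = filter_svs([call], [mol], None, [target])
        assert rej.iloc[0]["reason"] == "location"

    def test_breakpoint_beyond_pad_rejected(self, target):
        call, mol = _call_and_mol("c1", 1_000_100, 2_000_000)  # bp2 beyond pad
        _, rej = filter_svs([call], [mol], None, [target])
        assert rej.iloc[0]["reason"] == "location"

    def test_junction_in_two_samples_rejected_as_duplicate(self, target):
        c1, m1 = _call_and_mol("c1", 1_000_100, 1_500_100, sample="S1")
        c2, m2 = _call_and_mol("c2", 1_000_100, 1_500_100, sample="S2",
                               mol_span=(1_000_000, 1_000_400))
        kept, rej = filter_svs([c1, c2], [m1, m2], None, [target])
        assert kept == []
        assert set(rej["reason"]) == {"duplicate"}

    def test_rejection_order_duplicate_before_size(self, target):
        # a duplicated 5 kb deletion reports 'duplicate', the first failing rule
        c1, m1 = _call_and_mol("c1", 1_000_100, 1_005_100, sample="S1")
        c2, m2 = _call_and_mol("c2", 1_000_100, 1_005_100, sample="S2",
                               mol_span=(1_000_000, 1_000_400))
        _, rej = filter_svs([c1, c2], [m1, m2], None, [target])
        assert set(rej["reason"]) == {"duplicate"}

    def test_conservation_and_idempotence(self, target):
        calls, mols = [], []
        rng = np.random.default_rng(3)
        for i in range(30):
            p1 = 1_000_050 + i * 17
            c, m = _call_and_mol(
                f"c{i}", p1, p1 + int(rng.integers(5_000, 900_000)),
                rpc=int(rng.integers(1, 8)),
            )
            calls.append(c)
            mols.append(m)
        kept, rej = filter_svs(calls, mols, None, [target])
        assert len(kept) + len(rej) == len(calls)
        kept2, rej2 = filter_svs(kept, mols, None, [target])
        assert [c.id for c in kept2] == [c.id for c in kept]
        assert len(rej2) == 0

    def test_dangling_molecule_reference_raises(self, target):
        call = make_del_call(p1=1_000_100, p2=1_500_100, molecule_id="nope")
        with pytest.raises(IntegrityError):
            filter_svs([call], [], None, [target])


class TestCoverage:
    def test_closed_form_adjustment(self, target):
        """10 molecules of 140 bp on a 1 kb target: coverage is exactly
        10 x (140 - 40) / 1000 = 1.0."""
        mols = [
            make_molecule(f"m{i}", start=1_000_100 + i, end=1_000_100 + i + 139)
            for i in range(10)
        ]
        track = compute_coverage(mols, [target])
        assert abs(track.fold - 1.0) < 1e-9

    def test_short_molecule_contributes_zero(self, target):
        mols = [make_molecule("m1", start=1_000_100, end=1_000_139)]  # 40 bp
        track = compute_coverage(mols, [target])
        assert track.fold == 0.0

    def test_low_support_molecules_excluded(self, target):
        mols = [
            make_molecule(f"m{i}", start=1_000_100, end=1_000_539, rpc=2)
            for i in range(5)
        ]
        track = compute_coverage(mols, [target])
        assert track.fold == 0.0

    def test_sv_molecules_excluded(self, target):
        mols = [
            make_molecule("m1", start=1_000_100, end=1_000_539, carries_sv=True)
        ]
        assert compute_coverage(mols, [target]).fold == 0.0

    def test_uniform_cohort_closed_form(self, target):
        """n molecules of fixed length L: fold = n x (L - 40) / targetLen
        within 1e-9."""
        n, L = 500, 450
        rng = np.random.default_rng(9)
        starts = rng.integers(1_000_001 - L + 1, 1_001_001, size=n)
        mols = [
            make_molecule(f"m{i}", start=int(s), end=int(s) + L - 1)
            for i, s in enumerate(starts)
        ]
        track = compute_coverage(mols, [target])
        assert abs(track.fold - n * (L - 40) / target.length) < 1e-9

    def test_empty_targets_raise(self):
        with pytest.raises(ConfigError):
            compute_coverage([], [])

    def test_binned_track_covers_target(self, target):
        mols = [make_molecule("m1", start=1_000_101, end=1_000_540)]
        track = compute_coverage(mols, [target])
        assert len(track.bins100) == 10  # 1 kb target, 100 bp bins
        interior = track.bins100.iloc[2]
        assert interior["coverage"] == 1.0


class TestFrequency:
    def test_arithmetic(self):
        calls = [make_del_call(call_id=f"c{i}") for i in range(30)]
        f = sv_frequency(calls, 1500.0)
        assert f.frequency == pytest.approx(0.02)

    def test_zero_calls(self):
        assert sv_frequency([], 100.0).frequency == 0.0

    def test_zero_coverage_undefined(self):
        with pytest.raises(ConfigError):
            sv_frequency([], 0.0)

    def test_scale_invariance(self):
        calls = [make_del_call(call_id=f"c{i}") for i in range(12)]
        f1 = sv_frequency(calls, 600.0)
        f2 = sv_frequency(calls + [make_del_call(call_id=f"d{i}") for i in range(12)],
                          1200.0)
        assert f1.frequency == pytest.approx(f2.frequency)


class TestBreakpointDensity:
    def _track(self, target, per_base):
        """Coverage track with uniform base coverage built from stacked
        molecules."""
        mols = [
            make_molecule(
                f"m{i}", start=target.padded_start, end=target.padded_end + 40
            )
            for i in range(per_base)
        ]
        return compute_coverage(mols, [target])

    def test_threshold_boundary_masks_at_499(self):
        target = TargetRegion(
            name="t", chrom="chr1", capture_start=20_001, capture_end=30_000,
            pad=5_000,
        )
        track = self._track(target, 499)
        calls = [make_del_call(p1=21_000, p2=29_000, call_id="c1")]
        dens = breakpoint_density(calls, track)
        assert dens["density"].isna().all()
        assert (dens["count"] >= 0).all()

    def test_density_defined_at_500(self):
        target = TargetRegion(
            name="t", chrom="chr1", capture_start=20_001, capture_end=30_000,
            pad=5_000,
        )
        track = self._track(target, 500)
        calls = [make_del_call(p1=21_000, p2=29_000, call_id="c1")]
        dens = breakpoint_density(calls, track)
        hit = dens[dens["count"] > 0]
        assert len(hit) == 2
        assert np.allclose(hit["density"], hit["count"] / hit["coverage"])

    def test_no_calls_zero_counts_masks_unchanged(self):
        target = TargetRegion(
            name="t", chrom="chr1", capture_start=20_001, capture_end=30_000,
            pad=5_000,
        )
        track = self._track(target, 499)
        dens = breakpoint_density([], track)
        assert (dens["count"] == 0).all()
        assert dens["density"].isna().all()

    def test_uniform_breakpoints_flat_density(self):
        """Uniformly planted breakpoints with uniform coverage give a flat
        density within 3 SE of the Poisson expectation per bin."""
        target = TargetRegion(
            name="t", chrom="chr1", capture_start=100_001, capture_end=200_000,
            pad=0,
        )
        track = self._track(target, 600)
        rng = np.random.default_rng(11)
        n = 4000
        positions = rng.integers(100_001, 200_001, size=n)
        calls = [
            make_del_call(p1=int(p), p2=int(p) + 500_000, call_id=f"c{i}")
            for i, p in enumerate(positions)
        ]
        dens = breakpoint_density(calls, track)
        in_span = dens[dens["start"] >= 100_001]
        # only bp1 falls in the span; expect n / nbins per bin
        nbins = len(in_span)
        lam = n / nbins
        counts = in_span["count"].to_numpy()
        assert abs(counts.mean() - lam) < 3 * np.sqrt(lam / nbins)
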