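"""Coverage normalisation, status calling and per-nucleotide CNV testing."""

import numpy as np
import pandas as pd
import pytest

from hemiassoc import (
    CnvInjection,
    CohortConfig,
    DepthTrack,
    Region,
    bed_cnv_association,
    call_position_status,
    normalize_tracks,
    position_association,
    simulate_depth,
)
from hemiassoc.cnv import read_depth_tsv
from tests.conftest import SMALL_REGION

GROUPS_88 = np.array(["case"] * 40 + ["control"] * 48, dtype=object)
CTRL_88 = GROUPS_88 == "control"


def track(sample_id, depths, total=None):
    return DepthTrack(
        sample_id=sample_id,
        chrom="chr22",
        positions=np.arange(100, 100 + len(depths)),
        raw_depth=np.asarray(depths),
        total_reads=total,
    )


class TestNormalization:
    def test_constant_depth(self):
        t = track("s1", [20] * 5, total=1e6)
        assert np.allclose(t.normalized, 2e-5)

    def test_scale_invariance(self):
        a = track("s1", [10, 20, 30], total=600.0)
        b = track("s1", [20, 40, 60], total=1200.0)
        assert np.allclose(a.normalized, b.normalized)

    def test_hand_computed_matrix(self):
        tracks = [
            track("s1", [10, 20, 30]),  # total 60
            track("s2", [5, 5, 10]),    # total 20
            track("s3", [8, 0, 8]),     # total 16
        ]
        pos, norm, sids = normalize_tracks(tracks)
        expected = np.array([
            [10 / 60, 20 / 60, 30 / 60],
            [5 / 20, 5 / 20, 10 / 20],
            [8 / 16, 0.0, 8 / 16],
        ])
        assert np.allclose(norm, expected)
        assert sids == ["s1", "s2", "s3"]

    def test_zero_total_reads_is_error(self):
        t = track("s1", [0, 0, 0])
        with pytest.raises(ValueError, match="total_reads"):
            _ = t.normalized

    def test_mismatched_positions_rejected(self):
        a = track("s1", [1, 2, 3])
        b = DepthTrack("s2", "chr22", np.arange(200, 203), np.array([1, 2, 3]))
        with pytest.raises(ValueError, match="different positions"):
            normalize_tracks([a, b])


class TestStatusCalling:
    def test_identical_samples_all_normal(self):
        norm = np.ones((5, 10)) * 2e-5
        status, tested = call_position_status(norm)
        assert (status == 0).all()
        assert tested.all()

    def test_boundary_is_strictly_exclusive(self):
        """A sample at exactly loss_ratio x reference stays normal."""
        norm = np.ones((5, 1))
        norm[0, 0] = 0.75  # reference median = 1.0, cutoff 0.75 * 1.0
        status, _ = call_position_status(norm, loss_ratio=0.75)
        assert status[0, 0] == 0
        norm[0, 0] = 0.7499
        status, _ = call_position_status(norm, loss_ratio=0.75)
        assert status[0, 0] == -1

    def test_gain_calls(self):
        norm = np.ones((5, 1))
        norm[0, 0] = 1.51
        status, _ = call_position_status(norm, gain_ratio=1.5)
        assert status[0, 0] == 1

    def test_uncovered_positions_skipped(self):
        norm = np.ones((5, 2))
        raw = np.ones((5, 2))
        raw[:3, 1] = 0  # 60% of samples uncovered at position 1
        _, tested = call_position_status(norm, raw, min_covered_fraction=0.8)
        assert list(tested) == [True, False]

    def test_needs_three_reference_samples(self):
        with pytest.raises(ValueError, match=">= 3 reference"):
            call_position_status(np.ones((2, 4)))

    def test_injected_loss_flagged_in_carriers(self):
        """A 0.5x CNV in 10/40 cases flags those carriers at >=95% of positions."""
        cfg = CohortConfig(
            region=SMALL_REGION, seed=41,
            cnv_injection=CnvInjection(18_410_000, 18_420_000, 0.5, case_fraction=0.25),
        )
        ds = simulate_depth(cfg)
        norm = ds.depth / ds.depth.sum(axis=1, keepdims=True)
        status, _ = call_position_status(norm, ds.depth, reference_rows=CTRL_88)
        sel = np.nonzero((ds.positions >= 18_410_000) & (ds.positions <= 18_420_000))[0]
        carriers = [i for i, s in enumerate(ds.sample_ids) if s in ds.cnv_carriers]
        assert len(carriers) == 10
        flag_rate = (status[np.ix_(carriers, sel)] == -1).mean()
        assert flag_rate >= 0.95


class TestPositionAssociation:
    def test_noiseless_shared_cnv_gives_identical_adjacent_p(self):
        norm = np.ones((10, 6))
        norm[:3, 2:5] = 0.4  # 3 of 10 samples deleted over positions 2..4
        groups = np.array(["case"] * 5 + ["control"] * 5, dtype=object)
        status, tested = call_position_status(norm)
        res = position_association(status, groups, np.arange(100, 106), tested=tested)
        p = res.results["p_value"].to_numpy()
        assert p[2] == p[3] == p[4]
        assert p[0] == p[1] == p[5] == 1.0

    def test_single_aberrant_sample_never_significant(self):
        """One aberrant case cannot clear Bonferroni at these group sizes."""
        norm = np.ones((88, 100))
        norm[0, :] = 0.3  # one case deleted everywhere
        status, tested = call_position_status(norm, reference_rows=CTRL_88)
        res = position_association(status, GROUPS_88, np.arange(1, 101), tested=tested)
        assert int(res.results["significant"].sum()) == 0
        assert (res.results.loc[res.results["a"] > 0, "direction"] == "loss").all()

    def test_null_tracks_rarely_significant(self):
        """No injected CNV: zero Bonferroni-significant positions in >=95% of seeds."""
        clean = 0
        n_seeds = 25
        for seed in range(n_seeds):
            ds = simulate_depth(CohortConfig(region=SMALL_REGION, seed=200 + seed))
            norm = ds.depth / ds.depth.sum(axis=1, keepdims=True)
            status, tested = call_position_status(norm, ds.depth, reference_rows=CTRL_88)
            res = position_association(status, GROUPS_88, ds.positions, tested=tested)
            clean += int(res.results["significant"].sum()) == 0
        assert clean >= round(0.95 * n_seeds)

    def test_interval_merging(self):
        status = np.zeros((10, 8), dtype=np.int8)
        # make positions 1,2 and 5 significant by giving all cases a loss there
        status[:5, [1, 2, 5]] = -1
        groups = np.array(["case"] * 5 + ["control"] * 5, dtype=object)
        res = position_association(status, groups, np.arange(100, 108), alpha=0.5)
        assert res.results["significant"].tolist() == [False, True, True, False, False, True, False, False]
        assert res.intervals.values.tolist() == [["chr22", 100, 102], ["chr22", 104, 105]]


def test_depth_tsv_roundtrip(tmp_path):
    p = tmp_path / "s9.depth.tsv"
    pd.DataFrame({"c": ["chr22"] * 4, "p": [10, 11, 12, 13], "d": [5, 6, 0, 8]}).to_csv(
        p, sep="\t", index=False, header=False
    )
    t = read_depth_tsv(p)
    assert t.sample_id == "s9"
    assert list(t.raw_depth) == [5, 6, 0, 8]
    assert t.total_reads == 19.0


def test_bed_ingestion_hook():
    manifest = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(8)],
            "group": ["case"] * 4 + ["control"] * 4,
        }
    )
    calls = pd.DataFrame(
        {
            "sample_id": ["s0", "s1", "s2", "s7"],
            "chrom": ["chr22"] * 4,
            "start": [100, 150, 500, 120],
            "end": [200, 260, 600, 180],
        }
    )
    res = bed_cnv_association(calls, manifest, ("chr22", 110, 210))
    # overlapping the query interval: s0, s1 (cases), s7 (control); s2 is outside
    assert (res["a"], res["b"], res["c"], res["d"]) == (2, 2, 1, 3)
    assert 0 <= res["p_value"] <= 1
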