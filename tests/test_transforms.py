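"""Numeric transformations: quantization, sinogram decoding, padding, relinking."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tagmaps.archive import CorrelationRecord, StorageVersion
from tagmaps.transforms import (
    N_LEAVES,
    CouchInsertionSpec,
    LinkMethod,
    PlanSinogramV3,
    PlanSinogramV4,
    SinogramLayout,
    TransformError,
    compute_scale_factor,
    decode_plan_sinogram_payload,
    decode_sinogram_v4,
    dequantize_dose,
    detect_sinogram_version,
    encode_plan_sinogram_payload,
    insert_couch,
    pad_for_export,
    quantize_dose,
    quantize_grid,
    relink_corrections,
)
from tagmaps.synth import encode_sinogram_v4_events


# ---------------------------------------------------------------------------
# dose quantization


class TestScaleFactor:
    @pytest.mark.parametrize("k", [0.5, 1.0, 2.0, 1e-3])
    def test_definition_identity(self, k):
        grid = np.zeros((4, 4, 4), dtype=np.float32)
        grid[0, 0, 0] = 65535.0 * k
        assert compute_scale_factor(grid) == pytest.approx(k, rel=1e-6)

    def test_all_zero_grid_sentinel(self):
        grid = np.zeros((3, 3, 3), dtype=np.float32)
        assert compute_scale_factor(grid) == 1.0
        assert quantize_dose(grid, 1.0).voxels16.max() == 0

    @pytest.mark.parametrize("bad", [np.float32(-1.0), np.float32("nan")])
    def test_negative_or_nan_rejected(self, bad):
        grid = np.ones((2, 2, 2), dtype=np.float32)
        grid[0, 0, 0] = bad
        with pytest.raises(TransformError):
            compute_scale_factor(grid)

    def test_sf_times_range_reaches_max(self):
        rng = np.random.default_rng(1)
        grid = rng.uniform(0, 42.0, (16, 16, 16)).astype(np.float32)
        assert 65535.0 * compute_scale_factor(grid) == pytest.approx(float(grid.max()), rel=1e-6)


class TestQuantization:
    def test_max_voxel_is_exact_endpoint(self):
        grid = np.array([[[10.0, 5.0]]], dtype=np.float32)
        sf = compute_scale_factor(grid)
        sd = quantize_dose(grid, sf)
        assert sd.voxels16[0, 0, 0] == 65535
        assert dequantize_dose(sd).voxels[0, 0, 0] == pytest.approx(10.0, rel=1e-6)

    def test_vectorized_equals_brute_force(self):
        rng = np.random.default_rng(2)
        grid = rng.uniform(0, 60.0, (5, 5, 5)).astype(np.float32)
        sf = compute_scale_factor(grid)
        fast = quantize_grid(grid, sf)
        # per-voxel reference: divide, round half away from zero, clamp
        slow = np.empty_like(fast)
        for idx in np.ndindex(grid.shape):
            q = int(np.floor(float(grid[idx]) / sf + 0.5))
            slow[idx] = min(max(q, 0), 65535)
        assert np.array_equal(fast, slow)

    @given(seed=st.integers(0, 500), dose_max=st.floats(0.1, 80.0))
    def test_roundtrip_error_within_half_scale_step(self, seed, dose_max):
        rng = np.random.default_rng(seed)
        grid = (rng.random((8, 8, 8)) * dose_max).astype(np.float32)
        sf = compute_scale_factor(grid)
        sd = quantize_dose(grid, sf)
        # exact bound on the scaled integers; the float32 output adds at most
        # one representation rounding (max * eps / 2) on top
        exact = np.abs(sd.voxels16.astype(np.float64) * sf - grid.astype(np.float64)).max()
        assert exact <= sf / 2 + 1e-12
        back = dequantize_dose(sd).voxels
        err = np.abs(back.astype(np.float64) - grid.astype(np.float64)).max()
        assert err <= sf / 2 + float(grid.max()) * np.finfo(np.float32).eps / 2 + 1e-12
        assert err / grid.max() * 100 <= 0.001


# ---------------------------------------------------------------------------
# plan sinograms


def _sampling_oracle(sg4: PlanSinogramV4, n_proj: int, dt: float = 1e-3) -> np.ndarray:
    """Brute-force decode: sample the MLC state every ``dt`` seconds."""
    tau = sg4.projection_duration_s
    out = np.zeros((n_proj, N_LEAVES))
    for i, leaf in enumerate(sg4.open_leaf_indices):
        opens = sg4.events[2 * i]
        closes = sg4.events[2 * i + 1]
        ok = ~np.isnan(opens)
        for o, c in zip(opens[ok], closes[ok]):
            t = np.arange(o + dt / 2, c, dt)
            k = ((t - sg4.warmup_s) / tau).astype(int)
            k = k[(k >= 0) & (k < n_proj)]
            for kk in k:
                out[kk, leaf - 1] += dt / tau
    return out


def _random_sg4(rng, n_proj=10, tau=0.25, warmup=10.0, leaves=(12, 20, 33)):
    fractions = np.zeros((n_proj, N_LEAVES), dtype=np.float32)
    for leaf in leaves:
        f = rng.uniform(0, 1, n_proj)
        f[rng.random(n_proj) < 0.4] = 0.0
        f[rng.integers(0, n_proj)] = rng.uniform(0.3, 1.0)
        fractions[:, leaf - 1] = f.astype(np.float32)
    events = encode_sinogram_v4_events(fractions, leaves, warmup, tau)
    return fractions, PlanSinogramV4(
        events=events, open_leaf_indices=leaves, warmup_s=warmup, projection_duration_s=tau
    )


class TestSinogramDetection:
    def test_v3_layout(self):
        raw = np.zeros((5, 64), dtype=np.float32)
        assert detect_sinogram_version(raw, StorageVersion.V3) == SinogramLayout.V3_FRACTIONS

    def test_v4_layout(self):
        raw = np.zeros((6, 3), dtype=np.float64)
        assert detect_sinogram_version(raw, StorageVersion.V4_2PLUS) == SinogramLayout.V4_EVENTS

    def test_dtype_version_disagreement_is_error(self):
        raw = np.zeros((6, 3), dtype=np.float64)
        with pytest.raises(TransformError, match="inconsistent"):
            detect_sinogram_version(raw, StorageVersion.V3)


class TestSinogramDecoding:
    def test_single_full_projection_window(self):
        events = np.array([[10.0], [10.2]])  # open exactly during projection 0
        sg = PlanSinogramV4(events=events, open_leaf_indices=(30,), warmup_s=10.0, projection_duration_s=0.2)
        f = decode_sinogram_v4(sg, 3).fractions
        assert f[0, 29] == pytest.approx(1.0)
        assert f.sum() == pytest.approx(1.0)

    def test_closed_leaves_are_all_zero_and_row_count(self):
        rng = np.random.default_rng(0)
        leaves = tuple(range(11, 53))
        fractions = np.zeros((8, N_LEAVES), dtype=np.float32)
        for leaf in leaves:
            fractions[:, leaf - 1] = rng.uniform(0.1, 1.0, 8).astype(np.float32)
        events = encode_sinogram_v4_events(fractions, leaves, 10.0, 0.2)
        assert events.shape[0] == 84  # 42 recorded leaves x 2 rows
        sg = PlanSinogramV4(events=events, open_leaf_indices=leaves, warmup_s=10.0, projection_duration_s=0.2)
        out = decode_sinogram_v4(sg, 8).fractions
        assert np.all(out[:, :10] == 0) and np.all(out[:, 52:] == 0)

    @given(seed=st.integers(0, 200))
    def test_decode_matches_time_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fractions, sg = _random_sg4(rng)
        decoded = decode_sinogram_v4(sg, 10).fractions
        oracle = _sampling_oracle(sg, 10)
        assert np.abs(decoded - oracle).max() <= 2e-3 / sg.projection_duration_s

    @given(seed=st.integers(0, 200))
    def test_open_time_conservation(self, seed):
        rng = np.random.default_rng(seed)
        fractions, sg = _random_sg4(rng)
        decoded = decode_sinogram_v4(sg, 10).fractions
        tau = sg.projection_duration_s
        for i, leaf in enumerate(sg.open_leaf_indices):
            opens, closes = sg.events[2 * i], sg.events[2 * i + 1]
            ok = ~np.isnan(opens)
            total = float((closes[ok] - opens[ok]).sum())
            assert decoded[:, leaf - 1].sum() * tau == pytest.approx(total, abs=1e-6)

    def test_event_beyond_delivery_end_is_error(self):
        events = np.array([[10.0], [12.5]])
        sg = PlanSinogramV4(events=events, open_leaf_indices=(30,), warmup_s=10.0, projection_duration_s=0.2)
        with pytest.raises(TransformError, match="beyond"):
            decode_sinogram_v4(sg, 2)

    def test_overlapping_intervals_are_error(self):
        events = np.array([[10.0, 10.1], [10.3, 10.4]])
        sg = PlanSinogramV4(events=events, open_leaf_indices=(30,), warmup_s=10.0, projection_duration_s=0.5)
        with pytest.raises(TransformError, match="overlapping"):
            decode_sinogram_v4(sg, 1)

    def test_cross_version_equivalence(self):
        rng = np.random.default_rng(9)
        fractions, sg4 = _random_sg4(rng, n_proj=16)
        v3 = PlanSinogramV3(fractions=fractions)  # v3 storage: the fractions themselves
        decoded = decode_sinogram_v4(sg4, 16)
        assert np.abs(decoded.fractions - v3.fractions).max() <= 1e-6


class TestSinogramPayload:
    def test_v3_identity_roundtrip(self):
        rng = np.random.default_rng(4)
        sg = PlanSinogramV3(fractions=rng.random((7, N_LEAVES)).astype(np.float32))
        payload = encode_plan_sinogram_payload(sg)
        back = decode_plan_sinogram_payload(payload, 7)
        assert np.array_equal(back.fractions, sg.fractions)

    def test_v4_composition(self):
        rng = np.random.default_rng(5)
        fractions, sg4 = _random_sg4(rng)
        payload = encode_plan_sinogram_payload(decode_sinogram_v4(sg4, 10))
        assert np.abs(
            decode_plan_sinogram_payload(payload, 10).fractions - fractions
        ).max() <= 1e-6

    def test_out_of_range_rejected(self):
        bad = np.full((2, N_LEAVES), 0.5, dtype=np.float32)
        sg = PlanSinogramV3(fractions=bad)
        sg.fractions[0, 0] = 1.5  # mutate after construction to reach the encoder check
        with pytest.raises(TransformError):
            encode_plan_sinogram_payload(sg)


# ---------------------------------------------------------------------------
# couch insertion and export padding


class TestCouchInsertion:
    def test_enhancement_dimensions(self):
        img = np.arange(256 * 256, dtype=np.int16).reshape(256, 256)
        spec = CouchInsertionSpec(target_width=384, couch_height_px=28)
        out, shift = insert_couch(img, spec)
        assert out.shape == (284, 384)

    def test_zero_enhancement_is_identity(self):
        img = np.arange(64 * 64, dtype=np.int16).reshape(64, 64)
        out, shift = insert_couch(img, CouchInsertionSpec(target_width=64, couch_height_px=0))
        assert np.array_equal(out, img) and shift == (0, 0)

    def test_inherited_region_unchanged(self):
        rng = np.random.default_rng(6)
        img = rng.integers(-1000, 2000, (100, 120)).astype(np.int16)
        spec = CouchInsertionSpec(target_width=150, couch_height_px=10, pad_value=0)
        out, (dr, dc) = insert_couch(img, spec)
        assert np.array_equal(out[dr : dr + 100, dc : dc + 120], img)

    def test_isocenter_outside_output_is_error(self):
        img = np.zeros((10, 10), dtype=np.int16)
        spec = CouchInsertionSpec(target_width=12, couch_height_px=2, isocenter_px=(40, 5))
        with pytest.raises(TransformError, match="isocenter"):
            insert_couch(img, spec)


class TestExportPadding:
    def test_landscape_to_square(self):
        img = np.arange(284 * 384, dtype=np.int16).reshape(284, 384)
        out = pad_for_export(img, pad_value=0)
        assert out.shape == (384, 384)
        assert np.array_equal(out[:284, :], img)  # top-aligned
        assert np.all(out[284:, :] == 0)

    def test_square_unchanged(self):
        img = np.arange(16, dtype=np.int16).reshape(4, 4)
        assert pad_for_export(img) is img

    @given(h=st.integers(2, 40), w=st.integers(2, 40))
    def test_output_square_and_region_preserved(self, h, w):
        rng = np.random.default_rng(h * 100 + w)
        img = rng.integers(-1024, 3000, (h, w)).astype(np.int16)
        out = pad_for_export(img, pad_value=-5)
        n = max(h, w)
        assert out.shape == (n, n)
        if w >= h:
            assert np.array_equal(out[:h, :], img)
        else:
            left = (n - w) // 2
            assert np.array_equal(out[:, left : left + w], img)


# ---------------------------------------------------------------------------
# correction relinking


def _corr(uid, ts, linked=None):
    return CorrelationRecord(
        record_uid=uid, linked_scan_uid=linked, timestamp=ts,
        translations=(0.0, 0.0, 0.0), rotations=(0.0, 0.0, 0.0),
    )


def _nearest_oracle(corrections, scans, tolerance_s):
    """Brute-force nearest-in-time with injectivity, mirroring the contract."""
    out = {}
    claimed = {}
    for rec in corrections:
        if rec.linked_scan_uid is not None:
            out[rec.record_uid] = (rec.linked_scan_uid, LinkMethod.UID)
            continue
        best, best_uid, tie = None, None, False
        for uid, t in scans:
            d = abs((rec.timestamp - t).total_seconds())
            if best is None or d < best:
                best, best_uid, tie = d, uid, False
            elif d == best:
                tie = True
        if best is None or best > tolerance_s or tie:
            out[rec.record_uid] = (None, LinkMethod.UNLINKED)
        elif best_uid in claimed:
            out[claimed[best_uid]] = (None, LinkMethod.UNLINKED)
            out[rec.record_uid] = (None, LinkMethod.UNLINKED)
        else:
            claimed[best_uid] = rec.record_uid
            out[rec.record_uid] = (best_uid, LinkMethod.TIMESTAMP)
    return out


class TestRelinking:
    T0 = datetime(2011, 5, 10, 9, 0, 0)

    def test_intact_uid_kept(self):
        scans = [("S1", self.T0)]
        rec = _corr("C1", self.T0 + timedelta(hours=5), linked="S9")
        assert relink_corrections([rec], scans)["C1"] == ("S9", LinkMethod.UID)

    def test_fifty_jittered_scans_fully_recovered(self):
        rng = np.random.default_rng(7)
        scans = [(f"S{i}", self.T0 + timedelta(seconds=300 * i)) for i in range(50)]
        recs = [
            _corr(f"C{i}", self.T0 + timedelta(seconds=300 * i + float(rng.uniform(-30, 30))))
            for i in range(50)
        ]
        links = relink_corrections(recs, scans, tolerance_s=120.0)
        assert all(links[f"C{i}"] == (f"S{i}", LinkMethod.TIMESTAMP) for i in range(50))

    def test_far_correction_stays_unlinked(self):
        scans = [("S1", self.T0)]
        rec = _corr("C1", self.T0 + timedelta(hours=10))
        assert relink_corrections([rec], scans, tolerance_s=120.0)["C1"] == (None, LinkMethod.UNLINKED)

    def test_conflicting_claims_unlink_both(self):
        scans = [("S1", self.T0)]
        recs = [_corr("C1", self.T0 + timedelta(seconds=10)), _corr("C2", self.T0 - timedelta(seconds=5))]
        links = relink_corrections(recs, scans, tolerance_s=120.0)
        assert links["C1"] == (None, LinkMethod.UNLINKED)
        assert links["C2"] == (None, LinkMethod.UNLINKED)

    @given(seed=st.integers(0, 400))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_scans, n_corr = int(rng.integers(1, 9)), int(rng.integers(1, 9))
        scans = [
            (f"S{i}", self.T0 + timedelta(seconds=float(rng.uniform(0, 3600))))
            for i in range(n_scans)
        ]
        recs = [
            _corr(f"C{i}", self.T0 + timedelta(seconds=float(rng.uniform(0, 3600))),
                  linked="SX" if rng.random() < 0.2 else None)
            for i in range(n_corr)
        ]
        tol = float(rng.uniform(30, 600))
        assert relink_corrections(recs, scans, tol) == _nearest_oracle(recs, scans, tol)
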