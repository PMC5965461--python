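"""Raw-data transformations applied during DICOM-RT export.

Four families of transformation are needed to turn archived binaries into
standard DICOM-RT payloads:

* **Dose quantization** — archived voxel doses are float32 gray; RT-Dose
  stores unsigned 16-bit integers with a gray-per-unit scale factor
  ``SF = max dose / 65535`` (the ``DoseGridScaling`` element).  With
  round-half-away-from-zero the worst round-trip error is SF/2, i.e.
  1/(2*65535) ~ 0.00076% of the maximum dose.

* **Plan sinogram decoding** — v3 archives store the multileaf-collimator
  (MLC) sinogram directly as per-projection leaf-open fractions (float32,
  one column per leaf, 64 leaves); v4 archives store, for the open leaves
  only, cumulative open/close event times in seconds (float64, two rows
  per open leaf).  Both are converted to the common per-projection
  fraction layout before being embedded in the RT-Plan.

* **Couch-insertion padding** — treatment-planning replaces the diagnostic
  couch in the plan CT with the treatment-unit couch, widening the image
  and appending couch rows; DICOM export then pads the result to a square
  pixel grid.  Only the observable dimension arithmetic and the
  bit-preservation of the inherited region are reproduced here.

* **Correction relinking** — image-guidance positional corrections carry a
  UID link to their scan; when that link was lost at recording time, the
  nearest scan in acquisition time (within a tolerance) is matched instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum

import numpy as np

from .archive import CorrelationRecord, StorageVersion

__all__ = [
    "TransformError",
    "DoseGrid",
    "ScaledDose",
    "PlanSinogramV3",
    "PlanSinogramV4",
    "CouchInsertionSpec",
    "SinogramLayout",
    "LinkMethod",
    "N_LEAVES",
    "compute_scale_factor",
    "quantize_dose",
    "dequantize_dose",
    "quantize_grid",
    "detect_sinogram_version",
    "decode_sinogram_v4",
    "encode_plan_sinogram_payload",
    "decode_plan_sinogram_payload",
    "insert_couch",
    "pad_for_export",
    "relink_corrections",
]

#: the binary MLC has a fixed bank of 64 leaves
N_LEAVES = 64

#: 16-bit unsigned integer range maximum
U16_MAX = 65535


class TransformError(Exception):
    pass


# ---------------------------------------------------------------------------
# dose quantization


@dataclass
class DoseGrid:
    """Absorbed dose on a regular voxel grid, float32, units Gy."""

    voxels: np.ndarray  # 3-D float32, Gy
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, patient coords


@dataclass
class ScaledDose:
    """16-bit quantized dose: ``dose_Gy = voxels16 * scale_factor``."""

    voxels16: np.ndarray  # same shape, uint16
    scale_factor: float  # Gy per integer unit


def _as_voxels(grid: DoseGrid | np.ndarray) -> np.ndarray:
    return grid.voxels if isinstance(grid, DoseGrid) else np.asarray(grid)


def compute_scale_factor(grid: DoseGrid | np.ndarray) -> float:
    """Gy-per-unit scale factor: maximum voxel dose / 65535.

    An all-zero grid has no meaningful scale; the sentinel SF = 1 is used so
    that dequantization still reproduces the zeros exactly.
    """
    voxels = _as_voxels(grid)
    if voxels.size == 0:
        raise TransformError("empty dose grid")
    if np.isnan(voxels).any():
        raise TransformError("dose grid contains NaN")
    vmax = float(voxels.max())
    if not np.isfinite(vmax):
        raise TransformError("dose grid contains non-finite values")
    if float(voxels.min()) < 0:
        raise TransformError("dose grid contains negative values")
    if vmax == 0.0:
        return 1.0
    return vmax / U16_MAX


def quantize_grid(values: np.ndarray, scale: float) -> np.ndarray:
    """Divide by ``scale`` and round half away from zero, clamped to uint16.

    numpy's default rounding is half-to-even; half-away-from-zero keeps the
    worst-case reconstruction error at exactly scale/2 and matches the
    arithmetic the scale-factor definition implies.
    """
    if scale <= 0:
        raise TransformError(f"scale factor must be positive, got {scale}")
    q = np.floor(np.asarray(values, dtype=np.float64) / scale + 0.5)
    clipped = np.clip(q, 0, U16_MAX)
    if (clipped != q).any():
        import logging

        logging.getLogger(__name__).warning("quantization clamped out-of-range values")
    return clipped.astype(np.uint16)


def quantize_dose(grid: DoseGrid | np.ndarray, sf: float) -> ScaledDose:
    return ScaledDose(voxels16=quantize_grid(_as_voxels(grid), sf), scale_factor=sf)


def dequantize_dose(sd: ScaledDose) -> DoseGrid:
    return DoseGrid(voxels=(sd.voxels16.astype(np.float64) * sd.scale_factor).astype(np.float32))


# ---------------------------------------------------------------------------
# plan sinograms


@dataclass
class PlanSinogramV3:
    """Per-projection MLC leaf-open fractions (the common layout).

    ``fractions[k, j]`` is the fraction of projection k's duration during
    which leaf j+1 was open, in [0, 1]; always all 64 leaves.
    """

    fractions: np.ndarray  # (n_projections, 64) float32

    def __post_init__(self) -> None:
        f = self.fractions
        if f.ndim != 2 or f.shape[1] != N_LEAVES:
            raise TransformError(f"v3 sinogram must be (n_projections, {N_LEAVES}), got {f.shape}")
        if f.size and (float(f.min()) < 0 or float(f.max()) > 1.0 + 1e-6):
            raise TransformError("leaf-open fractions must lie in [0, 1]")


@dataclass
class PlanSinogramV4:
    """Cumulative open/close event times for the leaves ever open.

    ``events`` has two rows per open leaf: row 2i holds leaf
    ``open_leaf_indices[i]``'s opening times, row 2i+1 its closing times,
    both cumulative seconds since beam-on (including the warm-up offset).
    Rows are NaN-padded to a common event count.  Leaves absent from
    ``open_leaf_indices`` were closed for the whole delivery and are not
    recorded.
    """

    events: np.ndarray  # (2 * n_open_leaves, n_events) float64
    open_leaf_indices: tuple[int, ...]  # sorted, 1-based
    warmup_s: float
    projection_duration_s: float

    def __post_init__(self) -> None:
        if self.events.shape[0] != 2 * len(self.open_leaf_indices):
            raise TransformError(
                f"event grid has {self.events.shape[0]} rows for "
                f"{len(self.open_leaf_indices)} open leaves (need 2 per leaf)"
            )
        if list(self.open_leaf_indices) != sorted(set(self.open_leaf_indices)):
            raise TransformError("open_leaf_indices must be sorted and unique")
        if any(not 1 <= i <= N_LEAVES for i in self.open_leaf_indices):
            raise TransformError("leaf indices are 1-based in 1..64")


class SinogramLayout(Enum):
    V3_FRACTIONS = "v3"
    V4_EVENTS = "v4"


def detect_sinogram_version(raw: np.ndarray, declared: StorageVersion) -> SinogramLayout:
    """Classify a raw sinogram blob by dtype, cross-checked against the
    archive's declared storage version.

    float32 is the v3 per-projection-fraction layout, float64 the v4
    cumulative-event layout.  A dtype/version disagreement is an error —
    decoding must never guess.
    """
    if raw.size == 0:
        raise TransformError("empty sinogram blob")
    if raw.dtype == np.float32:
        layout = SinogramLayout.V3_FRACTIONS
    elif raw.dtype == np.float64:
        layout = SinogramLayout.V4_EVENTS
    else:
        raise TransformError(f"sinogram dtype {raw.dtype} is neither float32 nor float64")
    is_v3 = declared == StorageVersion.V3
    if is_v3 != (layout == SinogramLayout.V3_FRACTIONS):
        raise TransformError(
            f"sinogram dtype {raw.dtype} inconsistent with archive version {declared.name}"
        )
    return layout


def decode_sinogram_v4(sg: PlanSinogramV4, n_projections: int) -> PlanSinogramV3:
    """Convert cumulative open/close events to per-projection open fractions.

    Projection k spans the half-open window
    ``[warmup + k*tau, warmup + (k+1)*tau)``; a leaf's fraction in that
    projection is the total overlap of its open intervals with the window,
    divided by tau.  Leaves never open contribute all-zero columns, so the
    output always covers the full 64-leaf bank.
    """
    tau = sg.projection_duration_s
    if tau <= 0:
        raise TransformError("projection duration must be positive")
    t_end = sg.warmup_s + n_projections * tau
    fractions = np.zeros((n_projections, N_LEAVES), dtype=np.float64)
    edges = sg.warmup_s + tau * np.arange(n_projections + 1)

    for i, leaf in enumerate(sg.open_leaf_indices):
        opens = sg.events[2 * i]
        closes = sg.events[2 * i + 1]
        valid = ~np.isnan(opens)
        if not np.array_equal(valid, ~np.isnan(closes)):
            raise TransformError(f"leaf {leaf}: open/close events not paired")
        opens, closes = opens[valid], closes[valid]
        if opens.size == 0:
            continue
        if (closes <= opens).any():
            raise TransformError(f"leaf {leaf}: close time not after open time")
        if (opens[1:] < closes[:-1] - 1e-12).any():
            raise TransformError(f"leaf {leaf}: overlapping open intervals")
        if closes[-1] > t_end + 1e-9:
            raise TransformError(
                f"leaf {leaf}: event at {closes[-1]:.6f}s beyond delivery end {t_end:.6f}s"
            )
        # overlap of each (open, close) interval with each projection window
        lo = np.maximum(opens[:, None], edges[None, :-1])
        hi = np.minimum(closes[:, None], edges[None, 1:])
        fractions[:, leaf - 1] = np.clip(hi - lo, 0.0, None).sum(axis=0) / tau

    return PlanSinogramV3(fractions=np.clip(fractions, 0.0, 1.0).astype(np.float32))


def encode_plan_sinogram_payload(sg: PlanSinogramV3) -> bytes:
    """Row-major float32 bytes for the private RT-Plan sinogram element.

    The payload goes under the private tag (300D,10A7) with private creator
    ``TAGMAP-TOMO`` reserving block 0x10 of group 0x300D
    (:mod:`tagmaps.builders`).  Encoding is the identity on the v3 layout,
    so ``decode(encode(x)) == x`` bit-exactly.
    """
    f = sg.fractions
    if f.size and (float(f.min()) < 0 or float(f.max()) > 1.0):
        raise TransformError("fractions out of [0, 1]")
    data = np.ascontiguousarray(f, dtype="<f4").tobytes()
    if len(data) % 2:  # DICOM OB values must have even length
        data += b"\x00"
    return data


def decode_plan_sinogram_payload(payload: bytes, n_projections: int) -> PlanSinogramV3:
    n = n_projections * N_LEAVES * 4
    grid = np.frombuffer(payload[:n], dtype="<f4").reshape(n_projections, N_LEAVES)
    return PlanSinogramV3(fractions=grid)


# ---------------------------------------------------------------------------
# plan-CT couch insertion and export padding


@dataclass
class CouchInsertionSpec:
    """How the treatment-unit couch image is merged into a plan CT slice.

    The incoming slice is widened to ``target_width`` columns (split
    equally, extra column to the right) and ``couch_height_px`` rows
    carrying ``couch_profile`` are appended below; the inherited pixel
    block is never altered, which is what keeps the treatment isocenter
    position recoverable.
    """

    target_width: int
    couch_height_px: int
    couch_profile: np.ndarray | None = None  # stored values, length target_width
    pad_value: int = 0  # stored value for -1024 HU under the default rescale
    isocenter_px: tuple[int, int] | None = None  # (row, col) in the input slice


def _split_pad(total: int) -> tuple[int, int]:
    left = total // 2
    return left, total - left


def insert_couch(image: np.ndarray, spec: CouchInsertionSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Widen a slice and append couch rows; returns (enhanced image, shift).

    ``shift`` is the (row, col) offset of the inherited block inside the
    output, i.e. what must be added to any pixel position (the isocenter in
    particular) to keep pointing at the same anatomy.
    """
    image = np.asarray(image)
    h, w = image.shape
    if spec.target_width < w:
        raise TransformError(f"target width {spec.target_width} < source width {w}")
    left, right = _split_pad(spec.target_width - w)
    out = np.full((h + spec.couch_height_px, spec.target_width), spec.pad_value, dtype=image.dtype)
    out[:h, left : left + w] = image
    if spec.couch_height_px > 0:
        profile = spec.couch_profile
        if profile is None:
            profile = np.full(spec.target_width, spec.pad_value, dtype=image.dtype)
        out[h:, :] = np.asarray(profile, dtype=image.dtype)[None, :]
    shift = (0, left)
    if spec.isocenter_px is not None:
        r, c = spec.isocenter_px
        if not (0 <= r < out.shape[0] and 0 <= c + left < out.shape[1]):
            raise TransformError("isocenter falls outside the enhanced image")
    return out, shift


def pad_for_export(image: np.ndarray, pad_value: int = 0) -> np.ndarray:
    """Pad a slice to a square pixel grid for DICOM export.

    Landscape input (width > height) gets pad rows appended below, keeping
    the content top-aligned; portrait input gets pad columns split equally
    left/right (extra column right).  The inherited block is bit-identical
    to the input; a square input is returned unchanged.
    """
    image = np.asarray(image)
    h, w = image.shape
    n = max(h, w)
    if h == w:
        return image
    out = np.full((n, n), pad_value, dtype=image.dtype)
    if w > h:  # landscape: append rows below
        out[:h, :] = image
    else:  # portrait: split columns
        left, _ = _split_pad(n - w)
        out[:, left : left + w] = image
    return out


# ---------------------------------------------------------------------------
# correction relinking


class LinkMethod(Enum):
    UID = "UID"
    TIMESTAMP = "TIMESTAMP"
    UNLINKED = "UNLINKED"


def relink_corrections(
    corrections: list[CorrelationRecord],
    scans: list[tuple[str, datetime]],
    tolerance_s: float = 120.0,
) -> dict[str, tuple[str | None, LinkMethod]]:
    """Map each correction record to its image-guidance scan.

    Records with an intact ``linked_scan_uid`` keep it (method UID).  The
    rest are matched to the scan whose acquisition time is nearest their
    own timestamp, provided it lies within ``tolerance_s`` seconds (method
    TIMESTAMP).  A record with no scan in tolerance, a tied distance, or a
    scan already claimed by another timestamp match is left UNLINKED —
    the timestamp mapping must be injective, one correction per scan.

    Returns record_uid -> (scan_uid or None, method).
    """
    out: dict[str, tuple[str | None, LinkMethod]] = {}
    claimed: dict[str, str] = {}  # scan_uid -> record_uid (timestamp matches only)

    for rec in corrections:
        if rec.linked_scan_uid is not None:
            out[rec.record_uid] = (rec.linked_scan_uid, LinkMethod.UID)
            continue
        if not scans:
            out[rec.record_uid] = (None, LinkMethod.UNLINKED)
            continue
        deltas = [(abs((rec.timestamp - t).total_seconds()), uid) for uid, t in scans]
        best = min(d for d, _ in deltas)
        candidates = [uid for d, uid in deltas if d == best]
        if best > tolerance_s or len(candidates) > 1:
            out[rec.record_uid] = (None, LinkMethod.UNLINKED)
            continue
        scan_uid = candidates[0]
        if scan_uid in claimed:
            # conflict: two corrections claim one scan -> both unlinked
            other = claimed[scan_uid]
            out[other] = (None, LinkMethod.UNLINKED)
            out[rec.record_uid] = (None, LinkMethod.UNLINKED)
            import logging

            logging.getLogger(__name__).warning(
                "corrections %s and %s both match scan %s; both left unlinked",
                other,
                rec.record_uid,
                scan_uid,
            )
            continue
        claimed[scan_uid] = rec.record_uid
        out[rec.record_uid] = (scan_uid, LinkMethod.TIMESTAMP)
    return out
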