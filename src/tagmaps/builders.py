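"""Assembly of DICOM-RT files from evaluated TagMaps plus transformed payloads.

Each supported object type (plan CT, image-guidance MVCT, RT-Plan, RT-Dose,
RT-Structure Set, adaptive-dose "QADose", delivery-sinogram RT-Image) is a
specialization that shares the generic skeleton/evaluate pipeline and adds
its own raw-data transformation:

===================  ====================================================
variant              raw-data hook
===================  ====================================================
CTImage / MVCTImage  square export padding of the stored slice
RTPlan               sinogram version detection + v4 -> fraction decoding,
                     payload under private tag (300D,10A7)
RTDose / QADose      16-bit quantization, scale factor in DoseGridScaling
DeliverySinogram     16-bit detector-grid packing, scale in RescaleSlope
RTStruct             none (contours are textual)
===================  ====================================================

Cross-object UID links are preserved by rewriting every archive UID through
one deterministic hash namespace (:func:`assign_uids`), after which the
reference graph over an exported patient must be closed — no exported file
may reference an object that is not in the set.

Private blocks (all invented, documented here and in docs/methods.md):

* group 0x300D, creator ``TAGMAP-TOMO`` (block 0x10): (300D,10A0) number of
  projections, (300D,10A1) projection duration in s, (300D,10A7) the plan
  sinogram as row-major float32 leaf-open fractions.
* group 0x7771, creator ``TAGMAP-CORR`` (block 0x10): image-guidance
  positional corrections embedded in MVCT files — translations (mm),
  rotations (deg), timestamp, link method.
* group 0x7773, creator ``TAGMAP-QA``: QADose label element.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.tag import Tag
from pydicom.uid import ExplicitVRLittleEndian

from .archive import CorrelationRecord, VendorArchive
from .engine import (
    BindingContext,
    BlobRef,
    DicomObjectSpec,
    TagMap,
    XPathBackend,
    build_skeleton,
    evaluate,
)
from . import transforms
from .transforms import (
    LinkMethod,
    PlanSinogramV3,
    PlanSinogramV4,
    SinogramLayout,
    compute_scale_factor,
    quantize_grid,
)

__all__ = [
    "BuilderError",
    "VersionMismatchError",
    "DanglingReferenceError",
    "BuiltObject",
    "build_object",
    "build_qadose",
    "build_delivery_sinogram",
    "embed_corrections",
    "assign_uids",
    "write_dicom",
    "uid_reference_check",
    "DEFAULT_UID_ROOT",
    "SOP_CLASSES",
]


class BuilderError(Exception):
    pass


class VersionMismatchError(BuilderError):
    """TagMap's version scope does not include the archive's version."""


class DanglingReferenceError(BuilderError):
    """An exported object references a UID no exported object declares."""


#: SOP Class UIDs per variant; MVCT uses CT Image Storage and is
#: distinguished by series description, QADose uses RT Dose Storage plus a
#: private label element.
SOP_CLASSES = {
    "CT": "1.2.840.10008.5.1.4.1.1.2",
    "MVCT": "1.2.840.10008.5.1.4.1.1.2",
    "RTPLAN": "1.2.840.10008.5.1.4.1.1.481.5",
    "RTDOSE": "1.2.840.10008.5.1.4.1.1.481.2",
    "QADOSE": "1.2.840.10008.5.1.4.1.1.481.2",
    "RTSTRUCT": "1.2.840.10008.5.1.4.1.1.481.3",
    "DELIVERY_SINOGRAM": "1.2.840.10008.5.1.4.1.1.481.1",
}

DEFAULT_UID_ROOT = "1.2.826.0.1.3680043.10.424"

PIXEL_DATA = Tag(0x7FE0, 0x0010)
SINOGRAM_TAG = Tag(0x300D, 0x10A7)


@dataclass
class BuiltObject:
    """An assembled dataset plus its provenance and completeness state."""

    variant: str
    dataset: Dataset
    spec: DicomObjectSpec
    source_uid: str | None = None  # archive UID the object was built from

    @property
    def complete(self) -> bool:
        return self.spec.complete

    @property
    def failed_tags(self) -> list[str]:
        return [str(t) for t, _ in self.spec.failures]


# ---------------------------------------------------------------------------
# raw-data hooks


def _blob_value(spec: DicomObjectSpec, tag: Tag) -> BlobRef | None:
    try:
        el = spec.element(tag)
    except KeyError:
        return None
    return el.value if isinstance(el.value, BlobRef) else None


def _hook_image(spec: DicomObjectSpec, ds: Dataset, archive: VendorArchive) -> None:
    ref = _blob_value(spec, PIXEL_DATA)
    if ref is None:
        return
    blob = archive.resolve_uid(ref.uid)
    image = archive.read_blob(blob)
    intercept = float(ds.get("RescaleIntercept", -1024))
    slope = float(ds.get("RescaleSlope", 1)) or 1.0
    pad_value = int(round((-1024.0 - intercept) / slope))
    padded = transforms.pad_for_export(image, pad_value=pad_value)
    ds.Rows, ds.Columns = (int(s) for s in padded.shape)
    ds.PixelData = np.ascontiguousarray(padded, dtype="<i2").tobytes()


def _hook_dose(spec: DicomObjectSpec, ds: Dataset, archive: VendorArchive) -> None:
    ref = _blob_value(spec, PIXEL_DATA)
    if ref is None:
        return
    blob = archive.resolve_uid(ref.uid)
    grid = archive.read_blob(blob)
    sf = compute_scale_factor(grid)
    # DS is limited to 16 bytes; 10 significant digits keep the relative
    # truncation ~1e-10, far inside the SF/2 round-trip bound.
    ds.DoseGridScaling = format(sf, ".10g")
    voxels16 = quantize_grid(grid, float(ds.DoseGridScaling))
    frames, rows, cols = grid.shape
    ds.NumberOfFrames = frames
    ds.Rows, ds.Columns = rows, cols
    ds.FrameIncrementPointer = Tag(0x3004, 0x000C)
    dz = float(blob.meta.get("sliceSpacing", 3.0))
    ds.GridFrameOffsetVector = [format(k * dz, "g") for k in range(frames)]
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(voxels16, dtype="<u2").tobytes()


def _hook_plan(spec: DicomObjectSpec, ds: Dataset, archive: VendorArchive) -> None:
    ref = _blob_value(spec, SINOGRAM_TAG)
    if ref is None:
        return
    blob = archive.resolve_uid(ref.uid)
    raw = archive.read_blob(blob)
    layout = transforms.detect_sinogram_version(raw, archive.version)
    n_projections = int(blob.meta["nProjections"])
    if layout == SinogramLayout.V3_FRACTIONS:
        sg3 = PlanSinogramV3(fractions=raw)
    else:
        sg4 = PlanSinogramV4(
            events=raw,
            open_leaf_indices=tuple(int(i) for i in blob.meta["openLeafIndices"].split()),
            warmup_s=float(blob.meta.get("warmupTime", 10.0)),
            projection_duration_s=float(blob.meta["projectionDuration"]),
        )
        sg3 = transforms.decode_sinogram_v4(sg4, n_projections)
    ds.add_new(Tag(0x300D, 0x10A0), "IS", n_projections)
    ds.add_new(Tag(0x300D, 0x10A1), "DS", format(float(blob.meta["projectionDuration"]), "g"))
    ds.add_new(SINOGRAM_TAG, "OB", transforms.encode_plan_sinogram_payload(sg3))


def _hook_delivery(spec: DicomObjectSpec, ds: Dataset, archive: VendorArchive) -> None:
    ref = _blob_value(spec, PIXEL_DATA)
    if ref is None:
        return
    blob = archive.resolve_uid(ref.uid)
    grid = archive.read_blob(blob)  # (detector channels, projections)
    vmax = float(grid.max()) if grid.size else 0.0
    slope = vmax / 65535.0 if vmax > 0 else 1.0
    ds.RescaleSlope = format(slope, ".10g")
    ds.RescaleIntercept = "0"
    packed = quantize_grid(grid, float(ds.RescaleSlope))
    ds.Rows, ds.Columns = (int(s) for s in grid.shape)
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(packed, dtype="<u2").tobytes()


def _hook_none(spec: DicomObjectSpec, ds: Dataset, archive: VendorArchive) -> None:
    pass


_HOOKS = {
    "CT": _hook_image,
    "MVCT": _hook_image,
    "RTPLAN": _hook_plan,
    "RTDOSE": _hook_dose,
    "QADOSE": _hook_dose,
    "RTSTRUCT": _hook_none,
    "DELIVERY_SINOGRAM": _hook_delivery,
    "RTRECORD": _hook_none,
}


# ---------------------------------------------------------------------------
# building


def build_object(
    tagmap: TagMap,
    archive: VendorArchive,
    ctx: BindingContext,
    backend=None,
) -> BuiltObject:
    """Evaluate a TagMap against one patient and run the variant's raw-data hook.

    The archive's storage version must be inside the TagMap's declared
    scope — checked before any query runs, so a v3-only map can never be
    applied to a v4 archive by accident.
    """
    if archive.version not in tagmap.version_scope:
        raise VersionMismatchError(
            f"TagMap for {tagmap.target_type} covers "
            f"{sorted(v.name for v in tagmap.version_scope)}, archive is {archive.version.name}"
        )
    if backend is None:
        patient_id = ctx.user_inputs.get("patientID")
        backend = XPathBackend(archive.document_for(patient_id))
    spec = build_skeleton(tagmap)
    evaluate(spec, backend, ctx, blob_uids=set(archive.binary_index))
    ds = spec.to_dataset()
    _HOOKS[tagmap.target_type](spec, ds, archive)
    source = None
    for key in ("scanUID", "doseUID", "planUID", "structUID"):
        if key in ctx.user_inputs:
            source = str(ctx.user_inputs[key])
            break
    return BuiltObject(variant=tagmap.target_type, dataset=ds, spec=spec, source_uid=source)


def build_qadose(tagmap: TagMap, archive: VendorArchive, dose_uid: str, patient_id: str) -> BuiltObject:
    """Assemble a QADose (dose recalculated on a daily MVCT) for one stored
    adaptive-dose blob; its referenced series points at the MVCT, not the
    plan CT."""
    ctx = BindingContext(user_inputs={"patientID": patient_id, "doseUID": dose_uid})
    return build_object(tagmap, archive, ctx)


def build_delivery_sinogram(tagmap: TagMap, archive: VendorArchive, scan_uid: str, patient_id: str) -> BuiltObject:
    ctx = BindingContext(user_inputs={"patientID": patient_id, "scanUID": scan_uid})
    return build_object(tagmap, archive, ctx)


# ---------------------------------------------------------------------------
# hidden-data embedding

CORR_GROUP = 0x7771
CORR_CREATOR = "TAGMAP-CORR"


def embed_corrections(
    obj: BuiltObject | Dataset,
    record: CorrelationRecord,
    method: LinkMethod,
) -> None:
    """Write a positional-correction private block into an MVCT dataset.

    UNLINKED records write nothing (logged); otherwise the block is fully
    present: translations, rotations, timestamp and the link method that
    recovered the association.
    """
    ds = obj.dataset if isinstance(obj, BuiltObject) else obj
    if method == LinkMethod.UNLINKED:
        import logging

        logging.getLogger(__name__).warning(
            "correction %s is unlinked; not embedded", record.record_uid
        )
        return
    block = ds.private_block(CORR_GROUP, CORR_CREATOR, create=True)
    block.add_new(0x01, "DS", [format(v, "g") for v in record.translations])
    block.add_new(0x02, "DS", [format(v, "g") for v in record.rotations])
    block.add_new(0x03, "DT", record.timestamp.strftime("%Y%m%d%H%M%S"))
    block.add_new(0x04, "LO", method.value)


def read_embedded_corrections(ds: Dataset) -> dict | None:
    """Inverse of :func:`embed_corrections`, for QA and round-trip tests."""
    try:
        block = ds.private_block(CORR_GROUP, CORR_CREATOR)
    except KeyError:
        return None
    return {
        "translations": tuple(float(v) for v in block[0x01].value),
        "rotations": tuple(float(v) for v in block[0x02].value),
        "timestamp": str(block[0x03].value),
        "link_method": str(block[0x04].value),
    }


# ---------------------------------------------------------------------------
# UID assignment and reference closure

_STANDARD_PREFIX = "1.2.840.10008"

#: tags whose UI value *declares* an identity
_DECLARING = {
    Tag(0x0008, 0x0018),  # SOPInstanceUID
    Tag(0x0020, 0x000D),  # StudyInstanceUID
    Tag(0x0020, 0x000E),  # SeriesInstanceUID
    Tag(0x0020, 0x0052),  # FrameOfReferenceUID (declared by image variants)
}

_IMAGE_VARIANTS = {"CT", "MVCT", "DELIVERY_SINOGRAM"}


def hash_uid(archive_uid: str, seed: int, namespace_root: str = DEFAULT_UID_ROOT) -> str:
    """Deterministic export UID: namespace root + truncated SHA-256 of
    (archive UID, seed).  Same archive + same seed -> byte-identical UIDs."""
    digest = hashlib.sha256(f"{archive_uid}|{seed}".encode()).hexdigest()
    return f"{namespace_root}.{int(digest[:18], 16)}"


def _walk_ui(ds: Dataset, fn) -> None:
    for elem in ds.iterall():
        if elem.VR == "UI":
            fn(elem)


def assign_uids(
    objects: list[BuiltObject],
    namespace_root: str = DEFAULT_UID_ROOT,
    seed: int = 0,
    check: bool = True,
) -> list[BuiltObject]:
    """Rewrite every non-standard UID through the deterministic hash namespace.

    Standard UIDs (SOP classes, transfer syntaxes — the 1.2.840.10008 root)
    are left untouched.  Because the mapping is a pure function of the
    archive UID, every cross-reference (dose -> plan, plan -> structure
    set, QADose -> MVCT series, plan -> CT frame of reference) lands on the
    same exported UID, which is what keeps the links intact.  With
    ``check=True`` the reference graph is verified closed afterwards.
    """

    def remap(elem):
        def one(v: str) -> str:
            v = str(v)
            if not v or v.startswith(_STANDARD_PREFIX) or v.startswith(namespace_root + "."):
                return v
            return hash_uid(v, seed, namespace_root)

        if elem.VM > 1:
            elem.value = [one(v) for v in elem.value]
        else:
            elem.value = one(elem.value)

    for obj in objects:
        _walk_ui(obj.dataset, remap)
    if check:
        problems = uid_reference_check(objects)
        if problems:
            raise DanglingReferenceError("; ".join(problems))
    return objects


def uid_reference_check(objects: list[BuiltObject]) -> list[str]:
    """Return a description of every dangling UID reference (empty = closed).

    Declared identities are the top-level SOP/Study/Series instance UIDs
    plus the frame of reference declared by image objects; references are
    every ReferencedSOPInstanceUID, every UID inside sequence items, and
    the frame-of-reference element of non-image objects.
    """
    declared: set[str] = set()
    for obj in objects:
        ds = obj.dataset
        for tag in _DECLARING:
            if tag == Tag(0x0020, 0x0052) and obj.variant not in _IMAGE_VARIANTS:
                continue
            if tag in ds:
                declared.add(str(ds[tag].value))

    problems: list[str] = []
    for obj in objects:
        ds = obj.dataset
        refs: list[tuple[str, str]] = []
        nested: list = []
        for elem in ds:
            if elem.VR == "SQ":
                for item in elem.value:
                    nested.extend(item.iterall())
        for elem in nested:
            if elem.VR != "UI":
                continue
            if elem.tag == Tag(0x0008, 0x1155):
                refs.append(("ReferencedSOPInstanceUID", str(elem.value)))
            elif elem.tag == Tag(0x0020, 0x000E):
                # series UID inside a sequence item = a series reference
                refs.append(("referenced SeriesInstanceUID", str(elem.value)))
            elif elem.tag == Tag(0x0020, 0x0052):
                refs.append(("referenced FrameOfReferenceUID", str(elem.value)))
        if obj.variant not in _IMAGE_VARIANTS and Tag(0x0020, 0x0052) in ds:
            refs.append(("FrameOfReferenceUID", str(ds[Tag(0x0020, 0x0052)].value)))
        for what, uid in refs:
            if uid and uid not in declared:
                problems.append(f"{obj.variant} ({what}) -> {uid} is not declared by any exported object")
    return problems


# ---------------------------------------------------------------------------
# writing


def write_dicom(obj: BuiltObject, path: str | Path, policy: str = "lenient") -> Path | None:
    """Write one built object as a Part-10 file, Explicit VR Little Endian.

    Under the default lenient policy INCOMPLETE objects are still written
    (partial data is delivered, with completeness recorded by the caller's
    QA report); under ``strict`` they are withheld and ``None`` is returned.
    """
    if not obj.complete and policy == "strict":
        return None
    path = Path(path)
    ds = obj.dataset
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    fds = FileDataset(str(path), ds, file_meta=meta, preamble=b"\x00" * 128)
    path.parent.mkdir(parents=True, exist_ok=True)
    fds.save_as(path, enforce_file_format=True)
    return path
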