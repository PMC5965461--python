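"""Loading and UID-indexed access to tomo-lite patient archives.

A tomo-lite archive is a directory tree in which every patient directory
holds one ``patient.xml`` master document plus flat sibling binary files
named ``<UID>.img`` (image slices), ``<UID>.bin`` (dose grids and plan
sinograms) and ``<UID>.dpe`` (delivery sinograms).  All binaries are raw,
headerless, little-endian; their dtype and shape are declared by the XML
element that references them.  The full dialect is documented in
``docs/tomo-lite.md``.

Binary payloads are loaded lazily: :func:`load_archive` indexes every
referenced UID but touches no payload file until :meth:`VendorArchive.read_blob`
is called, so batch exports of many patients never hold all pixel data in
memory.  Referenced-but-absent binaries are recorded as missing rather than
aborting the load, because historic archives are routinely incomplete.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
from lxml import etree

__all__ = [
    "ArchiveError",
    "UnknownVersionError",
    "MissingBlobError",
    "BlobLengthError",
    "StorageVersion",
    "BinaryBlob",
    "CorrelationRecord",
    "VendorArchive",
    "load_archive",
    "detect_storage_version",
]


class ArchiveError(Exception):
    """Base class for archive loading/resolution failures."""


class UnknownVersionError(ArchiveError):
    """The master document declares no recognisable storage version."""


class MissingBlobError(ArchiveError):
    """A UID does not resolve to a binary payload."""

    def __init__(self, uid: str):
        self.uid = uid
        super().__init__(f"no binary payload for UID {uid!r}")


class BlobLengthError(ArchiveError):
    """A payload file's byte length disagrees with its declared dtype/shape."""


@functools.total_ordering
class StorageVersion(enum.Enum):
    """The three major archive storage generations.

    Ordering ``V3 < V4_0 < V4_2PLUS`` follows release chronology.  The only
    raw-data format that changed between generations is the plan sinogram
    (per-projection open fractions in v3, cumulative open/close event times
    in v4), so the version gates the sinogram decoding path.
    """

    V3 = 0
    V4_0 = 1
    V4_2PLUS = 2

    def __lt__(self, other: "StorageVersion") -> bool:
        if not isinstance(other, StorageVersion):
            return NotImplemented
        return self.value < other.value

    @classmethod
    def from_marker(cls, marker: str) -> "StorageVersion":
        """Map a ``formatVersion`` marker string to a version label.

        Prefix rules: ``3.*`` -> V3, ``4.0*`` -> V4_0, any other ``4.*`` ->
        V4_2PLUS.  Anything else is an explicit error — the decoder must
        never silently guess a sinogram layout.
        """
        marker = marker.strip()
        if marker.startswith("3."):
            return cls.V3
        if marker.startswith("4.0"):
            return cls.V4_0
        if marker.startswith("4."):
            return cls.V4_2PLUS
        raise UnknownVersionError(f"unknown storage version marker {marker!r}")


#: dtypes a tomo-lite binary may declare, all little-endian.
BLOB_DTYPES = {
    "float32": np.dtype("<f4"),
    "float64": np.dtype("<f8"),
    "int16": np.dtype("<i2"),
    "uint16": np.dtype("<u2"),
}

_KIND_SUFFIX = {"img": ".img", "bin": ".bin", "dpe": ".dpe"}


@dataclass(frozen=True)
class BinaryBlob:
    """Descriptor for one raw binary payload (not yet loaded).

    ``meta`` carries the simple child texts and attributes of the XML
    element that referenced the blob (projection counts, spacings, ...),
    so object builders can run their raw-data transformations without
    re-parsing the master document.
    """

    uid: str
    kind: str  # img | bin | dpe
    path: Path
    dtype: str
    shape: tuple[int, ...]
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def byte_length(self) -> int:
        n = BLOB_DTYPES[self.dtype].itemsize
        for s in self.shape:
            n *= s
        return n

    def check_length(self) -> None:
        actual = self.path.stat().st_size if self.path.exists() else -1
        if actual != self.byte_length:
            raise BlobLengthError(
                f"blob {self.uid}: file {self.path.name} has {actual} bytes, "
                f"declared {self.dtype}{self.shape} = {self.byte_length} bytes"
            )

    def read(self) -> np.ndarray:
        """Decode the payload into the declared dtype/shape (little-endian)."""
        self.check_length()
        data = np.fromfile(self.path, dtype=BLOB_DTYPES[self.dtype])
        return data.reshape(self.shape)


@dataclass
class CorrelationRecord:
    """One image-guidance positional correction (6 degrees of freedom).

    ``linked_scan_uid`` is the UID of the image-guidance scan the correction
    belongs to; it is ``None`` when the treatment-unit/database link was
    broken at recording time, in which case timestamp fallback relinking
    applies (:func:`tagmaps.transforms.relink_corrections`).
    """

    record_uid: str
    linked_scan_uid: str | None
    timestamp: datetime
    translations: tuple[float, float, float]  # lateral, longitudinal, vertical [mm]
    rotations: tuple[float, float, float]  # roll, pitch, yaw [deg]


def _text(elem: etree._Element, path: str) -> str | None:
    node = elem.find(path)
    if node is None or node.text is None:
        return None
    return node.text.strip()


def _uid_of(elem: etree._Element) -> str | None:
    return _text(elem, "dbInfo/databaseUID")


_VALID_UID_CHARS = set("0123456789.")


def is_valid_uid(uid: str) -> bool:
    """Syntactic DICOM UID check: dot-separated numeric components, <=64 chars."""
    if not uid or len(uid) > 64 or set(uid) - _VALID_UID_CHARS:
        return False
    parts = uid.split(".")
    return all(p != "" and (p == "0" or not p.startswith("0")) for p in parts)


@dataclass
class VendorArchive:
    """A parsed, indexed tomo-lite archive.

    ``payload_reads`` is an audit log of blob UIDs whose payload files were
    actually opened; tests use it to assert lazy loading.
    """

    root_path: Path
    master_docs: list  # list of (patient_id, ElementTree)
    binary_index: dict[str, BinaryBlob]
    version: StorageVersion
    patient_ids: list[str]
    missing_uids: set[str] = field(default_factory=set)
    payload_reads: list[str] = field(default_factory=list)

    def document_for(self, patient_id: str) -> etree._ElementTree:
        for pid, doc in self.master_docs:
            if pid == patient_id:
                return doc
        raise ArchiveError(f"no master document for patient {patient_id!r}")

    def resolve_uid(self, uid: str) -> BinaryBlob:
        """Resolve a UID to its payload descriptor without loading it."""
        blob = self.binary_index.get(uid)
        if blob is None:
            raise MissingBlobError(uid)
        blob.check_length()
        return blob

    def read_blob(self, blob: BinaryBlob | str) -> np.ndarray:
        if isinstance(blob, str):
            blob = self.resolve_uid(blob)
        self.payload_reads.append(blob.uid)
        grid = blob.read()
        # NaN passes through unmodified but is flagged — except in float64
        # event blobs, where NaN is the defined row padding (v4 sinograms).
        if (
            np.issubdtype(grid.dtype, np.floating)
            and grid.dtype != np.float64
            and np.isnan(grid).any()
        ):
            import logging

            logging.getLogger(__name__).warning(
                "blob %s contains NaN values (passed through)", blob.uid
            )
        return grid

    # -- typed views over the master documents ------------------------------

    def list_images(self, patient_id: str, image_type: str | None = None) -> list[str]:
        """UIDs of image entries for one patient, optionally filtered by type
        (``KVCT``, ``MVCT`` or ``DELIVERY``)."""
        doc = self.document_for(patient_id)
        out = []
        for elem in doc.findall("fullImageDataArray/imageData"):
            if image_type is not None and _text(elem, "imageType") != image_type:
                continue
            uid = _uid_of(elem)
            if uid:
                out.append(uid)
        return out

    def list_plans(self, patient_id: str) -> list[str]:
        doc = self.document_for(patient_id)
        return [u for e in doc.findall("fullPlanDataArray/planData") if (u := _uid_of(e))]

    def list_structs(self, patient_id: str) -> list[str]:
        doc = self.document_for(patient_id)
        return [
            u
            for e in doc.findall("fullPlanDataArray/planData/structureSet")
            if (u := _uid_of(e))
        ]

    def list_doses(self, patient_id: str, dose_type: str | None = None) -> list[str]:
        doc = self.document_for(patient_id)
        out = []
        for elem in doc.findall("fullDoseDataArray/doseData"):
            if dose_type is not None and _text(elem, "doseType") != dose_type:
                continue
            uid = _uid_of(elem)
            if uid:
                out.append(uid)
        return out

    def image_scans(self, patient_id: str, image_type: str = "MVCT") -> list[tuple[str, datetime]]:
        """(scan UID, acquisition datetime) pairs, for correction relinking."""
        doc = self.document_for(patient_id)
        out = []
        for elem in doc.findall("fullImageDataArray/imageData"):
            if _text(elem, "imageType") != image_type:
                continue
            uid = _uid_of(elem)
            ts = _text(elem, "acquisitionDateTime")
            if uid and ts:
                out.append((uid, datetime.fromisoformat(ts)))
        return out

    def correlation_records(self, patient_id: str) -> list[CorrelationRecord]:
        doc = self.document_for(patient_id)
        records = []
        for elem in doc.findall("fullCorrelationDataArray/correlationData"):
            uid = _uid_of(elem)
            linked = _text(elem, "linkedScanUID")
            if linked is not None and not is_valid_uid(linked):
                raise ArchiveError(
                    f"correlation record {uid}: linkedScanUID {linked!r} is not a valid UID"
                )
            ts = _text(elem, "timestamp")
            tr = tuple(float(v) for v in _text(elem, "translations").split())
            ro = tuple(float(v) for v in _text(elem, "rotations").split())
            records.append(
                CorrelationRecord(
                    record_uid=uid,
                    linked_scan_uid=linked,
                    timestamp=datetime.fromisoformat(ts),
                    translations=tr,
                    rotations=ro,
                )
            )
        return records


# ---------------------------------------------------------------------------
# loading

_BINARY_PARENTS = (
    # (xpath within patient.xml, blob kind resolver)
    ("fullImageDataArray/imageData", None),  # kind depends on imageType
    ("fullDoseDataArray/doseData", "bin"),
    ("fullPlanDataArray/planData/sinogram", "bin"),
)


def _blob_kind(elem: etree._Element, default: str | None) -> str:
    if default is not None:
        return default
    return "dpe" if _text(elem, "imageType") == "DELIVERY" else "img"


def _collect_meta(elem: etree._Element) -> dict:
    meta = dict(elem.attrib)
    header = elem.find("arrayHeader")
    if header is not None:
        meta.update(header.attrib)
    for child in elem:
        if child.tag in ("dbInfo", "arrayHeader"):
            continue
        if len(child) == 0 and child.text and child.text.strip():
            meta[child.tag] = child.text.strip()
    return meta


def load_archive(path: str | Path) -> VendorArchive:
    """Load and index every patient under ``path``.

    ``path`` is either a single patient directory (contains ``patient.xml``)
    or a root directory whose subdirectories are patient directories.  At
    least one master document must parse; missing binary payloads are
    recorded in ``missing_uids`` rather than raised, so incomplete or
    historic archives still load.
    """
    root = Path(path)
    if not root.is_dir():
        raise ArchiveError(f"archive path {root} is not a directory")
    masters = sorted(root.glob("patient.xml")) or sorted(root.glob("*/patient.xml"))
    if not masters:
        raise ArchiveError(f"no patient.xml master document found under {root}")

    master_docs: list[tuple[str, etree._ElementTree]] = []
    binary_index: dict[str, BinaryBlob] = {}
    missing: set[str] = set()
    versions: set[StorageVersion] = set()
    patient_ids: list[str] = []

    for master in masters:
        try:
            doc = etree.parse(str(master))
        except etree.XMLSyntaxError as exc:
            raise ArchiveError(f"malformed master document {master}: {exc}") from exc
        top = doc.getroot()
        if top.tag != "fullPatient":
            raise ArchiveError(f"{master}: root element is <{top.tag}>, expected <fullPatient>")
        marker = top.get("formatVersion")
        if marker is None:
            raise UnknownVersionError(f"{master}: missing formatVersion marker")
        versions.add(StorageVersion.from_marker(marker))

        pid = _text(top, "briefPatient/patientID")
        if pid is None:
            raise ArchiveError(f"{master}: briefPatient/patientID missing")
        patient_ids.append(pid)
        master_docs.append((pid, doc))

        pdir = master.parent
        for parent_path, kind_default in _BINARY_PARENTS:
            for elem in top.findall(parent_path):
                uid = _uid_of(elem)
                header = elem.find("arrayHeader")
                if uid is None or header is None:
                    continue
                kind = _blob_kind(elem, kind_default)
                dtype = header.get("dtype")
                if dtype not in BLOB_DTYPES:
                    raise ArchiveError(f"{master}: blob {uid} declares unknown dtype {dtype!r}")
                shape = tuple(int(s) for s in header.get("shape").split())
                if any(s <= 0 for s in shape):
                    raise ArchiveError(f"{master}: blob {uid} declares non-positive shape {shape}")
                if uid in binary_index:
                    raise ArchiveError(f"duplicate binary UID {uid}")
                blob = BinaryBlob(
                    uid=uid,
                    kind=kind,
                    path=pdir / f"{uid}{_KIND_SUFFIX[kind]}",
                    dtype=dtype,
                    shape=shape,
                    meta=_collect_meta(elem),
                )
                if blob.path.exists():
                    binary_index[uid] = blob
                else:
                    missing.add(uid)

    if len(versions) > 1:
        raise ArchiveError(f"mixed storage versions in one archive: {sorted(v.name for v in versions)}")

    return VendorArchive(
        root_path=root,
        master_docs=master_docs,
        binary_index=binary_index,
        version=versions.pop(),
        patient_ids=patient_ids,
        missing_uids=missing,
    )


def detect_storage_version(archive: VendorArchive) -> StorageVersion:
    """The storage generation declared by the archive's master documents."""
    return archive.version
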