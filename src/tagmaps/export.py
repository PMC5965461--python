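"""Batch export orchestration: unattended patient-by-patient DICOM-RT export.

One export job walks every selected patient of an archive, builds all
requested object types from the packaged (or user-supplied) TagMaps,
relinks and embeds the positional corrections, rewrites UIDs through the
deterministic export namespace, writes Part-10 files plus a per-patient QA
report, and aggregates the completeness accounting.  A failure inside one
patient is recorded and never aborts the batch — only configuration errors
(unparseable TagMaps, unknown object types) are fatal, and they are raised
before any patient is touched.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pydicom
from pydicom.tag import Tag

from .archive import VendorArchive, load_archive
from .builders import (
    DEFAULT_UID_ROOT,
    BuiltObject,
    assign_uids,
    build_object,
    hash_uid,
    read_embedded_corrections,
    uid_reference_check,
    write_dicom,
)
from .engine import BindingContext, TagMap, parse_tagmap
from .transforms import LinkMethod, relink_corrections

__all__ = [
    "ExportJob",
    "ExportReport",
    "load_tagmaps",
    "run_export",
    "validate_outputs",
    "SUPPORTED_TYPES",
]

log = logging.getLogger("tagmaps.export")

SUPPORTED_TYPES = ["CT", "MVCT", "RTSTRUCT", "RTPLAN", "RTDOSE", "QADOSE", "DELIVERY_SINOGRAM"]

#: maps each type to (archive listing method, binding input name)
_SOURCES = {
    "CT": ("list_images", "KVCT", "scanUID"),
    "MVCT": ("list_images", "MVCT", "scanUID"),
    "DELIVERY_SINOGRAM": ("list_images", "DELIVERY", "scanUID"),
    "RTPLAN": ("list_plans", None, "planUID"),
    "RTSTRUCT": ("list_structs", None, "structUID"),
    "RTDOSE": ("list_doses", "PLAN", "doseUID"),
    "QADOSE": ("list_doses", "QA", "doseUID"),
}


@dataclass
class ExportJob:
    archive_path: str | Path
    out_root: str | Path
    patients: list[str] | None = None  # None = all
    types: list[str] = field(default_factory=lambda: list(SUPPORTED_TYPES))
    tagmap_dir: str | Path | None = None  # None = packaged maps
    seed: int = 0
    uid_root: str = DEFAULT_UID_ROOT
    policy: str = "lenient"  # lenient writes INCOMPLETE objects, strict withholds
    relink_tolerance_s: float = 120.0

    def __post_init__(self) -> None:
        unknown = set(self.types) - set(SUPPORTED_TYPES)
        if unknown:
            raise ValueError(f"unknown object types requested: {sorted(unknown)}")
        if self.policy not in ("lenient", "strict"):
            raise ValueError(f"policy must be 'lenient' or 'strict', got {self.policy!r}")


@dataclass
class ExportReport:
    """Per-patient accounting plus batch aggregates.

    Invariant (checked by tests): objects complete + incomplete = processed,
    per patient and in aggregate; likewise for data sets.
    """

    seed: int
    patients: list[dict] = field(default_factory=list)

    @property
    def aggregate(self) -> dict:
        ok = [p for p in self.patients if p.get("error") is None]
        failed = [p for p in self.patients if p.get("error") is not None]
        complete = sum(p["objects_complete"] for p in ok)
        incomplete = sum(p["objects_incomplete"] for p in ok)
        datasets_complete = sum(1 for p in ok if p["objects_incomplete"] == 0)
        return {
            "patients_processed": len(self.patients),
            "patients_failed": len(failed),
            "objects_complete": complete,
            "objects_incomplete": incomplete,
            "objects_processed": complete + incomplete,
            "datasets_complete": datasets_complete,
            "datasets_needing_processing": len(ok) - datasets_complete,
        }

    def to_dict(self) -> dict:
        return {"seed": self.seed, "aggregate": self.aggregate, "patients": self.patients}


def load_tagmaps(tagmap_dir: str | Path | None = None) -> dict[str, TagMap]:
    """Parse every TagMap XML in a directory (default: the packaged maps).

    Returns target_type -> TagMap; RTRECORD maps are keyed by file stem so
    both backend variants stay addressable.
    """
    if tagmap_dir is None:
        base = resources.files("tagmaps") / "maps"
        files = [p for p in base.iterdir() if p.name.endswith(".xml")]
    else:
        files = sorted(Path(tagmap_dir).glob("*.xml"))
    maps: dict[str, TagMap] = {}
    for f in files:
        tm = parse_tagmap(f.read_text())
        key = tm.target_type if tm.target_type != "RTRECORD" else Path(str(f)).stem
        maps[key] = tm
    return maps


# ---------------------------------------------------------------------------


def _export_patient(
    archive: VendorArchive,
    pid: str,
    maps: dict[str, TagMap],
    job: ExportJob,
    out_dir: Path,
) -> dict:
    objects: list[BuiltObject] = []
    for obj_type in job.types:
        method, selector, input_name = _SOURCES[obj_type]
        lister = getattr(archive, method)
        uids = lister(pid, selector) if selector is not None else lister(pid)
        for uid in uids:
            ctx = BindingContext(user_inputs={"patientID": pid, input_name: uid})
            objects.append(build_object(maps[obj_type], archive, ctx))

    # hidden data: relink corrections and embed them in the MVCT files
    relink_counts = {m.value: 0 for m in LinkMethod}
    if "MVCT" in job.types:
        records = archive.correlation_records(pid)
        scans = archive.image_scans(pid, "MVCT")
        links = relink_corrections(records, scans, tolerance_s=job.relink_tolerance_s)
        mvct_by_source = {o.source_uid: o for o in objects if o.variant == "MVCT"}
        for rec in records:
            scan_uid, method_ = links[rec.record_uid]
            relink_counts[method_.value] += 1
            target = mvct_by_source.get(scan_uid)
            if target is not None:
                from .builders import embed_corrections

                embed_corrections(target, rec, method_)

    assign_uids(objects, namespace_root=job.uid_root, seed=job.seed, check=True)

    written: list[str] = []
    withheld: list[str] = []
    for obj in objects:
        modality = str(obj.dataset.get("Modality", "UN"))
        fname = f"{modality}.{obj.dataset.SOPInstanceUID}.dcm"
        path = write_dicom(obj, out_dir / fname, policy=job.policy)
        if path is None:
            withheld.append(fname)
        else:
            written.append(fname)

    row = {
        "patient_id": pid,
        "objects_complete": sum(1 for o in objects if o.complete),
        "objects_incomplete": sum(1 for o in objects if not o.complete),
        "objects_written": len(written),
        "objects_withheld": len(withheld),
        "incomplete_detail": [
            {"variant": o.variant, "failed_tags": o.failed_tags} for o in objects if not o.complete
        ],
        "relink_methods": relink_counts,
        "files": sorted(written),
        "error": None,
    }
    (out_dir / "manifest.json").write_text(json.dumps(row, indent=1, sort_keys=True))
    return row


def run_export(job: ExportJob) -> ExportReport:
    """Run a whole export job; never raises for per-patient data problems."""
    maps = load_tagmaps(job.tagmap_dir)  # config errors are fatal, up front
    missing_maps = set(job.types) - set(maps)
    if missing_maps:
        raise ValueError(f"no TagMap available for requested types {sorted(missing_maps)}")

    out_root = Path(job.out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    report = ExportReport(seed=job.seed)

    archive_root = Path(job.archive_path)
    patient_dirs = (
        {p.name: p for p in sorted(archive_root.iterdir()) if (p / "patient.xml").exists()}
        if not (archive_root / "patient.xml").exists()
        else {archive_root.name: archive_root}
    )
    selected = job.patients if job.patients is not None else sorted(patient_dirs)

    for pid in selected:
        out_dir = out_root / pid
        try:
            pdir = patient_dirs.get(pid)
            if pdir is None:
                raise FileNotFoundError(f"no patient directory {pid} under {archive_root}")
            archive = load_archive(pdir)
            out_dir.mkdir(parents=True, exist_ok=True)
            row = _export_patient(archive, archive.patient_ids[0], maps, job, out_dir)
        except Exception as exc:  # crash isolation: one patient never kills the batch
            log.error("patient %s failed: %s", pid, exc)
            row = {
                "patient_id": pid,
                "objects_complete": 0,
                "objects_incomplete": 0,
                "objects_written": 0,
                "objects_withheld": 0,
                "incomplete_detail": [],
                "relink_methods": {},
                "files": [],
                "error": str(exc),
            }
        report.patients.append(row)

    (out_root / "report.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# validation

_RT_SOP_MODALITY = {
    "1.2.840.10008.5.1.4.1.1.2": "CT",
    "1.2.840.10008.5.1.4.1.1.481.1": "RTIMAGE",
    "1.2.840.10008.5.1.4.1.1.481.2": "RTDOSE",
    "1.2.840.10008.5.1.4.1.1.481.3": "RTSTRUCT",
    "1.2.840.10008.5.1.4.1.1.481.5": "RTPLAN",
}

_IMAGE_SOPS = {"1.2.840.10008.5.1.4.1.1.2", "1.2.840.10008.5.1.4.1.1.481.1"}


def _closure_over_files(datasets: list) -> list[str]:
    declared: set[str] = set()
    for ds in datasets:
        for tag in (Tag(0x0008, 0x0018), Tag(0x0020, 0x000D), Tag(0x0020, 0x000E)):
            if tag in ds:
                declared.add(str(ds[tag].value))
        if str(ds.get("SOPClassUID", "")) in _IMAGE_SOPS and Tag(0x0020, 0x0052) in ds:
            declared.add(str(ds[Tag(0x0020, 0x0052)].value))
    problems = []
    for ds in datasets:
        refs: list[tuple[str, str]] = []
        for elem in ds:
            if elem.VR == "SQ":
                for item in elem.value:
                    for sub in item.iterall():
                        if sub.VR != "UI":
                            continue
                        if sub.tag in (Tag(0x0008, 0x1155), Tag(0x0020, 0x000E), Tag(0x0020, 0x0052)):
                            refs.append((str(sub.tag), str(sub.value)))
        if str(ds.get("SOPClassUID", "")) not in _IMAGE_SOPS and Tag(0x0020, 0x0052) in ds:
            refs.append(("FrameOfReferenceUID", str(ds[Tag(0x0020, 0x0052)].value)))
        for what, uid in refs:
            if uid and uid not in declared:
                problems.append(f"{ds.get('SOPInstanceUID', '?')}: {what} -> {uid} dangling")
    return problems


def validate_outputs(output_root: str | Path, archive_manifest: dict | None = None) -> list[dict]:
    """Reparse every exported file and check structure, links and key values.

    Three layers: (1) every ``.dcm`` must reparse cleanly and carry a SOP
    class consistent with its modality; (2) the UID reference graph over
    each patient's files must be closed; (3) when the generator's
    ground-truth manifest is supplied, dose maxima (DoseGridScaling x max
    stored value vs. true maximum within half a scale step), patient names
    and embedded correction vectors are cross-checked through the hashed
    UID namespace.

    Returns one result dict per file plus one per-patient "linkage" row.
    """
    out_root = Path(output_root)
    results: list[dict] = []
    report = None
    report_path = out_root / "report.json"
    if report_path.exists():
        report = json.loads(report_path.read_text())
    seed = report["seed"] if report else 0

    truth: dict[str, dict] = {}
    if archive_manifest is not None:
        for pat in archive_manifest["patients"]:
            for dose in pat["doses"]:
                truth[hash_uid(dose["uid"], seed)] = {"kind": "dose", "max_dose": dose["max_dose"], "name": pat["name"]}
            for corr in pat["corrections"]:
                link = corr["linked_scan_uid"] or corr["true_scan_uid"]
                truth[hash_uid(link, seed)] = {
                    "kind": "mvct",
                    "translations": corr["translations"],
                    "rotations": corr["rotations"],
                    "name": pat["name"],
                }

    for pdir in sorted(p for p in out_root.iterdir() if p.is_dir()):
        datasets = []
        for f in sorted(pdir.glob("*.dcm")):
            row = {"file": str(f.relative_to(out_root)), "ok": True, "problems": []}
            try:
                ds = pydicom.dcmread(f)
            except Exception as exc:
                row["ok"] = False
                row["problems"].append(f"unreadable: {exc}")
                results.append(row)
                continue
            sop = str(ds.get("SOPClassUID", ""))
            expected_modality = _RT_SOP_MODALITY.get(sop)
            if expected_modality is None:
                row["problems"].append(f"unexpected SOP class {sop}")
            elif str(ds.get("Modality", "")) != expected_modality:
                row["problems"].append(
                    f"modality {ds.get('Modality')} inconsistent with SOP class {sop}"
                )
            info = truth.get(str(ds.get("SOPInstanceUID", "")))
            if info is not None:
                if str(ds.get("PatientName", "")) != info["name"]:
                    row["problems"].append("patient name mismatch vs manifest")
                if info["kind"] == "dose":
                    sf = float(ds.DoseGridScaling)
                    vmax = float(np.frombuffer(ds.PixelData, dtype="<u2").max()) * sf
                    if abs(vmax - info["max_dose"]) > sf / 2 + 1e-9:
                        row["problems"].append(
                            f"max dose {vmax} deviates from manifest {info['max_dose']}"
                        )
                elif info["kind"] == "mvct":
                    emb = read_embedded_corrections(ds)
                    if emb is not None and (
                        list(emb["translations"]) != info["translations"]
                        or list(emb["rotations"]) != info["rotations"]
                    ):
                        row["problems"].append("embedded corrections mismatch vs manifest")
            row["ok"] = not row["problems"]
            results.append(row)
            datasets.append(ds)
        link_problems = _closure_over_files(datasets)
        results.append(
            {"file": f"{pdir.name}/<linkage>", "ok": not link_problems, "problems": link_problems}
        )
    return results
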