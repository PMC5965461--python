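"""Synthetic tomo-lite archive generator with a ground-truth manifest.

Real tomotherapy archives are proprietary; everything in this package is
exercised against archives this module generates.  The generator emits the
documented tomo-lite dialect in all three storage-version variants and
writes a JSON manifest holding every ground-truth value (UIDs, dtypes,
shapes, maximum doses, leaf open times, true correction/scan links), so
any exported DICOM value can be verified without re-reading the archive.

What is emulated: the storage *structures* — UID-linked XML fragments plus
raw little-endian binaries, per-projection (v3) versus cumulative-event
(v4) plan sinograms with a 10 s beam warm-up, couch-insertion image
reshaping, broken correction links.  What is not: clinical anatomy or
realistic delivery patterns; images are geometric phantoms (ellipse body
plus a rectangular couch profile) and dose grids are smooth Gaussian-sum
fields, because every assertion downstream is structural or numeric.

The same seed also drives :func:`generate_sql_fixture`, which emits a
plain-text SQL script mirroring the oncology-information-system tables
(Patient / DCMStudy / DCMSeries / TreatmentList) with rows consistent with
the XML archive — the basis of the backend-agnosticism tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from lxml import etree

from .archive import StorageVersion
from .transforms import N_LEAVES, CouchInsertionSpec, insert_couch

__all__ = ["ArchiveSpec", "generate_archive", "generate_sql_fixture", "encode_sinogram_v4_events"]

_GIVEN = ["Ann", "John", "Mary", "Peter", "Rita", "Tom", "Vera", "Hugh", "Iris", "Carl"]
_FAMILY = ["Smith", "Jones", "Brown", "Taylor", "Wilson", "Davies", "Evans", "Walker", "Wright", "Hall"]

_SCENARIOS = ("none", "vertical", "horizontal", "both")

_VERSION_MARKERS = {
    StorageVersion.V3: "3.14",
    StorageVersion.V4_0: "4.0",
    StorageVersion.V4_2PLUS: "4.2",
}


@dataclass
class ArchiveSpec:
    """Generation parameters; the seed fully determines the output bytes.

    Defaults describe one typical helical delivery: a 256x256 plan CT
    widened to 384 columns with a 28-row treatment-couch block (so the
    stored slice is 384x284 and export pads it to 384x384), 200 projections
    of 0.2 s with leaves 11-52 ever open and a 10 s beam warm-up, 32^3 dose
    grids with maxima below 80 Gy, and a 640-channel detector.
    """

    n_patients: int = 1
    n_fractions: int = 3
    image_shape: tuple[int, int] = (256, 256)  # pre-insertion plan CT (rows, cols)
    mvct_shape: tuple[int, int] = (128, 128)
    couch_scenario: str = "both"  # none | vertical | horizontal | both | mixed
    target_width: int = 384
    couch_height_px: int = 28
    version: StorageVersion = StorageVersion.V4_2PLUS
    broken_link_fraction: float = 0.0
    include_adaptive_dose: bool = True
    include_delivery_sinogram: bool = True
    n_ct_slices: int = 2
    n_projections: int = 200
    projection_duration_s: float = 0.2
    warmup_s: float = 10.0
    open_leaves: tuple[int, ...] = tuple(range(11, 53))
    dose_shape: tuple[int, int, int] = (32, 32, 32)
    delivery_channels: int = 640
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.couch_scenario not in _SCENARIOS + ("mixed",):
            raise ValueError(f"unknown couch scenario {self.couch_scenario!r}")


# ---------------------------------------------------------------------------
# content synthesis


def _phantom(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Ellipse body on air background, stored int16 values (intercept -1024)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    body = ((yy - cy) / (0.42 * h)) ** 2 + ((xx - cx) / (0.45 * w)) ** 2 <= 1.0
    img = np.zeros(shape, dtype=np.int16)
    tissue = 1024 + rng.integers(-40, 40, size=shape)
    img[body] = tissue[body]
    return img


def _couch_profile(width: int, rng: np.random.Generator) -> np.ndarray:
    profile = np.zeros(width, dtype=np.int16)
    lo, hi = int(0.2 * width), int(0.8 * width)
    profile[lo:hi] = 300 + rng.integers(-10, 10, size=hi - lo)
    return profile


def _gaussian_sum_field(shape: tuple[int, ...], max_value: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth non-negative random field scaled so its maximum equals max_value."""
    grids = np.meshgrid(*[np.linspace(0, 1, s) for s in shape], indexing="ij")
    out = np.zeros(shape, dtype=np.float64)
    for _ in range(rng.integers(3, 7)):
        centre = rng.uniform(0.2, 0.8, size=len(shape))
        width = rng.uniform(0.08, 0.3, size=len(shape))
        amp = rng.uniform(0.3, 1.0)
        r2 = sum(((g - c) / w) ** 2 for g, c, w in zip(grids, centre, width))
        out += amp * np.exp(-0.5 * r2)
    out *= max_value / out.max()
    return out.astype(np.float32)


def _plan_fractions(spec: ArchiveSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-projection leaf-open fractions, float32, closed leaves all-zero.

    Each ever-open leaf gets a smooth modulation pattern with ~30% fully
    closed projections and at least one open projection, mimicking the
    sparsity of helical deliveries without claiming clinical realism.
    """
    f = np.zeros((spec.n_projections, N_LEAVES), dtype=np.float32)
    for leaf in spec.open_leaves:
        base = rng.uniform(0.05, 1.0, size=spec.n_projections)
        closed = rng.random(spec.n_projections) < 0.3
        base[closed] = 0.0
        if not base.any():
            base[rng.integers(0, spec.n_projections)] = rng.uniform(0.2, 1.0)
        f[:, leaf - 1] = base.astype(np.float32)
    return f


def encode_sinogram_v4_events(
    fractions: np.ndarray,
    open_leaves: tuple[int, ...],
    warmup_s: float,
    tau: float,
) -> np.ndarray:
    """Encode per-projection fractions as cumulative open/close event times.

    For each recorded leaf, every projection with a non-zero fraction f
    becomes one open interval of length f*tau centred in the projection
    window.  Rows (two per leaf: opens, closes) are NaN-padded to the
    maximum event count.  All times include the warm-up offset.
    """
    n_proj = fractions.shape[0]
    per_leaf: list[tuple[np.ndarray, np.ndarray]] = []
    for leaf in open_leaves:
        f = fractions[:, leaf - 1].astype(np.float64)
        k = np.nonzero(f)[0]
        start = warmup_s + k * tau + (tau - f[k] * tau) / 2.0
        per_leaf.append((start, start + f[k] * tau))
    n_events = max((o.size for o, _ in per_leaf), default=0)
    events = np.full((2 * len(open_leaves), n_events), np.nan, dtype=np.float64)
    for i, (opens, closes) in enumerate(per_leaf):
        events[2 * i, : opens.size] = opens
        events[2 * i + 1, : closes.size] = closes
    return events


# ---------------------------------------------------------------------------
# XML emission helpers


def _sub(parent: etree._Element, tag: str, text: str | None = None, **attrib) -> etree._Element:
    el = etree.SubElement(parent, tag, **{k: str(v) for k, v in attrib.items()})
    if text is not None:
        el.text = str(text)
    return el


def _db_info(parent: etree._Element, uid: str) -> None:
    _sub(_sub(parent, "dbInfo"), "databaseUID", uid)


def _array_header(parent: etree._Element, dtype: str, shape: tuple[int, ...]) -> None:
    _sub(parent, "arrayHeader", dtype=dtype, shape=" ".join(str(s) for s in shape))


class _UidFactory:
    def __init__(self, seed: int):
        self.prefix = f"1.2.826.0.1.3680043.10.511.{seed % 100000}"
        self.counter = 0

    def __call__(self) -> str:
        self.counter += 1
        return f"{self.prefix}.{self.counter}"


# ---------------------------------------------------------------------------
# generation


def generate_archive(spec: ArchiveSpec, out_dir: str | Path) -> dict:
    """Write a tomo-lite archive under ``out_dir``; returns the manifest.

    The manifest is also written as ``manifest.json`` next to the patient
    directories.  Generation is fully deterministic in ``spec.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    uid = _UidFactory(spec.seed)

    manifest: dict = {
        "seed": spec.seed,
        "version": spec.version.name,
        "patients": [],
    }

    for p in range(spec.n_patients):
        pid = f"P{p + 1:04d}"
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        given = _GIVEN[int(rng.integers(0, len(_GIVEN)))]
        family = _FAMILY[int(rng.integers(0, len(_FAMILY)))]
        name = f"{family}^{given}"
        birth = f"{int(rng.integers(1930, 1990))}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
        sex = "MF"[int(rng.integers(0, 2))]
        study_uid, for_uid = uid(), uid()
        ct_series, plan_uid, plan_series = uid(), uid(), uid()
        struct_uid, struct_series = uid(), uid()
        sinogram_uid = uid()
        scenario = (
            _SCENARIOS[p % 4] if spec.couch_scenario == "mixed" else spec.couch_scenario
        )

        root = etree.Element("fullPatient", formatVersion=_VERSION_MARKERS[spec.version])
        brief = _sub(root, "briefPatient")
        _sub(brief, "patientID", pid)
        _sub(brief, "patientName", name)
        _sub(brief, "birthDate", birth)
        _sub(brief, "sex", sex)
        _sub(brief, "frameOfReferenceUID", for_uid)
        _db_info(brief, study_uid)

        images = _sub(root, "fullImageDataArray")
        doses = _sub(root, "fullDoseDataArray")
        plans = _sub(root, "fullPlanDataArray")
        corrs = _sub(root, "fullCorrelationDataArray")

        pat_manifest: dict = {
            "patient_id": pid,
            "name": name,
            "birth_date": birth,
            "sex": sex,
            "study_uid": study_uid,
            "frame_of_reference_uid": for_uid,
            "scenario": scenario,
            "ct_series_uid": ct_series,
            "ct_slices": [],
            "plan": {},
            "doses": [],
            "mvct_scans": [],
            "delivery_sinograms": [],
            "corrections": [],
        }

        # ---- plan CT slices (post couch insertion) -----------------------
        base = _phantom(spec.image_shape, rng)
        h, w = spec.image_shape
        tw = spec.target_width if scenario in ("horizontal", "both") else w
        ch = spec.couch_height_px if scenario in ("vertical", "both") else 0
        couch = _couch_profile(tw, rng) if ch else None
        ins = CouchInsertionSpec(target_width=tw, couch_height_px=ch, couch_profile=couch, pad_value=0)
        for s in range(spec.n_ct_slices):
            slice_img = base.copy()
            if s:  # slices differ slightly so per-slice assertions bite
                slice_img = np.clip(slice_img + rng.integers(-5, 5, size=base.shape), -1024, 3000).astype(np.int16)
            stored, shift = insert_couch(slice_img, ins)
            slice_uid = uid()
            stored.astype("<i2").tofile(pdir / f"{slice_uid}.img")
            el = _sub(images, "imageData")
            _db_info(el, slice_uid)
            _sub(el, "imageType", "KVCT")
            _array_header(el, "int16", stored.shape)
            _sub(el, "seriesUID", ct_series)
            _sub(el, "frameOfReferenceUID", for_uid)
            _sub(el, "acquisitionDateTime", "2011-05-02T08:15:00")
            _sub(el, "instanceNumber", s + 1)
            _sub(el, "pixelSpacing", f"{spec.pixel_spacing[0]:g} {spec.pixel_spacing[1]:g}")
            _sub(el, "sliceThickness", f"{spec.slice_thickness:g}")
            _sub(el, "origin", f"{-tw / 2:g} {-stored.shape[0] / 2:g} {s * spec.slice_thickness:g}")
            _sub(el, "rescaleIntercept", "-1024")
            _sub(el, "rescaleSlope", "1")
            pat_manifest["ct_slices"].append(
                {
                    "uid": slice_uid,
                    "dtype": "int16",
                    "shape": list(stored.shape),
                    "pre_insertion_shape": [h, w],
                    "insertion_shift": list(shift),
                }
            )

        # ---- plan with sinogram ------------------------------------------
        fractions = _plan_fractions(spec, rng)
        plan_el = _sub(plans, "planData")
        _db_info(plan_el, plan_uid)
        _sub(plan_el, "planLabel", f"HT-{pid}")
        _sub(plan_el, "planDate", "2011-05-03T10:00:00")
        _sub(plan_el, "seriesUID", plan_series)
        _sub(plan_el, "referencedImageSeriesUID", ct_series)
        _sub(plan_el, "referencedStructUID", struct_uid)
        sg_el = _sub(plan_el, "sinogram")
        _db_info(sg_el, sinogram_uid)
        _sub(sg_el, "nProjections", spec.n_projections)
        _sub(sg_el, "projectionDuration", f"{spec.projection_duration_s:g}")
        if spec.version == StorageVersion.V3:
            fractions.astype("<f4").tofile(pdir / f"{sinogram_uid}.bin")
            _array_header(sg_el, "float32", fractions.shape)
        else:
            events = encode_sinogram_v4_events(
                fractions, spec.open_leaves, spec.warmup_s, spec.projection_duration_s
            )
            events.astype("<f8").tofile(pdir / f"{sinogram_uid}.bin")
            _array_header(sg_el, "float64", events.shape)
            _sub(sg_el, "warmupTime", f"{spec.warmup_s:g}")
            _sub(sg_el, "openLeafIndices", " ".join(str(i) for i in spec.open_leaves))
        pat_manifest["plan"] = {
            "uid": plan_uid,
            "series_uid": plan_series,
            "label": f"HT-{pid}",
            "sinogram_uid": sinogram_uid,
            "n_projections": spec.n_projections,
            "projection_duration_s": spec.projection_duration_s,
            "warmup_s": spec.warmup_s,
            "open_leaves": list(spec.open_leaves),
            "leaf_open_time_s": (fractions.astype(np.float64).sum(axis=0) * spec.projection_duration_s).tolist(),
        }

        # ---- structure set (textual contours, no binary) -----------------
        st_el = _sub(plan_el, "structureSet")
        _db_info(st_el, struct_uid)
        _sub(st_el, "seriesUID", struct_series)
        roi_names = ["BODY", "PTV", "COUCH"]
        for rname in roi_names:
            roi = _sub(st_el, "roi")
            _sub(roi, "name", rname)
            pts = rng.uniform(-80, 80, size=(4, 2)).round(2)
            coords = " ".join(f"{x:g} {y:g} 0" for x, y in pts)
            _sub(roi, "contour", coords)
        pat_manifest["plan"]["struct_uid"] = struct_uid
        pat_manifest["plan"]["struct_series_uid"] = struct_series
        pat_manifest["plan"]["roi_names"] = roi_names

        # ---- plan dose ----------------------------------------------------
        def add_dose(dose_type: str, ref_scan: str | None) -> None:
            dose_uid, dose_series = uid(), uid()
            max_dose = float(80.0 * (1.0 - rng.random()))  # in (0, 80]
            grid = _gaussian_sum_field(spec.dose_shape, max_dose, rng)
            grid.astype("<f4").tofile(pdir / f"{dose_uid}.bin")
            el = _sub(doses, "doseData")
            _db_info(el, dose_uid)
            _sub(el, "doseType", dose_type)
            _array_header(el, "float32", grid.shape)
            _sub(el, "seriesUID", dose_series)
            _sub(el, "referencedPlanUID", plan_uid)
            if ref_scan is not None:
                _sub(el, "referencedScanUID", ref_scan)
            _sub(el, "gridSpacing", "2 2")
            _sub(el, "sliceSpacing", "3")
            _sub(el, "origin", "-32 -32 0")
            pat_manifest["doses"].append(
                {
                    "uid": dose_uid,
                    "series_uid": dose_series,
                    "type": dose_type,
                    "dtype": "float32",
                    "shape": list(grid.shape),
                    "max_dose": float(grid.max()),
                    "referenced_scan_uid": ref_scan,
                }
            )

        add_dose("PLAN", None)

        # ---- per-fraction MVCT, corrections, QA dose, delivery sinogram --
        n_corr = spec.n_fractions
        n_broken = int(round(spec.broken_link_fraction * n_corr))
        broken = set(rng.choice(n_corr, size=n_broken, replace=False).tolist()) if n_broken else set()
        for f in range(spec.n_fractions):
            mvct_uid, mvct_series = uid(), uid()
            img = _phantom(spec.mvct_shape, rng)
            img.astype("<i2").tofile(pdir / f"{mvct_uid}.img")
            acq = f"2011-05-{10 + f:02d}T09:30:00"
            el = _sub(images, "imageData")
            _db_info(el, mvct_uid)
            _sub(el, "imageType", "MVCT")
            _array_header(el, "int16", img.shape)
            _sub(el, "seriesUID", mvct_series)
            _sub(el, "frameOfReferenceUID", for_uid)
            _sub(el, "acquisitionDateTime", acq)
            _sub(el, "instanceNumber", 1)
            _sub(el, "fractionNumber", f + 1)
            _sub(el, "pixelSpacing", "2 2")
            _sub(el, "sliceThickness", "4")
            _sub(el, "origin", f"{-spec.mvct_shape[1]:g} {-spec.mvct_shape[0]:g} 0")
            _sub(el, "rescaleIntercept", "-1024")
            _sub(el, "rescaleSlope", "1")
            pat_manifest["mvct_scans"].append(
                {
                    "uid": mvct_uid,
                    "series_uid": mvct_series,
                    "fraction": f + 1,
                    "acquired": acq,
                    "shape": list(img.shape),
                }
            )

            corr_uid = uid()
            jitter = float(rng.uniform(-30.0, 30.0))
            offset = 90.0 + jitter  # correction recorded ~1.5 min after the scan
            ts_seconds = 9 * 3600 + 30 * 60 + offset
            hh, rem = divmod(int(ts_seconds), 3600)
            mm, ss = divmod(rem, 60)
            ts = f"2011-05-{10 + f:02d}T{hh:02d}:{mm:02d}:{ss:02d}"
            translations = tuple(round(float(v), 2) for v in rng.normal(0.0, 3.0, 3))
            rotations = tuple(round(float(v), 2) for v in rng.normal(0.0, 1.0, 3))
            el = _sub(corrs, "correlationData")
            _db_info(el, corr_uid)
            if f not in broken:
                _sub(el, "linkedScanUID", mvct_uid)
            _sub(el, "timestamp", ts)
            _sub(el, "translations", " ".join(f"{v:g}" for v in translations))
            _sub(el, "rotations", " ".join(f"{v:g}" for v in rotations))
            pat_manifest["corrections"].append(
                {
                    "uid": corr_uid,
                    "true_scan_uid": mvct_uid,
                    "linked_scan_uid": None if f in broken else mvct_uid,
                    "timestamp": ts,
                    "translations": list(translations),
                    "rotations": list(rotations),
                }
            )

            if spec.include_adaptive_dose:
                add_dose("QA", mvct_uid)

            if spec.include_delivery_sinogram:
                del_uid, del_series = uid(), uid()
                sino = _gaussian_sum_field(
                    (spec.delivery_channels, spec.n_projections), float(rng.uniform(50, 500)), rng
                )
                sino.astype("<f4").tofile(pdir / f"{del_uid}.dpe")
                el = _sub(images, "imageData")
                _db_info(el, del_uid)
                _sub(el, "imageType", "DELIVERY")
                _array_header(el, "float32", sino.shape)
                _sub(el, "seriesUID", del_series)
                _sub(el, "acquisitionDateTime", acq)
                _sub(el, "fractionNumber", f + 1)
                pat_manifest["delivery_sinograms"].append(
                    {
                        "uid": del_uid,
                        "series_uid": del_series,
                        "fraction": f + 1,
                        "dtype": "float32",
                        "shape": list(sino.shape),
                        "max_value": float(sino.max()),
                    }
                )

        etree.ElementTree(root).write(
            str(pdir / "patient.xml"), pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )
        manifest["patients"].append(pat_manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def generate_sql_fixture(spec: ArchiveSpec, manifest: dict | None = None) -> str:
    """Plain-text SQL script mirroring the OIS tables for the same records.

    Table and column names follow the altered MOSAIQ-style names used by
    the shipped RT-Record TagMap; the rows are consistent with the archive
    generated from the same spec, so staged SQL evaluation must reproduce
    the manifest's plan UID.
    """
    if manifest is None:
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            manifest = generate_archive(spec, tmp)
    lines = [
        "CREATE TABLE Patient (ID TEXT PRIMARY KEY, Pat_ID1 INTEGER, FIRST_NAME TEXT, LAST_NAME TEXT);",
        "CREATE TABLE DCMStudy (Pat_ID1 INTEGER, StudyInstanceUID TEXT);",
        "CREATE TABLE DCMSeries (DCMStudy_ID TEXT, SeriesInstanceUID TEXT);",
        "CREATE TABLE TreatmentList (ID TEXT, ImageSeriesUID TEXT, PlanInstanceUID TEXT);",
    ]
    for k, pat in enumerate(manifest["patients"], start=1):
        family, given = pat["name"].split("^")
        lines.append(
            f"INSERT INTO Patient VALUES ('{pat['patient_id']}', {k}, '{given}', '{family}');"
        )
        lines.append(f"INSERT INTO DCMStudy VALUES ({k}, '{pat['study_uid']}');")
        lines.append(
            f"INSERT INTO DCMSeries VALUES ('{pat['study_uid']}', '{pat['ct_series_uid']}');"
        )
        lines.append(
            f"INSERT INTO TreatmentList VALUES ('{pat['patient_id']}', "
            f"'{pat['ct_series_uid']}', '{pat['plan']['uid']}');"
        )
    return "\n".join(lines) + "\n"
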