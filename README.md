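# tagmaps

Declarative translation of tomotherapy-style radiotherapy archives into
linked, standards-compliant DICOM-RT objects — including the "hidden"
data commercial exports omit: image-guidance positional corrections,
adaptive-RT doses and delivery sinograms.

**Who it is for.** Medical physicists and RT informatics teams who need
to batch-recover treatment records (plan CT, daily MVCT, RT-Plan,
RT-Dose, RT-Structure Set) from archive storage for clinical trials,
audit, QA or radiomics — without a clinical workstation in the loop, and
without writing new export code for every storage quirk.

**How it works.** Each DICOM-RT object type is described by a
human-readable XML *TagMap* that assigns every DICOM tag either a
constant or a query into the source storage:

```xml
<attr tag="0020000E" vr="UI" params="tag:0020,000D">
  SELECT SeriesInstanceUID FROM DCMSeries D WHERE D.DCMStudy_ID = ?
</attr>
```

The engine builds a query-bearing skeleton from the map, evaluates it in
document order against a pluggable backend (XPath over archive XML, or
SQL over an oncology-information-system database), so later tags can
bind earlier results (patient → study → series → plan), then applies the
object-specific raw-data transformation and writes Part-10 files with a
closed UID reference graph. The numeric core:

* **Dose quantization** — float32 voxel doses D₃₂ (Gy) are packed to
  unsigned 16-bit D₁₆ with scale factor SF = max(D₃₂)/65535
  (`DoseGridScaling`): D₁₆ = round(D₃₂/SF), reconstruction D₁₆·SF.
  Worst-case round-trip error is SF/2 ≈ 0.00076% of the maximum dose.
* **MLC sinogram decoding** — v3 archives store per-projection leaf-open
  fractions (float32, 64 leaves); v4 archives store cumulative open/close
  event times for the ever-open leaves only (float64, two rows per leaf,
  warm-up offset included). Both are decoded to the common fraction
  layout and embedded in the RT-Plan under private tag (300D,10A7).
* **Plan-CT couch handling** — stored slices (diagnostic couch replaced
  by the treatment couch, e.g. 384×284) are padded to a square grid
  (384×384) at export, inherited pixels bit-identical.
* **Correction relinking** — corrections that lost their scan link are
  re-associated to the nearest MVCT by timestamp within a tolerance
  (injective, ties degrade to UNLINKED) and embedded as private tags.

Real archives are proprietary, so the repository defines a documented
archive dialect ("tomo-lite", `docs/tomo-lite.md`) and ships a
deterministic generator for it in all three storage-version variants,
with a ground-truth manifest that every exported value can be checked
against. See `docs/methods.md` for conventions and limitations.

## Worked example

```sh
tagmaps generate --out arc --seed 5 --patients 1 --sql-fixture fixture.sql
# wrote 1 patient(s) to arc
tagmaps export --archive arc --out out --seed 5
# processed 1 patient(s): 1 complete, 0 needing additional processing, 0 failed
tagmaps validate --out out --manifest arc/manifest.json
# 15/15 checks passed
```

`out/P0001/` now holds one file per object
(`<Modality>.<SOPInstanceUID>.dcm`: plan-CT slices and MVCTs as CT,
plan, doses, structure set, delivery sinograms as RTIMAGE) plus a
`manifest.json` QA report with completeness and relink accounting.
Checking the plan dose against the generator's ground truth:

```python
>>> import pydicom, numpy as np
>>> ds = pydicom.dcmread("out/P0001/RTDOSE.1.2.826.0.1.3680043.10.424.3414928725349463757251.dcm")
>>> ds.DoseGridScaling
'0.0006091433276'
>>> float(np.frombuffer(ds.PixelData, dtype="<u2").max()) * float(ds.DoseGridScaling)
39.920207974266
```

The manifest's true maximum is 39.92020797729492 Gy: the 16-bit
round trip reproduces it to 7.6e-9 % of the maximum dose, and
`DoseGridScaling` equals max dose / 65535. The export is deterministic —
re-running with the same seed reproduces the output tree byte for byte.

`tagmaps inspect-tagmap src/tagmaps/maps/rtdose.xml` shows the
intermediate skeleton (which tags are constants, which are queries) for
any map without touching an archive.

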