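# Methods

This note records the models, conventions and numerical choices behind the
package, in the spirit of a software methods section: what is computed,
under which assumptions, and what the synthetic test bed does and does not
demonstrate.

## Problem setting

Helical tomotherapy treatment records live in proprietary electronic
archives: XML master files whose fragments are linked by DICOM UIDs to raw
binary payloads (images, voxel doses, multileaf-collimator sinograms,
detector data). Recovering those records as standards-compliant DICOM-RT
normally requires restoring archives onto a clinical workstation and
exporting interactively — slow, error-prone, and blind to data the vendor
export omits (image-guidance positional corrections, adaptive-RT doses,
delivery sinograms).

The package takes the declarative route: a human-readable *TagMap* per
DICOM-RT object type assigns every DICOM tag either a constant or a query
into the source storage. The engine builds a query-bearing skeleton from
the map, evaluates it in document order against a pluggable backend (XPath
over archive XML, SQL over a relational oncology information system),
applies the object-specific raw-data transformation, and writes linked
Part-10 files. Adapting the export to a new storage layout or selection
rule means editing XML, not code.

Because genuine archives cannot be redistributed, the package defines and
documents its own archive dialect (tomo-lite, `docs/tomo-lite.md`) and
ships a generator for it; every numeric contract below is exercised
against generated archives with a ground-truth manifest.

## Raw-data transformations

### Dose quantization

Archived voxel doses are float32 gray. RT-Dose stores unsigned 16-bit
integers with a gray-per-unit scale factor

    SF = max voxel dose / 65535,        DoseGridScaling element

so quantization is `D16 = round(D32 / SF)` and reconstruction
`D32' = D16 * SF`. Rounding is half-away-from-zero (numpy's default
half-to-even would be equally valid; half-away keeps the worst case at
exactly SF/2 and is the natural reading of the scale-factor definition —
truncation would double the worst-case error). The worst-case
reconstruction error is therefore SF/2 = max/(2*65535), i.e. ~0.00076% of
the maximum dose, within the ±0.001% figure the conversion is expected to
hold; storing the reconstruction as float32 adds at most one
representation rounding (max * eps/2, relative ~6e-8). The all-zero grid
gets the sentinel SF = 1 so zeros reconstruct exactly. The same packing,
with the scale in RescaleSlope, serves the delivery-sinogram detector
grids. DoseGridScaling is written with 10 significant digits (DS is
capped at 16 bytes); the induced relative error ~1e-10 is negligible
against SF/2.

### Plan sinogram decoding

The planned fluence is a sinogram over 64 binary MLC leaves and the
delivery's projections (control points). Two storage generations exist:

* **v3**: float32 grid, one row per projection, 64 columns, each value the
  fraction of the projection duration the leaf was open — already the
  target layout.
* **v4**: float64 cumulative open/close event times in seconds for the
  leaves ever open only (two rows per recorded leaf, NaN-padded to a
  common event count); leaves closed for the whole delivery are not
  recorded. Event times include the beam warm-up offset that precedes
  projection 0 (10 s by default).

The layout is detected from the blob dtype (float32 → v3, float64 → v4)
and must agree with the archive's declared storage version; disagreement
is an error, never a guess. v4 decoding assigns projection k the half-open
window `[warmup + k*tau, warmup + (k+1)*tau)` and computes each leaf's
fraction as its total open-interval overlap with the window divided by
tau. Unrecorded leaves yield all-zero columns, so the output always covers
the full 64-leaf bank. Two conventions here are package choices, made once
and documented rather than inferable from any source: the half-open
window semantics, and that stored event times include the warm-up
interval (the generator adopts the same convention, and the
cross-version equivalence test pins both encodings to the same decoded
fractions within 1e-6).

The decoded fractions are embedded in the RT-Plan as row-major float32
under private tag (300D,10A7), with creator `TAGMAP-TOMO` reserving block
0x10 of group 0x300D and companions (300D,10A0)/(300D,10A1) holding the
projection count and duration. Decode(encode(x)) is bit-exact.

### Plan-CT couch insertion and export padding

Treatment planning replaces the diagnostic couch in the plan CT with the
treatment-unit couch, which may widen the image and append couch rows;
DICOM export then pads the slice to a square grid. Only the observable
dimension arithmetic and region preservation are reproduced — the
vendor's internal algorithm is not available, so the contract is: the
inherited pixel block is bit-identical, output dimensions follow the
stated arithmetic for all four scenarios (no change, vertical,
horizontal, both), and the isocenter position stays recoverable through
the recorded shift. Column padding is split equally with the extra column
to the right; export padding keeps content top-aligned (landscape) or
centred (portrait); the pad value is the stored value for −1024 HU under
the slice's rescale. With the default geometry a 256x256 acquisition
becomes a stored 384x284 slice and exports as 384x384.

### Correction relinking

Image-guidance positional corrections (3 translations mm, 3 rotations
deg, timestamped to the second) carry a UID link to their MVCT scan; when
the treatment-unit/database connection drops, the correction is recorded
but the link lost. Relinking matches each unlinked correction to the scan
with the nearest acquisition time, accepting the match only within a
tolerance (default 120 s — half the shortest plausible interval between
consecutive daily scans). The mapping is injective: a tie, an
out-of-tolerance distance, or two corrections claiming one scan all
degrade to UNLINKED with a warning, never a silent guess. Linked or
relinked corrections are embedded in the exported MVCT under private
group 0x7771 (creator `TAGMAP-CORR`), including the link method, so
downstream QA can distinguish recovered from original associations.

## Engine semantics

Literal-vs-query classification, `?`-binding order and the `$i` item
variable are not decidable from a TagMap file alone, so the dialect makes
them explicit (`src`, `params`, documented `$i` scoping); see
`docs/tomo-lite.md`. Evaluation is staged strictly in document order;
only earlier top-level results are visible to later queries. Mandatory
(Type-1) tags per object type are listed in a conformance table; a query
returning nothing for one of them marks the dataset INCOMPLETE with the
failure recorded, anything else degrades to a logged warning. Under the
default lenient policy INCOMPLETE objects are still written with their
state in the QA report — incomplete or historic archives should export
partially, with accounting, rather than fail. The XPath backend is
lxml's XPath 1.0 engine; the practical query language for a single
master document is its path/predicate/count() subset, and any construct
it cannot evaluate raises an error naming the expression.

## UID namespace and determinism

Exported UIDs are `namespace_root.int(sha256(archive_uid | seed)[:18 hex])`,
a pure function of the archive UID and the export seed. Every
cross-reference therefore lands on the same exported UID, keeping the
reference graph closed (checked: dose → plan, plan → structure set,
QADose → MVCT series, plan/dose/struct → CT frame of reference), and a
repeated export with the same seed is byte-identical — the basis of the
regression contract. Standard UIDs (root 1.2.840.10008) are never
rewritten. Files are written Explicit VR Little Endian with standard
preamble and meta group, named `<Modality>.<SOPInstanceUID>.dcm`.

QADose (dose recalculated on a daily MVCT) uses RT Dose Storage plus a
private label element (group 0x7773, creator `TAGMAP-QA`) and a
referenced-series pointer at the MVCT series instead of the plan CT;
MVCT uses CT Image Storage distinguished by series description. These
SOP-class assignments are package choices where no standard class exists.

## Synthetic archives: what they show and what they do not

The generator emulates storage *structure*, not clinical content: ellipse
phantom slices with a rectangular couch profile, Gaussian-sum dose fields
(maxima sampled in (0, 80] Gy), sparsely modulated sinograms over leaves
11–52 with 200 projections of 0.2 s and a 10 s warm-up, a 640-channel
detector, and per-fraction corrections ~90 s after each scan with ±30 s
jitter. Passing tests therefore demonstrate format, linkage and numeric
correctness of the translation — they say nothing about anatomical
plausibility, registration quality, or vendor-software idiosyncrasies,
all of which would require real clinical archives to probe. Test fixtures scale the geometry down (64x64 slices, 8³–32³ dose
grids, 20–40 projections) except where a contract names the full-size
figures (the 384x284 → 384x384 padding path, the 42-open-leaf event
layout); the batch-robustness suite runs 20 generated patients
end-to-end.

## Known limitations

* XPath coverage is the 1.0 subset; XPath 2.0-only constructs (sequences,
  `for` expressions) are rejected, not emulated.
* The SQL backend targets sqlite fixtures; engine semantics (positional
  binding, single-row scalar contexts) are the contract, not dialect
  coverage of a production MOSAIQ server.
* RT-Treatment-Record maps exercise the engine and staged evaluation;
  a complete treatment-record exporter is out of scope.
* The couch-insertion transform reproduces dimension arithmetic and
  region preservation, not the vendor's pixel-level couch template.
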