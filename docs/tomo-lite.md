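# The tomo-lite archive dialect

Real tomotherapy electronic archives are proprietary and undocumented.
This package therefore defines its own archive dialect, **tomo-lite**,
that reproduces the documented *structure* of such archives — XML master
files carrying treatment metadata, raw little-endian binaries named by
DICOM UID, UID links between XML fragments and payloads, and three
storage-version generations that differ only in plan-sinogram layout.
The translation engine itself is schema-agnostic (every query lives in a
TagMap, not in code), so any fully documented dialect exercises it
faithfully; tomo-lite is that dialect.

## Layout

```
<archive root>/
  <patient_id>/
    patient.xml            one master document per patient
    <UID>.img              image slices, raw int16, little-endian
    <UID>.bin              dose grids and plan sinograms (float32/float64)
    <UID>.dpe              delivery sinograms, raw float32
  manifest.json            generator ground truth (synthetic archives only)
```

All binaries are headerless: dtype and shape are declared by the
`arrayHeader` element of the XML fragment that references the payload.
Byte order is fixed little-endian. The invariant
`file size = itemsize(dtype) x prod(shape)` is checked at UID resolution
time; a mismatch is a hard error, a missing file is a recorded flag.

## Master document

Root element `fullPatient` with a `formatVersion` attribute; the prefix
decides the storage generation: `3.*` → V3, `4.0*` → V4_0, any other
`4.*` → V4_2PLUS. Anything else is an explicit unknown-version error.

Annotated example (v4.2, one slice / fraction of everything):

```xml
<fullPatient formatVersion="4.2">
  <briefPatient>                          <!-- demographics -->
    <patientID>P0001</patientID>
    <patientName>Smith^Ann</patientName>  <!-- DICOM PN order -->
    <birthDate>1955-03-02</birthDate>     <!-- ISO-8601 throughout -->
    <sex>F</sex>
    <frameOfReferenceUID>1.2.826...12</frameOfReferenceUID>
    <dbInfo><databaseUID>1.2.826...11</databaseUID></dbInfo>  <!-- study UID -->
  </briefPatient>

  <fullImageDataArray>
    <imageData>                           <!-- one stored 2-D slice -->
      <dbInfo><databaseUID>1.2.826...21</databaseUID></dbInfo>
      <imageType>KVCT</imageType>         <!-- KVCT | MVCT | DELIVERY -->
      <arrayHeader dtype="int16" shape="284 384"/>   <!-- rows cols -->
      <seriesUID>1.2.826...22</seriesUID>
      <frameOfReferenceUID>1.2.826...12</frameOfReferenceUID>
      <acquisitionDateTime>2011-05-02T08:15:00</acquisitionDateTime>
      <instanceNumber>1</instanceNumber>
      <pixelSpacing>1 1</pixelSpacing>
      <sliceThickness>2.5</sliceThickness>
      <origin>-192 -142 0</origin>
      <rescaleIntercept>-1024</rescaleIntercept>
      <rescaleSlope>1</rescaleSlope>
    </imageData>
    <!-- MVCT entries add <fractionNumber>; DELIVERY entries reference a
         .dpe payload of detector channels x projections -->
  </fullImageDataArray>

  <fullPlanDataArray>
    <planData>
      <dbInfo><databaseUID>1.2.826...31</databaseUID></dbInfo>
      <planLabel>HT-P0001</planLabel>
      <planDate>2011-05-03T10:00:00</planDate>
      <seriesUID>1.2.826...32</seriesUID>
      <referencedImageSeriesUID>1.2.826...22</referencedImageSeriesUID>
      <referencedStructUID>1.2.826...41</referencedStructUID>
      <sinogram>
        <dbInfo><databaseUID>1.2.826...33</databaseUID></dbInfo>
        <nProjections>200</nProjections>
        <projectionDuration>0.2</projectionDuration>   <!-- seconds -->
        <!-- v3: float32 (nProjections x 64) leaf-open fractions -->
        <!-- v4: float64 (2 x open leaves, events) cumulative times: -->
        <arrayHeader dtype="float64" shape="84 167"/>
        <warmupTime>10</warmupTime>                    <!-- v4 only -->
        <openLeafIndices>11 12 ... 52</openLeafIndices><!-- v4 only -->
      </sinogram>
      <structureSet>                       <!-- textual contours, no binary -->
        <dbInfo><databaseUID>1.2.826...41</databaseUID></dbInfo>
        <seriesUID>1.2.826...42</seriesUID>
        <roi><name>BODY</name><contour>x y z x y z ...</contour></roi>
      </structureSet>
    </planData>
  </fullPlanDataArray>

  <fullDoseDataArray>
    <doseData>
      <dbInfo><databaseUID>1.2.826...51</databaseUID></dbInfo>
      <doseType>PLAN</doseType>            <!-- PLAN | QA (adaptive) -->
      <arrayHeader dtype="float32" shape="32 32 32"/> <!-- frames rows cols, Gy -->
      <seriesUID>1.2.826...52</seriesUID>
      <referencedPlanUID>1.2.826...31</referencedPlanUID>
      <!-- QA doses additionally: <referencedScanUID> of the daily MVCT -->
      <gridSpacing>2 2</gridSpacing>       <!-- in-plane mm -->
      <sliceSpacing>3</sliceSpacing>       <!-- mm between frames -->
      <origin>-32 -32 0</origin>
    </doseData>
  </fullDoseDataArray>

  <fullCorrelationDataArray>
    <correlationData>                      <!-- image-guidance correction -->
      <dbInfo><databaseUID>1.2.826...61</databaseUID></dbInfo>
      <linkedScanUID>1.2.826...21</linkedScanUID>  <!-- absent if link lost -->
      <timestamp>2011-05-10T09:31:12</timestamp>
      <translations>1.2 -3.4 0</translations>      <!-- lat long vert, mm -->
      <rotations>0.1 -0.2 0.3</rotations>          <!-- roll pitch yaw, deg -->
    </correlationData>
  </fullCorrelationDataArray>
</fullPatient>
```

## TagMap dialect

One XML file per DICOM-RT object type, root `<dicom type="..."
version_scope="V3 V4_0 V4_2PLUS">`:

```xml
<attr tag="GGGGEEEE" vr="XX" [src="literal|query"]
      [count="query"] [params="input:name,tag:GGGG,EEEE,item"]>payload</attr>
```

* `vr` may be omitted for tags in the standard dictionary.
* A payload is classified as a *query* when it starts with `SELECT `, `$`
  or `(`, or contains `/`; `src` overrides the heuristic.
* Sequences (`vr="SQ"`) carry exactly one `<item>` template; `count` is a
  query yielding the number of items to expand (default 1). Inside an
  expanded item, queries see the 1-based item index as `$i`; an uncounted
  nested sequence inherits the enclosing index.
* XPath queries (lxml's XPath 1.0 path/predicate subset; unsupported
  constructs fail loudly) see every user input and every
  already-evaluated top-level element (`$tGGGGEEEE`) as variables.
* SQL queries bind `?` placeholders positionally from `params`:
  `input:<name>` reads a user input, `tag:GGGG,EEEE` a previously
  evaluated element (staged evaluation), `item` the item index.
* Elements with binary VRs (OB/OW/OF/UN) must evaluate to the UID of a
  raw payload; the object builders replace the reference with the
  transformed bytes.

Evaluation is strictly in document order, so later tags may bind earlier
results — e.g. patient → study → series → plan.
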