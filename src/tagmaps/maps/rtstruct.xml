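<dicom type="RTSTRUCT" version_scope="V3 V4_0 V4_2PLUS">
  <!--SOP Class UID (constant value)-->
  <attr tag="00080016" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.3</attr>
  <attr tag="00080018" vr="UI">/fullPatient/fullPlanDataArray/planData/structureSet[dbInfo/databaseUID=$structUID]/dbInfo/databaseUID/text()</attr>
  <attr tag="00080060" vr="CS" src="literal">RTSTRUCT</attr>
  <attr tag="00100010" vr="PN">/fullPatient/briefPatient/patientName/text()</attr>
  <attr tag="00100020" vr="LO">/fullPatient/briefPatient/patientID/text()</attr>
  <attr tag="00100030" vr="DA">/fullPatient/briefPatient/birthDate/text()</attr>
  <attr tag="00100040" vr="CS">/fullPatient/briefPatient/sex/text()</attr>
  <attr tag="0020000D" vr="UI">/fullPatient/briefPatient/dbInfo/databaseUID/text()</attr>
  <attr tag="0020000E" vr="UI">/fullPatient/fullPlanDataArray/planData/structureSet[dbInfo/databaseUID=$structUID]/seriesUID/text()</attr>
  <attr tag="30060002" vr="SH">/fullPatient/fullPlanDataArray/planData[structureSet/dbInfo/databaseUID=$structUID]/planLabel/text()</attr>
  <!--Referenced Frame of Reference Sequence-->
  <attr tag="30060010" vr="SQ">
    <item>
      <attr tag="00200052" vr="UI">/fullPatient/briefPatient/frameOfReferenceUID/text()</attr>
    </item>
  </attr>
  <!--Structure Set ROI Sequence: one template item, count from the ROI count-->
  <attr tag="30060020" vr="SQ" count="count(/fullPatient/fullPlanDataArray/planData/structureSet[dbInfo/databaseUID=$structUID]/roi)">
    <item>
      <attr tag="30060022" vr="IS">$i</attr>
      <attr tag="30060024" vr="UI">/fullPatient/briefPatient/frameOfReferenceUID/text()</attr>
      <attr tag="30060026" vr="LO">/fullPatient/fullPlanDataArray/planData/structureSet[dbInfo/databaseUID=$structUID]/roi[$i]/name/text()</attr>
    </item>
  </attr>
  <!--ROI Contour Sequence-->
  <attr tag="30060039" vr="SQ" count="count(/fullPatient/fullPlanDataArray/planData/structureSet[dbInfo/databaseUID=$structUID]/roi)">
    <item>
      <attr tag="30060084" vr="IS">$i</attr>
      <attr tag="30060040" vr="SQ">
        <item>
          <attr tag="30060042" vr="CS" src="literal">CLOSED_PLANAR</attr>
          <attr tag="30060046" vr="IS" src="literal">4</attr>
          <attr tag="30060050" vr="DS">/fullPatient/fullPlanDataArray/planData/structureSet[dbInfo/databaseUID=$structUID]/roi[$i]/contour/text()</attr>
        </item>
      </attr>
    </item>
  </attr>
</dicom>
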