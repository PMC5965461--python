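<dicom type="RTRECORD" version_scope="V3 V4_0 V4_2PLUS">
  <!--Same record as rtrecord_sql.xml served from the archive XML; used by the
      backend-agnosticism tests: both backends must yield identical datasets.-->
  <!--Patients Name-->
  <attr tag="00100010" vr="PN">/fullPatient/briefPatient/patientName/text()</attr>
  <!--Study Instance UID-->
  <attr tag="0020000D" vr="UI">/fullPatient/briefPatient/dbInfo/databaseUID/text()</attr>
  <!--Series Instance UID (plan CT series), staged on the study UID-->
  <attr tag="0020000E" vr="UI">/fullPatient[briefPatient/dbInfo/databaseUID=$t0020000D]/fullImageDataArray/imageData[imageType='KVCT'][1]/seriesUID/text()</attr>
  <!--Referenced RT Plan Sequence-->
  <attr tag="300C0002" vr="SQ">
    <item>
      <!--Referenced SOP Class UID (constant value)-->
      <attr tag="00081150" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.5</attr>
      <!--Referenced SOP Instance UID, staged on the series UID-->
      <attr tag="00081155" vr="UI">/fullPatient/fullPlanDataArray/planData[referencedImageSeriesUID=$t0020000E]/dbInfo/databaseUID/text()</attr>
    </item>
  </attr>
</dicom>
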