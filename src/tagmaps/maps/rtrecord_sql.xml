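<dicom type="RTRECORD" version_scope="V3 V4_0 V4_2PLUS">
  <!--Patients Name-->
  <attr tag="00100010" vr="PN" params="input:patientID">SELECT FIRST_NAME, LAST_NAME FROM Patient WHERE Patient.ID = ?</attr>
  <!--Study Instance UID-->
  <attr tag="0020000D" vr="UI" params="input:patientID">SELECT S.StudyInstanceUID FROM DCMStudy S INNER JOIN Patient P ON P.Pat_ID1 = S.Pat_ID1 WHERE P.ID = ?</attr>
  <!--Series Instance UID-->
  <attr tag="0020000E" vr="UI" params="tag:0020,000D">SELECT SeriesInstanceUID FROM DCMSeries D WHERE D.DCMStudy_ID = ?</attr>
  <!--Referenced RT Plan Sequence-->
  <attr tag="300C0002" vr="SQ">
    <item>
      <!--Referenced SOP Class UID (constant value)-->
      <attr tag="00081150" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.5</attr>
      <!--Referenced SOP Instance UID-->
      <attr tag="00081155" vr="UI" params="input:patientID,tag:0020,000E">SELECT PlanInstanceUID FROM TreatmentList T WHERE T.ID = ? AND T.ImageSeriesUID = ?</attr>
    </item>
  </attr>
</dicom>
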