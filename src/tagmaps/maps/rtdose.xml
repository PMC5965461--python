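<dicom type="RTDOSE" version_scope="V3 V4_0 V4_2PLUS">
  <!--SOP Class UID (constant value)-->
  <attr tag="00080016" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.2</attr>
  <attr tag="00080018" vr="UI">/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/dbInfo/databaseUID/text()</attr>
  <attr tag="00080060" vr="CS" src="literal">RTDOSE</attr>
  <attr tag="00100010" vr="PN">/fullPatient/briefPatient/patientName/text()</attr>
  <attr tag="00100020" vr="LO">/fullPatient/briefPatient/patientID/text()</attr>
  <attr tag="00100030" vr="DA">/fullPatient/briefPatient/birthDate/text()</attr>
  <attr tag="00100040" vr="CS">/fullPatient/briefPatient/sex/text()</attr>
  <attr tag="0020000D" vr="UI">/fullPatient/briefPatient/dbInfo/databaseUID/text()</attr>
  <attr tag="0020000E" vr="UI">/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/seriesUID/text()</attr>
  <attr tag="00200032" vr="DS">/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/origin/text()</attr>
  <attr tag="00200037" vr="DS" src="literal">1\0\0\0\1\0</attr>
  <attr tag="00200052" vr="UI">/fullPatient/briefPatient/frameOfReferenceUID/text()</attr>
  <attr tag="00280030" vr="DS">/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/gridSpacing/text()</attr>
  <attr tag="30040002" vr="CS" src="literal">GY</attr>
  <attr tag="30040004" vr="CS" src="literal">PHYSICAL</attr>
  <attr tag="3004000A" vr="CS" src="literal">PLAN</attr>
  <!--Referenced RT Plan Sequence-->
  <attr tag="300C0002" vr="SQ">
    <item>
      <!--Referenced SOP Class UID (constant value)-->
      <attr tag="00081150" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.5</attr>
      <attr tag="00081155" vr="UI">/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/referencedPlanUID/text()</attr>
    </item>
  </attr>
  <!--Pixel Data: float32 voxel doses, quantized to 16 bit with DoseGridScaling-->
  <attr tag="7FE00010" vr="OW">/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/dbInfo/databaseUID/text()</attr>
</dicom>
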