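<dicom type="QADOSE" version_scope="V3 V4_0 V4_2PLUS">
  <!--RT Dose Storage; QADose is labelled by a private element-->
  <attr tag="00080016" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.2</attr>
  <attr tag="00080018" vr="UI">/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/dbInfo/databaseUID/text()</attr>
  <attr tag="00080060" vr="CS" src="literal">RTDOSE</attr>
  <attr tag="0008103E" vr="LO" src="literal">QADose</attr>
  <!--Referenced Series Sequence: points at the daily MVCT, not the plan CT-->
  <attr tag="00081115" vr="SQ">
    <item>
      <attr tag="0020000E" vr="UI">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/referencedScanUID]/seriesUID/text()</attr>
    </item>
  </attr>
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
  <attr tag="3004000A" vr="CS" src="literal">FRACTION</attr>
  <attr tag="300C0002" vr="SQ">
    <item>
      <attr tag="00081150" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.5</attr>
      <attr tag="00081155" vr="UI">/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/referencedPlanUID/text()</attr>
    </item>
  </attr>
  <!--Private QADose label-->
  <attr tag="77730010" vr="LO" src="literal">TAGMAP-QA</attr>
  <attr tag="77731001" vr="LO" src="literal">QADOSE</attr>
  <attr tag="7FE00010" vr="OW">/fullPatient/fullDoseDataArray/doseData[dbInfo/databaseUID=$doseUID]/dbInfo/databaseUID/text()</attr>
</dicom>
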