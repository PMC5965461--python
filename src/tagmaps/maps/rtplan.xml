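<dicom type="RTPLAN" version_scope="V3 V4_0 V4_2PLUS">
  <!--SOP Class UID (constant value)-->
  <attr tag="00080016" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.5</attr>
  <attr tag="00080018" vr="UI">/fullPatient/fullPlanDataArray/planData[dbInfo/databaseUID=$planUID]/dbInfo/databaseUID/text()</attr>
  <attr tag="00080060" vr="CS" src="literal">RTPLAN</attr>
  <attr tag="00100010" vr="PN">/fullPatient/briefPatient/patientName/text()</attr>
  <attr tag="00100020" vr="LO">/fullPatient/briefPatient/patientID/text()</attr>
  <attr tag="00100030" vr="DA">/fullPatient/briefPatient/birthDate/text()</attr>
  <attr tag="00100040" vr="CS">/fullPatient/briefPatient/sex/text()</attr>
  <attr tag="0020000D" vr="UI">/fullPatient/briefPatient/dbInfo/databaseUID/text()</attr>
  <attr tag="0020000E" vr="UI">/fullPatient/fullPlanDataArray/planData[dbInfo/databaseUID=$planUID]/seriesUID/text()</attr>
  <attr tag="00200052" vr="UI">/fullPatient/briefPatient/frameOfReferenceUID/text()</attr>
  <attr tag="300A0002" vr="SH">/fullPatient/fullPlanDataArray/planData[dbInfo/databaseUID=$planUID]/planLabel/text()</attr>
  <attr tag="300A0006" vr="DA">/fullPatient/fullPlanDataArray/planData[dbInfo/databaseUID=$planUID]/planDate/text()</attr>
  <attr tag="300A0007" vr="TM">/fullPatient/fullPlanDataArray/planData[dbInfo/databaseUID=$planUID]/planDate/text()</attr>
  <!--Referenced Structure Set Sequence-->
  <attr tag="300C0060" vr="SQ">
    <item>
      <!--Referenced SOP Class UID (constant value)-->
      <attr tag="00081150" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.3</attr>
      <attr tag="00081155" vr="UI">/fullPatient/fullPlanDataArray/planData[dbInfo/databaseUID=$planUID]/referencedStructUID/text()</attr>
    </item>
  </attr>
  <!--Private creator reserving block 0x10 of group 300D for the sinogram-->
  <attr tag="300D0010" vr="LO" src="literal">TAGMAP-TOMO</attr>
  <!--Plan sinogram payload UID; decoded to per-projection leaf-open fractions-->
  <attr tag="300D10A7" vr="OB">/fullPatient/fullPlanDataArray/planData[dbInfo/databaseUID=$planUID]/sinogram/dbInfo/databaseUID/text()</attr>
</dicom>
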