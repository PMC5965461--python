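<dicom type="MVCT" version_scope="V3 V4_0 V4_2PLUS">
  <!--SOP Class UID (constant value)-->
  <attr tag="00080016" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.2</attr>
  <!--SOP Instance UID-->
  <attr tag="00080018" vr="UI">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/dbInfo/databaseUID/text()</attr>
  <attr tag="00080022" vr="DA">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/acquisitionDateTime/text()</attr>
  <attr tag="00080032" vr="TM">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/acquisitionDateTime/text()</attr>
  <attr tag="00080060" vr="CS" src="literal">CT</attr>
  <attr tag="0008103E" vr="LO" src="literal">MVCT</attr>
  <!--Patient demographics-->
  <attr tag="00100010" vr="PN">/fullPatient/briefPatient/patientName/text()</attr>
  <attr tag="00100020" vr="LO">/fullPatient/briefPatient/patientID/text()</attr>
  <attr tag="00100030" vr="DA">/fullPatient/briefPatient/birthDate/text()</attr>
  <attr tag="00100040" vr="CS">/fullPatient/briefPatient/sex/text()</attr>
  <attr tag="0020000D" vr="UI">/fullPatient/briefPatient/dbInfo/databaseUID/text()</attr>
  <attr tag="0020000E" vr="UI">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/seriesUID/text()</attr>
  <attr tag="00200013" vr="IS">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/instanceNumber/text()</attr>
  <attr tag="00200032" vr="DS">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/origin/text()</attr>
  <attr tag="00200037" vr="DS" src="literal">1\0\0\0\1\0</attr>
  <attr tag="00200052" vr="UI">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/frameOfReferenceUID/text()</attr>
  <attr tag="00280002" vr="US" src="literal">1</attr>
  <attr tag="00280004" vr="CS" src="literal">MONOCHROME2</attr>
  <attr tag="00280030" vr="DS">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/pixelSpacing/text()</attr>
  <attr tag="00180050" vr="DS">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/sliceThickness/text()</attr>
  <attr tag="00280100" vr="US" src="literal">16</attr>
  <attr tag="00280101" vr="US" src="literal">16</attr>
  <attr tag="00280102" vr="US" src="literal">15</attr>
  <attr tag="00280103" vr="US" src="literal">1</attr>
  <attr tag="00281052" vr="DS">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/rescaleIntercept/text()</attr>
  <attr tag="00281053" vr="DS">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/rescaleSlope/text()</attr>
  <!--Pixel Data: raw payload UID, padded to a square grid at export-->
  <attr tag="7FE00010" vr="OW">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/dbInfo/databaseUID/text()</attr>
</dicom>
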