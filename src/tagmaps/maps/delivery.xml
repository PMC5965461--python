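<dicom type="DELIVERY_SINOGRAM" version_scope="V3 V4_0 V4_2PLUS">
  <!--RT Image Storage carrying the detector sinogram-->
  <attr tag="00080016" vr="UI" src="literal">1.2.840.10008.5.1.4.1.1.481.1</attr>
  <attr tag="00080018" vr="UI">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/dbInfo/databaseUID/text()</attr>
  <attr tag="00080023" vr="DA">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/acquisitionDateTime/text()</attr>
  <attr tag="00080033" vr="TM">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/acquisitionDateTime/text()</attr>
  <attr tag="00080060" vr="CS" src="literal">RTIMAGE</attr>
  <attr tag="0008103E" vr="LO" src="literal">Delivery sinogram</attr>
  <attr tag="00100010" vr="PN">/fullPatient/briefPatient/patientName/text()</attr>
  <attr tag="00100020" vr="LO">/fullPatient/briefPatient/patientID/text()</attr>
  <attr tag="00100030" vr="DA">/fullPatient/briefPatient/birthDate/text()</attr>
  <attr tag="00100040" vr="CS">/fullPatient/briefPatient/sex/text()</attr>
  <attr tag="0020000D" vr="UI">/fullPatient/briefPatient/dbInfo/databaseUID/text()</attr>
  <attr tag="0020000E" vr="UI">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/seriesUID/text()</attr>
  <attr tag="30020002" vr="SH" src="literal">SINOGRAM</attr>
  <attr tag="3002000C" vr="CS" src="literal">NON_NORMAL</attr>
  <!--Pixel Data: detector channels x projections, packed to 16 bit-->
  <attr tag="7FE00010" vr="OW">/fullPatient/fullImageDataArray/imageData[dbInfo/databaseUID=$scanUID]/dbInfo/databaseUID/text()</attr>
</dicom>
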