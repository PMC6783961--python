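"""Profile-mode mzML reading and writing for simulated runs.

The writer emits a minimal but standard-conforming mzML 1.1 document: MS1
profile spectra with scan start times in minutes and uncompressed 64-bit
little-endian m/z and intensity arrays. The reader is a small streaming
parser over the same vocabulary (it also accepts zlib-compressed and 32-bit
arrays, the common variants in the wild). Run metadata (product, treatment,
duration, replicate, seed) travels in a JSON sidecar next to the mzML file.
"""

from __future__ import annotations

import base64
import json
import zlib as _zlib
from pathlib import Path
from xml.etree import ElementTree

import numpy as np

from .simulate import AcquisitionParams, ChromatographicRun, Scan

_NS = "{http://psi.hupo.org/ms/mzml}"

# cvParam accessions understood by the reader
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="middleup" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="dp1">
      <processingMethod order="1" softwareRef="middleup">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="dp1">
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode(array: np.ndarray) -> str:
    return base64.b64encode(np.asarray(array, dtype="<f8").tobytes()).decode()


def _spectrum_xml(index: int, scan: Scan) -> str:
    mz_b64 = _encode(scan.mz)
    int_b64 = _encode(scan.intensity)
    return (
        f'      <spectrum index="{index}" id="scan={index + 1}" '
        f'defaultArrayLength="{scan.mz.size}">\n'
        '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
        '        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n'
        '        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>\n'
        '        <scanList count="1">\n'
        '          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
        '          <scan>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
        "          </scan>\n"
        "        </scanList>\n"
        '        <binaryDataArrayList count="2">\n'
        f'          <binaryDataArray encodedLength="{len(mz_b64)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
        f"            <binary>{mz_b64}</binary>\n"
        "          </binaryDataArray>\n"
        f'          <binaryDataArray encodedLength="{len(int_b64)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>\n'
        f"            <binary>{int_b64}</binary>\n"
        "          </binaryDataArray>\n"
        "        </binaryDataArrayList>\n"
        "      </spectrum>\n"
    )


def write_mzml(run: ChromatographicRun, path) -> None:
    """Write a run's profile spectra as mzML 1.1."""
    run_id = (
        f"{run.mab_name}_{run.role}_{run.treatment}_"
        f"{run.duration:g}h_r{run.replicate}"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER.format(run_id=run_id, count=len(run.scans)))
        for i, scan in enumerate(run.scans):
            fh.write(_spectrum_xml(i, scan))
        fh.write(_FOOTER)


def write_run(run: ChromatographicRun, directory) -> Path:
    """Write mzML plus the metadata/ground-truth sidecar; returns mzML path."""
    from .simulate import ground_truth_sidecar

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = (
        f"{run.mab_name}_{run.role}_{run.treatment}_"
        f"{run.duration:g}h_r{run.replicate}"
    )
    mzml_path = directory / f"{stem}.mzML"
    write_mzml(run, mzml_path)
    sidecar = ground_truth_sidecar(run)
    sidecar["acquisition"] = {
        "mz_range": list(run.acquisition.mz_range),
        "grid_pitch": run.acquisition.grid_pitch,
        "rt_sigma": run.acquisition.rt_sigma,
        "base_rt": run.acquisition.base_rt,
    }
    with open(directory / f"{stem}.truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return mzml_path


def _decode_array(bda: ElementTree.Element) -> tuple[str | None, np.ndarray]:
    """Decode one binaryDataArray element to (kind, values)."""
    kind = None
    dtype = "<f8"
    compressed = False
    for cv in bda.iter(f"{_NS}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_MZ_ARRAY:
            kind = "mz"
        elif acc == _ACC_INT_ARRAY:
            kind = "intensity"
        elif acc == _ACC_F32:
            dtype = "<f4"
        elif acc == _ACC_F64:
            dtype = "<f8"
        elif acc == _ACC_ZLIB:
            compressed = True
    binary = bda.find(f"{_NS}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = _zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[Scan]:
    """Read MS1 profile scans (RT in minutes) back from an mzML file."""
    scans: list[Scan] = []
    for _, elem in ElementTree.iterparse(str(path), events=("end",)):
        if elem.tag != f"{_NS}spectrum":
            continue
        rt = 0.0
        for cv in elem.iter(f"{_NS}cvParam"):
            if cv.get("accession") == _ACC_SCAN_START:
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter(f"{_NS}binaryDataArray"):
            kind, values = _decode_array(bda)
            if kind:
                arrays[kind] = values
        scans.append(
            Scan(
                rt=rt,
                mz=arrays.get("mz", np.empty(0)),
                intensity=arrays.get("intensity", np.empty(0)),
            )
        )
        elem.clear()
    scans.sort(key=lambda s: s.rt)
    return scans


def read_run(mzml_path) -> ChromatographicRun:
    """Rebuild a :class:`ChromatographicRun` from mzML + its truth sidecar."""
    mzml_path = Path(mzml_path)
    sidecar_path = mzml_path.parent / (mzml_path.stem + ".truth.json")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    meta = sidecar["metadata"]
    acq_info = sidecar.get("acquisition", {})
    acq_kwargs = dict(
        mz_range=tuple(acq_info.get("mz_range", (600.0, 3200.0))),
        grid_pitch=acq_info.get("grid_pitch", 0.02),
        rt_sigma=acq_info.get("rt_sigma", 0.08),
        seed=meta["seed"],
    )
    if acq_info.get("base_rt"):
        acq_kwargs["base_rt"] = acq_info["base_rt"]
    acq = AcquisitionParams(**acq_kwargs)
    return ChromatographicRun(
        mab_name=meta["mab_name"],
        role=meta["role"],
        treatment=meta["treatment"],
        duration=meta["duration"],
        replicate=meta["replicate"],
        seed=meta["seed"],
        scans=read_mzml(mzml_path),
        ground_truth=sidecar["fractions"],
        acquisition=acq,
    )
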