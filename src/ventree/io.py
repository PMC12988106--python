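"""Text-format I/O: scan CSV, MSP libraries, MGF spectra, feature tables.

MSP reading/writing is delegated to matchms, MGF writing to pyteomics;
runs travel as plain scan CSV (rt_min, mz, intensity) so panels stay
text-only and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AlignedFeature, LibraryRecord, Spectrum
from .deconvolution import DeconvolvedSpectrum
from .synthetic import COMPOUND_CLASSES, CompoundSpec, GroundTruth, RawRun


# ---------------------------------------------------------------------------
# scan CSV
# ---------------------------------------------------------------------------

def write_scan_csv(run: RawRun, path: str | Path) -> None:
    rows = []
    for rt, peaks in run.scans():
        for mz, inten in peaks:
            rows.append((rt, mz, inten))
    pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"]).to_csv(path, index=False)


def read_scan_csv(path: str | Path, sample_id: str = "run",
                  vent_field: str = "Edmond", activity: str = "active") -> RawRun:
    df = pd.read_csv(path)
    rts = np.sort(df["rt_min"].unique())
    idx = {rt: i for i, rt in enumerate(rts)}
    traces: dict[float, np.ndarray] = {}
    for mz, sub in df.groupby("mz"):
        arr = np.zeros(rts.size)
        for rt, inten in zip(sub["rt_min"], sub["intensity"]):
            arr[idx[rt]] += inten
        traces[float(mz)] = arr
    return RawRun(sample_id, vent_field, activity, rts, traces)


def read_mzml(path: str | Path, sample_id: str = "run",
              vent_field: str = "Edmond", activity: str = "active") -> RawRun:
    """Read a centroided mzML run through pyteomics."""
    from pyteomics import mzml as _mzml

    rts, scans = [], []
    with _mzml.read(str(path)) as reader:
        for spec in reader:
            rt = float(spec["scanList"]["scan"][0]["scan start time"])
            rts.append(rt)
            scans.append((spec["m/z array"], spec["intensity array"]))
    order = np.argsort(rts)
    rts = np.asarray(rts)[order]
    traces: dict[float, np.ndarray] = {}
    for i, k in enumerate(order):
        for mz, inten in zip(*scans[k]):
            traces.setdefault(float(mz), np.zeros(rts.size))[i] += float(inten)
    return RawRun(sample_id, vent_field, activity, rts, traces)


# ---------------------------------------------------------------------------
# MSP libraries (via matchms)
# ---------------------------------------------------------------------------

def write_msp(records: list[LibraryRecord] | list[CompoundSpec], path: str | Path) -> None:
    from matchms import Spectrum as MmsSpectrum
    from matchms.exporting import save_as_msp

    specs = []
    for rec in records:
        if isinstance(rec, CompoundSpec):
            name, cls, pairs = rec.id, rec.class_label, rec.spectrum
            formula = None
        else:
            name, cls, pairs = rec.name, rec.class_label, rec.spectrum.peaks
            formula = rec.formula
        mz = np.array([float(m) for m, _ in pairs])
        inten = np.array([float(i) for _, i in pairs])
        meta = {"compound_name": name, "compound_class": cls}
        if formula:
            meta["formula"] = formula
        specs.append(MmsSpectrum(mz=mz, intensities=inten, metadata=meta,
                                 metadata_harmonization=False))
    path = Path(path)
    if path.exists():
        path.unlink()  # save_as_msp appends
    save_as_msp(specs, str(path), style="nist")


def read_msp(path: str | Path) -> list[LibraryRecord]:
    from matchms.importing import load_from_msp

    records = []
    for s in load_from_msp(str(path), metadata_harmonization=False):
        name = s.get("compound_name") or s.get("name") or "unknown"
        cls = s.get("compound_class") or "other"
        if cls not in COMPOUND_CLASSES:
            cls = "other"
        spectrum = Spectrum.from_pairs(zip(s.peaks.mz, s.peaks.intensities))
        records.append(LibraryRecord(name, cls, spectrum, s.get("formula")))
    return records


def library_records(library: list[CompoundSpec]) -> list[LibraryRecord]:
    """View CompoundSpecs as annotation library records."""
    return [LibraryRecord(c.id, c.class_label, Spectrum.from_pairs(c.spectrum))
            for c in library]


# ---------------------------------------------------------------------------
# MGF + spectrum table
# ---------------------------------------------------------------------------

def write_mgf(spectra: list[DeconvolvedSpectrum], path: str | Path,
              sample_id: str = "run") -> None:
    from pyteomics import mgf as _mgf

    entries = []
    for k, s in enumerate(spectra):
        entries.append({
            "m/z array": np.array([m for m, _ in s.peaks], dtype=float),
            "intensity array": np.array([i for _, i in s.peaks]),
            "params": {
                "title": f"{sample_id}_spec{k:04d}",
                "rtinseconds": s.rt_apex * 60.0,
                "pepmass": (float(s.model_mz), s.amplitude),
            },
        })
    _mgf.write(entries, str(path), file_mode="w")


def spectrum_table(spectra: list[DeconvolvedSpectrum], sample_id: str) -> pd.DataFrame:
    return pd.DataFrame([
        {"sample_id": sample_id, "rt_apex": s.rt_apex, "model_mz": s.model_mz,
         "n_fragments": len(s.peaks), "amplitude": s.amplitude}
        for s in spectra
    ])


def feature_table(features: list[AlignedFeature]) -> pd.DataFrame:
    rows = []
    for f in features:
        row: dict = {
            "feature_id": f.feature_id,
            "n_hits": len(f.hits),
            "mean_rt": f.mean_rt,
            "annotation": f.annotation[0] if f.annotation else "",
            "annotation_score": f.annotation[1] if f.annotation else np.nan,
            "class_label": f.class_label or "",
        }
        for sid, h in sorted(f.hits.items()):
            row[f"rt_{sid}"] = h.rt
            row[f"amp_{sid}"] = h.amplitude
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground truth JSON
# ---------------------------------------------------------------------------

def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "shared_ids": sorted(truth.shared_ids),
        "placements": {
            sid: [{"compound_id": p.compound_id, "rt": p.rt, "abundance": p.abundance}
                  for p in pls]
            for sid, pls in truth.placements.items()
        },
    }
    if truth.ftms is not None:
        doc["ftms"] = truth.ftms.to_dict(orient="records")
    if truth.hg is not None:
        doc["hg"] = truth.hg
    Path(path).write_text(json.dumps(doc, indent=1))
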