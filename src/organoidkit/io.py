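"""Reading and writing the pipeline's on-disk formats.

* Recordings: HDF5 container with ``/data`` (channels x samples, float)
  and attributes ``fs``, ``protocol``, ``channel_ids``; small recordings
  can also round-trip through multi-column CSV.
* Ground truth: JSON sidecars.
* Feature tables: signal TSV (analytes in rows, samples in columns,
  mirroring instrument source-data exports) plus a sample-metadata TSV
  (sample_id, group, is_qc) and an optional analyte-map TSV.
* OCR traces: CSV with columns time_min, ocr (+ optional well), plus an
  injections CSV (time_min, label).
* RT-QuIC plates: wide CSV (wells x timepoints, columns = hours) plus a
  replicate-map TSV (well, sample_id).

Missing values in tabular inputs are empty fields or "NA"; zeros are
observed values.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .assays import OCRTrace, QuICPlate
from .conditioning import Recording
from .errors import ParameterError
from .omics import FeatureTable


# --------------------------------------------------------------------------
# Recordings
# --------------------------------------------------------------------------


def write_recording(path: str | Path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.samples, dtype="f8")
        d.attrs["fs"] = rec.fs
        d.attrs["protocol"] = rec.protocol
        d.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]


def read_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        d = f["data"]
        return Recording(
            samples=d[...],
            fs=float(d.attrs["fs"]),
            protocol=str(d.attrs["protocol"]),
            channel_ids=[str(c) for c in d.attrs["channel_ids"]],
        )


def recording_to_csv(path: str | Path, rec: Recording) -> None:
    """Multi-column CSV export (time_s + one column per channel)."""
    df = pd.DataFrame(rec.samples.T, columns=list(rec.channel_ids))
    df.insert(0, "time_s", np.arange(rec.n_samples) / rec.fs)
    df.to_csv(path, index=False)


def recording_from_csv(
    path: str | Path, fs: float | None = None, protocol: str = "organoid_mea"
) -> Recording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ParameterError("recording CSV must have a time_s column")
    t = df.pop("time_s").to_numpy()
    if fs is None:
        if len(t) < 2:
            raise ParameterError("cannot infer fs from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    return Recording(
        samples=df.to_numpy().T, fs=fs, protocol=protocol,
        channel_ids=list(df.columns),
    )


# --------------------------------------------------------------------------
# JSON sidecars
# --------------------------------------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# --------------------------------------------------------------------------
# Feature tables
# --------------------------------------------------------------------------


def write_feature_table(
    signal_path: str | Path,
    meta_path: str | Path,
    table: FeatureTable,
    feature_meta_path: str | Path | None = None,
) -> None:
    """Signal TSV is written features-in-rows, samples-in-columns."""
    table.signal.T.to_csv(signal_path, sep="\t", index_label="feature_id")
    meta = table.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")
    if feature_meta_path is not None:
        fm = table.feature_meta.copy()
        fm.index.name = "feature_id"
        fm.to_csv(feature_meta_path, sep="\t")


def read_feature_table(
    signal_path: str | Path,
    meta_path: str | Path,
    feature_meta_path: str | Path | None = None,
) -> FeatureTable:
    """Read a signal TSV/CSV and sample metadata; orientation auto-detected.

    The signal table may be features x samples (source-data layout) or
    samples x features; whichever axis matches the metadata's sample ids
    is treated as the sample axis.
    """
    sep = "\t" if str(signal_path).endswith((".tsv", ".txt")) else ","
    sig = pd.read_csv(signal_path, sep=sep, index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    if "is_qc" not in meta.columns:
        meta["is_qc"] = meta.get("group", pd.Series(index=meta.index)).eq("QC")
    meta["is_qc"] = meta["is_qc"].astype(bool)

    samples = set(meta.index)
    if samples.issubset(sig.columns):
        sig = sig.T  # features were in rows
    elif not samples.issubset(sig.index):
        raise ParameterError(
            "sample ids in metadata match neither axis of the signal table"
        )
    sig = sig.loc[meta.index]
    sig.index.name = None
    sig.columns.name = None

    if feature_meta_path is not None:
        fmeta = pd.read_csv(feature_meta_path, sep="\t", index_col="feature_id")
        fmeta = fmeta.loc[sig.columns]
    else:
        fmeta = pd.DataFrame(
            {"analyte_id": sig.columns, "class": "metabolite"}, index=sig.columns
        )
    return FeatureTable(signal=sig, sample_meta=meta, feature_meta=fmeta)


# --------------------------------------------------------------------------
# OCR traces and RT-QuIC plates
# --------------------------------------------------------------------------


def read_ocr_csv(
    trace_path: str | Path,
    injections: str | Path | list[tuple[float, str]],
    well: str | None = None,
    protein: float | None = None,
) -> OCRTrace:
    df = pd.read_csv(trace_path)
    for col in ("time_min", "ocr"):
        if col not in df.columns:
            raise ParameterError(f"OCR CSV must have a {col!r} column")
    if well is not None and "well" in df.columns:
        df = df[df["well"] == well]
    if isinstance(injections, (str, Path)):
        inj_df = pd.read_csv(injections)
        injections = [
            (float(r["time_min"]), str(r["label"])) for _, r in inj_df.iterrows()
        ]
    return OCRTrace(
        times=df["time_min"].to_numpy(),
        ocr=df["ocr"].to_numpy(),
        injections=injections,
        protein=protein,
        well=well or "well",
    )


def write_ocr_csv(
    trace_path: str | Path, injections_path: str | Path, trace: OCRTrace
) -> None:
    pd.DataFrame(
        {"time_min": trace.times, "ocr": trace.ocr, "well": trace.well}
    ).to_csv(trace_path, index=False)
    pd.DataFrame(
        [(t, lab) for t, lab in trace.injections], columns=["time_min", "label"]
    ).to_csv(injections_path, index=False)


def read_quic_csv(
    plate_path: str | Path,
    replicate_map_path: str | Path | None = None,
    cadence_min: float = 45.0,
) -> QuICPlate:
    """Wide plate CSV: index = well id, columns = time in hours."""
    df = pd.read_csv(plate_path, index_col=0)
    times_h = np.asarray([float(c) for c in df.columns])
    wells = list(df.index.astype(str))
    if replicate_map_path is not None:
        rmap_df = pd.read_csv(replicate_map_path, sep="\t")
        rmap: dict[str, list[int]] = {}
        for _, row in rmap_df.iterrows():
            rmap.setdefault(str(row["sample_id"]), []).append(
                wells.index(str(row["well"]))
            )
    else:
        rmap = {"plate": list(range(len(wells)))}
    return QuICPlate(
        fluorescence=df.to_numpy(),
        times_h=times_h,
        replicate_map=rmap,
        cadence_min=cadence_min,
    )


def write_quic_csv(
    plate_path: str | Path,
    plate: QuICPlate,
    replicate_map_path: str | Path | None = None,
) -> None:
    wells = [f"W{i:02d}" for i in range(plate.fluorescence.shape[0])]
    df = pd.DataFrame(
        plate.fluorescence, index=wells, columns=[f"{t:g}" for t in plate.times_h]
    )
    df.index.name = "well"
    df.to_csv(plate_path)
    if replicate_map_path is not None:
        rows = [
            {"well": wells[i], "sample_id": sid}
            for sid, idxs in plate.replicate_map.items()
            for i in idxs
        ]
        pd.DataFrame(rows).to_csv(replicate_map_path, sep="\t", index=False)
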