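"""Record and fixture I/O.

Two on-disk representations are supported:

* a minimal WFDB adapter (``.hea`` header + format-16 ``.dat`` signal
  file, the encoding used by the PTB and NSTDB databases).  Only what
  the pipeline needs is implemented: one signal file per record,
  16-bit little-endian samples, gain/baseline scaling.  WFDB is an
  integer format, so writing quantizes at the ADC resolution (1/gain).
* a plain-text fixture format (per-record CSV of lead columns plus a
  JSON manifest recording seeds and parameters), which round-trips
  floating-point samples exactly and is the default for synthetic
  cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import ECGRecord
from .errors import InvalidArgumentError

__all__ = [
    "write_wfdb_record", "read_wfdb_record", "select_leads",
    "resample_to", "write_fixture", "read_fixture", "write_manifest",
]

_STANDARD_12 = ("I", "II", "III", "aVR", "aVL", "aVF",
                "V1", "V2", "V3", "V4", "V5", "V6")


# ----------------------------------------------------------------------
# WFDB (header + format-16 signal)
# ----------------------------------------------------------------------

def write_wfdb_record(record: ECGRecord, directory: str | Path,
                      name: str | None = None, gain: float = 1000.0) -> Path:
    """Write ``record`` as ``<name>.hea`` + ``<name>.dat`` (format 16).

    Samples are quantized to ``round(x * gain)`` 16-bit integers;
    amplitudes must stay within the int16 range at the chosen gain.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or record.patient_id or "record"
    adc = np.round(record.signal * gain)
    if np.abs(adc).max() > 32767:
        raise InvalidArgumentError("signal exceeds int16 range at this gain")
    adc = adc.astype("<i2")

    lines = [f"{name} {record.n_leads} {record.fs:g} {record.n_samples}"]
    for i, lead in enumerate(record.lead_names):
        first = int(adc[i, 0]) if record.n_samples else 0
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 {first} 0 0 {lead}")
    lines.append(f"# patient_id {record.patient_id}")
    lines.append(f"# label {record.label}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    # format 16: samples interleaved across signals, little-endian
    adc.T.reshape(-1).tofile(directory / f"{name}.dat")
    return directory / f"{name}.hea"


def read_wfdb_record(path: str | Path) -> ECGRecord:
    """Read a format-16 WFDB record written by :func:`write_wfdb_record`
    (or any single-``.dat``, format-16 record with the same layout)."""
    path = Path(path)
    header = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not header.exists():
        raise InvalidArgumentError(f"missing header file: {header}")
    lines = [ln.rstrip() for ln in header.read_text().splitlines() if ln.strip()]
    fields = lines[0].split()
    if len(fields) < 4:
        raise InvalidArgumentError("malformed header: record line needs name, n_sig, fs, n_samples")
    rec_name, n_sig, fs, n_samples = fields[0], int(fields[1]), float(fields[2]), int(fields[3])

    lead_names, gains, baselines, dat_name = [], [], [], None
    comments: dict[str, str] = {}
    for ln in lines[1:]:
        if ln.startswith("#"):
            parts = ln[1:].split(maxsplit=1)
            if len(parts) == 2:
                comments[parts[0]] = parts[1]
            continue
        parts = ln.split()
        if len(parts) < 3:
            raise InvalidArgumentError(f"malformed header: bad signal line {ln!r}")
        dat_name = parts[0]
        if parts[1] != "16":
            raise InvalidArgumentError(f"unsupported signal format {parts[1]!r} (only 16)")
        gain_field = parts[2]
        if "(" in gain_field:
            g, rest = gain_field.split("(", 1)
            baselines.append(float(rest.split(")")[0]))
        else:
            g = gain_field.split("/")[0]
            baselines.append(0.0)
        gains.append(float(g.split("/")[0]))
        lead_names.append(parts[-1] if len(parts) >= 9 else f"L{len(lead_names)}")
    if len(lead_names) != n_sig:
        raise InvalidArgumentError(
            f"malformed header: {n_sig} signals declared, {len(lead_names)} signal lines"
        )

    dat_path = header.parent / dat_name
    if not dat_path.exists():
        raise InvalidArgumentError(f"missing signal file: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    expected = n_sig * n_samples
    if raw.size < expected:
        raise InvalidArgumentError(
            f"truncated signal file: {raw.size} samples on disk, {expected} declared"
        )
    adc = raw[:expected].reshape(n_samples, n_sig).T.astype(float)
    signal = (adc - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]
    return ECGRecord(
        signal=signal,
        fs=fs,
        patient_id=comments.get("patient_id", rec_name),
        label=comments.get("label", "NOR"),
        lead_names=tuple(lead_names),
    )


def select_leads(record: ECGRecord, names=_STANDARD_12) -> ECGRecord:
    """Subset a record to the named leads (e.g. the 12 standard leads)."""
    index = {n: i for i, n in enumerate(record.lead_names)}
    missing = [n for n in names if n not in index]
    if missing:
        raise InvalidArgumentError(f"record lacks leads: {missing}")
    rows = [index[n] for n in names]
    return ECGRecord(
        signal=record.signal[rows],
        fs=record.fs,
        patient_id=record.patient_id,
        label=record.label,
        lead_names=tuple(names),
        r_peaks=record.r_peaks,
    )


def resample_to(x: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    """Polyphase resampling (e.g. 360 Hz noise records to 1000 Hz)."""
    if fs_from == fs_to:
        return np.asarray(x, dtype=float)
    from fractions import Fraction

    frac = Fraction(fs_to / fs_from).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


# ----------------------------------------------------------------------
# plain-text fixtures
# ----------------------------------------------------------------------

def write_fixture(records: list[ECGRecord], directory: str | Path,
                  parameters: dict | None = None) -> Path:
    """Per-record CSVs plus a JSON manifest of seeds/parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        fname = f"{rec.patient_id}.csv"
        frame = pd.DataFrame(rec.signal.T, columns=list(rec.lead_names))
        frame.to_csv(directory / fname, index=False, float_format="%.17g")
        entries.append(
            {
                "file": fname,
                "patient_id": rec.patient_id,
                "label": rec.label,
                "fs": rec.fs,
                "lead_names": list(rec.lead_names),
                "r_peaks": None if rec.r_peaks is None else [int(p) for p in rec.r_peaks],
            }
        )
    manifest = {"records": entries, "parameters": parameters or {}}
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def read_fixture(directory: str | Path) -> list[ECGRecord]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    records = []
    for entry in manifest["records"]:
        frame = pd.read_csv(directory / entry["file"], float_precision="round_trip")
        records.append(
            ECGRecord(
                signal=frame.to_numpy(dtype=float).T,
                fs=entry["fs"],
                patient_id=entry["patient_id"],
                label=entry["label"],
                lead_names=tuple(entry["lead_names"]),
                r_peaks=None if entry["r_peaks"] is None else np.asarray(entry["r_peaks"]),
            )
        )
    return records


def write_manifest(path: str | Path, config: dict, seeds: dict | None = None) -> None:
    """Run manifest: config hash, seeds and library versions."""
    import hashlib
    import sklearn
    import scipy

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds or {},
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
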