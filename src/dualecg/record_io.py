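"""Annotated ECG record I/O and the AAMI class mapping.

Two on-disk dialects are supported:

* the package's **CSV fixture** pair — ``<base>.sig.csv`` (header comments
  ``# fs=`` / leads as column names, samples in mV) plus ``<base>.ann.csv``
  (``sample_index,symbol``);
* a minimal subset of the **WFDB** format — ``.hea`` header, ``.dat``
  signal in format 212 (two 12-bit samples packed into 3 bytes) and ``.atr``
  MIT annotation stream — enough to read MIT-BIH-style records and to
  round-trip fixtures written by this module.

Beat symbols are mapped to the four AAMI classes (paced and unclassifiable
beats, and all non-beat annotations, are EXCLUDED).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classes import EXCLUDED

# symbol -> AAMI class (ANSI/AAMI EC57 grouping of MIT-BIH beat codes)
_SYMBOL_CLASS = {
    **{s: "N" for s in "NLRej"},
    **{s: "VEB" for s in "VE"},
    **{s: "SVEB" for s in "AaJS"},
    "F": "F",
}


def map_symbol_to_aami(symbol: str) -> str:
    """Map an annotation symbol to {N, VEB, SVEB, F, EXCLUDED}.

    Total function: paced ('/'), fusion-of-paced ('f'), unclassifiable
    ('Q') and every non-beat symbol map to EXCLUDED.
    """
    return _SYMBOL_CLASS.get(symbol, EXCLUDED)


@dataclass(frozen=True)
class BeatAnnotation:
    """One beat annotation: R-peak sample index (0-based) and symbol."""

    sample_index: int
    symbol: str

    @property
    def aami_class(self) -> str:
        return map_symbol_to_aami(self.symbol)


@dataclass
class ECGRecord:
    """One annotated single-lead recording (samples in mV)."""

    record_id: str
    fs: float
    lead: str
    samples: np.ndarray
    annotations: list[BeatAnnotation]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        idx = [a.sample_index for a in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotations must be strictly sorted by sample index")
        if idx and (idx[0] < 0 or idx[-1] >= self.samples.size):
            raise ValueError("annotation index outside the signal")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.annotations:
            counts[a.aami_class] = counts.get(a.aami_class, 0) + 1
        return counts


@dataclass(frozen=True)
class DatasetSplit:
    name: str
    record_ids: tuple[str, ...]


_DS1 = (
    "101", "103", "105", "106", "109", "111", "113", "115", "117", "119",
    "121", "122", "123", "200", "202", "203", "207", "210", "212", "213",
    "214", "219", "221", "222", "228", "230", "231", "232", "233", "234",
)
_DS2 = (
    "100", "108", "112", "114", "116", "118", "124", "201", "205", "208",
    "209", "215", "220", "223",
)
PACED_RECORDS = ("102", "104", "107", "217")


def standard_splits() -> tuple[DatasetSplit, DatasetSplit]:
    """The inter-patient MIT-BIH split: 30 training and 14 test records.

    The four paced records (102, 104, 107, 217) appear in neither set.
    """
    return DatasetSplit("DS-I", _DS1), DatasetSplit("DS-II", _DS2)


# ---------------------------------------------------------------------------
# CSV fixture dialect


def write_fixture(record: ECGRecord, base: str | Path) -> tuple[Path, Path]:
    """Write the two-file CSV fixture: ``<base>.sig.csv`` + ``<base>.ann.csv``."""
    base = Path(base)
    sig_path = base.parent / (base.name + ".sig.csv")
    ann_path = base.parent / (base.name + ".ann.csv")
    with open(sig_path, "w") as f:
        f.write(f"# record_id={record.record_id}\n# fs={record.fs:g}\n")
        f.write(f"{record.lead}\n")
        np.savetxt(f, record.samples, fmt="%.17g")  # full round-trip precision
    with open(ann_path, "w") as f:
        f.write("sample_index,symbol\n")
        for a in record.annotations:
            f.write(f"{a.sample_index},{a.symbol}\n")
    return sig_path, ann_path


def _read_fixture(sig_path: Path, lead: str | None) -> ECGRecord:
    meta = {}
    with open(sig_path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = f.tell()
            line = f.readline()
        leads = [c.strip() for c in line.strip().split(",")]
        data = np.loadtxt(f, delimiter=",", ndmin=2)
    if lead is None:
        lead = leads[0]
    if lead not in leads:
        raise ValueError(f"lead {lead!r} not in fixture; available leads: {leads}")
    samples = data[:, leads.index(lead)]

    ann_path = sig_path.with_name(sig_path.name.replace(".sig.csv", ".ann.csv"))
    annotations = []
    if ann_path.exists():
        with open(ann_path) as f:
            header = f.readline()
            if "sample_index" not in header:
                raise ValueError(f"malformed annotation file {ann_path}")
            for line in f:
                if not line.strip():
                    continue
                idx, sym = line.strip().split(",")
                annotations.append(BeatAnnotation(int(idx), sym))
    else:
        raise FileNotFoundError(f"annotation file {ann_path} not found")
    return ECGRecord(
        record_id=meta.get("record_id", sig_path.stem.replace(".sig", "")),
        fs=float(meta.get("fs", 360)),
        lead=lead,
        samples=samples,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Minimal WFDB support (.hea / .dat format 212 / .atr)

# MIT annotation code <-> symbol (beat + common non-beat codes)
_WFDB_CODE_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    22: '"', 25: "B", 27: "t", 28: "+", 30: "?", 31: "!", 32: "[", 33: "]",
    34: "e", 35: "n", 37: "x", 38: "f", 41: "r",
}
_WFDB_SYMBOL_CODE = {s: c for c, s in _WFDB_CODE_SYMBOL.items()}


def _read_header(hea_path: Path):
    lines = [
        ln.strip() for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_id = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        baseline = 0
        if "(" in gain_str:
            gain_str, rest = gain_str.split("(")
            baseline = int(rest.rstrip(")"))
        gain = float(gain_str) or 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if "(" not in gain_field:
            baseline = adc_zero
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(signals)}"
        signals.append(
            {"file": fname, "fmt": int(fmt), "gain": gain, "baseline": baseline,
             "desc": desc}
        )
    return record_id, n_sig, fs, signals


def _read_dat212(dat_path: Path, n_sig: int) -> np.ndarray:
    raw = np.frombuffer(dat_path.read_bytes(), dtype=np.uint8)
    raw = raw[: 3 * (raw.size // 3)].reshape(-1, 3).astype(np.int32)
    s0 = raw[:, 0] | ((raw[:, 1] & 0x0F) << 8)
    s1 = raw[:, 2] | ((raw[:, 1] & 0xF0) << 4)
    s0 = np.where(s0 > 2047, s0 - 4096, s0)
    s1 = np.where(s1 > 2047, s1 - 4096, s1)
    flat = np.empty(raw.shape[0] * 2, dtype=np.int32)
    flat[0::2], flat[1::2] = s0, s1
    flat = flat[: n_sig * (flat.size // n_sig)]
    return flat.reshape(-1, n_sig)


def _write_dat212(dat_path: Path, adc: np.ndarray) -> None:
    flat = adc.reshape(-1).astype(np.int32)
    if flat.size % 2:
        flat = np.append(flat, 0)
    u = np.where(flat < 0, flat + 4096, flat).astype(np.uint32)
    s0, s1 = u[0::2], u[1::2]
    out = np.empty((s0.size, 3), dtype=np.uint8)
    out[:, 0] = s0 & 0xFF
    out[:, 1] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
    out[:, 2] = s1 & 0xFF
    dat_path.write_bytes(out.tobytes())


def _read_atr(atr_path: Path) -> list[BeatAnnotation]:
    data = atr_path.read_bytes()
    anns: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if code == 0 and delta == 0:  # end of file
            break
        if code == 59:  # SKIP: next 4 bytes are a long interval
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            t += (hi << 16) | lo
            i += 4
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers: ignore
            continue
        elif code == 63:  # AUX: skip payload (padded to even)
            i += delta + (delta & 1)
        else:
            t += delta
            sym = _WFDB_CODE_SYMBOL.get(code)
            if sym is not None:
                anns.append(BeatAnnotation(sample_index=t, symbol=sym))
    return anns


def _write_atr(atr_path: Path, annotations: list[BeatAnnotation]) -> None:
    out = bytearray()
    t = 0
    for a in annotations:
        code = _WFDB_SYMBOL_CODE.get(a.symbol, 13)  # unknown -> Q
        delta = a.sample_index - t
        if delta >= 1024 or delta < 0:
            out += struct.pack("<H", (59 << 10))
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        t = a.sample_index
    out += struct.pack("<H", 0)
    atr_path.write_bytes(bytes(out))


def write_wfdb(record: ECGRecord, base: str | Path, gain: float = 200.0) -> None:
    """Write ``<base>.hea/.dat/.atr`` (format 212, single signal)."""
    base = Path(base)
    name = base.name
    adc = np.clip(np.round(record.samples * gain), -2048, 2047).astype(np.int32)
    adc = adc[:, None]
    _write_dat212(base.with_suffix(".dat"), adc)
    _write_atr(base.with_suffix(".atr"), record.annotations)
    hea = (
        f"{name} 1 {record.fs:g} {record.samples.size}\n"
        f"{name}.dat 212 {gain:g}/mV 12 0 0 0 0 {record.lead}\n"
    )
    base.with_suffix(".hea").write_text(hea)


def _read_wfdb(hea_path: Path, lead: str | None) -> ECGRecord:
    record_id, n_sig, fs, signals = _read_header(hea_path)
    descs = [s["desc"] for s in signals]
    if lead is None:
        ch = 0
    elif lead in descs:
        ch = descs.index(lead)
    else:
        raise ValueError(f"lead {lead!r} not in record; available leads: {descs}")
    sig = signals[ch]
    if sig["fmt"] != 212:
        raise NotImplementedError(f"WFDB format {sig['fmt']} not supported (only 212)")
    dat_path = hea_path.parent / sig["file"]
    adc = _read_dat212(dat_path, n_sig)
    samples = (adc[:, ch] - sig["baseline"]) / sig["gain"]
    atr_path = hea_path.with_suffix(".atr")
    if not atr_path.exists():
        raise FileNotFoundError(f"annotation stream {atr_path} not found")
    annotations = [a for a in _read_atr(atr_path) if a.sample_index < samples.size]
    return ECGRecord(
        record_id=record_id, fs=fs, lead=descs[ch], samples=samples,
        annotations=annotations,
    )


def load_record(path: str | Path, lead: str | None = "MLII") -> ECGRecord:
    """Load an annotated record from either supported dialect.

    ``path`` may be the base path (no extension), a ``.sig.csv`` file or a
    ``.hea`` file.  A missing lead raises with the list of available leads
    rather than silently substituting another channel.  Pass ``lead=None``
    to take the first channel whatever its name.
    """
    path = Path(path)
    if path.name.endswith(".sig.csv"):
        return _read_fixture(path, lead)
    if path.suffix == ".hea":
        return _read_wfdb(path, lead)
    if path.with_suffix(".sig.csv").exists():
        return _read_fixture(path.with_suffix(".sig.csv"), lead)
    if path.with_suffix(".hea").exists():
        return _read_wfdb(path.with_suffix(".hea"), lead)
    raise FileNotFoundError(f"no record found at {path} (.sig.csv or .hea)")
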