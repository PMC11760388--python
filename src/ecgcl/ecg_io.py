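"""Reading PhysioNet-style WFDB records and persisting segment datasets.

A deliberately small WFDB reader lives here: text ``.hea`` headers, binary
signal files in formats 16 (little-endian int16) and 212 (packed 12-bit
pairs), and MIT-format annotation files (from which rhythm-change events are
extracted via their ``(``-prefixed aux strings, e.g. ``(AFIB``).  Only
reading is supported.

Conventions used throughout the package: 0-based sample indices and
half-open intervals ``[start, end)``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np

logger = logging.getLogger(__name__)

STORE_VERSION = 1

#: Rhythm codes mapped to the positive (AF) class: atrial fibrillation and
#: atrial flutter; every other rhythm is non-AF.
AF_CODES = frozenset({"AFIB", "AFL"})

#: Rhythm codes commonly seen in the PhysioNet AF/arrhythmia databases.
KNOWN_NON_AF_CODES = frozenset({
    "N", "NSR", "SR", "J", "AB", "B", "BII", "IVR", "NOD", "P", "PREX",
    "SBR", "SVTA", "T", "VFL", "VT",
})


@dataclass
class ECGRecord:
    """Multi-channel ECG with a uniform sampling rate."""

    signals: np.ndarray  # (n_channels, n_samples), physical units
    fs: float
    lead_names: List[str]
    record_id: str

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals))
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass(frozen=True)
class RhythmInterval:
    """One rhythm stretch, half-open in samples."""

    start_sample: int
    end_sample: int
    rhythm_code: str

    def __post_init__(self) -> None:
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError("require 0 <= start < end")


@dataclass
class SegmentStore:
    """A dataset of fixed-length segment pairs with provenance.

    ``segments`` holds the analysis lead, ``paired_segments`` the
    simultaneously recorded second lead of the same windows.  ``labels`` is
    optional (0 = non-AF, 1 = AF).  ``r_peaks`` (per-segment sample indices,
    when ground truth or detections are available) ride along for
    augmentation.
    """

    segments: np.ndarray
    paired_segments: np.ndarray
    labels: Optional[np.ndarray]
    fs: float
    record_ids: List[str]
    start_samples: np.ndarray
    r_peaks: Optional[List[np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.segments.shape != self.paired_segments.shape:
            raise ValueError("segments and paired_segments must share a shape")
        if self.labels is not None and len(self.labels) != len(self.segments):
            raise ValueError("labels must have one entry per segment")

    def __len__(self) -> int:
        return len(self.segments)

    def subset(self, idx) -> "SegmentStore":
        idx = np.asarray(idx)
        return SegmentStore(
            segments=self.segments[idx],
            paired_segments=self.paired_segments[idx],
            labels=None if self.labels is None else self.labels[idx],
            fs=self.fs,
            record_ids=[self.record_ids[i] for i in idx],
            start_samples=self.start_samples[idx],
            r_peaks=None if self.r_peaks is None else [self.r_peaks[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# WFDB header / signal reading
# ---------------------------------------------------------------------------

def _parse_header(hea_path: str):
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    record_id = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    sig_specs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fname = tok[0]
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, 0
        if len(tok) > 2:
            gspec = tok[2].split("/")[0]
            if "(" in gspec:
                gpart, bpart = gspec.split("(")
                gain = float(gpart) if gpart else 200.0
                baseline = int(bpart.rstrip(")"))
            else:
                gain = float(gspec) if gspec else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if len(tok) > 2 and "(" not in tok[2]:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else ""
        sig_specs.append({"file": fname, "fmt": fmt, "gain": gain or 200.0,
                          "baseline": baseline, "desc": desc})
    return record_id, n_sig, fs, n_samples, sig_specs


def _read_dat(path: str, fmt: str, n_sig: int, n_samples: int) -> np.ndarray:
    with open(path, "rb") as fh:
        raw = fh.read()
    if fmt == "16":
        data = np.frombuffer(raw, dtype="<i2")
        if n_samples:
            data = data[: n_sig * n_samples]
        return data.reshape(-1, n_sig).T.astype(np.int32)
    if fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: 3 * (len(b) // 3)].reshape(-1, 3).astype(np.int32)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        data = np.empty(2 * len(b), dtype=np.int32)
        data[0::2] = first
        data[1::2] = second
        if n_samples:
            data = data[: n_sig * n_samples]
        return data.reshape(-1, n_sig).T
    raise ValueError(f"unsupported WFDB signal format {fmt!r}")


def choose_channels(lead_names: Sequence[str],
                    preference: Sequence[str] = ("II", "I")) -> Tuple[int, Optional[int]]:
    """Pick the analysis channel (preferring lead II, then I) and its pair."""
    names = [str(n).strip().upper() for n in lead_names]
    analysis = 0
    for pref in preference:
        matches = [i for i, n in enumerate(names) if n == pref or n == "ML" + pref]
        if matches:
            analysis = matches[0]
            break
    others = [i for i in range(len(names)) if i != analysis]
    paired = others[0] if others else None
    return analysis, paired


def read_wfdb_record(path: str,
                     preference: Sequence[str] = ("II", "I"),
                     ) -> Tuple[ECGRecord, int, Optional[int]]:
    """Read ``path(.hea/.dat)``; returns the record plus the analysis-channel
    index and the paired-channel index (None for single-channel records)."""
    hea_path = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    record_id, n_sig, fs, n_samples, specs = _parse_header(hea_path)
    base = os.path.dirname(hea_path)
    signals = []
    # group channels by signal file (all our targets keep one file per record)
    by_file: Dict[str, List[int]] = {}
    for i, s in enumerate(specs):
        by_file.setdefault(s["file"], []).append(i)
    chan_data: Dict[int, np.ndarray] = {}
    for fname, chans in by_file.items():
        dat_path = os.path.join(base, fname)
        if not os.path.exists(dat_path):
            raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
        adc = _read_dat(dat_path, specs[chans[0]]["fmt"], len(chans), n_samples)
        for j, ch in enumerate(chans):
            s = specs[ch]
            chan_data[ch] = (adc[j] - s["baseline"]) / s["gain"]
    signals = np.stack([chan_data[i] for i in range(n_sig)])
    record = ECGRecord(signals=signals, fs=fs,
                       lead_names=[s["desc"] for s in specs],
                       record_id=record_id)
    analysis, paired = choose_channels(record.lead_names)
    if paired is None:
        logger.warning("record %s has a single channel; pairing disabled", record_id)
    return record, analysis, paired


# ---------------------------------------------------------------------------
# MIT-format annotations -> rhythm intervals
# ---------------------------------------------------------------------------

def read_annotation_events(path: str) -> List[Tuple[int, str]]:
    """Extract ``(sample, aux_string)`` rhythm-change events from a MIT-format
    annotation file (aux strings such as ``(AFIB`` attached to annotations)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    words = np.frombuffer(raw, dtype="<u2")
    events: List[Tuple[int, str]] = []
    t = 0
    i = 0
    pending_aux_time: Optional[int] = None
    while i < len(words):
        w = int(words[i])
        code, data = w >> 10, w & 0x3FF
        if code == 0 and data == 0:
            break
        if code == 59:  # SKIP: 4-byte time offset follows (high word first)
            if i + 2 >= len(words):
                raise ValueError("truncated SKIP in annotation file")
            offset = (int(words[i + 1]) << 16) | int(words[i + 2])
            if offset >= 2**31:
                offset -= 2**32
            t += offset
            i += 3
            continue
        if code == 63:  # AUX: byte count, then the string (even-padded)
            n_bytes = data
            start = 2 * (i + 1)
            aux = raw[start : start + n_bytes].rstrip(b"\x00").decode(
                "ascii", errors="replace")
            if aux.startswith("("):
                events.append((pending_aux_time if pending_aux_time is not None
                               else t, aux))
            i += 1 + (n_bytes + 1) // 2
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers: no time advance
            i += 1
            continue
        t += data
        pending_aux_time = t
        i += 1
    return events


def parse_rhythm_annotations(events: Sequence[Tuple[int, str]],
                             record_length: int) -> List[RhythmInterval]:
    """Tile ``[first event, record_length)`` with rhythm intervals.

    Each rhythm-change event opens an interval closed by the next event (or
    the record end); the WFDB aux convention's leading ``(`` is stripped.
    """
    if not events:
        return []
    samples = [s for s, _ in events]
    if any(b < a for a, b in zip(samples, samples[1:])):
        raise ValueError("annotation samples are not monotonically increasing")
    intervals = []
    for (s, aux), nxt in zip(events, samples[1:] + [record_length]):
        code = aux.lstrip("(").strip()
        if s < nxt:  # zero-length stretches (duplicate samples) are dropped
            intervals.append(RhythmInterval(s, min(nxt, record_length), code))
    return intervals


def rhythm_to_binary(rhythm_code: str) -> int:
    """1 for AF/AFL (case-insensitive, after '(' stripping), else 0."""
    code = rhythm_code.lstrip("(").strip().upper()
    if code in AF_CODES:
        return 1
    if code not in KNOWN_NON_AF_CODES:
        logger.info("unknown rhythm code %r mapped to non-AF", rhythm_code)
    return 0


# ---------------------------------------------------------------------------
# segment-store persistence (HDF5)
# ---------------------------------------------------------------------------

def save_store(store: SegmentStore, path: str) -> None:
    """Write the store to an HDF5 container; arrays round-trip bit-exactly."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = STORE_VERSION
        f.attrs["fs"] = store.fs
        f.create_dataset("segments", data=store.segments)
        f.create_dataset("paired_segments", data=store.paired_segments)
        if store.labels is not None:
            f.create_dataset("labels", data=np.asarray(store.labels, dtype=np.int8))
        f.create_dataset("record_ids",
                         data=np.array(store.record_ids, dtype=h5py.string_dtype()))
        f.create_dataset("start_samples", data=store.start_samples)
        if store.r_peaks is not None:
            flat = (np.concatenate(store.r_peaks) if store.r_peaks
                    else np.empty(0, dtype=np.int64))
            offs = np.cumsum([0] + [len(r) for r in store.r_peaks])
            f.create_dataset("rpeaks_flat", data=flat.astype(np.int64))
            f.create_dataset("rpeaks_offsets", data=offs.astype(np.int64))


def load_store(path: str) -> SegmentStore:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("version", -1))
        if version != STORE_VERSION:
            raise ValueError(
                f"segment store version {version} != supported {STORE_VERSION}")
        r_peaks = None
        if "rpeaks_flat" in f:
            flat = f["rpeaks_flat"][:]
            offs = f["rpeaks_offsets"][:]
            r_peaks = [flat[a:b] for a, b in zip(offs[:-1], offs[1:])]
        return SegmentStore(
            segments=f["segments"][:],
            paired_segments=f["paired_segments"][:],
            labels=f["labels"][:] if "labels" in f else None,
            fs=float(f.attrs["fs"]),
            record_ids=[s.decode() if isinstance(s, bytes) else str(s)
                        for s in f["record_ids"][:]],
            start_samples=f["start_samples"][:],
            r_peaks=r_peaks,
        )
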