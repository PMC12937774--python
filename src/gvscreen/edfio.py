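"""Minimal EDF (European Data Format) writer/reader.

Supports continuous multichannel recordings with a common sampling rate,
1-second data records and 16-bit samples, which is all the session I/O here
needs.  Data shorter than a whole number of records is zero-padded on write;
readers recover the true length from the events table.
"""
from __future__ import annotations

import numpy as np

_HDR_BYTES = 256
DIG_MIN, DIG_MAX = -32768, 32767
DEFAULT_PHYS_RANGE = (-2000.0, 2000.0)  # microvolts


def _fix(s: str, width: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _num(x, width: int) -> bytes:
    s = f"{x:.{width}g}"
    while len(s) > width:
        s = s[:-1]
    return _fix(s, width)


def _write_header(fh, fs: int, channel_names: list[str],
                  phys_range: tuple[float, float], n_records: int) -> int:
    """Write the EDF header; returns the byte offset of the record-count
    field so it can be patched once streaming finishes."""
    ns = len(channel_names)
    pmin, pmax = phys_range
    fh.write(_fix("0", 8))
    fh.write(_fix("X X X X", 80))
    fh.write(_fix("Startdate 01-JAN-2000 X X X", 80))
    fh.write(_fix("01.01.00", 8))
    fh.write(_fix("00.00.00", 8))
    fh.write(_num(_HDR_BYTES * (1 + ns), 8))
    fh.write(_fix("", 44))
    n_records_pos = fh.tell()
    fh.write(_num(n_records, 8))
    fh.write(_num(1, 8))  # record duration, seconds
    fh.write(_num(ns, 4))
    for name in channel_names:
        fh.write(_fix(f"EEG {name}", 16))
    for _ in channel_names:
        fh.write(_fix("AgAgCl electrode", 80))
    for _ in channel_names:
        fh.write(_fix("uV", 8))
    for _ in channel_names:
        fh.write(_num(pmin, 8))
    for _ in channel_names:
        fh.write(_num(pmax, 8))
    for _ in channel_names:
        fh.write(_num(DIG_MIN, 8))
    for _ in channel_names:
        fh.write(_num(DIG_MAX, 8))
    for _ in channel_names:
        fh.write(_fix("", 80))
    for _ in channel_names:
        fh.write(_num(fs, 8))
    for _ in channel_names:
        fh.write(_fix("", 32))
    return n_records_pos


def _digitize(block: np.ndarray, phys_range: tuple[float, float]) -> bytes:
    pmin, pmax = phys_range
    scale = (DIG_MAX - DIG_MIN) / (pmax - pmin)
    dig = np.round((np.clip(block, pmin, pmax) - pmin) * scale + DIG_MIN)
    return dig.astype("<i2").tobytes()


class EdfWriter:
    """Incremental EDF writer; feed (channels, k*fs) blocks via append().

    Records are written as they arrive so whole sessions never need to be
    held in memory; the record count in the header is patched on close().
    """

    def __init__(self, path, fs: int, channel_names: list[str],
                 phys_range: tuple[float, float] = DEFAULT_PHYS_RANGE):
        self._fh = open(path, "wb")
        self._fs = int(fs)
        self._names = list(channel_names)
        self._range = phys_range
        self._n_rec = 0
        self._count_pos = _write_header(self._fh, self._fs, self._names,
                                        self._range, -1)

    def append(self, data: np.ndarray) -> None:
        """Append (channels, n) samples; n is zero-padded up to whole records."""
        data = np.asarray(data, dtype=float)
        if data.shape[0] != len(self._names):
            raise ValueError(
                f"expected {len(self._names)} channels, got {data.shape[0]}")
        n = data.shape[1]
        for r in range(int(np.ceil(n / self._fs))):
            block = data[:, r * self._fs:(r + 1) * self._fs]
            if block.shape[1] < self._fs:
                block = np.pad(block, ((0, 0), (0, self._fs - block.shape[1])))
            self._fh.write(_digitize(block, self._range))
            self._n_rec += 1

    def close(self) -> None:
        self._fh.seek(self._count_pos)
        self._fh.write(_num(self._n_rec, 8))
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def write_edf(path, data: np.ndarray, fs: int, channel_names: list[str],
              phys_range: tuple[float, float] = DEFAULT_PHYS_RANGE) -> None:
    """Write a (channels, samples) float array as an EDF file."""
    with EdfWriter(path, fs, channel_names, phys_range) as w:
        w.append(np.asarray(data, dtype=float))


def read_edf(path) -> tuple[np.ndarray, int, list[str]]:
    """Read an EDF file; returns (data (channels, samples), fs, channel_names)."""
    with open(path, "rb") as fh:
        hdr = fh.read(_HDR_BYTES)
        if len(hdr) < _HDR_BYTES:
            raise ValueError(f"malformed EDF file (truncated header): {path}")
        n_records = int(hdr[236:244].decode().strip())
        rec_dur = float(hdr[244:252].decode().strip())
        ns = int(hdr[252:256].decode().strip())
        sig_hdr = fh.read(_HDR_BYTES * ns)
        if len(sig_hdr) < _HDR_BYTES * ns:
            raise ValueError(f"malformed EDF file (truncated signal header): {path}")

        # fields are stored column-major: all labels, all transducers, ...
        def col(byte_off: int, width: int) -> list[str]:
            return [sig_hdr[byte_off + width * i: byte_off + width * (i + 1)]
                    .decode().strip() for i in range(ns)]

        labels = [lab[4:] if lab.startswith("EEG ") else lab
                  for lab in col(0, 16)]
        base = 16 * ns + 80 * ns + 8 * ns  # after labels/transducers/dims
        pmins = [float(v) for v in col(base, 8)]
        pmaxs = [float(v) for v in col(base + 8 * ns, 8)]
        dmins = [float(v) for v in col(base + 16 * ns, 8)]
        dmaxs = [float(v) for v in col(base + 24 * ns, 8)]
        spr = [int(float(v)) for v in col(base + 32 * ns + 80 * ns, 8)]

        raw = np.frombuffer(fh.read(), dtype="<i2")
        per_rec = sum(spr)
        if raw.size < n_records * per_rec:
            raise ValueError(f"malformed EDF file (truncated data): {path}")
        raw = raw[: n_records * per_rec].reshape(n_records, per_rec)
        data = np.empty((ns, n_records * spr[0]))
        pos = 0
        for i in range(ns):
            sig = raw[:, pos:pos + spr[i]].reshape(-1).astype(float)
            gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
            data[i] = (sig - dmins[i]) * gain + pmins[i]
            pos += spr[i]
        fs = int(round(spr[0] / rec_dur))
        return data, fs, labels


def quantization_step(phys_range: tuple[float, float] = DEFAULT_PHYS_RANGE) -> float:
    return (phys_range[1] - phys_range[0]) / (DIG_MAX - DIG_MIN)
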