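"""Test-local writers for tiny synthetic WFDB fixtures (header, signal,
MIT-format annotation files).  Only what the reader tests need."""

import numpy as np


def write_wfdb(directory, name, adc, fs, lead_names, fmt="16",
               gain=200.0, baseline=0):
    """Write ``name.hea`` + ``name.dat`` for integer ADC samples
    ``adc (n_sig, n_samples)``."""
    adc = np.asarray(adc, dtype=np.int32)
    n_sig, n_samples = adc.shape
    lines = [f"{name} {n_sig} {fs:g} {n_samples}"]
    for ch in range(n_sig):
        lines.append(
            f"{name}.dat {fmt} {gain:g}({baseline})/mV 12 0 "
            f"{adc[ch, 0]} 0 0 {lead_names[ch]}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")

    if fmt == "16":
        data = adc.T.reshape(-1).astype("<i2")
        (directory / f"{name}.dat").write_bytes(data.tobytes())
    elif fmt == "212":
        flat = adc.T.reshape(-1)
        if len(flat) % 2:
            flat = np.append(flat, 0)
        flat = np.where(flat < 0, flat + 4096, flat).astype(np.uint16)
        first, second = flat[0::2], flat[1::2]
        packed = np.empty((len(first), 3), dtype=np.uint8)
        packed[:, 0] = first & 0xFF
        packed[:, 1] = ((first >> 8) & 0x0F) | (((second >> 8) & 0x0F) << 4)
        packed[:, 2] = second & 0xFF
        (directory / f"{name}.dat").write_bytes(packed.tobytes())
    else:
        raise ValueError(fmt)


def write_annotations(path, events):
    """Write a MIT-format annotation file from ``(sample, type_code, aux)``
    tuples (aux may be None); times are encoded as deltas."""
    out = bytearray()
    prev = 0
    for sample, code, aux in events:
        delta = sample - prev
        prev = sample
        if delta > 1023:  # SKIP carries the full 4-byte interval
            out += int.to_bytes(59 << 10, 2, "little")
            out += int.to_bytes((delta >> 16) & 0xFFFF, 2, "little")
            out += int.to_bytes(delta & 0xFFFF, 2, "little")
            delta = 0
        out += int.to_bytes((code << 10) | delta, 2, "little")
        if aux is not None:
            data = aux.encode("ascii")
            out += int.to_bytes((63 << 10) | len(data), 2, "little")
            out += data
            if len(data) % 2:
                out += b"\x00"
    out += b"\x00\x00"
    path.write_bytes(bytes(out))
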