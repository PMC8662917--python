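"""Reader/writer for the non-encrypted binary IDAT scanner format.

One IDAT file holds one sample's single-channel scan: per bead address the
mean intensity, the intensity standard deviation and the number of beads
averaged.  The layout is the documented field-table format: the 4-byte
magic ``IDAT``, a version long, a field count and a table of
``(field code, byte offset)`` entries.  Only the fields needed here are
written (probe count, addresses, SD, mean, bead counts, barcode); unknown
field codes in files from other sources are skipped with a warning.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ChannelScan", "IdatFormatError", "read_idat", "write_idat"]

log = logging.getLogger(__name__)

MAGIC = b"IDAT"
VERSION = 3

# field codes of the standard format
F_N_PROBES = 1000
F_ADDRESS = 102
F_SD = 103
F_MEAN = 104
F_NBEADS = 107
F_BARCODE = 402

_KNOWN = {F_N_PROBES, F_ADDRESS, F_SD, F_MEAN, F_NBEADS, F_BARCODE}


class IdatFormatError(ValueError):
    """Raised when a file is not a readable IDAT."""


@dataclass
class ChannelScan:
    """A single-channel scan: per-address mean/sd/nbeads for one sample."""

    sample_id: str
    channel: str  # "Red" or "Grn"
    data: pd.DataFrame  # index address; columns mean, sd, nbeads

    def __post_init__(self) -> None:
        if self.channel not in ("Red", "Grn"):
            raise ValueError(f"channel must be Red or Grn, got {self.channel!r}")
        if self.data.index.has_duplicates:
            raise ValueError("scan addresses must be unique")
        if (self.data["mean"] < 0).any() or (self.data["sd"] < 0).any():
            raise ValueError("intensities must be non-negative")
        if (self.data["nbeads"] < 0).any():
            raise ValueError("bead counts must be non-negative")

    @property
    def addresses(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=np.int64)


def _read_exact(fh, n: int, what: str) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise IdatFormatError(f"truncated IDAT file while reading {what}")
    return buf


def _read_string(fh) -> str:
    # 7-bit varint length prefix, then UTF-8 bytes
    n, shift = 0, 0
    while True:
        b = _read_exact(fh, 1, "string length")[0]
        n |= (b & 0x7F) << shift
        if not b & 0x80:
            break
        shift += 7
    return _read_exact(fh, n, "string body").decode("utf-8")


def _write_string(fh, s: str) -> None:
    data = s.encode("utf-8")
    n = len(data)
    while True:
        byte = n & 0x7F
        n >>= 7
        if n:
            fh.write(bytes([byte | 0x80]))
        else:
            fh.write(bytes([byte]))
            break
    fh.write(data)


def read_idat(path, sample_id: str | None = None, channel: str = "Grn") -> ChannelScan:
    """Parse an IDAT file into a :class:`ChannelScan`.

    ``sample_id`` defaults to the stored barcode (or the file name when the
    file has no barcode field).
    """
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != MAGIC:
            raise IdatFormatError(f"bad magic {magic!r}; not an IDAT file")
        (version,) = struct.unpack("<q", _read_exact(fh, 8, "version"))
        if version != VERSION:
            raise IdatFormatError(f"unsupported IDAT version {version}")
        (nfields,) = struct.unpack("<i", _read_exact(fh, 4, "field count"))
        offsets: dict[int, int] = {}
        for _ in range(nfields):
            code, offset = struct.unpack("<Hq", _read_exact(fh, 10, "field table"))
            offsets[code] = offset
        unknown = sorted(set(offsets) - _KNOWN)
        if unknown:
            log.warning("skipping unknown IDAT field codes %s in %s", unknown, path)
        for needed, name in [
            (F_N_PROBES, "nProbes"),
            (F_ADDRESS, "IlluminaID"),
            (F_SD, "SD"),
            (F_MEAN, "Mean"),
            (F_NBEADS, "NBeads"),
        ]:
            if needed not in offsets:
                raise IdatFormatError(f"IDAT file lacks required field {name}")

        fh.seek(offsets[F_N_PROBES])
        (n,) = struct.unpack("<i", _read_exact(fh, 4, "nProbes"))

        def _array(code: int, dtype, what: str) -> np.ndarray:
            fh.seek(offsets[code])
            nbytes = n * np.dtype(dtype).itemsize
            return np.frombuffer(_read_exact(fh, nbytes, what), dtype=dtype)

        addresses = _array(F_ADDRESS, "<i4", "IlluminaID")
        sd = _array(F_SD, "<u2", "SD")
        mean = _array(F_MEAN, "<u2", "Mean")
        nbeads = _array(F_NBEADS, "u1", "NBeads")
        barcode = None
        if F_BARCODE in offsets:
            fh.seek(offsets[F_BARCODE])
            barcode = _read_string(fh)

    if sample_id is None:
        sample_id = barcode if barcode else str(path)
    data = pd.DataFrame(
        {
            "mean": mean.astype(np.float64),
            "sd": sd.astype(np.float64),
            "nbeads": nbeads.astype(np.int64),
        },
        index=pd.Index(addresses.astype(np.int64), name="address"),
    )
    return ChannelScan(sample_id=sample_id, channel=channel, data=data)


def write_idat(scan: ChannelScan, path) -> None:
    """Write a scan as an IDAT file.

    Means and SDs are stored as uint16 (rounded; values above 65535 are
    clipped with a warning), bead counts as uint8.
    """
    mean = scan.data["mean"].to_numpy()
    sd = scan.data["sd"].to_numpy()
    if (mean < 0).any() or (sd < 0).any():
        raise ValueError("negative intensity cannot be written")
    if (mean > 65535).any() or (sd > 65535).any():
        log.warning("intensities above 65535 clipped when writing %s", path)
    mean_u = np.clip(np.rint(mean), 0, 65535).astype("<u2")
    sd_u = np.clip(np.rint(sd), 0, 65535).astype("<u2")
    nbeads_u = np.clip(scan.data["nbeads"].to_numpy(), 0, 255).astype("u1")
    addresses = scan.addresses.astype("<i4")
    n = len(addresses)

    payloads = [
        (F_N_PROBES, struct.pack("<i", n)),
        (F_ADDRESS, addresses.tobytes()),
        (F_SD, sd_u.tobytes()),
        (F_MEAN, mean_u.tobytes()),
        (F_NBEADS, nbeads_u.tobytes()),
    ]
    import io as _io

    bc = _io.BytesIO()
    _write_string(bc, scan.sample_id)
    payloads.append((F_BARCODE, bc.getvalue()))

    header_size = 4 + 8 + 4 + 10 * len(payloads)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<q", VERSION))
        fh.write(struct.pack("<i", len(payloads)))
        offset = header_size
        for code, blob in payloads:
            fh.write(struct.pack("<Hq", code, offset))
            offset += len(blob)
        for _, blob in payloads:
            fh.write(blob)
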