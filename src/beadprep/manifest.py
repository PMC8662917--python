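"""Probe manifest model and Illumina-style manifest CSV reading/writing.

A manifest describes every probe on a BeadChip: its Infinium design type
(I or II), the bead address(es) it occupies, the color channel it is read
in (type I only; type II probes are read in both channels at a single
address), and its genomic location.  A ``[Controls]`` section lists
non-genomic control beads (negative controls, paired red/green
normalization controls, bisulfite-conversion controls).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ProbeRecord",
    "ProbeManifest",
    "ManifestFormatError",
    "ProbeRecordError",
    "read_manifest",
    "write_manifest",
]

REQUIRED_COLUMNS = (
    "IlmnID",
    "AddressA_ID",
    "AddressB_ID",
    "Infinium_Design_Type",
    "Color_Channel",
    "CHR",
    "MAPINFO",
)

CONTROL_COLUMNS = ("Address", "Type", "Channel")


class ManifestFormatError(ValueError):
    """The manifest file does not have the expected layout."""


class ProbeRecordError(ValueError):
    """A probe row violates the design-type invariants."""


@dataclass(frozen=True)
class ProbeRecord:
    """One probe: identity, chemistry, addresses and genomic position."""

    probe_id: str
    design_type: str  # "I" or "II"
    color_channel: Optional[str]  # "Red"/"Grn" for type I, None for type II
    address_a: int
    address_b: Optional[int]  # None iff type II
    chrom: str
    position: int  # 1-based (MAPINFO convention)

    def __post_init__(self) -> None:
        if self.design_type not in ("I", "II"):
            raise ProbeRecordError(
                f"probe {self.probe_id}: unknown design type {self.design_type!r}"
            )
        if self.design_type == "II":
            if self.color_channel is not None:
                raise ProbeRecordError(
                    f"probe {self.probe_id}: type II probe must not declare a color channel"
                )
            if self.address_b is not None:
                raise ProbeRecordError(
                    f"probe {self.probe_id}: type II probe must not have AddressB"
                )
        else:
            if self.color_channel not in ("Red", "Grn"):
                raise ProbeRecordError(
                    f"probe {self.probe_id}: type I probe needs color channel Red or Grn"
                )
            if self.address_b is None:
                raise ProbeRecordError(
                    f"probe {self.probe_id}: type I probe is missing AddressB"
                )


@dataclass
class ProbeManifest:
    """Ordered probe records plus control-bead definitions.

    ``controls`` rows are ``(address, control_type, expected_channel)`` with
    channel one of ``Red``, ``Grn`` or ``Both``.
    """

    records: list[ProbeRecord]
    controls: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["address", "control_type", "expected_channel"]
        )
    )

    def __post_init__(self) -> None:
        ids = [r.probe_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ManifestFormatError("duplicate probe ids in manifest")
        addresses: list[int] = []
        for r in self.records:
            addresses.append(r.address_a)
            if r.address_b is not None:
                addresses.append(r.address_b)
        addresses.extend(int(a) for a in self.controls["address"])
        if len(set(addresses)) != len(addresses):
            raise ManifestFormatError("addresses are not unique across probes and controls")

    def __len__(self) -> int:
        return len(self.records)

    @cached_property
    def df(self) -> pd.DataFrame:
        """Probe table with one row per probe, indexed by probe_id."""
        return pd.DataFrame(
            {
                "probe_id": [r.probe_id for r in self.records],
                "design_type": [r.design_type for r in self.records],
                "color_channel": [r.color_channel for r in self.records],
                "address_a": [r.address_a for r in self.records],
                "address_b": [r.address_b for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "position": [r.position for r in self.records],
            }
        ).set_index("probe_id", drop=False)

    @property
    def probe_ids(self) -> list[str]:
        return [r.probe_id for r in self.records]

    def probe_addresses(self) -> np.ndarray:
        """All genomic-probe addresses (A then B for type I)."""
        out: list[int] = []
        for r in self.records:
            out.append(r.address_a)
            if r.address_b is not None:
                out.append(r.address_b)
        return np.asarray(out, dtype=np.int64)

    def all_addresses(self) -> np.ndarray:
        return np.concatenate(
            [self.probe_addresses(), self.controls["address"].to_numpy(dtype=np.int64)]
        ) if len(self.controls) else self.probe_addresses()

    def control_addresses(self, control_type: str) -> np.ndarray:
        sub = self.controls[self.controls["control_type"] == control_type]
        return sub["address"].to_numpy(dtype=np.int64)

    # --- design strata -------------------------------------------------
    def type_i(self, channel: str) -> pd.DataFrame:
        df = self.df
        return df[(df["design_type"] == "I") & (df["color_channel"] == channel)]

    def type_ii(self) -> pd.DataFrame:
        df = self.df
        return df[df["design_type"] == "II"]

    def inband_addresses(self, channel: str) -> np.ndarray:
        """Addresses whose in-band read lives in ``channel``.

        Type I probes contribute both their addresses to their declared
        channel; type II probes contribute their single address to both
        channels (Grn carries meth, Red carries unmeth).
        """
        t1 = self.type_i(channel)
        t2 = self.type_ii()
        return np.concatenate(
            [
                t1["address_a"].to_numpy(dtype=np.int64),
                t1["address_b"].to_numpy(dtype=np.int64),
                t2["address_a"].to_numpy(dtype=np.int64),
            ]
        )

    def oob_addresses(self, channel: str) -> np.ndarray:
        """Addresses that are out-of-band when read in ``channel``.

        These are the addresses of type I probes designed for the *other*
        channel; by construction they carry background only in ``channel``.
        """
        other = "Grn" if channel == "Red" else "Red"
        t1 = self.type_i(other)
        return np.concatenate(
            [t1["address_a"].to_numpy(dtype=np.int64), t1["address_b"].to_numpy(dtype=np.int64)]
        )


def _parse_probe_row(row: pd.Series) -> ProbeRecord:
    design = str(row["Infinium_Design_Type"]).strip()
    cc = row["Color_Channel"]
    cc = None if (pd.isna(cc) or str(cc).strip() in ("", "NA")) else str(cc).strip()
    ab = row["AddressB_ID"]
    if pd.isna(ab) or str(ab).strip() == "":
        ab_val: Optional[int] = None
    else:
        ab_val = int(float(ab))
    if design == "II" and ab_val is not None:
        raise ProbeRecordError(
            f"probe {row['IlmnID']}: type II row has AddressB populated"
        )
    return ProbeRecord(
        probe_id=str(row["IlmnID"]),
        design_type=design,
        color_channel=cc,
        address_a=int(float(row["AddressA_ID"])),
        address_b=ab_val,
        chrom=str(row["CHR"]),
        position=int(float(row["MAPINFO"])),
    )


def read_manifest(path) -> ProbeManifest:
    """Read an Illumina-style manifest CSV with an optional [Controls] section."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if "[Controls]" in text:
        probe_text, control_text = text.split("[Controls]", 1)
    else:
        probe_text, control_text = text, ""
    # tolerate an [Assay] header line as real manifests have
    lines = [ln for ln in probe_text.splitlines() if ln.strip() and ln.strip() != "[Assay]"]
    probes = pd.read_csv(io.StringIO("\n".join(lines)), dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in probes.columns]
    if missing:
        raise ManifestFormatError(f"manifest is missing required columns: {missing}")
    records = [_parse_probe_row(row) for _, row in probes.iterrows()]

    if control_text.strip():
        controls = pd.read_csv(io.StringIO(control_text.strip()), dtype=str)
        missing = [c for c in CONTROL_COLUMNS if c not in controls.columns]
        if missing:
            raise ManifestFormatError(f"[Controls] section missing columns: {missing}")
        controls = pd.DataFrame(
            {
                "address": controls["Address"].astype(int),
                "control_type": controls["Type"].astype(str),
                "expected_channel": controls["Channel"].astype(str),
            }
        )
    else:
        controls = pd.DataFrame(columns=["address", "control_type", "expected_channel"])
    return ProbeManifest(records=records, controls=controls)


def write_manifest(manifest: ProbeManifest, path) -> None:
    """Write a manifest CSV readable back by :func:`read_manifest`."""
    rows = []
    for r in manifest.records:
        rows.append(
            {
                "IlmnID": r.probe_id,
                "AddressA_ID": r.address_a,
                "AddressB_ID": "" if r.address_b is None else r.address_b,
                "Infinium_Design_Type": r.design_type,
                "Color_Channel": "" if r.color_channel is None else r.color_channel,
                "CHR": r.chrom,
                "MAPINFO": r.position,
            }
        )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        pd.DataFrame(rows).to_csv(fh, index=False)
        if len(manifest.controls):
            fh.write("[Controls]\n")
            out = manifest.controls.rename(
                columns={
                    "address": "Address",
                    "control_type": "Type",
                    "expected_channel": "Channel",
                }
            )
            out.to_csv(fh, index=False)
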