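"""Plain-text matrix bundle: the simulator's default on-disk format.

A bundle directory contains ``red.tsv``, ``grn.tsv``, ``nbeads.tsv``
(address x sample, all probe and control addresses as rows),
``controls.tsv`` (control metadata) and ``manifest.csv``.  Floats are
written with 17 significant digits so a reread is bit-exact.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import CT_BISULFITE, CT_NEGATIVE, CT_NORM, RawDataset
from .manifest import ProbeManifest, read_manifest, write_manifest

__all__ = ["write_bundle", "read_bundle"]


def _full_matrix(raw: RawDataset, channel: str) -> pd.DataFrame:
    parts = {
        "Red": (raw.red, raw.negctrl_red, raw.normctrl_red, raw.bisulfite_red),
        "Grn": (raw.grn, raw.negctrl_grn, raw.normctrl_grn, raw.bisulfite_grn),
    }[channel]
    return pd.concat(parts)


def write_bundle(raw: RawDataset, manifest: ProbeManifest, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    for name, df in (
        ("red.tsv", _full_matrix(raw, "Red")),
        ("grn.tsv", _full_matrix(raw, "Grn")),
    ):
        df.index.name = "address"
        df.to_csv(os.path.join(directory, name), sep="\t", float_format="%.17g")
    nb = raw.nbeads.copy()
    nb.index.name = "address"
    nb.to_csv(os.path.join(directory, "nbeads.tsv"), sep="\t")
    ctrl = manifest.controls.copy()
    ctrl.to_csv(os.path.join(directory, "controls.tsv"), sep="\t", index=False)
    write_manifest(manifest, os.path.join(directory, "manifest.csv"))


def read_bundle(directory) -> tuple[RawDataset, ProbeManifest]:
    manifest = read_manifest(os.path.join(directory, "manifest.csv"))
    red = pd.read_csv(os.path.join(directory, "red.tsv"), sep="\t", index_col="address", float_precision="round_trip")
    grn = pd.read_csv(os.path.join(directory, "grn.tsv"), sep="\t", index_col="address", float_precision="round_trip")
    nbeads = pd.read_csv(
        os.path.join(directory, "nbeads.tsv"), sep="\t", index_col="address"
    )
    samples = list(red.columns)
    probe_addr = pd.Index(manifest.probe_addresses(), name="address")
    raw = RawDataset(
        samples=samples,
        red=red.loc[probe_addr],
        grn=grn.loc[probe_addr],
        nbeads=nbeads.loc[probe_addr],
        negctrl_red=red.loc[manifest.control_addresses(CT_NEGATIVE)],
        negctrl_grn=grn.loc[manifest.control_addresses(CT_NEGATIVE)],
        normctrl_red=red.loc[manifest.control_addresses(CT_NORM)],
        normctrl_grn=grn.loc[manifest.control_addresses(CT_NORM)],
        bisulfite_red=red.loc[manifest.control_addresses(CT_BISULFITE)],
        bisulfite_grn=grn.loc[manifest.control_addresses(CT_BISULFITE)],
    )
    return raw, manifest
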