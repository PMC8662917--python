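import numpy as np
import pandas as pd
import pytest

from beadprep.manifest import ProbeManifest, ProbeRecord


@pytest.fixture
def toy_manifest() -> ProbeManifest:
    """Three probes: one type I Red, one type I Grn, one type II; plus controls."""
    records = [
        ProbeRecord("cgA", "I", "Red", 100, 101, "chr1", 1000),
        ProbeRecord("cgB", "I", "Grn", 102, 103, "chr1", 2000),
        ProbeRecord("cgC", "II", None, 104, None, "chr1", 3000),
    ]
    controls = pd.DataFrame(
        {
            "address": list(range(200, 212)) + list(range(300, 312)) + [400, 401],
            "control_type": ["NEGATIVE"] * 12 + ["NORM_PAIRED"] * 12 + ["BISULFITE"] * 2,
            "expected_channel": ["Both"] * 26,
        }
    )
    return ProbeManifest(records=records, controls=controls)


def truncated_normal(rng, mu, sd, size):
    """Reference truncated-at-zero normal sampler for fixtures."""
    x = rng.normal(mu, sd, size)
    while (x < 0).any():
        bad = x < 0
        x[bad] = rng.normal(mu, sd, int(bad.sum()))
    return x
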