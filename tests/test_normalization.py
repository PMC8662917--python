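"""Subset quantile normalization and RCP probe-type calibration."""

import numpy as np
import pandas as pd
import pytest

from beadprep.core import BetaMatrix, MethylDataset, compute_beta, to_methyl
from beadprep.manifest import ProbeManifest, ProbeRecord
from beadprep.normalization import (
    RcpPair,
    apply_rcp,
    find_rcp_pairs,
    fit_rcp,
    quantile_normalize_subsets,
)
from beadprep.simulate import SimConfig, build_manifest, simulate_intensities, simulate_population


def manifest_iiii(n_i=3, n_ii=3):
    """Small manifest with type I Red probes and type II probes only."""
    records = []
    addr = 10
    for j in range(n_i):
        records.append(ProbeRecord(f"i{j}", "I", "Red", addr, addr + 1, "chr1", 100 * (j + 1)))
        addr += 2
    for j in range(n_ii):
        records.append(ProbeRecord(f"ii{j}", "II", None, addr, None, "chr1", 10_000 + 100 * j))
        addr += 1
    return ProbeManifest(records=records)


def methyl_from(manifest, meth, unmeth):
    meth = np.asarray(meth, float)
    return MethylDataset(
        meth, np.asarray(unmeth, float), np.zeros_like(meth, dtype=bool),
        manifest.probe_ids, [f"s{j}" for j in range(meth.shape[1])],
    )


class TestQuantileNormalization:
    def test_hand_example_mean_order_statistics(self):
        man = manifest_iiii(n_i=3, n_ii=2)
        meth = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [5.0, 5.0], [6.0, 6.0]])
        md = methyl_from(man, meth, meth + 1)
        out = quantile_normalize_subsets(md, man)
        # type I subset: samples [1,2,3] and [2,4,6] -> both become [1.5,3,4.5]
        assert np.allclose(out.meth[:3, 0], [1.5, 3.0, 4.5])
        assert np.allclose(out.meth[:3, 1], [1.5, 3.0, 4.5])

    def test_identical_samples_fixed_point(self):
        man = manifest_iiii()
        meth = np.tile(np.array([[5.0], [1.0], [9.0], [2.0], [4.0], [6.0]]), (1, 3))
        md = methyl_from(man, meth, meth)
        out = quantile_normalize_subsets(md, man)
        assert np.allclose(out.meth, meth)

    def test_exact_idempotence(self):
        rng = np.random.default_rng(0)
        man = manifest_iiii(n_i=20, n_ii=30)
        meth = rng.uniform(10, 1000, (50, 4))
        md = methyl_from(man, meth, rng.uniform(10, 1000, (50, 4)))
        once = quantile_normalize_subsets(md, man)
        twice = quantile_normalize_subsets(once, man)
        assert np.array_equal(once.meth, twice.meth)
        assert np.array_equal(once.unmeth, twice.unmeth)

    def test_sorted_columns_identical_within_subsets(self):
        rng = np.random.default_rng(1)
        cfg = SimConfig(n_probes=500, n_samples=3, seed=2)
        man = build_manifest(cfg)
        md = to_methyl(simulate_intensities(simulate_population(cfg), man), man)
        out = quantile_normalize_subsets(md, man)
        df = man.df
        for sel in [
            ((df["design_type"] == "I") & (df["color_channel"] == "Red")).to_numpy(),
            (df["design_type"] == "II").to_numpy(),
        ]:
            srt = np.sort(out.meth[sel], axis=0)
            assert np.allclose(srt, srt[:, [0]])

    def test_subset_isolation(self):
        rng = np.random.default_rng(2)
        man = manifest_iiii(n_i=10, n_ii=10)
        meth = rng.uniform(10, 1000, (20, 3))
        md = methyl_from(man, meth, meth.copy())
        out = quantile_normalize_subsets(md, man)
        # scramble type II inputs; type I outputs must not change
        meth2 = meth.copy()
        meth2[10:] = rng.uniform(10, 1000, (10, 3))
        md2 = methyl_from(man, meth2, meth2.copy())
        out2 = quantile_normalize_subsets(md2, man)
        assert np.allclose(out.meth[:10], out2.meth[:10])


class TestRcpPairs:
    def _man(self, pos_ii, pos_i=(100, 200)):
        records = [
            ProbeRecord(f"i{k}", "I", "Red", 10 + 2 * k, 11 + 2 * k, "chr1", p)
            for k, p in enumerate(pos_i)
        ]
        records.append(ProbeRecord("ii0", "II", None, 50, None, "chr1", pos_ii))
        return ProbeManifest(records=records)

    def test_close_pair_found(self):
        pairs = find_rcp_pairs(self._man(130), max_dist=50)
        assert pairs == [RcpPair("i0", "ii0", 30)]

    def test_distant_probe_not_paired(self):
        assert find_rcp_pairs(self._man(260), max_dist=50) == []

    def test_equidistant_tie_prefers_lower_position(self):
        # type II at 150 sits exactly 25 bp from type I probes at 125 and 175
        pairs = find_rcp_pairs(self._man(150, pos_i=(125, 175)), max_dist=50)
        assert pairs == [RcpPair("i0", "ii0", 25)]


class TestRcpCalibration:
    def _betas(self, seed=0, kappa=0.6, n=30_000):
        cfg = SimConfig(
            n_probes=n, n_samples=2, seed=seed, dye_factor=1.0, dye_log_sd=0.0,
            bg_mu=2.0, bg_sd=0.5, bg_sample_log_sd=0.0, kappa=kappa, kappa_sd=0.0,
        )
        man = build_manifest(cfg)
        raw = simulate_intensities(simulate_population(cfg), man)
        return compute_beta(to_methyl(raw, man), offset=0.0), man

    def test_identity_when_no_compression(self):
        beta, man = self._betas(kappa=1.0)
        calib = fit_rcp(beta, find_rcp_pairs(man))
        for c in calib.values():
            assert abs(c.intercept) < 0.05
            assert abs(c.slope - 1.0) < 0.05

    def test_compression_recovery(self):
        beta, man = self._betas(kappa=0.6)
        calib = fit_rcp(beta, find_rcp_pairs(man))
        for c in calib.values():
            assert c.slope == pytest.approx(1 / 0.6, rel=0.10)

    def test_degenerate_pairs_rejected(self):
        man = manifest_iiii(n_i=60, n_ii=60)
        v = np.full((120, 1), 0.4)
        beta = BetaMatrix(v, man.probe_ids, ["s0"])
        pairs = [RcpPair(f"i{k}", f"ii{k}", 10) for k in range(60)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_rcp(beta, pairs)

    def test_apply_identity_calibration_is_noop(self):
        beta, man = self._betas(kappa=1.0)
        from beadprep.normalization import RcpCalibration

        calib = {s: RcpCalibration(0.0, 1.0, 100) for s in beta.sample_ids}
        out = apply_rcp(beta, calib, man)
        sel = ~np.isnan(beta.values) & (beta.values > 0.01) & (beta.values < 0.99)
        assert np.max(np.abs(out.values[sel] - beta.values[sel])) < 1e-6

    def test_apply_preserves_type_ii_rank_order(self):
        beta, man = self._betas(kappa=0.6, n=5000)
        calib = fit_rcp(beta, find_rcp_pairs(man))
        out = apply_rcp(beta, calib, man)
        sel = (man.df["design_type"] == "II").to_numpy()
        before = beta.values[sel, 0]
        after = out.values[sel, 0]
        order = np.argsort(before)
        assert (np.diff(after[order]) >= 0).all()

    def test_mode_gap_collapse(self):
        from beadprep.evaluation import density_mode

        beta, man = self._betas(kappa=0.6)
        calib = fit_rcp(beta, find_rcp_pairs(man))
        out = apply_rcp(beta, calib, man)
        dt = man.df["design_type"].to_numpy()

        def gaps(b):
            v = b.values[:, 0]
            res = []
            for side in (v < 0.5, v > 0.5):
                m_i = density_mode(v[side & (dt == "I")])
                m_ii = density_mode(v[side & (dt == "II")])
                res.append(abs(m_i - m_ii))
            return res

        pre = gaps(beta)
        post = gaps(out)
        assert all(p > 0.02 for p in pre)
        assert all(q <= 0.2 * p for p, q in zip(pre, post))
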