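from __future__ import annotations

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from netdissim import DistanceMatrix, ModelSpec, deviance_partition, fit_additive_model, gam_mrm
from netdissim.distmat import devectorize_lower_triangle
from netdissim.gammrm import jackknife_by_study
from netdissim.synthdata import injected_boundary_response


def _dm(labels, condensed):
    return DistanceMatrix(tuple(labels), squareform(np.asarray(condensed)))


def _random_distance(rng, labels):
    """Distance matrix from |diff| of random per-network values."""
    v = rng.normal(0, 1, len(labels))
    return DistanceMatrix(tuple(labels), np.abs(v[:, None] - v[None, :]))


def _binary_regions(labels, n_regions, rng):
    regions = rng.integers(0, n_regions, len(labels))
    vals = (regions[:, None] != regions[None, :]).astype(float)
    return DistanceMatrix(tuple(labels), vals, kind="binary")


class TestFitAdditiveModel:
    def test_saturated_parametric(self):
        rng = np.random.default_rng(0)
        ind = (rng.random(500) < 0.4).astype(float)
        spec = ModelSpec(response="y", parametric_terms=("g",), n_perm=0)
        fit = fit_additive_model(pd.DataFrame({"g": ind}), ind, spec)
        assert fit.parametric_stats()["g"][0] == pytest.approx(1.0, abs=1e-8)
        assert fit.deviance_explained == pytest.approx(1.0, abs=1e-8)

    def test_noise_low_deviance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 1200)
        spec = ModelSpec(response="y", smooth_terms=("x",), n_perm=0)
        fit = fit_additive_model(pd.DataFrame({"x": x}), rng.normal(0, 1, 1200), spec)
        assert fit.deviance_explained <= 0.05

    def test_sine_signal_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 4950)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.2, 4950)
        spec = ModelSpec(response="y", smooth_terms=("x",), n_perm=0)
        fit = fit_additive_model(pd.DataFrame({"x": x}), y, spec)
        edf, F = fit.smooth_stats()["x"]
        assert edf > 1.0
        assert fit.deviance_explained > 0.9

    def test_missing_values_rejected(self):
        spec = ModelSpec(response="y", smooth_terms=("x",), n_perm=0)
        with pytest.raises(ValueError, match="missing"):
            fit_additive_model(
                pd.DataFrame({"x": [0.0, np.nan, 1.0, 2.0]}),
                np.zeros(4),
                spec,
            )

    def test_matches_mgcv_reference(self, tmp_path):
        """Independent oracle: mgcv's Gaussian REML GAM on the same data."""
        rng = np.random.default_rng(8)
        n = 800
        x = rng.uniform(0, 1, n)
        ind = (rng.random(n) < 0.5).astype(float)
        y = 0.6 + 0.25 * np.sin(2 * np.pi * x) - 0.07 * ind + rng.normal(0, 0.05, n)
        spec = ModelSpec(response="y", parametric_terms=("ind",), smooth_terms=("x",), n_perm=0)
        fit = fit_additive_model(pd.DataFrame({"ind": ind, "x": x}), y, spec)
        csv = tmp_path / "dat.csv"
        pd.DataFrame({"y": y, "x": x, "ind": ind}).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(mgcv))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- gam(y ~ ind + s(x, k=10, bs='tp'), data=d, method='REML')\n"
            "s <- summary(m)\n"
            "cat(coef(m)['ind'], s$p.t['ind'], s$edf, s$dev.expl)\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        est_r, t_r, edf_r, dev_r = (float(v) for v in out.stdout.split())
        est, t = fit.parametric_stats()["ind"]
        edf, _ = fit.smooth_stats()["x"]
        assert est == pytest.approx(est_r, abs=5e-3)
        assert t == pytest.approx(t_r, rel=0.02)
        assert edf == pytest.approx(edf_r, abs=0.5)
        assert fit.deviance_explained == pytest.approx(dev_r, abs=0.01)


class TestGamMrm:
    def _labels(self, n):
        return [f"n{i:02d}" for i in range(n)]

    def test_identity_permutation_reproduces_observed(self):
        rng = np.random.default_rng(3)
        labels = self._labels(12)
        eco = _binary_regions(labels, 3, rng)
        spat = _random_distance(rng, labels)
        resp = injected_boundary_response(eco, spat, rng=rng)
        spec = ModelSpec(response="y", parametric_terms=("eco",), smooth_terms=("spat",), n_perm=0, seed=5)
        res1 = gam_mrm({"y": resp, "eco": eco, "spat": spat}, spec)
        res2 = gam_mrm({"y": resp, "eco": eco, "spat": spat}, spec)
        assert res1 == res2  # deterministic, bit-for-bit

    def test_seed_reproducibility_with_permutations(self):
        rng = np.random.default_rng(4)
        labels = self._labels(10)
        eco = _binary_regions(labels, 3, rng)
        spat = _random_distance(rng, labels)
        resp = injected_boundary_response(eco, spat, rng=rng)
        spec = ModelSpec(response="y", parametric_terms=("eco",), smooth_terms=("spat",), n_perm=49, seed=9)
        r1 = gam_mrm({"y": resp, "eco": eco, "spat": spat}, spec)
        r2 = gam_mrm({"y": resp, "eco": eco, "spat": spat}, spec)
        assert r1 == r2

    def test_thread_count_invariance(self):
        rng = np.random.default_rng(12)
        labels = self._labels(10)
        eco = _binary_regions(labels, 3, rng)
        spat = _random_distance(rng, labels)
        resp = injected_boundary_response(eco, spat, rng=rng)
        spec = ModelSpec(response="y", parametric_terms=("eco",), smooth_terms=("spat",), n_perm=29, seed=2)
        r1 = gam_mrm({"y": resp, "eco": eco, "spat": spat}, spec, threads=1)
        r2 = gam_mrm({"y": resp, "eco": eco, "spat": spat}, spec, threads=3)
        assert r1 == r2

    def test_joint_relabeling_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(5)
        labels = self._labels(14)
        eco = _binary_regions(labels, 4, rng)
        spat = _random_distance(rng, labels)
        resp = injected_boundary_response(eco, spat, rng=rng)
        spec = ModelSpec(response="y", parametric_terms=("eco",), smooth_terms=("spat",), n_perm=0)
        base = gam_mrm({"y": resp, "eco": eco, "spat": spat}, spec)
        perm = rng.permutation(len(labels))

        def permuted(dm):
            return DistanceMatrix(
                dm.labels, dm.values[np.ix_(perm, perm)], kind=dm.kind
            )

        shuf = gam_mrm(
            {"y": permuted(resp), "eco": permuted(eco), "spat": permuted(spat)}, spec
        )
        t1 = base.term("eco")
        t2 = shuf.term("eco")
        assert t1.estimate == pytest.approx(t2.estimate, abs=1e-8)
        assert t1.t == pytest.approx(t2.t, rel=1e-6)
        assert base.term("spat").F == pytest.approx(shuf.term("spat").F, rel=1e-6)

    def test_response_equal_to_smooth_predictor_hits_p_floor(self):
        rng = np.random.default_rng(6)
        labels = self._labels(12)
        spat = _random_distance(rng, labels)
        eco = _binary_regions(labels, 3, rng)
        spec = ModelSpec(response="y", parametric_terms=("eco",), smooth_terms=("spat",), n_perm=99, seed=1)
        res = gam_mrm({"y": spat, "eco": eco, "spat": spat}, spec)
        assert res.term("spat").p_perm == pytest.approx(1 / 100)

    def test_too_few_networks_rejected(self):
        rng = np.random.default_rng(7)
        labels = self._labels(3)
        spat = _random_distance(rng, labels)
        spec = ModelSpec(response="y", smooth_terms=("spat",), n_perm=0)
        with pytest.raises(ValueError, match="4 networks"):
            gam_mrm({"y": spat, "spat": spat}, spec)

    def test_unaligned_matrices_rejected(self):
        rng = np.random.default_rng(8)
        spat = _random_distance(rng, self._labels(6))
        other = _random_distance(rng, [f"m{i}" for i in range(6)])
        spec = ModelSpec(response="y", smooth_terms=("spat",), n_perm=0)
        with pytest.raises(ValueError, match="aligned"):
            gam_mrm({"y": other, "spat": spat}, spec)

    def test_boundary_effect_recovered_single_dataset(self):
        rng = np.random.default_rng(9)
        labels = self._labels(60)
        eco = _binary_regions(labels, 8, rng)
        spat = _random_distance(rng, labels)
        resp = injected_boundary_response(eco, spat, effect=-0.07, noise_sd=0.05, rng=rng)
        spec = ModelSpec(
            response="y", parametric_terms=("eco",), smooth_terms=("spat",), n_perm=99, seed=3
        )
        res = gam_mrm({"y": resp, "eco": eco, "spat": spat}, spec)
        tr = res.term("eco")
        assert tr.estimate == pytest.approx(-0.07, abs=0.02)
        assert tr.p_perm < 0.05


class TestDeviancePartition:
    def _setup(self, rng, n=40):
        labels = [f"n{i:02d}" for i in range(n)]
        order = sorted(labels)
        n_pairs = n * (n - 1) // 2
        # iid pair-level predictors: independent by construction
        x1 = devectorize_lower_triangle(np.abs(rng.normal(0, 1, n_pairs)), order)
        x2 = devectorize_lower_triangle(np.abs(rng.normal(0, 1, n_pairs)), order)
        iu = np.triu_indices(n, k=1)
        y1 = x1.reindex(order).values[iu]
        y2 = x2.reindex(order).values[iu]
        # high intercept: the nonnegativity clip must never bind; modest
        # effects keep the chance-correlation amplification of the shared
        # component small
        y = 1.5 + 0.05 * y1 + 0.05 * y2 + rng.normal(0, 0.1, y1.size)
        resp = devectorize_lower_triangle(np.clip(y, 0, None), order)
        return {"y": resp, "x1": x1, "x2": x2}

    def test_single_variable_unique_component(self):
        rng = np.random.default_rng(10)
        data = self._setup(rng)
        spec = ModelSpec(response="y", smooth_terms=("x1", "x2"), n_perm=0)
        part = deviance_partition(data, spec, ["x1"])
        full = part.full_deviance_explained
        # unique component = full - reduced, by definition
        assert part.component("x1") == pytest.approx(part.attributable, abs=1e-12)

    def test_components_sum_to_attributable(self):
        rng = np.random.default_rng(11)
        data = self._setup(rng)
        spec = ModelSpec(response="y", smooth_terms=("x1", "x2"), n_perm=0)
        part = deviance_partition(data, spec, ["x1", "x2"])
        total = sum(part.components.values())
        assert total == pytest.approx(part.attributable, abs=1e-6)

    def test_orthogonal_predictors_share_nothing(self):
        rng = np.random.default_rng(12)
        data = self._setup(rng, n=100)
        spec = ModelSpec(response="y", smooth_terms=("x1", "x2"), n_perm=0)
        part = deviance_partition(data, spec, ["x1", "x2"])
        assert abs(part.component("x1", "x2")) < 0.01

    def test_guard_on_variable_count(self):
        rng = np.random.default_rng(13)
        data = self._setup(rng, n=10)
        spec = ModelSpec(response="y", smooth_terms=("x1", "x2"), n_perm=0)
        with pytest.raises(ValueError, match="variables of interest"):
            deviance_partition(data, spec, ["x1", "x2"], max_variables=1)


class TestJackknife:
    def test_one_row_per_study(self, small_dataset):
        from netdissim.distmat import build_predictor_matrices
        from netdissim.pipeline import build_responses

        nets, meta = list(small_dataset.networks), small_dataset.metadata

        def rebuild(sub_nets, sub_meta):
            return {
                **build_predictor_matrices(sub_meta, include=("ecoregion", "spatial")),
                **{"beta_wn": __import__("netdissim").pairwise_beta(sub_nets, "interaction")},
            }

        spec = ModelSpec(
            response="beta_wn", parametric_terms=("ecoregion",), smooth_terms=("spatial",), n_perm=0
        )
        jk = jackknife_by_study(nets, meta, rebuild, spec)
        assert len(jk) == meta["study_id"].nunique()
        assert not jk["skipped"].any()
        assert "t_ecoregion" in jk.columns and "F_spatial" in jk.columns

    def test_influential_study_detected(self):
        """A study that carries all the boundary signal shows the largest
        drop in |t| when left out."""
        rng = np.random.default_rng(14)
        n = 30
        labels = [f"n{i:02d}" for i in range(n)]
        meta = pd.DataFrame(
            {
                "network_id": labels,
                # study S0 holds the first 10 networks
                "study_id": ["S0"] * 10 + ["S1"] * 10 + ["S2"] * 10,
            }
        )
        # S0 is region-dense (many same-region pairs, i.e. most of the
        # boundary information); S1/S2 contribute only one same-pair each
        regions = np.concatenate(
            [np.repeat([0, 1], 5), [2, 2, 3, 4, 5, 6, 7, 8, 9, 10],
             [11, 11, 12, 13, 14, 15, 16, 17, 18, 19]]
        )
        eco = DistanceMatrix(
            tuple(labels), (regions[:, None] != regions[None, :]).astype(float), kind="binary"
        )
        spat = _random_distance(rng, labels)
        resp = injected_boundary_response(eco, spat, effect=-0.2, noise_sd=0.05, rng=rng)

        def rebuild(sub_nets, sub_meta):
            ids = list(sub_meta["network_id"])
            return {
                "y": resp.reindex(ids),
                "eco": eco.reindex(ids),
                "spat": spat.reindex(ids),
            }

        class FakeNet:
            def __init__(self, nid):
                self.network_id = nid

        spec = ModelSpec(response="y", parametric_terms=("eco",), smooth_terms=("spat",), n_perm=0)
        jk = jackknife_by_study([FakeNet(l) for l in labels], meta, rebuild, spec)
        jk = jk.set_index("study_id")
        # only S0 contains same-region pairs carrying the effect
        assert abs(jk.loc["S0", "t_eco"]) == min(abs(jk["t_eco"]))
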