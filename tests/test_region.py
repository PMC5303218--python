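"""Sliding-window construction and first-principal-component summaries."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from famassoc.phenotype import PhenotypeTable
from famassoc.region import build_windows, run_region_scan, summarize_window
from famassoc.vc import AssocOptions, run_association_scan


def _map(names, chroms, positions):
    return pd.DataFrame(
        {"chrom": chroms, "position": positions}, index=pd.Index(names, name="name")
    )


class TestBuildWindows:
    def test_exact_tiling_in_predictor_units(self):
        m = _map([f"p{k}" for k in range(10)], ["1"] * 10, range(100, 1100, 100))
        windows = build_windows(m, size=5, unit="predictors", step=5)
        assert len(windows) == 2
        assert windows[0].predictor_ids == [f"p{k}" for k in range(5)]
        assert windows[1].predictor_ids == [f"p{k}" for k in range(5, 10)]

    def test_size_one_gives_one_window_per_predictor(self):
        m = _map(["a", "b", "c"], ["1"] * 3, [10, 20, 30])
        windows = build_windows(m, size=1, unit="predictors", step=1)
        assert [w.predictor_ids for w in windows] == [["a"], ["b"], ["c"]]

    def test_base_pair_windows_match_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        positions = np.sort(rng.choice(np.arange(1, 101), size=40, replace=False))
        names = [f"p{k}" for k in range(40)]
        m = _map(names, ["1"] * 40, positions)
        size, step = 30, 10
        windows = build_windows(m, size=size, unit="bases", step=step)
        # brute force: check every start offset and every position by hand
        expected = []
        for s in range(int(positions[0]), int(positions[-1]) + 1, step):
            members = [n for n, p in zip(names, positions) if s <= p < s + size]
            if members:
                expected.append(members)
            if s + step > positions[-1]:
                break
        assert [w.predictor_ids for w in windows] == expected

    def test_windows_never_span_chromosomes(self):
        m = _map(["a", "b", "c", "d"], ["1", "1", "2", "2"], [10, 20, 10, 20])
        windows = build_windows(m, size=4, unit="predictors", step=1)
        for w in windows:
            assert len({w.chrom}) == 1
        assert {tuple(w.predictor_ids) for w in windows} >= {("a", "b"), ("c", "d")}

    def test_unsorted_map_instructs_to_sort(self):
        m = _map(["a", "b"], ["1", "1"], [20, 10])
        with pytest.raises(ValueError, match="sort"):
            build_windows(m, size=2)

    def test_degenerate_sizes_rejected(self):
        m = _map(["a"], ["1"], [1])
        with pytest.raises(ValueError):
            build_windows(m, size=0)
        with pytest.raises(ValueError):
            build_windows(m, size=2, step=0)


class TestSummarizeWindow:
    def test_single_member_is_its_standardized_self(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame({"a": rng.standard_normal(30)})
        scores, varexp = summarize_window(vals)
        assert varexp == pytest.approx(1.0, abs=1e-12)
        z = (vals["a"] - vals["a"].mean()) / vals["a"].std(ddof=1)
        agreement = abs(np.corrcoef(scores, z)[0, 1])
        assert agreement == pytest.approx(1.0, abs=1e-12)

    def test_perfectly_correlated_members_are_rank_one(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(25)
        vals = pd.DataFrame({"a": a, "b": 3.0 * a - 1.0})
        _scores, varexp = summarize_window(vals)
        assert varexp == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.standard_normal((50, 5)),
                            columns=list("abcde"))
        scores, varexp = summarize_window(vals)
        Z = (vals - vals.mean()) / vals.std(ddof=1)
        corr = np.corrcoef(Z.to_numpy(), rowvar=False)
        w, v = np.linalg.eigh(corr)
        assert varexp == pytest.approx(w[-1] / 5, abs=1e-8)
        oracle = Z.to_numpy() @ v[:, -1]
        oracle /= oracle.std(ddof=1)
        # unit-variance (ddof=1) series: |cross product / (n-1)| -> 1 iff
        # equal up to sign
        agreement = abs(float(np.dot(scores, oracle)) / (len(scores) - 1))
        assert agreement == pytest.approx(1.0, abs=1e-8)

    def test_member_order_does_not_change_the_summary(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("abcd"))
        s1, v1 = summarize_window(vals)
        s2, v2 = summarize_window(vals[["d", "b", "a", "c"]])
        assert v1 == pytest.approx(v2, abs=1e-12)
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_zero_variance_member_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame({"a": rng.standard_normal(20), "flat": 1.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            _scores, varexp = summarize_window(vals)
        assert varexp == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError, match="zero variance"), pytest.warns(UserWarning):
            summarize_window(pd.DataFrame({"flat": np.ones(20)}))

    def test_variance_explained_dilutes_with_independent_noise(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(60)
        cols = {f"m{k}": base + 0.3 * rng.standard_normal(60) for k in range(3)}
        vals = pd.DataFrame(cols)
        _s, before = summarize_window(vals)
        worse = 0
        for draw in range(20):
            vals2 = vals.copy()
            vals2["noise"] = rng.standard_normal(60)
            _s2, after = summarize_window(vals2)
            worse += after <= before + 1e-8
        assert worse == 20


class TestRegionScan:
    def test_size_one_window_reproduces_single_predictor_p(self, small_families):
        ped, rel, responses, predictors = small_families
        names = predictors.variables
        m = _map(names, ["1"] * len(names), range(1000, 1000 * (len(names) + 1), 1000))
        opts = AssocOptions(family_diagnostics=False)
        single = run_association_scan(responses, predictors, rel, options=opts)
        region, windows = run_region_scan(
            responses, predictors, m, rel, size=1, unit="predictors", step=1,
            options=opts,
        )
        assert len(region) == len(single)
        for w, rres in zip(windows, region):
            sres = next(r for r in single if r.predictor == w.predictor_ids[0])
            assert rres.p == pytest.approx(sres.p, abs=1e-10)
            assert rres.lrt == pytest.approx(sres.lrt, abs=1e-8)

    def test_window_positions_flow_into_results(self, small_families):
        ped, rel, responses, predictors = small_families
        names = predictors.variables
        m = _map(names, ["1"] * len(names), [100, 200, 300])
        region, windows = run_region_scan(
            responses, predictors, m, rel, size=3, unit="predictors", step=3,
            options=AssocOptions(family_diagnostics=False),
        )
        assert len(region) == 1
        assert region[0].chrom == "1"
        assert region[0].position == (100 + 300) // 2
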