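"""Association scan, clumping, loci, expected chi-square, residualization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regle.assoc import (
    Locus,
    association_scan,
    clump_hits,
    define_loci,
    expected_chi2,
    genomic_inflation,
    hwe_chi2,
    match_known_loci,
    residualize,
    variant_qc,
)
from regle.core import GenotypePanel
from regle.synthgen import SimConfig, simulate_genotypes


def _panel(dosages, chrom=None, pos=None, freq=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "chromosome": chrom if chrom is not None else np.ones(m, int),
            "position": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "frequency": freq if freq is not None else dosages.mean(axis=0) / 2,
            "info": 1.0,
            "missing_rate": 0.0,
        }
    )
    return GenotypePanel(dosages=dosages, variants=variants)


class TestVariantQC:
    def test_hwe_chi2_hand_computation(self):
        # counts (60, 20, 20) at n=100: p_alt = 0.3, expected (49, 42, 9)
        chi2, p = hwe_chi2(60, 20, 20)
        expected = (60 - 49) ** 2 / 49 + (20 - 42) ** 2 / 42 + (20 - 9) ** 2 / 9
        assert chi2 == pytest.approx(expected, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(expected, 1))

    def test_low_maf_removed(self, rng):
        dosages = rng.integers(0, 3, size=(50, 2)).astype(float)
        panel = _panel(dosages, freq=np.array([0.0005, 0.3]))
        kept, report = variant_qc(panel)
        assert list(kept.variants["id"]) == ["v1"]
        assert not report.loc[0, "pass_maf"]

    def test_hwe_variant_retained(self, rng):
        cfg = SimConfig(n_individuals=2000, n_variants=5, causal_per_factor=1, seed=3)
        panel = simulate_genotypes(cfg)
        kept, report = variant_qc(panel)
        assert report["pass_hwe"].all()
        assert kept.M == 5

    def test_extreme_hwe_violation_removed(self):
        # all hets is a gross HWE violation at large n
        dosages = np.ones((3000, 1))
        panel = _panel(dosages, freq=np.array([0.5]))
        kept, report = variant_qc(panel)
        assert kept.M == 0 and not report.loc[0, "pass_hwe"]

    def test_missing_metadata_column_named(self):
        panel = _panel(np.zeros((5, 2)) + 1.0)
        panel.variants = panel.variants.drop(columns=["info"])
        with pytest.raises(ValueError, match="info"):
            variant_qc(panel)


class TestAssociationScan:
    def test_matches_closed_form_ols(self, rng):
        # oracle: explicit normal-equations solve per variant on 50 x 20
        n, m = 50, 20
        dosages = rng.integers(0, 3, size=(n, m)).astype(float)
        panel = _panel(dosages)
        y = rng.standard_normal(n)
        cov = pd.DataFrame({"age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n)})
        res = association_scan(panel, y, cov, standardize=False)
        X0 = np.column_stack([np.ones(n), cov.to_numpy()])
        for j in range(m):
            X = np.column_stack([X0, dosages[:, j]])
            coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            sigma2 = (resid @ resid) / (n - X.shape[1])
            cov_beta = sigma2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(cov_beta[-1, -1])
            assert res.loc[j, "BETA"] == pytest.approx(coef[-1], abs=1e-8)
            assert res.loc[j, "SE"] == pytest.approx(se, abs=1e-8)

    def test_noiseless_recovery_caps_chi2(self, rng):
        dosages = rng.integers(0, 3, size=(100, 3)).astype(float)
        panel = _panel(dosages)
        y = 0.5 * dosages[:, 1]
        res = association_scan(panel, y, standardize=False)
        assert res.loc[1, "BETA"] == pytest.approx(0.5, abs=1e-8)
        assert res.loc[1, "CHI2"] == 1e8 and res.loc[1, "P"] == 0.0

    def test_null_type_one_error(self, rng):
        cfg = SimConfig(n_individuals=500, n_variants=2000, ld_block_size=1,
                        causal_per_factor=1, seed=10)
        panel = simulate_genotypes(cfg)
        y = rng.standard_normal(500)
        res = association_scan(panel, y)
        frac = float((res["P"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_chi2_p_consistency(self, rng):
        dosages = rng.integers(0, 3, size=(80, 10)).astype(float)
        res = association_scan(_panel(dosages), rng.standard_normal(80))
        assert np.allclose(res["CHI2"], (res["BETA"] / res["SE"]) ** 2, atol=1e-6)
        assert np.allclose(res["P"], stats.chi2.sf(res["CHI2"], 1))

    def test_collinear_covariates_rejected(self, rng):
        dosages = rng.integers(0, 3, size=(30, 2)).astype(float)
        cov = pd.DataFrame({"a": np.ones(30), "b": 2 * np.ones(30)})
        with pytest.raises(ValueError, match="rank-deficient"):
            association_scan(_panel(dosages), rng.standard_normal(30), cov)


class TestClump:
    def _results(self, panel, p_values):
        return pd.DataFrame(
            {
                "CHR": panel.variants["chromosome"],
                "POS": panel.variants["position"],
                "ID": panel.variants["id"],
                "REF": "A",
                "ALT": "G",
                "BETA": 0.1,
                "SE": 0.01,
                "CHI2": 100.0,
                "P": p_values,
            }
        )

    def test_perfectly_correlated_pair_yields_one_hit(self, rng):
        g = rng.integers(0, 3, size=(200, 1)).astype(float)
        panel = _panel(np.hstack([g, g]))
        res = self._results(panel, [1e-10, 1e-9])
        hits = clump_hits(res, panel)
        assert len(hits) == 1 and hits.loc[0, "ID"] == "v0"

    def test_no_significant_variants_empty(self, rng):
        panel = _panel(rng.integers(0, 3, size=(50, 5)).astype(float))
        hits = clump_hits(self._results(panel, [1e-3] * 5), panel)
        assert len(hits) == 0

    def test_matches_exhaustive_greedy_oracle(self, rng):
        cfg = SimConfig(n_individuals=400, n_variants=50, ld_block_size=5,
                        ld_rho=0.6, causal_per_factor=1, seed=17)
        panel = simulate_genotypes(cfg)
        p_values = 10.0 ** rng.uniform(-12, -2, 50)
        res = self._results(panel, p_values)
        hits = clump_hits(res, panel, p_thresh=5e-8, r2_thresh=0.1)

        # independent greedy re-implementation with explicit sorting
        order = sorted(range(50), key=lambda j: (p_values[j],
                                                 panel.variants.loc[j, "chromosome"],
                                                 panel.variants.loc[j, "position"]))
        alive = set(range(50))
        expected = []
        corr = np.corrcoef(panel.dosages.T) ** 2
        for j in order:
            if j not in alive or p_values[j] > 5e-8:
                continue
            expected.append(panel.variants.loc[j, "id"])
            alive.discard(j)
            for k in list(alive):
                same = panel.variants.loc[k, "chromosome"] == panel.variants.loc[j, "chromosome"]
                if same and corr[j, k] >= 0.1:
                    alive.discard(k)
        assert list(hits["ID"]) == expected

    def test_invariant_to_variant_ordering(self, rng):
        cfg = SimConfig(n_individuals=300, n_variants=30, ld_block_size=3,
                        ld_rho=0.5, causal_per_factor=1, seed=23)
        panel = simulate_genotypes(cfg)
        p_values = 10.0 ** rng.uniform(-12, -6, 30)
        res = self._results(panel, p_values)
        shuffled = res.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = clump_hits(res, panel)
        b = clump_hits(shuffled, panel)
        assert list(a["ID"]) == list(b["ID"])


class TestLoci:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["CHR", "POS", "ID", "P"]).assign(
            REF="A", ALT="G", BETA=0.1, SE=0.01, CHI2=50.0
        )

    def test_nearby_loci_merged(self, rng):
        # two hits with LD spans separated by a 200-kb gap merge into one
        g = rng.integers(0, 3, size=(100, 2)).astype(float)
        panel = _panel(g, pos=[1_000_000, 1_204_000])
        hits = self._hits([(1, 1_000_000, "v0", 1e-10), (1, 1_204_000, "v1", 1e-9)])
        loci = define_loci(hits, panel, merge_dist=250_000)
        assert len(loci) == 1
        assert loci[0].start == 1_000_000 and loci[0].end == 1_204_000
        assert loci[0].lead_id == "v0"

    def test_isolated_hit_point_locus(self, rng):
        g = rng.integers(0, 3, size=(200, 3)).astype(float)
        panel = _panel(g, pos=[1000, 500_000, 900_000])
        hits = self._hits([(1, 500_000, "v1", 1e-12)])
        loci = define_loci(hits, panel)
        assert len(loci) == 1
        # independent dosage columns: span collapses to the hit position
        assert loci[0].start == loci[0].end == 500_000

    def test_merging_matches_union_find_oracle(self, rng):
        # 20 random intervals on one chromosome; oracle: connected
        # components of the "gap < merge_dist" graph via union-find
        starts = rng.integers(0, 5_000_000, 20)
        widths = rng.integers(1, 200_000, 20)
        hits = self._hits(
            [(1, int(s), f"v{i}", 1e-9) for i, s in enumerate(starts)]
        )
        # independent dosages at n=800: no LD partners, so spans are points
        panel = _panel(
            rng.integers(0, 3, size=(800, 20)).astype(float), pos=starts
        )
        loci = define_loci(hits, panel, merge_dist=300_000)

        intervals = [(int(s), int(s)) for s in starts]
        parent = list(range(20))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(20):
            for j in range(i + 1, 20):
                lo = max(intervals[i][0], intervals[j][0])
                hi = min(intervals[i][1], intervals[j][1])
                gap = lo - hi
                if gap < 300_000:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(20)})
        assert len(loci) == n_components

    def test_hit_absent_from_panel_warns_point_locus(self, rng):
        panel = _panel(rng.integers(0, 3, size=(50, 1)).astype(float), pos=[100])
        hits = self._hits([(2, 999, "missing", 1e-9)])
        with pytest.warns(UserWarning):
            loci = define_loci(hits, panel)
        assert loci[0].start == loci[0].end == 999


class TestExpectedChi2:
    def _scan_frame(self, chi2):
        m = len(chi2)
        return pd.DataFrame(
            {
                "CHR": 1, "POS": np.arange(m), "ID": [f"v{j}" for j in range(m)],
                "REF": "A", "ALT": "G", "BETA": 0.0, "SE": 1.0,
                "CHI2": chi2, "P": stats.chi2.sf(chi2, 1),
            }
        )

    def test_single_coordinate_is_mean_chi2(self, rng):
        chi2 = rng.chisquare(1, 100)
        mean, df = expected_chi2([self._scan_frame(chi2)])
        assert mean == pytest.approx(chi2.mean()) and df == 1

    def test_sum_then_average_arithmetic(self):
        a = self._scan_frame(np.array([1.0, 2.0, 3.0]))
        b = self._scan_frame(np.array([0.5, 0.5, 0.5]))
        mean, df = expected_chi2([a, b])
        assert mean == pytest.approx(np.mean([1.5, 2.5, 3.5])) and df == 2

    def test_subset_restriction(self):
        a = self._scan_frame(np.array([1.0, 10.0, 3.0]))
        mean, _ = expected_chi2([a], subset=["v1"])
        assert mean == 10.0

    def test_mismatched_variants_error(self):
        a = self._scan_frame(np.ones(3))
        b = self._scan_frame(np.ones(4))
        with pytest.raises(ValueError):
            expected_chi2([a, b])


class TestResidualize:
    def test_self_prediction_zero_residuals(self, rng):
        y = rng.standard_normal(30)
        res = residualize(y, pd.DataFrame({"y": y}))
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_no_predictors_centers(self, rng):
        y = rng.standard_normal(40) + 5.0
        assert np.allclose(residualize(y, None), y - y.mean())

    def test_matches_hat_matrix_oracle(self, rng):
        # oracle: explicit projection I - X (X'X)^-1 X' on a 20 x 3 instance
        y = rng.standard_normal(20)
        pred = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        X = np.column_stack([np.ones(20), pred.to_numpy()])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        assert np.allclose(residualize(y, pred), (np.eye(20) - H) @ y, atol=1e-10)

    def test_orthogonal_to_predictors(self, rng):
        y = rng.standard_normal(50)
        pred = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        res = residualize(y, pred)
        centered = pred.to_numpy() - pred.to_numpy().mean(axis=0)
        assert np.all(np.abs(centered.T @ res) < 1e-8)


class TestKnownLoci:
    def _loci(self, spans):
        return [Locus(c, s, e, f"l{i}", 1e-9, [f"l{i}"])
                for i, (c, s, e) in enumerate(spans)]

    def test_empty_catalog_all_unknown(self):
        catalog = pd.DataFrame(columns=["chromosome", "start", "end"])
        table, counts = match_known_loci(self._loci([(1, 10, 20)]), catalog)
        assert counts["n_known"] == 0 and counts["n_unknown"] == 1

    def test_self_catalog_all_known(self):
        loci = self._loci([(1, 10, 20), (2, 5, 8)])
        catalog = pd.DataFrame(
            {"chromosome": [1, 2], "start": [10, 5], "end": [20, 8]}
        )
        _, counts = match_known_loci(loci, catalog)
        assert counts["n_known"] == 2 and counts["pct_known"] == 100.0

    def test_matches_all_pairs_oracle(self, rng):
        spans = [(int(rng.integers(1, 3)), int(s), int(s + rng.integers(1, 5000)))
                 for s in rng.integers(0, 100_000, 30)]
        loci = self._loci(spans)
        catalog = pd.DataFrame(
            {
                "chromosome": rng.integers(1, 3, 10),
                "start": rng.integers(0, 100_000, 10),
            }
        )
        catalog["end"] = catalog["start"] + rng.integers(1, 8000, 10)
        table, _ = match_known_loci(loci, catalog)
        for i, (c, s, e) in enumerate(spans):
            overlap = any(
                (row.chromosome == c and row.start <= e and row.end >= s)
                for row in catalog.itertuples()
            )
            assert table.loc[i, "known"] == overlap

    def test_malformed_catalog_rejected(self):
        catalog = pd.DataFrame({"chromosome": [1], "start": [10], "end": [5]})
        with pytest.raises(ValueError):
            match_known_loci(self._loci([(1, 1, 2)]), catalog)


def test_genomic_inflation_null_near_one(rng):
    chi2 = rng.chisquare(1, 50_000)
    assert genomic_inflation(chi2) == pytest.approx(1.0, abs=0.03)
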