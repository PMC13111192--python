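"""Group contrast with permutation cluster FWE, and cognition correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from cascnet.sim import SimConfig, generate_cohort, make_synthetic_atlas, \
    rasterize_to_maps
from cascnet.vbm import correlate_cognition, group_contrast


def _cohort_maps(seed, deficit=0.0, grid=(10, 10, 10), n_rois=4,
                 n_patients=15, n_controls=15):
    names = tuple(f"R{i}" for i in range(n_rois))
    config = SimConfig(
        n_patients=n_patients,
        n_controls=n_controls,
        roi_names=names,
        noise_sd=0.3,
        group_deficit={"R0": deficit} if deficit else {},
        rng_seed=seed,
    )
    records, table = generate_cohort(config)
    atlas = make_synthetic_atlas(grid, n_rois, rng_seed=seed, roi_names=list(names))
    maps = rasterize_to_maps(table, atlas, voxel_noise_sd=0.05, rng_seed=seed + 1)
    pmaps = {r.subject_id: maps[r.subject_id] for r in records if r.group == "patient"}
    cmaps = {r.subject_id: maps[r.subject_id] for r in records if r.group == "control"}
    cov = pd.DataFrame.from_dict(
        {
            r.subject_id: {
                "sex": 1.0 if r.sex == "M" else 0.0,
                "age": r.age,
                "education": r.education,
                "tiv": r.tiv,
                "months_post_rt": r.months_post_rt or 0.0,
            }
            for r in records
        },
        orient="index",
    )
    return pmaps, cmaps, cov, atlas


class TestGroupContrast:
    def test_planted_deficit_is_peak_cluster(self):
        hits = 0
        n_rep = 12
        for s in range(n_rep):
            pmaps, cmaps, cov, atlas = _cohort_maps(100 + s, deficit=0.9)
            res = group_contrast(pmaps, cmaps, cov, atlas=atlas,
                                 n_permutations=150, rng_seed=s)
            if res.clusters and res.clusters[0].atlas_label == "R0" \
                    and res.clusters[0].sign == "decrease":
                hits += 1
        assert hits >= int(0.9 * n_rep)

    def test_null_groups_rarely_survive(self):
        n_rep = 30
        false_pos = 0
        for s in range(n_rep):
            pmaps, cmaps, cov, atlas = _cohort_maps(500 + s, deficit=0.0)
            res = group_contrast(pmaps, cmaps, cov, atlas=atlas,
                                 n_permutations=150, rng_seed=s)
            false_pos += bool(res.clusters)
        # familywise alpha 0.05: Binomial(30, .05), P(>6) < 1e-3
        assert false_pos <= 6

    def test_permutation_determinism(self):
        pmaps, cmaps, cov, atlas = _cohort_maps(7, deficit=0.9)
        a = group_contrast(pmaps, cmaps, cov, atlas=atlas, n_permutations=120,
                           rng_seed=42)
        b = group_contrast(pmaps, cmaps, cov, atlas=atlas, n_permutations=120,
                           rng_seed=42)
        assert a.cluster_extent_threshold == b.cluster_extent_threshold
        assert [vars(c) for c in a.clusters] == [vars(c) for c in b.clusters]

    def test_identical_groups_single_voxel_t_zero(self):
        val = np.full((4, 4, 4), 5.0)
        pmaps = {f"P{i}": val for i in range(8)}
        cmaps = {f"C{i}": val for i in range(8)}
        cov = pd.DataFrame(
            {"sex": 1.0, "age": 50.0, "education": 12.0, "tiv": 1400.0,
             "months_post_rt": 0.0},
            index=list(pmaps) + list(cmaps),
        )
        mask = np.zeros((4, 4, 4), bool)
        mask[2, 2, 2] = True
        with pytest.warns(UserWarning, match="n_permutations"):
            res = group_contrast(pmaps, cmaps, cov, mask=mask, n_permutations=99,
                                 rng_seed=0)
        assert res.t_values[2, 2, 2] == 0.0
        assert res.clusters == []

    def test_t_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        pmaps, cmaps, cov, atlas = _cohort_maps(11, deficit=0.5)
        res = group_contrast(pmaps, cmaps, cov, atlas=atlas, n_permutations=100,
                             rng_seed=0)
        ids = sorted(pmaps) + sorted(cmaps)
        allmaps = {**pmaps, **cmaps}
        rng = np.random.default_rng(0)
        in_mask = np.argwhere(atlas.analysis_mask())
        vox = [tuple(v) for v in in_mask[rng.choice(len(in_mask), 5, replace=False)]]
        group = np.array([1.0 if s in pmaps else 0.0 for s in ids])
        X = sm.add_constant(np.column_stack([
            group,
            cov.loc[ids, ["sex", "age", "education", "tiv",
                          "months_post_rt"]].to_numpy(),
        ]))
        for v in vox:
            y = np.array([allmaps[s][v] for s in ids])
            fit = sm.OLS(y, X).fit()
            assert res.t_values[v] == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_grid_mismatch_rejected(self):
        pmaps = {f"P{i}": np.zeros((4, 4, 4)) for i in range(8)}
        cmaps = {f"C{i}": np.zeros((5, 4, 4)) for i in range(8)}
        cov = pd.DataFrame(
            {"sex": 0.0, "age": 50.0, "education": 12.0, "tiv": 1400.0,
             "months_post_rt": 0.0},
            index=list(pmaps) + list(cmaps),
        )
        with pytest.raises(ValueError, match="grids differ"):
            group_contrast(pmaps, cmaps, cov, n_permutations=100)


def _flood_fill_components(mask26):
    """Independent 26-connectivity component labeling by BFS."""
    visited = np.zeros_like(mask26, bool)
    comps = []
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for idx in np.argwhere(mask26):
        idx = tuple(idx)
        if visited[idx]:
            continue
        stack, comp = [idx], set()
        visited[idx] = True
        while stack:
            cur = stack.pop()
            comp.add(cur)
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if all(0 <= nb[d] < mask26.shape[d] for d in range(3)) \
                        and mask26[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def test_cluster_labeling_agrees_with_flood_fill(rng):
    structure = np.ones((3, 3, 3), bool)
    for _ in range(20):
        mask = rng.random((8, 8, 8)) < 0.2
        lab, n = ndimage.label(mask, structure=structure)
        scipy_comps = {
            frozenset(map(tuple, np.argwhere(lab == k))) for k in range(1, n + 1)
        }
        assert scipy_comps == _flood_fill_components(mask)


class TestCorrelateCognition:
    def test_perfect_monotone_association(self, rng):
        feat = rng.standard_normal(20)
        scores = pd.DataFrame({"mirror": np.exp(feat)})
        out = correlate_cognition(feat, scores)
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-10

    def test_hand_computed_rank_example(self):
        # no ties: rho = 1 - 6*sum(d^2) / (n(n^2-1)); d^2 sums to 8 here
        feat = pd.Series(np.arange(1.0, 9.0))
        scores = pd.DataFrame({"t": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0]})
        out = correlate_cognition(feat, scores)
        assert out.loc[0, "rho"] == pytest.approx(1 - 6 * 8 / (8 * 63), abs=1e-12)

    def test_fdr_calibration_under_null(self, rng):
        n_rep, n_tests, fam_hits = 300, 12, 0
        for _ in range(n_rep):
            feat = rng.standard_normal(20)
            scores = pd.DataFrame(rng.standard_normal((20, n_tests)),
                                  columns=[f"t{i}" for i in range(n_tests)])
            out = correlate_cognition(feat, scores)
            fam_hits += bool(out["significant"].any())
        rate = fam_hits / n_rep
        assert 0.005 <= rate <= 0.1  # nominal familywise level is 0.05

    def test_zero_variance_score_warns(self, rng):
        feat = rng.standard_normal(12)
        scores = pd.DataFrame({"flat": np.full(12, 3.0),
                               "ok": rng.standard_normal(12)})
        with pytest.warns(UserWarning, match="flat"):
            out = correlate_cognition(feat, scores)
        assert np.isnan(out.set_index("test").loc["flat", "rho"])

    def test_missing_scores_dropped_pairwise(self, rng):
        feat = rng.standard_normal(15)
        col = rng.standard_normal(15)
        col[3] = np.nan
        out = correlate_cognition(feat, pd.DataFrame({"t": col}))
        assert out.loc[0, "n"] == 14
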