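"""Panel selection: examples, oracle equivalence, and panel invariants.

``reference_select_panel`` below is an independent, deliberately naive
transcription of the selection procedure (subsample -> variance filter ->
pairwise-complete correlations -> median-correlation ranking -> iterative
threshold removal), kept free of any code shared with the implementation.
"""

import numpy as np
import pytest

from drpscreen.data_model import ResponseMatrix
from drpscreen.panel_select import (Panel, select_panel, threshold_for_size,
                                    variance_filter)
from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def reference_select_panel(m, axis, threshold, subsample_frac=0.7, seed=None,
                           min_overlap=10):
    if axis == "drugs":
        ids, data = list(m.drug_ids), m.values
        obs_ids = list(m.cell_ids)
    else:
        ids, data = list(m.cell_ids), m.values.T
        obs_ids = list(m.drug_ids)
    # (1) observation subsample
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_frac * len(obs_ids))))
    rows = np.sort(rng.choice(len(obs_ids), size=n_sub, replace=False))
    data = data[rows, :]
    # (2) variance filter: keep variance >= median
    variances = {}
    for j, sid in enumerate(ids):
        col = data[:, j][np.isfinite(data[:, j])]
        if len(col) >= 2:
            variances[sid] = np.var(col, ddof=1)
    med = np.median(sorted(variances.values()))
    survivors = [sid for sid in ids if sid in variances and variances[sid] >= med]
    sidx = {s: ids.index(s) for s in survivors}
    # (3) one symmetric pairwise-complete Pearson correlation matrix
    cmat = {}
    for ai, a in enumerate(survivors):
        for b in survivors[ai + 1:]:
            xa, xb = data[:, sidx[a]], data[:, sidx[b]]
            ok = np.isfinite(xa) & np.isfinite(xb)
            if ok.sum() < min_overlap:
                r = 0.0
            else:
                xa, xb = xa[ok], xb[ok]
                if xa.std() == 0 or xb.std() == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(xa, xb)[0, 1])
            cmat[a, b] = cmat[b, a] = r

    def corr(a, b):
        return cmat[a, b]
    # (4) ascending median correlation to all other survivors, id tie-break
    med_corr = {a: np.median([corr(a, b) for b in survivors if b != a])
                for a in survivors}
    order = sorted(survivors, key=lambda a: (med_corr[a], a))
    # (5) iterative selection with threshold removal
    chosen = []
    while order:
        pick = order.pop(0)
        chosen.append(pick)
        order = [q for q in order if corr(pick, q) <= threshold]
    return chosen


def random_matrix(rng, n_cells, n_drugs, missing=0.0, latent=2):
    u = rng.standard_normal((n_cells, latent))
    v = rng.standard_normal((n_drugs, latent))
    vals = 5 + u @ v.T + 0.5 * rng.standard_normal((n_cells, n_drugs))
    if missing:
        vals[rng.random(vals.shape) < missing] = np.nan
    return make_matrix(vals)


# ---------------------------------------------------------------------------
# variance filter
# ---------------------------------------------------------------------------

class TestVarianceFilter:
    def test_median_of_four_variances(self):
        # variances approximately (0, 0.1, 1.0, 2.0): median 0.55; keep top 2
        cols = []
        rng = np.random.default_rng(1)
        for target in (0.0, 0.1, 1.0, 2.0):
            x = rng.standard_normal(200)
            x = (x - x.mean())
            if x.std() > 0:
                x = x / x.std(ddof=1) * np.sqrt(target)
            cols.append(5 + x)
        m = make_matrix(np.column_stack(cols), drugs=["a", "b", "c", "d"])
        assert variance_filter(m, "drugs") == ["c", "d"]

    def test_all_equal_variance_all_survive(self):
        base = np.array([4.0, 5.0, 6.0])
        m = make_matrix(np.column_stack([base, base + 1, base + 2]))
        assert variance_filter(m, "drugs") == ["D0", "D1", "D2"]

    def test_two_samples_higher_survives(self):
        m = make_matrix(np.column_stack([[5.0, 5.1, 4.9], [3.0, 6.0, 9.0]]))
        assert variance_filter(m, "drugs") == ["D1"]

    def test_sample_with_one_observation_warned_not_fatal(self):
        vals = np.array([[5.0, 5.0], [6.0, np.nan], [7.0, np.nan]])
        m = make_matrix(vals)
        with pytest.warns(UserWarning, match="<2 observed"):
            out = variance_filter(m, "drugs")
        assert out == ["D0"]


# ---------------------------------------------------------------------------
# select_panel
# ---------------------------------------------------------------------------

class TestSelectPanel:
    def test_uncorrelated_survivors_all_selected(self):
        rng = np.random.default_rng(2)
        # orthogonal-ish columns: independent noise, correlations near 0
        vals = 5 + rng.standard_normal((60, 6))
        m = make_matrix(vals)
        panel = select_panel(m, "drugs", threshold=0.8, seed=0)
        survivors = set(panel.member_ids)
        assert len(survivors) >= 3  # half pass the variance filter and stay

    def test_correlated_pair_collapses_to_one(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(80)
        vals = np.column_stack([
            5 + base, 5 + base + 0.01 * rng.standard_normal(80),
            5 + rng.standard_normal(80), 5 + rng.standard_normal(80),
        ])
        m = make_matrix(vals, drugs=["a", "b", "c", "d"])
        panel = select_panel(m, "drugs", threshold=0.9, seed=1,
                             subsample_frac=1.0)
        assert len({"a", "b"} & set(panel.member_ids)) == 1

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_reference_transcription(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_cells = int(rng.integers(12, 16))
        n_drugs = int(rng.integers(6, 16))
        m = random_matrix(rng, n_cells, n_drugs, missing=0.1)
        t = float(rng.uniform(0.2, 0.9))
        axis = "drugs" if seed % 2 == 0 else "cell_lines"
        got = select_panel(m, axis, t, seed=seed, min_overlap=4)
        want = reference_select_panel(m, axis, t, seed=seed, min_overlap=4)
        assert got.member_ids == want

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 30, 12)
        a = select_panel(m, "drugs", 0.5, seed=9)
        b = select_panel(m, "drugs", 0.5, seed=9)
        assert a.member_ids == b.member_ids
        assert a.subsample_ids == b.subsample_ids

    def test_members_passed_variance_filter(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 40, 15)
        panel = select_panel(m, "drugs", 0.6, seed=2)
        sub = m.subset(cells=panel.subsample_ids)
        for d in panel.member_ids:
            col = sub.values[:, sub.drug_ids.index(d)]
            col = col[np.isfinite(col)]
            assert np.var(col, ddof=1) >= panel.variance_cutoff - 1e-12

    def test_pairwise_correlation_bounded_by_threshold(self):
        rng = np.random.default_rng(6)
        for trial in range(20):
            m = random_matrix(rng, 40, 12, latent=3)
            t = float(rng.uniform(0.3, 0.9))
            panel = select_panel(m, "drugs", t, seed=trial)
            sub = m.subset(cells=panel.subsample_ids, drugs=panel.member_ids)
            r = np.corrcoef(sub.values.T)
            np.fill_diagonal(r, -np.inf)
            assert r.max() <= t + 1e-9

    def test_too_few_samples_rejected(self):
        m = make_matrix(np.full((5, 3), 5.0))
        with pytest.raises(ValueError, match="at least 4"):
            select_panel(m, "drugs", 0.5, seed=0)

    def test_panel_save_load_roundtrip(self, tmp_path):
        p = Panel("drugs", ["D1", "D2"], 0.65, ["L1", "L2"], seed=3,
                  variance_cutoff=0.4)
        path = tmp_path / "panel.txt"
        p.save(path)
        q = Panel.load(path)
        assert q.member_ids == p.member_ids
        assert q.axis == p.axis
        assert q.threshold == pytest.approx(p.threshold)
        assert q.seed == p.seed


class TestThresholdForSize:
    def test_target_all_survivors_reachable(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 40, 12)
        n_surv = len(select_panel(m, "drugs", 0.995, seed=1).member_ids)
        t, size = threshold_for_size(m, "drugs", n_surv, seed=1)
        assert size >= n_surv

    def test_target_one_smallest_threshold(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 40, 12)
        t, size = threshold_for_size(m, "drugs", 1, seed=1)
        assert t == pytest.approx(0.005)
        assert size >= 1

    def test_threshold_is_minimal_at_resolution(self):
        rng = np.random.default_rng(9)
        u = rng.standard_normal((50, 3))
        v = rng.standard_normal((40, 3))
        m = make_matrix(5 + u @ v.T + 0.3 * rng.standard_normal((50, 40)))
        t, size = threshold_for_size(m, "drugs", 10, seed=2)
        assert size >= 10
        if t > 0.005:
            below = select_panel(m, "drugs", t - 0.005, seed=2)
            assert len(below) < 10

    def test_unreachable_target_rejected(self):
        rng = np.random.default_rng(10)
        m = random_matrix(rng, 30, 8)
        with pytest.raises(ValueError, match="unreachable"):
            threshold_for_size(m, "drugs", 50, seed=0)
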