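"""Per-drug response models, data splits, metrics and evaluation protocols.

Models are scikit-learn gradient-boosted regression trees; the working
configuration is deliberately small (50 trees, depth 2, learning rate 0.1)
because training panels hold only tens of cell lines.  Evaluation is run
both globally (pooling every drug-cell line pair) and per drug: pooled
correlations absorb between-drug potency differences and are systematically
higher than the mean of per-drug correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, floor

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

from .data_model import ResponseMatrix, SENSITIVITY_PIC50
from .features import DRPFeatureSet, ReducedExpression, build_drp
from .panel_select import Panel, select_panel, threshold_for_size

DEFAULT_HYPERPARAMS = {"n_estimators": 50, "max_depth": 2, "learning_rate": 0.1}

METRIC_NAMES = ("pearson", "spearman", "mse", "rmse", "mae")


@dataclass
class DrugModel:
    """A trained per-drug regressor with its training provenance."""

    target_drug_id: str
    descriptor_kind: str  # "DRP" | "omics"
    estimator: GradientBoostingRegressor
    hyperparams: dict
    training_cell_ids: list[str]
    seed: int | None
    panel: Panel | None = None
    zero_variance_target: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))


@dataclass
class EvalReport:
    """Metric summary, global (pooled pairs) or per-drug aggregated."""

    scope: str  # "global" | "per_drug"
    metrics: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)
    n_pairs: int = 0
    n_drugs: int = 0
    n_undefined_correlation: int = 0
    replicate_seeds: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = {k: {"mean": self.metrics.get(k, np.nan),
                    "sd": self.sd.get(k, np.nan)} for k in METRIC_NAMES}
        return pd.DataFrame(rows).T


def split_cell_lines(cell_ids: list[str],
                     fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int | None = None
                     ) -> tuple[list[str], list[str], list[str]]:
    """Random train/validation/test partition of cell lines.

    Validation and test take floor(fraction * n) lines each; the remainder
    goes to training, so the three sets are disjoint and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = [str(c) for c in cell_ids]
    if len(ids) < 3:
        raise ValueError("need at least 3 cell lines to split")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_val = floor(fractions[1] * len(ids))
    n_test = floor(fractions[2] * len(ids))
    test = sorted(perm[:n_test])
    val = sorted(perm[n_test:n_test + n_val])
    train = sorted(perm[n_test + n_val:])
    return train, val, test


def train_drug_model(features, labels: np.ndarray, target_drug_id: str = "",
                     descriptor_kind: str | None = None,
                     hyperparams: dict | None = None,
                     seed: int | None = None,
                     cell_ids: list[str] | None = None) -> DrugModel:
    """Fit a gradient-boosted tree regressor for one drug.

    ``features`` may be a DRPFeatureSet, a ReducedExpression, or a plain
    array whose rows align with ``labels``.
    """
    if isinstance(features, DRPFeatureSet):
        X = features.features
        ids = features.cell_ids
        kind = descriptor_kind or "DRP"
        panel = Panel("drugs", list(features.panel_drug_ids), float("nan"))
        target = target_drug_id or features.target_drug_id
    elif isinstance(features, ReducedExpression):
        X = features.component_scores
        ids = features.cell_ids
        kind = descriptor_kind or "omics"
        panel = None
        target = target_drug_id
    else:
        X = np.asarray(features, dtype=float)
        ids = cell_ids if cell_ids is not None else [str(i) for i in range(len(X))]
        kind = descriptor_kind or "raw"
        panel = None
        target = target_drug_id
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature rows must align with labels")
    if y.shape[0] < 5:
        raise ValueError("need at least 5 labelled cell lines")
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    est = GradientBoostingRegressor(random_state=seed, **hp)
    est.fit(X, y)
    return DrugModel(
        target_drug_id=str(target),
        descriptor_kind=kind,
        estimator=est,
        hyperparams=hp,
        training_cell_ids=list(ids),
        seed=seed,
        panel=panel,
        zero_variance_target=bool(np.ptp(y) == 0),
    )


def compute_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """Pearson, Spearman, MSE, RMSE, MAE for one prediction vector.

    Correlations are NaN (flagged via ``correlation_defined``) when either
    vector is constant; error metrics are always defined.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 pairs")
    err = y - yhat
    out: dict[str, float] = {
        "mse": float(np.mean(err ** 2)),
        "mae": float(np.mean(np.abs(err))),
    }
    out["rmse"] = float(np.sqrt(out["mse"]))
    defined = bool(np.ptp(y) > 0 and np.ptp(yhat) > 0)
    out["correlation_defined"] = defined
    if defined:
        out["pearson"] = float(stats.pearsonr(y, yhat).statistic)
        out["spearman"] = float(stats.spearmanr(y, yhat).statistic)
    else:
        out["pearson"] = float("nan")
        out["spearman"] = float("nan")
    return out


def evaluate_global_and_perdrug(predictions: dict[str, tuple[np.ndarray, np.ndarray]]
                                ) -> tuple[EvalReport, EvalReport]:
    """Global (pooled) and per-drug metric reports.

    ``predictions`` maps drug id -> (observed, predicted) over its evaluated
    cell lines.  Per-drug correlations undefined on constant vectors are
    excluded from the correlation aggregation and counted.
    """
    if not predictions:
        raise ValueError("no predictions supplied")
    ys, yhats = [], []
    per_drug_rows = {}
    for drug, (y, yhat) in predictions.items():
        y = np.asarray(y, dtype=float)
        yhat = np.asarray(yhat, dtype=float)
        if y.size >= 2:
            per_drug_rows[drug] = compute_metrics(y, yhat)
        ys.append(y)
        yhats.append(yhat)
    if not per_drug_rows:
        raise ValueError("no drug has >= 2 evaluated pairs")
    y_all = np.concatenate(ys)
    yhat_all = np.concatenate(yhats)
    g = compute_metrics(y_all, yhat_all)
    global_report = EvalReport(
        scope="global",
        metrics={k: g[k] for k in METRIC_NAMES},
        n_pairs=int(y_all.size),
        n_drugs=len(predictions),
    )
    tbl = pd.DataFrame(per_drug_rows).T
    undefined = int((~tbl["correlation_defined"].astype(bool)).sum())
    means, sds = {}, {}
    for k in METRIC_NAMES:
        col = tbl[k].astype(float)
        if k in ("pearson", "spearman"):
            col = col[tbl["correlation_defined"].astype(bool)]
        means[k] = float(col.mean())
        sds[k] = float(col.std(ddof=0)) if len(col) else float("nan")
    per_drug_report = EvalReport(
        scope="per_drug",
        metrics=means,
        sd=sds,
        n_pairs=int(y_all.size),
        n_drugs=len(per_drug_rows),
        n_undefined_correlation=undefined,
    )
    return global_report, per_drug_report


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def _predict_all_drugs(m: ResponseMatrix, descriptor: str, drug_panel: Panel,
                       omics: ReducedExpression | None,
                       train_cells: list[str], eval_cells: list[str],
                       hyperparams: dict | None, seed: int | None
                       ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Train one model per drug on ``train_cells`` and predict ``eval_cells``."""
    preds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    cell_pos = {c: i for i, c in enumerate(m.cell_ids)}
    for j, drug in enumerate(m.drug_ids):
        tr = [c for c in train_cells if m.observed[cell_pos[c], j]]
        ev = [c for c in eval_cells if m.observed[cell_pos[c], j]]
        if len(tr) < 5 or len(ev) < 2:
            continue
        y_tr = m.values[[cell_pos[c] for c in tr], j]
        y_ev = m.values[[cell_pos[c] for c in ev], j]
        if descriptor == "DRP":
            fs = build_drp(m, drug_panel, drug, impute="median",
                           train_cell_ids=tr)
            X_tr, X_ev = fs.rows(tr), fs.rows(ev)
        elif descriptor == "omics":
            X_tr, X_ev = omics.rows(tr), omics.rows(ev)
        else:
            raise ValueError(f"unknown descriptor {descriptor!r}")
        model = train_drug_model(X_tr, y_tr, target_drug_id=drug,
                                 descriptor_kind=descriptor,
                                 hyperparams=hyperparams, seed=seed,
                                 cell_ids=tr)
        preds[drug] = (y_ev, model.predict(X_ev))
    return preds


def run_panel_benchmark(m: ResponseMatrix, omics: ReducedExpression | None = None,
                        omics_raw=None,
                        drug_panel_size: int = 50, cell_panel_size: int = 50,
                        n_replicates: int = 5, seeds: list[int] | None = None,
                        hyperparams: dict | None = None) -> dict:
    """Head-to-head DRP vs omics benchmark over independent replicates.

    Per replicate: fresh 80/10/10 cell-line split; drug and cell-line panels
    selected on training data only (sized via threshold search); one model
    per drug trained on the panel cell lines for each descriptor kind;
    global test-set metrics.  The report carries per-descriptor mean +/- sd
    and a two-sided paired t-test on the replicate RMSEs.

    ``omics`` supplies precomputed projections; alternatively ``omics_raw``
    (a transformed ExpressionMatrix) is reduced per replicate on training
    lines only.  With neither, only the DRP arm runs.
    """
    from .features import reduce_expression

    if seeds is None:
        seeds = list(range(n_replicates))
    if len(seeds) != n_replicates:
        raise ValueError("need one seed per replicate")
    arms = ["DRP"] + (["omics"] if (omics is not None or omics_raw is not None) else [])
    rows = []
    replicate_details = []
    for rep, seed in enumerate(seeds):
        train, val, test = split_cell_lines(m.cell_ids, seed=seed)
        m_train = m.subset(cells=train)
        t_drug, _ = threshold_for_size(m_train, "drugs", drug_panel_size, seed=seed)
        drug_panel = select_panel(m_train, "drugs", t_drug, seed=seed)
        cell_pool = m_train.subset(drugs=drug_panel.member_ids)
        t_cell, _ = threshold_for_size(cell_pool, "cell_lines", cell_panel_size,
                                       seed=seed)
        cell_panel = select_panel(cell_pool, "cell_lines", t_cell, seed=seed)
        panel_cells = cell_panel.member_ids[:cell_panel_size]
        rep_omics = omics
        if rep_omics is None and omics_raw is not None:
            rep_omics = reduce_expression(omics_raw, fit_ids=train)
        row = {"replicate": rep, "seed": seed}
        for arm in arms:
            preds = _predict_all_drugs(
                m, arm, drug_panel, rep_omics, panel_cells, test,
                hyperparams, seed)
            g, _ = evaluate_global_and_perdrug(preds)
            for k in METRIC_NAMES:
                row[f"{arm}_{k}"] = g.metrics[k]
        rows.append(row)
        replicate_details.append({
            "seed": seed,
            "drug_panel": list(drug_panel.member_ids),
            "cell_panel": list(panel_cells),
            "n_test": len(test),
        })
    tbl = pd.DataFrame(rows)
    report = {"replicates": tbl, "details": replicate_details, "arms": arms,
              "summary": {}}
    for arm in arms:
        report["summary"][arm] = {
            k: (float(tbl[f"{arm}_{k}"].mean()), float(tbl[f"{arm}_{k}"].std(ddof=1)))
            for k in METRIC_NAMES
        }
    if len(arms) == 2:
        t = stats.ttest_rel(tbl["DRP_rmse"], tbl["omics_rmse"])
        report["paired_ttest_rmse"] = {
            "statistic": float(t.statistic) if np.isfinite(t.statistic) else float("nan"),
            "pvalue": float(t.pvalue) if np.isfinite(t.pvalue) else 1.0,
            "mean_difference": float((tbl["DRP_rmse"] - tbl["omics_rmse"]).mean()),
            "drp_wins": int((tbl["DRP_rmse"] < tbl["omics_rmse"]).sum()),
        }
    return report


def hyperparameter_sweep(m: ResponseMatrix, configs: list[dict] | None = None,
                         **kwargs) -> pd.DataFrame:
    """Run the panel benchmark for each hyperparameter configuration.

    Default grid mirrors the working sweep: tree depths 2-4 crossed with
    50 or 100 trees.
    """
    if configs is None:
        configs = [{"n_estimators": n, "max_depth": d}
                   for d in (2, 3, 4) for n in (50, 100)]
    rows = []
    for cfg in configs:
        rep = run_panel_benchmark(m, hyperparams=cfg, **kwargs)
        mean_rmse, sd_rmse = rep["summary"]["DRP"]["rmse"]
        rows.append({**cfg, "rmse_mean": mean_rmse, "rmse_sd": sd_rmse})
    return pd.DataFrame(rows)


def crossval_protocol(m: ResponseMatrix, omics: ReducedExpression | None = None,
                      k_folds: int = 10, panel_mode: str = "selected",
                      train_frac_within_fold: float = 0.05,
                      drug_panel_size: int | None = None,
                      descriptor: str = "DRP",
                      hyperparams: dict | None = None,
                      seed: int | None = None) -> tuple[EvalReport, EvalReport]:
    """k-fold cross-validation with a limited training panel per fold.

    Cell lines are partitioned into ``k_folds`` folds.  Within each fold's
    training portion, a small cell-line panel (``train_frac_within_fold`` of
    training lines) is drawn — randomly (``panel_mode='random'``, suited to
    small drug sets) or by the greedy selection (``panel_mode='selected'``) —
    and per-drug models trained on it predict the held-out fold.  Metrics are
    aggregated over all folds.
    """
    ids = list(m.cell_ids)
    if k_folds > len(ids):
        raise ValueError("k_folds exceeds the number of cell lines")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = [sorted(ids[i] for i in perm[f::k_folds]) for f in range(k_folds)]
    all_preds: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for f, heldout in enumerate(folds):
        train_all = sorted(set(ids) - set(heldout))
        n_panel = max(5, int(round(train_frac_within_fold * len(train_all))))
        if n_panel > len(train_all):
            warnings.warn(f"fold {f}: too few training lines for a panel; skipped")
            continue
        if panel_mode == "random":
            pick = rng.choice(len(train_all), size=n_panel, replace=False)
            panel_cells = sorted(train_all[i] for i in np.sort(pick))
        elif panel_mode == "all":
            panel_cells = train_all
        elif panel_mode == "selected":
            m_train = m.subset(cells=train_all)
            try:
                t, _ = threshold_for_size(m_train, "cell_lines", n_panel,
                                          seed=seed)
                cp = select_panel(m_train, "cell_lines", t, seed=seed)
                panel_cells = cp.member_ids[:n_panel]
            except ValueError as e:
                warnings.warn(f"fold {f}: panel selection failed ({e}); skipped")
                continue
        else:
            raise ValueError(f"unknown panel_mode {panel_mode!r}")
        if descriptor == "DRP":
            m_panel_sel = m.subset(cells=train_all)
            want = drug_panel_size or max(4, min(20, len(m.drug_ids) // 2))
            try:
                t_drug, _ = threshold_for_size(m_panel_sel, "drugs", want,
                                               seed=seed)
            except ValueError:
                t_drug = 0.995  # take every variance-filter survivor
            drug_panel = select_panel(m_panel_sel, "drugs", t_drug, seed=seed)
        else:
            drug_panel = None
        preds = _predict_all_drugs(m, descriptor, drug_panel, omics,
                                   panel_cells, heldout, hyperparams, seed)
        for drug, (y, yhat) in preds.items():
            all_preds.setdefault(drug, []).append((y, yhat))
    merged = {
        drug: (np.concatenate([y for y, _ in parts]),
               np.concatenate([p for _, p in parts]))
        for drug, parts in all_preds.items()
    }
    return evaluate_global_and_perdrug(merged)


def selective_drugs(m: ResponseMatrix, sensitivity_cut: float = SENSITIVITY_PIC50,
                    max_active_frac: float = 0.25) -> list[str]:
    """Drugs active (pIC50 >= cut) in strictly fewer than ``max_active_frac``
    of their observed cell lines."""
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("empty response matrix")
    out = []
    for j, d in enumerate(m.drug_ids):
        col = m.values[:, j]
        obs = np.isfinite(col)
        if not obs.any():
            warnings.warn(f"drug {d!r} has no observed entries; excluded")
            continue
        frac = float((col[obs] >= sensitivity_cut).mean())
        if frac < max_active_frac:
            out.append(d)
    return out


def screening_efficiency(ranked_cells: list[str], labels: dict[str, int],
                         recall_target: float = 0.75,
                         scores: dict[str, float] | None = None
                         ) -> tuple[float, int]:
    """Fraction of a ranked cell-line list that must be screened to recover
    ``recall_target`` of all actives.

    ``ranked_cells`` is ordered by predicted sensitivity, best first; ties in
    ``scores`` (when given) are re-broken by id order.  Returns
    (fraction_tested, recovered_count).
    """
    cells = [str(c) for c in ranked_cells]
    if scores is not None:
        cells = sorted(cells, key=lambda c: (-scores[c], c))
    total_pos = sum(int(bool(labels[c])) for c in cells)
    if total_pos == 0:
        raise ValueError("no positive labels")
    need = ceil(recall_target * total_pos)
    recovered = 0
    for k, c in enumerate(cells, start=1):
        recovered += int(bool(labels[c]))
        if recovered >= need:
            return k / len(cells), recovered
    return 1.0, recovered
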