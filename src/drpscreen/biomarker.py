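"""Biomarker discovery on enriched, high-contrast cell-line panels.

The workflow: take the selected cell-line panel, add the top and bottom
predicted responders for the drug of interest (maximising response contrast),
pre-select the genes most correlated with sensitivity within that cohort,
fit a random forest on their expression, and interpret it with impurity
importances plus SHAP values computed on held-out cell lines that never
entered the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .data_model import ExpressionMatrix
from .panel_select import Panel
from . import treeshap


@dataclass
class BiomarkerReport:
    """Per-gene correlation, forest importance and SHAP summary for one drug."""

    drug_id: str
    panel_cell_ids: list[str]
    gene_ids: list[str]  # ordered by descending |correlation|
    correlations: np.ndarray  # signed Pearson r to sensitivity, same order
    importances: np.ndarray | None = None  # sums to 1
    shap_mean_abs: np.ndarray | None = None
    shap_sign: np.ndarray | None = None  # sign of expression-attribution assoc.
    shap_variant: str = treeshap.VARIANT
    seed: int | None = None
    constant_target: bool = False

    def top_genes(self, n: int, by: str = "shap") -> list[str]:
        key = {"shap": self.shap_mean_abs, "importance": self.importances,
               "correlation": np.abs(self.correlations)}[by]
        if key is None:
            raise ValueError(f"report has no {by!r} ranking")
        order = np.argsort(-np.asarray(key), kind="stable")
        return [self.gene_ids[i] for i in order[:n]]

    def to_frame(self) -> pd.DataFrame:
        data = {"gene": self.gene_ids, "correlation": self.correlations}
        if self.importances is not None:
            data["importance"] = self.importances
        if self.shap_mean_abs is not None:
            data["shap_mean_abs"] = self.shap_mean_abs
            data["shap_sign"] = self.shap_sign
        return pd.DataFrame(data)


def enriched_panel(base_panel: Panel, predictions: dict[str, float],
                   n_extreme: int = 10) -> list[str]:
    """Union of the cell-line panel with the top/bottom predicted responders.

    ``predictions`` maps candidate cell id -> predicted pIC50 for the drug of
    interest.  Ties at the extremes break by id order; duplicates collapse.
    """
    if base_panel.axis != "cell_lines":
        raise ValueError("enriched_panel requires a cell-line panel")
    base = list(base_panel.member_ids)
    outside = sorted(set(predictions) - set(base))
    if len(outside) < 2 * n_extreme:
        warnings.warn(f"only {len(outside)} candidate lines outside the panel "
                      f"for 2x{n_extreme} extremes; taking what exists")
    ranked = sorted(outside, key=lambda c: (-predictions[c], c))
    top = ranked[:n_extreme]
    bottom = [c for c in reversed(ranked) if c not in top][:n_extreme]
    out = list(base)
    for c in top + sorted(bottom):
        if c not in out:
            out.append(c)
    return out


def top_correlated_genes(x: ExpressionMatrix, sensitivity: dict[str, float],
                         n: int = 500) -> tuple[list[str], np.ndarray]:
    """Genes ranked by |Pearson r| between expression and drug sensitivity.

    Computed across the panel cells named in ``sensitivity``; zero-variance
    genes are excluded.  Returns (gene ids, signed correlations) of length
    min(n, surviving genes).
    """
    if not x.transformed:
        raise ValueError("expected log2(TPM+1) expression")
    cells = [str(c) for c in sensitivity]
    if len(cells) < 3:
        raise ValueError("need at least 3 cells for correlation ranking")
    idx = [x.cell_ids.index(c) for c in cells]
    expr = x.values[:, idx]  # genes x panel cells
    y = np.array([float(sensitivity[c]) for c in cells])
    if np.ptp(y) == 0:
        raise ValueError("sensitivity is constant across panel cells")
    gene_sd = expr.std(axis=1)
    keep = np.where(gene_sd > 0)[0]
    if keep.size == 0:
        raise ValueError("all genes have zero variance across the panel")
    yc = y - y.mean()
    ec = expr[keep] - expr[keep].mean(axis=1, keepdims=True)
    r = (ec @ yc) / (np.linalg.norm(ec, axis=1) * np.linalg.norm(yc))
    order = np.argsort(-np.abs(r), kind="stable")[:min(n, keep.size)]
    return [x.gene_ids[keep[i]] for i in order], r[order]


def fit_importance_model(x_subset: np.ndarray, sensitivity: np.ndarray,
                         n_trees: int = 200, seed: int | None = None
                         ) -> tuple[RandomForestRegressor, np.ndarray]:
    """Random-forest regressor with normalised impurity importances.

    ``x_subset`` is cells x genes over the enriched panel.  A constant target
    still fits but yields uniform (uninformative) importances with a warning.
    """
    X = np.asarray(x_subset, dtype=float)
    y = np.asarray(sensitivity, dtype=float)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 cells to fit the forest")
    model = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    model.fit(X, y)
    if np.ptp(y) == 0:
        warnings.warn("constant sensitivity target: importances undefined, "
                      "returning uniform vector")
        imp = np.full(X.shape[1], 1.0 / X.shape[1])
    else:
        imp = model.feature_importances_.copy()
        s = imp.sum()
        if s > 0:
            imp = imp / s
    return model, imp


def shap_summary(model, x_holdout: np.ndarray,
                 training_cell_ids: list[str] | None = None,
                 holdout_cell_ids: list[str] | None = None
                 ) -> dict[str, np.ndarray]:
    """Per-gene SHAP statistics on cells never used to fit the model.

    Returns per-gene mean |SHAP|, the sign of the expression-attribution
    association, the raw attribution matrix and the model's expected value.
    When both id lists are given, any overlap is a hard error (the point of
    the holdout is leakage-free interpretation).
    """
    if training_cell_ids is not None and holdout_cell_ids is not None:
        overlap = set(training_cell_ids) & set(holdout_cell_ids)
        if overlap:
            raise ValueError(f"holdout overlaps training cells: {sorted(overlap)}")
    X = np.asarray(x_holdout, dtype=float)
    phi, expected = treeshap.shap_values(model, X)
    mean_abs = np.abs(phi).mean(axis=0)
    signs = np.zeros(X.shape[1])
    for g in range(X.shape[1]):
        if np.ptp(X[:, g]) > 0 and np.ptp(phi[:, g]) > 0:
            signs[g] = np.sign(stats.pearsonr(X[:, g], phi[:, g]).statistic)
    return {
        "mean_abs_shap": mean_abs,
        "sign": signs,
        "values": phi,
        "expected_value": expected,
        "variant": treeshap.VARIANT,
    }


def biomarker_workflow(x: ExpressionMatrix, sensitivity: dict[str, float],
                       panel_cells: list[str], holdout_cells: list[str],
                       drug_id: str, n_genes: int = 500, n_trees: int = 200,
                       seed: int | None = None) -> BiomarkerReport:
    """End-to-end biomarker report for one drug.

    Gene pre-selection and the forest fit use only ``panel_cells``; SHAP is
    computed on ``holdout_cells``, reserved before panel enrichment.
    """
    overlap = set(panel_cells) & set(holdout_cells)
    if overlap:
        raise ValueError(f"holdout overlaps the panel: {sorted(overlap)}")
    panel_sens = {c: sensitivity[c] for c in panel_cells}
    genes, corrs = top_correlated_genes(x, panel_sens, n=n_genes)
    gidx = [x.gene_ids.index(g) for g in genes]
    pidx = [x.cell_ids.index(c) for c in panel_cells]
    hidx = [x.cell_ids.index(c) for c in holdout_cells]
    X_panel = x.values[np.ix_(gidx, pidx)].T
    X_hold = x.values[np.ix_(gidx, hidx)].T
    y = np.array([float(sensitivity[c]) for c in panel_cells])
    model, imp = fit_importance_model(X_panel, y, n_trees=n_trees, seed=seed)
    summ = shap_summary(model, X_hold, training_cell_ids=panel_cells,
                        holdout_cell_ids=holdout_cells)
    return BiomarkerReport(
        drug_id=str(drug_id),
        panel_cell_ids=list(panel_cells),
        gene_ids=genes,
        correlations=corrs,
        importances=imp,
        shap_mean_abs=summ["mean_abs_shap"],
        shap_sign=summ["sign"],
        seed=seed,
        constant_target=bool(np.ptp(y) == 0),
    )


def overlap_analysis(report_small: BiomarkerReport, report_large: BiomarkerReport,
                     top_n: int = 20, by: str = "shap") -> float:
    """Fraction of the top-``top_n`` genes shared between two reports.

    Used to check that compact enriched panels recover the same biomarkers
    as much larger random cell-line subsets.
    """
    if report_small.drug_id != report_large.drug_id:
        raise ValueError("reports describe different drugs")
    limit = min(len(report_small.gene_ids), len(report_large.gene_ids))
    if top_n > limit:
        warnings.warn(f"top_n={top_n} exceeds report size; clamped to {limit}")
        top_n = limit
    a = set(report_small.top_genes(top_n, by=by))
    b = set(report_large.top_genes(top_n, by=by))
    return len(a & b) / top_n
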