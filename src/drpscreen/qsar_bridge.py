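"""Structure-based (QSAR) harmonisation of incomplete drug-response panels.

When the reference panel has been measured on only some cell lines, per-line
QSAR models — gradient-boosted trees from MACCS fingerprint bits to pIC50 —
fill the gaps, yielding a unified DRP feature space over every line.
Measured values are never overwritten; every entry carries a source label.
QSAR models get more capacity (100 trees, depth 4) than the DRP response
models because their training sets (hundreds to thousands of compounds per
line) are much larger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

from .data_model import FingerprintTable, ResponseMatrix
from .features import build_drp
from .models_eval import train_drug_model
from .panel_select import Panel

QSAR_HYPERPARAMS = {"n_estimators": 100, "max_depth": 4, "learning_rate": 0.1}

#: held-out Pearson below which a per-line QSAR model triggers a warning
QSAR_QUALITY_GATE = 0.3


@dataclass
class QSARModel:
    """Per-cell-line fingerprint -> pIC50 regressor with a quality estimate."""

    cell_id: str
    estimator: GradientBoostingRegressor
    heldout_pearson: float
    n_training_drugs: int
    seed: int | None

    def predict_bits(self, bits: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(bits, dtype=float))


@dataclass
class HarmonisedPanel:
    """Response matrix over all lines x panel drugs with per-entry source."""

    matrix: ResponseMatrix
    source: np.ndarray  # same shape, values in {"measured", "qsar_predicted"}
    quality: dict[str, float] = field(default_factory=dict)  # per-line Pearson

    def __post_init__(self):
        self.source = np.asarray(self.source, dtype=object)
        if self.source.shape != self.matrix.shape:
            raise ValueError("source mask shape must match the matrix")
        bad = set(np.unique(self.source)) - {"measured", "qsar_predicted"}
        if bad:
            raise ValueError(f"invalid source labels: {bad}")

    @property
    def n_measured(self) -> int:
        return int((self.source == "measured").sum())


def train_qsar(fp: FingerprintTable, activities: dict[str, float],
               cell_id: str = "", hyperparams: dict | None = None,
               holdout_frac: float = 0.2, seed: int | None = None) -> QSARModel:
    """Fit a per-cell-line QSAR model from fingerprints to pIC50.

    Quality is the Pearson correlation on an internal random drug holdout
    (``holdout_frac``); the final model is refitted on all drugs.  Requires
    at least 20 measured drugs so the quality estimate is meaningful.
    """
    drugs = [str(d) for d in activities]
    missing = [d for d in drugs if d not in fp.drug_ids]
    if missing:
        raise ValueError(f"drugs without fingerprints: {sorted(missing)}")
    if len(drugs) < 20:
        raise ValueError(
            f"need >= 20 measured drugs to train a QSAR model "
            f"(got {len(drugs)}): held-out quality unestimable")
    X = np.array([fp.vector(d) for d in drugs], dtype=float)
    y = np.array([float(activities[d]) for d in drugs])
    hp = dict(QSAR_HYPERPARAMS, **(hyperparams or {}))

    rng = np.random.default_rng(seed)
    n_hold = max(2, int(round(holdout_frac * len(drugs))))
    hold = np.zeros(len(drugs), dtype=bool)
    hold[rng.choice(len(drugs), size=n_hold, replace=False)] = True
    est = GradientBoostingRegressor(random_state=seed, **hp)
    est.fit(X[~hold], y[~hold])
    pred = est.predict(X[hold])
    if np.ptp(y[hold]) > 0 and np.ptp(pred) > 0:
        q = float(stats.pearsonr(y[hold], pred).statistic)
    else:
        q = float("nan")
    if not (q >= QSAR_QUALITY_GATE):
        warnings.warn(f"QSAR model for {cell_id or '<line>'} has held-out "
                      f"Pearson {q:.3f} < {QSAR_QUALITY_GATE}")
    final = GradientBoostingRegressor(random_state=seed, **hp)
    final.fit(X, y)
    return QSARModel(
        cell_id=str(cell_id), estimator=final, heldout_pearson=q,
        n_training_drugs=len(drugs), seed=seed,
    )


def harmonise_drp(measured: ResponseMatrix, fp: FingerprintTable,
                  panel_drugs: list[str],
                  qsar_models: dict[str, QSARModel]) -> HarmonisedPanel:
    """Unified (all lines x panel drugs) response matrix.

    Measured entries are kept verbatim; gaps are filled by the line's QSAR
    prediction.  A line with missing entries but no QSAR model is a hard
    error.
    """
    panel_drugs = [str(d) for d in panel_drugs]
    missing_fp = [d for d in panel_drugs if d not in fp.drug_ids]
    if missing_fp:
        raise ValueError(f"panel drugs without fingerprints: {sorted(missing_fp)}")
    sub = measured.subset(drugs=[d for d in panel_drugs if d in measured.drug_ids])
    vals = np.full((len(measured.cell_ids), len(panel_drugs)), np.nan)
    source = np.full(vals.shape, "qsar_predicted", dtype=object)
    col_of = {d: j for j, d in enumerate(panel_drugs)}
    for jj, d in enumerate(sub.drug_ids):
        j = col_of[d]
        obs = sub.observed[:, jj]
        vals[obs, j] = sub.values[obs, jj]
        source[obs, j] = "measured"
    bits = np.array([fp.vector(d) for d in panel_drugs], dtype=float)
    quality = {}
    for i, cell in enumerate(measured.cell_ids):
        gap = source[i] == "qsar_predicted"
        if not gap.any():
            continue
        model = qsar_models.get(cell)
        if model is None:
            raise ValueError(f"cell line {cell!r} has missing panel entries "
                             "and no QSAR model")
        vals[i, gap] = model.predict_bits(bits[gap])
        quality[cell] = model.heldout_pearson
    matrix = ResponseMatrix(list(measured.cell_ids), panel_drugs, vals,
                            np.isfinite(vals))
    return HarmonisedPanel(matrix=matrix, source=source, quality=quality)


def predict_new_lines(harmonised: HarmonisedPanel,
                      library_labels: ResponseMatrix,
                      target_lines: list[str],
                      hyperparams: dict | None = None,
                      seed: int | None = None) -> ResponseMatrix:
    """Predict library-drug responses for target lines from harmonised DRPs.

    For each library drug, a small DRP model (50 trees, depth 2) is trained
    on the reference lines' harmonised panel features against that drug's
    measured labels, then applied to the target lines' panel rows.  A library
    drug that also sits in the panel is a leakage error; drugs with fewer
    than 5 labelled reference lines are skipped with a warning.
    """
    panel_drugs = list(harmonised.matrix.drug_ids)
    clash = sorted(set(library_labels.drug_ids) & set(panel_drugs))
    if clash:
        raise ValueError(f"library drugs overlap the panel (leakage): {clash}")
    target_lines = [str(c) for c in target_lines]
    unknown = [c for c in target_lines if c not in harmonised.matrix.cell_ids]
    if unknown:
        raise ValueError(f"target lines missing from harmonised panel: {unknown}")
    panel = Panel("drugs", panel_drugs, float("nan"))
    ref_lines = [c for c in library_labels.cell_ids
                 if c in harmonised.matrix.cell_ids and c not in target_lines]
    preds = np.full((len(target_lines), len(library_labels.drug_ids)), np.nan)
    lab_pos = {c: i for i, c in enumerate(library_labels.cell_ids)}
    for j, drug in enumerate(library_labels.drug_ids):
        labelled = [c for c in ref_lines
                    if library_labels.observed[lab_pos[c], j]]
        if len(labelled) < 5:
            warnings.warn(f"library drug {drug!r} has {len(labelled)} labelled "
                          "reference lines (<5); skipped")
            continue
        fs = build_drp(harmonised.matrix, panel, drug, impute="median",
                       train_cell_ids=labelled)
        y = library_labels.values[[lab_pos[c] for c in labelled], j]
        model = train_drug_model(fs.rows(labelled), y, target_drug_id=drug,
                                 descriptor_kind="DRP",
                                 hyperparams=hyperparams, seed=seed,
                                 cell_ids=labelled)
        preds[:, j] = model.predict(fs.rows(target_lines))
    return ResponseMatrix(target_lines, list(library_labels.drug_ids), preds,
                          np.isfinite(preds))
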