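"""Model descriptors: DRP vectors, reduced expression profiles, MACCS keys.

A DRP (drug response profile) descriptor represents each cell line by its
pIC50 vector over the panel drugs.  The drug being predicted is always
excluded from its own descriptor so the model never sees the target column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .data_model import ExpressionMatrix, FingerprintTable, ResponseMatrix
from .panel_select import Panel


@dataclass
class DRPFeatureSet:
    """Per-cell-line pIC50 feature matrix over panel drugs for one target drug."""

    cell_ids: list[str]
    panel_drug_ids: list[str]
    target_drug_id: str
    features: np.ndarray  # cells x panel drugs, fully observed after imputation
    imputed: np.ndarray  # boolean, marks originally missing cells
    impute_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.target_drug_id in self.panel_drug_ids:
            raise ValueError("target drug must not be among the panel features")
        self.features = np.asarray(self.features, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)

    def rows(self, cell_ids: list[str]) -> np.ndarray:
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return self.features[idx]


@dataclass
class ReducedExpression:
    """PCA-projected expression profiles (components fitted on training lines)."""

    cell_ids: list[str]
    component_scores: np.ndarray  # cells x n_components
    n_components: int
    explained_fraction: float
    fit_cell_ids: list[str]

    def rows(self, cell_ids: list[str]) -> np.ndarray:
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return self.component_scores[idx]


def build_drp(m: ResponseMatrix, panel: Panel, target_drug: str,
              impute: str = "median",
              train_cell_ids: list[str] | None = None) -> DRPFeatureSet:
    """DRP descriptor matrix for all cell lines of ``m`` against one target drug.

    The target drug is removed from the feature set if it sits in the panel.
    Residual missing entries are filled with per-drug medians computed only
    over ``train_cell_ids`` (defaults to all cell lines); ``impute='none'``
    demands complete data instead.
    """
    if panel.axis != "drugs":
        raise ValueError("build_drp requires a drug-axis panel")
    missing_panel = [d for d in panel.member_ids if d not in m.drug_ids]
    if missing_panel:
        raise ValueError(f"panel drugs absent from matrix: {missing_panel}")
    target_drug = str(target_drug)
    feat_drugs = [d for d in panel.member_ids if d != target_drug]
    if not feat_drugs:
        raise ValueError("panel degenerates to nothing once the target drug "
                         "is excluded")
    sub = m.subset(drugs=feat_drugs)
    feats = sub.values.copy()
    miss = ~sub.observed
    impute_values: dict[str, float] = {}
    if impute == "none":
        if miss.any():
            raise ValueError("missing panel entries present with impute='none'")
    elif impute == "median":
        train = train_cell_ids if train_cell_ids is not None else m.cell_ids
        tr_idx = [sub.cell_ids.index(c) for c in train]
        for j, d in enumerate(feat_drugs):
            col = sub.values[tr_idx, j]
            col = col[np.isfinite(col)]
            med = float(np.median(col)) if col.size else 0.0
            impute_values[d] = med
            feats[miss[:, j], j] = med
    else:
        raise ValueError(f"unknown impute mode {impute!r}")
    return DRPFeatureSet(
        cell_ids=list(sub.cell_ids),
        panel_drug_ids=feat_drugs,
        target_drug_id=target_drug,
        features=feats,
        imputed=miss,
        impute_values=impute_values,
    )


def transform_expression(x: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1)."""
    if x.transformed:
        raise ValueError("expression matrix already transformed")
    if np.any(x.values < 0):
        raise ValueError("raw TPM values must be >= 0")
    return ExpressionMatrix(
        gene_ids=list(x.gene_ids),
        cell_ids=list(x.cell_ids),
        values=np.log2(x.values + 1.0),
        transformed=True,
    )


def reduce_expression(x: ExpressionMatrix, fit_ids: list[str],
                      target_fraction: float = 0.9,
                      scale: bool = False) -> ReducedExpression:
    """PCA on log2(TPM+1) expression, fitted on ``fit_ids`` only.

    Keeps the minimal number of components whose cumulative explained
    variance reaches ``target_fraction``; all cell lines are projected.
    Centring only by default (``scale=True`` adds unit scaling).
    """
    if not x.transformed:
        raise ValueError("reduce_expression expects log2(TPM+1) input")
    if not (0 < target_fraction <= 1):
        raise ValueError("target_fraction must be in (0, 1]")
    fit_ids = [str(c) for c in fit_ids]
    unknown = [c for c in fit_ids if c not in x.cell_ids]
    if unknown:
        raise ValueError(f"fit ids not in expression matrix: {unknown}")
    if len(fit_ids) < 2:
        raise ValueError("need at least 2 cell lines to fit the projection")

    data = x.values.T  # cells x genes
    fit_idx = [x.cell_ids.index(c) for c in fit_ids]
    fit_data = data[fit_idx]
    if scale:
        sd = fit_data.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mean = fit_data.mean(axis=0)
        fit_data = (fit_data - mean) / sd
        data = (data - mean) / sd
    pca = PCA(n_components=min(fit_data.shape), svd_solver="full")
    pca.fit(fit_data)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, target_fraction - 1e-12) + 1)
    n_comp = min(n_comp, len(cum))
    scores = pca.transform(data)[:, :n_comp]
    return ReducedExpression(
        cell_ids=list(x.cell_ids),
        component_scores=scores,
        n_components=n_comp,
        explained_fraction=float(cum[n_comp - 1]),
        fit_cell_ids=fit_ids,
    )


def maccs_from_smiles(smiles_table) -> tuple[FingerprintTable, list[tuple[str, str]]]:
    """166-bit MACCS key fingerprints from a (drug_id, smiles) table.

    Returns (fingerprints, rejects) where rejects lists (drug_id, reason) for
    unparseable SMILES.  RDKit's MACCS vector has 167 positions with bit 0
    always unset; the leading dummy bit is dropped.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    rows = list(zip(smiles_table["drug_id"], smiles_table["smiles"]))
    if not rows:
        raise ValueError("empty SMILES table")
    ids, bits, rejects = [], [], []
    for drug_id, smi in rows:
        mol = Chem.MolFromSmiles(str(smi))
        if mol is None:
            rejects.append((str(drug_id), f"unparseable SMILES {smi!r}"))
            continue
        fp = MACCSkeys.GenMACCSKeys(mol)
        vec = np.zeros(167, dtype=np.uint8)
        vec[list(fp.GetOnBits())] = 1
        ids.append(str(drug_id))
        bits.append(vec[1:])  # drop the unused dummy bit
    if not ids:
        raise ValueError("no SMILES could be parsed")
    return FingerprintTable(ids, np.array(bits)), rejects
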