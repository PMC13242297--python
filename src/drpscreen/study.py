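"""Canonical synthetic-study recipes exercising the full pipeline.

Each function generates its own data from the default synthetic conditions
(200 cell lines x 100 drugs, 5 latent factors, response noise sd 0.3),
runs one published-style analysis end to end and returns the headline
numbers.  They are used by the acceptance checks and the reproduction
script; problem sizes are chosen so each study runs in about a minute on
one CPU.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import synth
from .biomarker import biomarker_workflow, enriched_panel
from .data_model import ResponseMatrix
from .features import build_drp, transform_expression
from .models_eval import (evaluate_global_and_perdrug, run_panel_benchmark,
                          screening_efficiency, split_cell_lines,
                          train_drug_model, _predict_all_drugs)
from .panel_select import Panel, select_panel, threshold_for_size
from .qsar_bridge import harmonise_drp, predict_new_lines, train_qsar


def drp_recovery_study(seed: int = 0, drug_panel_size: int = 20) -> dict:
    """Held-out recovery of per-drug response models on DRP descriptors.

    Default synthetic matrix; 80/10/10 cell-line split; a compact drug panel
    selected on training data; one model per drug trained on training lines
    and evaluated on the test lines.  A label-permuted control repeats the
    fit with training labels shuffled.  Returns global and per-drug
    correlations plus the permuted-control summary.
    """
    m, _ = synth.simulate_response_matrix(seed=seed)
    train, val, test = split_cell_lines(m.cell_ids, seed=seed)
    m_train = m.subset(cells=train)
    t, _ = threshold_for_size(m_train, "drugs", drug_panel_size, seed=seed)
    panel = select_panel(m_train, "drugs", t, seed=seed)

    preds = _predict_all_drugs(m, "DRP", panel, None, train, test, None, seed)
    g, p = evaluate_global_and_perdrug(preds)
    per_drug_r = [np.corrcoef(y, yhat)[0, 1] for y, yhat in preds.values()]

    # permutation control: each drug's label vector is permuted across all
    # cell lines before splitting, making labels independent of the features
    # everywhere; held-out correlation is then a genuine null
    rng = np.random.default_rng(seed + 10_000)
    cell_pos = {c: i for i, c in enumerate(m.cell_ids)}
    heldout = sorted(set(val) | set(test))
    null_r = []
    for j, drug in enumerate(m.drug_ids):
        fs = build_drp(m, panel, drug, impute="median", train_cell_ids=train)
        y_perm = rng.permutation(m.values[:, j])
        y_tr = y_perm[[cell_pos[c] for c in train]]
        y_ho = y_perm[[cell_pos[c] for c in heldout]]
        model = train_drug_model(fs.rows(train), y_tr, target_drug_id=drug,
                                 seed=seed, cell_ids=train)
        null_r.append(np.corrcoef(y_ho, model.predict(fs.rows(heldout)))[0, 1])
    return {
        "panel_size": len(panel),
        "median_per_drug_pearson": float(np.median(per_drug_r)),
        "global_pearson": float(g.metrics["pearson"]),
        "per_drug_mean_pearson": float(p.metrics["pearson"]),
        "permuted_median_abs_pearson": float(np.median(np.abs(null_r))),
        "n_test_lines": len(test),
    }


def descriptor_comparison_study(seed: int = 0, expression_noise_sd: float = 2.0,
                                n_replicates: int = 5) -> dict:
    """DRP vs expression descriptors under noisy transcriptomes.

    Both descriptor sets derive from the same latent truth; the expression
    noise is raised so the omics view is degraded while the DRP view keeps
    its information, and the benchmark asks which arm wins on test RMSE.
    """
    m, truth = synth.simulate_response_matrix(seed=seed)
    x = synth.simulate_expression(truth, noise_sd=expression_noise_sd,
                                  seed=seed + 1)
    xt = transform_expression(x)
    report = run_panel_benchmark(
        m, omics_raw=xt, drug_panel_size=20, cell_panel_size=50,
        n_replicates=n_replicates,
        seeds=[seed + r for r in range(n_replicates)])
    tt = report["paired_ttest_rmse"]
    return {
        "drp_rmse_mean": report["summary"]["DRP"]["rmse"][0],
        "omics_rmse_mean": report["summary"]["omics"]["rmse"][0],
        "drp_pearson_mean": report["summary"]["DRP"]["pearson"][0],
        "omics_pearson_mean": report["summary"]["omics"]["pearson"][0],
        "drp_wins": tt["drp_wins"],
        "n_replicates": n_replicates,
        "paired_ttest_p": tt["pvalue"],
    }


def biomarker_recovery_study(seed: int = 0, n_seeds: int = 5) -> dict:
    """Recovery of planted informative genes via enriched panels and SHAP.

    Per replicate: fresh default truth; 40 holdout lines reserved; a random
    40-line base panel enriched with the top/bottom 10 responders for the
    first drug; forest + SHAP biomarker report; count of the 10 planted
    genes inside the top 50 by mean |SHAP|.
    """
    hits, additivity_err = [], 0.0
    for k in range(n_seeds):
        s = seed + k
        m, truth = synth.simulate_response_matrix(seed=s)
        x = synth.simulate_expression(truth, seed=s + 5000)
        xt = transform_expression(x)
        drug = truth.drug_ids[0]
        sens = {c: float(m.values[i, 0]) for i, c in enumerate(m.cell_ids)}
        rng = np.random.default_rng(s)
        cells = list(m.cell_ids)
        holdout = sorted(np.array(cells)[rng.choice(len(cells), 40,
                                                    replace=False)])
        work = sorted(set(cells) - set(holdout))
        base = Panel("cell_lines",
                     sorted(rng.choice(work, 40, replace=False)), 0.5)
        panel = enriched_panel(base, {c: sens[c] for c in work}, n_extreme=10)
        report = biomarker_workflow(xt, sens, panel, holdout, drug, seed=s)
        hits.append(len(set(report.top_genes(50, by="shap"))
                        & set(truth.informative_genes)))
        # verify SHAP additivity on this replicate's holdout
        from .biomarker import fit_importance_model, shap_summary
        gidx = [xt.gene_ids.index(g) for g in report.gene_ids]
        pidx = [xt.cell_ids.index(c) for c in panel]
        hidx = [xt.cell_ids.index(c) for c in holdout]
        model, _ = fit_importance_model(
            xt.values[np.ix_(gidx, pidx)].T,
            np.array([sens[c] for c in panel]), seed=s)
        summ = shap_summary(model, xt.values[np.ix_(gidx, hidx)].T)
        pred = model.predict(xt.values[np.ix_(gidx, hidx)].T)
        total = summ["values"].sum(axis=1) + summ["expected_value"]
        rel = np.max(np.abs(total - pred) / np.maximum(np.abs(pred), 1e-12))
        additivity_err = max(additivity_err, float(rel))
    return {
        "hits_per_seed": hits,
        "n_seeds_recovered": int(sum(h >= 7 for h in hits)),
        "n_seeds": n_seeds,
        "max_relative_additivity_error": additivity_err,
    }


def qsar_chain_study(seed: int = 0) -> dict:
    """End-to-end QSAR harmonisation: one latent truth drives everything.

    30 panel drugs are partially measured (40% missing at random outside
    fully measured reference coverage); per-line QSAR models fill the gaps;
    DRP models trained on the harmonised panel predict 50 library drugs for
    5 held-back target lines.
    """
    m, truth = synth.simulate_response_matrix(n_lines=60, n_drugs=80,
                                              seed=seed)
    fp = synth.simulate_fingerprints(truth, seed=seed + 1)
    panel_drugs = truth.drug_ids[:30]
    lib_drugs = truth.drug_ids[30:]
    target = m.cell_ids[-5:]
    gapped = synth.mask_missing(m.subset(drugs=panel_drugs), frac=0.4,
                                seed=seed + 2)
    qsar_models = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, cell in enumerate(m.cell_ids):
            if gapped.observed[i].all():
                continue
            acts = {d: float(m.values[i, j])
                    for j, d in enumerate(m.drug_ids)}
            qsar_models[cell] = train_qsar(fp, acts, cell_id=cell,
                                           seed=seed + i)
    h = harmonise_drp(gapped, fp, panel_drugs, qsar_models)
    mask_conserved = (h.n_measured
                      == int(gapped.subset(drugs=panel_drugs).observed.sum()))

    lib = m.subset(drugs=lib_drugs)
    lv, lo = lib.values.copy(), lib.observed.copy()
    for c in target:
        i = lib.cell_ids.index(c)
        lo[i, :] = False
        lv[i, :] = np.nan
    lib_ref = ResponseMatrix(lib.cell_ids, lib.drug_ids,
                             np.where(lo, lv, np.nan), lo)
    preds = predict_new_lines(h, lib_ref, target, seed=seed)
    rs = []
    for j, d in enumerate(lib_drugs):
        yt = np.array([m.values[m.cell_ids.index(c), m.drug_ids.index(d)]
                       for c in target])
        rs.append(float(np.corrcoef(yt, preds.values[:, j])[0, 1]))
    return {
        "median_per_drug_pearson": float(np.median(rs)),
        "source_mask_conserved": bool(mask_conserved),
        "n_library_drugs": len(lib_drugs),
        "n_qsar_models": len(qsar_models),
    }


def screening_efficiency_study(seed: int = 0, n_permutations: int = 1000) -> dict:
    """The selective-compound screening statistic and its null behaviour.

    Hand-enumerable case: 10 ranked lines with positives at ranks 1, 2, 3
    and 7, recall target 0.75 -> 30% of lines must be screened.  Under
    random rankings the expected tested fraction approaches the recall
    target.
    """
    cells = [f"c{i}" for i in range(10)]
    labels = {c: 0 for c in cells}
    for i in (0, 1, 2, 6):
        labels[cells[i]] = 1
    frac_hand, _ = screening_efficiency(cells, labels, recall_target=0.75)

    # the exchangeable-rank expectation equals the recall target only
    # asymptotically (for m of k positives among n lines the expected rank
    # of the m-th positive is m(n+1)/(k+1)), so the null runs at n = 200
    # where the finite-size bias is negligible
    rng = np.random.default_rng(seed)
    big = [f"c{i}" for i in range(200)]
    big_labels = {c: int(i < 50) for i, c in enumerate(big)}
    fracs = []
    for _ in range(n_permutations):
        order = [big[i] for i in rng.permutation(len(big))]
        fracs.append(screening_efficiency(order, big_labels,
                                          recall_target=0.75)[0])
    return {
        "hand_case_fraction": float(frac_hand),
        "random_ranking_mean_fraction": float(np.mean(fracs)),
        "n_permutations": n_permutations,
    }
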