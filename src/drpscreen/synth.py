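"""Synthetic pharmacogenomic data from a single latent ground truth.

A low-rank latent-factor model ties everything together: cell lines carry
latent pathway activities, drugs load on those factors in mechanism clusters,
informative genes report individual factors, and fingerprint bits encode
cluster membership with additive potency weights.  The same truth therefore
makes DRP descriptors, expression descriptors and QSAR models all learnable,
which is the statistical premise the DRP method exploits — drugs with shared
mechanism produce correlated response columns.

Defaults (200 cell lines x 100 drugs, 5 factors, 10 mechanism clusters,
response noise sd 0.3 pIC50 units, baseline pIC50 5.5) are sized so that the
full pipeline runs in seconds while keeping a realistic signal-to-noise
ratio for a screening panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionMatrix, FingerprintTable, ResponseMatrix


@dataclass
class SyntheticTruth:
    """Latent ground truth shared by all generated tables."""

    n_factors: int
    cell_ids: list[str]
    drug_ids: list[str]
    cell_loadings: np.ndarray  # n_lines x L
    drug_loadings: np.ndarray  # n_drugs x L
    drug_offsets: np.ndarray  # per-drug baseline pIC50
    clusters: np.ndarray  # per-drug cluster index
    cluster_effects: np.ndarray  # per-cluster potency offset
    noise_sd: float
    seed: int | None
    informative_genes: dict[str, tuple[int, float]] = field(default_factory=dict)
    fingerprint_effect_bits: dict[int, dict[int, float]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_effects)

    def clean_response(self) -> np.ndarray:
        """Noise-free pIC50 matrix (offset + latent part)."""
        return self.drug_offsets[None, :] + self.cell_loadings @ self.drug_loadings.T


def simulate_response_matrix(n_lines: int = 200, n_drugs: int = 100,
                             n_factors: int = 5, n_clusters: int = 10,
                             noise_sd: float = 0.3, baseline: float = 5.5,
                             active_fraction: float | None = None,
                             within_cluster_sd: float = 0.25,
                             offset_sd: float = 0.3,
                             seed: int | None = None,
                             ) -> tuple[ResponseMatrix, SyntheticTruth]:
    """Low-rank cell-line x drug pIC50 matrix with mechanism-clustered drugs.

    value(i, j) = offset_j + u_i . v_j + N(0, noise_sd), where drug loadings
    v_j scatter around their mechanism cluster's centre.  Cluster potency
    offsets feed both drug_offsets and, later, the fingerprint bit weights,
    so structure-activity models are learnable.  If ``active_fraction`` is
    given, the matrix is shifted so that fraction of entries exceeds pIC50 6.
    """
    if n_factors > n_drugs:
        raise ValueError("n_factors must be <= n_drugs")
    if n_clusters > n_drugs:
        raise ValueError("n_clusters must be <= n_drugs")
    rng = np.random.default_rng(seed)
    cell_ids = [f"L{i:04d}" for i in range(n_lines)]
    drug_ids = [f"D{j:04d}" for j in range(n_drugs)]

    u = rng.standard_normal((n_lines, n_factors))
    # Cluster centres have equal magnitude 1/sqrt(L) on every factor with a
    # random sign pattern per mechanism: each drug integrates all modelled
    # pathway axes (so every latent factor is identifiable from any single
    # drug's response), and the latent part of each column has ~unit
    # variance, keeping pIC50 values in a plausible 1-10 band.
    scale = 1.0 / np.sqrt(n_factors)
    signs = rng.choice([-1.0, 1.0], size=(n_clusters, n_factors))
    centres = scale * signs
    clusters = np.arange(n_drugs) % n_clusters
    v = centres[clusters] + scale * within_cluster_sd * rng.standard_normal(
        (n_drugs, n_factors))
    cluster_effects = rng.standard_normal(n_clusters)
    offsets = baseline + cluster_effects[clusters] + offset_sd * rng.standard_normal(n_drugs)

    values = offsets[None, :] + u @ v.T
    values = values + noise_sd * rng.standard_normal(values.shape)
    if active_fraction is not None:
        if not (0 < active_fraction < 1):
            raise ValueError("active_fraction must be in (0, 1)")
        shift = 6.0 - float(np.quantile(values, 1.0 - active_fraction))
        values = values + shift
        offsets = offsets + shift

    truth = SyntheticTruth(
        n_factors=n_factors, cell_ids=cell_ids, drug_ids=drug_ids,
        cell_loadings=u, drug_loadings=v, drug_offsets=offsets,
        clusters=clusters, cluster_effects=cluster_effects,
        noise_sd=noise_sd, seed=seed,
    )
    m = ResponseMatrix(cell_ids, drug_ids, values, np.ones_like(values, dtype=bool))
    return m, truth


def simulate_expression(truth: SyntheticTruth, n_genes: int = 2000,
                        n_informative: int = 10, effect_sd: float = 1.0,
                        noise_sd: float = 0.5, log_mean: float = 4.0,
                        seed: int | None = None) -> ExpressionMatrix:
    """Expression matrix whose informative genes track the latent factors.

    Informative gene g on factor f(g): log2 expression is
    ``log_mean + effect(g) * u[:, f(g)] + noise``; remaining genes are pure
    noise around ``log_mean``.  Output is raw TPM (2^log2 - 1, floored at 0)
    so the log2(TPM+1) transform recovers the latent scale.  Informative-gene
    assignments and effect sizes are recorded on ``truth``.
    """
    if n_informative > n_genes:
        raise ValueError("n_informative must be <= n_genes")
    rng = np.random.default_rng(seed)
    n_lines = len(truth.cell_ids)
    gene_ids = [f"G{g:05d}" for g in range(n_genes)]
    log2x = log_mean + noise_sd * rng.standard_normal((n_genes, n_lines))
    truth.informative_genes = {}
    for k in range(n_informative):
        f = k % truth.n_factors
        effect = float(effect_sd * (1.0 + 0.25 * rng.standard_normal()))
        log2x[k, :] += effect * truth.cell_loadings[:, f]
        truth.informative_genes[gene_ids[k]] = (f, effect)
    tpm = np.maximum(np.exp2(np.maximum(log2x, 0.0)) - 1.0, 0.0)
    return ExpressionMatrix(gene_ids, list(truth.cell_ids), tpm, transformed=False)


def simulate_fingerprints(truth: SyntheticTruth, n_bits: int = 166,
                          bits_per_cluster: int = 8,
                          set_prob: float = 0.9, background_prob: float = 0.1,
                          seed: int | None = None) -> FingerprintTable:
    """Binary fingerprints whose cluster bits additively encode potency.

    Each mechanism cluster owns ``bits_per_cluster`` dedicated bit positions,
    set with probability ``set_prob`` in its member drugs; every other bit is
    random background.  Per-bit weights summing to the cluster's potency
    effect are recorded on ``truth`` so fingerprint -> activity regression is
    learnable by construction.
    """
    n_clusters = truth.n_clusters
    if bits_per_cluster * n_clusters > n_bits:
        raise ValueError("bits_per_cluster * n_clusters must be <= n_bits")
    rng = np.random.default_rng(seed)
    n_drugs = len(truth.drug_ids)
    bits = (rng.random((n_drugs, n_bits)) < background_prob).astype(np.uint8)
    truth.fingerprint_effect_bits = {}
    for c in range(n_clusters):
        pos = list(range(c * bits_per_cluster, (c + 1) * bits_per_cluster))
        weight = float(truth.cluster_effects[c]) / (set_prob * bits_per_cluster)
        truth.fingerprint_effect_bits[c] = {p: weight for p in pos}
        members = np.where(truth.clusters == c)[0]
        for p in pos:
            on = rng.random(members.size) < set_prob
            bits[members, p] = 0
            bits[members[on], p] = 1
    return FingerprintTable(list(truth.drug_ids), bits)


def mask_missing(m: ResponseMatrix, frac: float = 0.05,
                 seed: int | None = None) -> ResponseMatrix:
    """Set a uniformly random fraction of observed entries to unobserved."""
    if not (0 <= frac < 1):
        raise ValueError("frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    drop = rng.random(m.shape) < frac
    obs = m.observed & ~drop
    return ResponseMatrix(
        list(m.cell_ids), list(m.drug_ids),
        np.where(obs, m.values, np.nan), obs,
        provenance=dict(m.provenance),
    )
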