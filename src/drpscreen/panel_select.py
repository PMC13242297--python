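"""Greedy selection of compact, information-rich drug or cell-line panels.

The same procedure applies to either axis of a response matrix:

1. draw a random 70% subsample of the observation axis (so repeated
   experiments do not produce identical selections),
2. drop samples in the bottom half of response variance,
3. compute the Pearson correlation matrix among survivors
   (pairwise-complete observations),
4. rank survivors ascending by median correlation to all other survivors,
5. repeatedly select the lowest-ranked remaining sample and discard every
   remaining sample correlated with it above the threshold ``t``.

The threshold controls panel stringency: lower ``t`` gives smaller, less
redundant panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import ResponseMatrix

AXES = ("drugs", "cell_lines")


@dataclass
class Panel:
    """An ordered panel of drugs or cell lines with selection provenance."""

    axis: str
    member_ids: list[str]
    threshold: float
    subsample_ids: list[str] = field(default_factory=list)
    seed: int | None = None
    variance_cutoff: float = float("nan")

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")

    def __len__(self) -> int:
        return len(self.member_ids)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# axis={self.axis} threshold={self.threshold!r} "
                     f"seed={self.seed} n_subsample={len(self.subsample_ids)} "
                     f"variance_cutoff={self.variance_cutoff!r}\n")
            for m in self.member_ids:
                fh.write(m + "\n")

    @classmethod
    def load(cls, path) -> "Panel":
        meta: dict[str, str] = {}
        members = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            meta[k] = v
                elif line:
                    members.append(line)
        return cls(
            axis=meta.get("axis", "drugs"),
            member_ids=members,
            threshold=float(meta.get("threshold", "nan")),
            seed=int(meta["seed"]) if meta.get("seed", "None") != "None" else None,
            variance_cutoff=float(meta.get("variance_cutoff", "nan")),
        )


def _samples_view(m: ResponseMatrix, axis: str) -> tuple[list[str], np.ndarray]:
    """Return (sample ids, observations x samples matrix) for the given axis."""
    if axis == "drugs":
        return list(m.drug_ids), m.values  # rows = cell lines (observations)
    return list(m.cell_ids), m.values.T  # rows = drugs


def _variance_filter(m: ResponseMatrix, axis: str) -> tuple[list[str], float]:
    ids, data = _samples_view(m, axis)
    if len(ids) < 2:
        raise ValueError(f"need at least 2 samples on axis {axis!r}")
    variances = {}
    for j, sid in enumerate(ids):
        col = data[:, j]
        col = col[np.isfinite(col)]
        if col.size < 2:
            warnings.warn(f"sample {sid!r} has <2 observed values; excluded "
                          "from variance filter")
            continue
        variances[sid] = float(np.var(col, ddof=1))
    if not variances:
        raise ValueError("no sample has enough observations for a variance")
    cutoff = float(np.median(list(variances.values())))
    keep = [sid for sid in ids if sid in variances and variances[sid] >= cutoff]
    return keep, cutoff


def variance_filter(m: ResponseMatrix, axis: str) -> list[str]:
    """Ids on ``axis`` whose response variance is >= the median sample variance.

    Variance is computed over observed entries only.  Samples with fewer than
    two observed values cannot have a variance and are excluded with a
    warning.  Ties at the median are retained.
    """
    return _variance_filter(m, axis)[0]


def _pairwise_pearson(data: np.ndarray, min_overlap: int = 10) -> np.ndarray:
    """Pearson correlation between columns using pairwise-complete rows.

    Pairs with fewer than ``min_overlap`` shared observations get r = 0 with
    a warning.
    """
    n = data.shape[1]
    corr = np.eye(n)
    finite = np.isfinite(data)
    short = 0
    for a in range(n):
        for b in range(a + 1, n):
            both = finite[:, a] & finite[:, b]
            k = int(both.sum())
            if k < min_overlap:
                short += 1
                r = 0.0
            else:
                xa, xb = data[both, a], data[both, b]
                sa, sb = xa.std(), xb.std()
                if sa == 0 or sb == 0:
                    r = 0.0
                else:
                    r = float(np.corrcoef(xa, xb)[0, 1])
            corr[a, b] = corr[b, a] = r
    if short:
        warnings.warn(f"{short} sample pairs had < {min_overlap} shared "
                      "observations; correlation set to 0")
    return corr


def select_panel(m: ResponseMatrix, axis: str, threshold: float,
                 subsample_frac: float = 0.7, seed: int | None = None,
                 min_overlap: int = 10, absolute: bool = False,
                 rerank: bool = False) -> Panel:
    """Greedy variance-and-correlation panel selection on one axis.

    ``absolute`` switches the removal rule from signed r > t to |r| > t
    (anti-correlated samples are informative and retained by default).
    ``rerank`` recomputes the median-correlation ranking after every removal
    round instead of fixing it upfront.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    ids, data = _samples_view(m, axis)
    if len(ids) < 4:
        raise ValueError("need at least 4 samples on the selection axis")
    obs_ids = list(m.cell_ids) if axis == "drugs" else list(m.drug_ids)

    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_frac * len(obs_ids))))
    sub_idx = np.sort(rng.choice(len(obs_ids), size=n_sub, replace=False))
    sub_ids = [obs_ids[i] for i in sub_idx]
    sub = data[sub_idx, :]

    sub_m = ResponseMatrix(
        cell_ids=sub_ids if axis == "drugs" else ids,
        drug_ids=ids if axis == "drugs" else sub_ids,
        values=sub if axis == "drugs" else sub.T,
        observed=np.isfinite(sub) if axis == "drugs" else np.isfinite(sub).T,
    )
    survivors, var_cutoff = _variance_filter(sub_m, axis)
    if len(survivors) < 2:
        raise ValueError("fewer than 2 samples survive the variance filter")
    surv_idx = [ids.index(s) for s in survivors]
    surv_data = sub[:, surv_idx]

    corr = _pairwise_pearson(surv_data, min_overlap=min_overlap)
    removal = np.abs(corr) if absolute else corr

    def ranking(active: list[int]) -> list[int]:
        med = {}
        for a in active:
            others = [corr[a, b] for b in active if b != a]
            med[a] = float(np.median(others)) if others else 0.0
        return sorted(active, key=lambda a: (med[a], survivors[a]))

    active = list(range(len(survivors)))
    order = ranking(active)
    selected: list[int] = []
    while order:
        pick = order.pop(0)
        selected.append(pick)
        removed = {q for q in order if removal[pick, q] > threshold}
        order = [q for q in order if q not in removed]
        if rerank:
            order = ranking(order)
    return Panel(
        axis=axis,
        member_ids=[survivors[k] for k in selected],
        threshold=threshold,
        subsample_ids=sub_ids,
        seed=seed,
        variance_cutoff=var_cutoff,
    )


def threshold_for_size(m: ResponseMatrix, axis: str, target_size: int,
                       seed: int | None = None, resolution: float = 0.005,
                       **kwargs) -> tuple[float, int]:
    """Smallest threshold (to ``resolution``) whose panel reaches ``target_size``.

    Panel size is non-decreasing in the threshold (a higher threshold removes
    fewer correlated samples), so a bisection over the grid
    {resolution, 2*resolution, ..., 1 - resolution} applies.  Returns
    (threshold, realised panel size).
    """
    n_grid = int(round(1.0 / resolution)) - 1
    grid = [resolution * i for i in range(1, n_grid + 1)]

    def size_at(t: float) -> int:
        return len(select_panel(m, axis, t, seed=seed, **kwargs))

    if size_at(grid[-1]) < target_size:
        raise ValueError(
            f"target size {target_size} unreachable: even at threshold "
            f"{grid[-1]:.3f} the panel has {size_at(grid[-1])} members"
        )
    lo, hi = 0, len(grid) - 1  # invariant: size(grid[hi]) >= target
    while lo < hi:
        mid = (lo + hi) // 2
        if size_at(grid[mid]) >= target_size:
            hi = mid
        else:
            lo = mid + 1
    return grid[hi], size_at(grid[hi])
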