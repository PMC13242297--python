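"""Core containers and I/O for drug-response, expression and fingerprint tables.

The canonical response unit throughout the package is pIC50 = -log10(IC50 in
molar).  Readers must be told the unit of the source table; downstream code can
then rely on the fixed sensitivity threshold pIC50 >= 6 (IC50 <= 1 uM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNITS = ("pIC50_molar", "IC50_micromolar")

#: pIC50 at which a cell line counts as sensitive (IC50 = 1 uM).
SENSITIVITY_PIC50 = 6.0


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))}")
    return ids


@dataclass
class ResponseMatrix:
    """Cell line x drug matrix of pIC50 values with explicit missingness.

    ``values`` holds NaN at unobserved entries; ``observed`` is the boolean
    mask of measured entries.  ``provenance`` optionally records a free-text
    source label per drug.
    """

    cell_ids: list[str]
    drug_ids: list[str]
    values: np.ndarray
    observed: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        shape = (len(self.cell_ids), len(self.drug_ids))
        if self.values.shape != shape or self.observed.shape != shape:
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, observed "
                f"{self.observed.shape}, ids imply {shape}"
            )
        if not np.all(np.isfinite(self.values[self.observed])):
            raise ValueError("observed entries must be finite")
        # unobserved entries are never read as numbers
        self.values = np.where(self.observed, self.values, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.drug_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict[str, str] | None = None) -> "ResponseMatrix":
        vals = df.to_numpy(dtype=float)
        return cls(
            cell_ids=list(df.index.astype(str)),
            drug_ids=list(df.columns.astype(str)),
            values=vals,
            observed=np.isfinite(vals),
            provenance=provenance or {},
        )

    def subset(self, cells=None, drugs=None) -> "ResponseMatrix":
        """Restrict to the given identifiers, preserving their given order."""
        cells = self.cell_ids if cells is None else [str(c) for c in cells]
        drugs = self.drug_ids if drugs is None else [str(d) for d in drugs]
        ci = [self.cell_ids.index(c) for c in cells]
        di = [self.drug_ids.index(d) for d in drugs]
        return ResponseMatrix(
            cell_ids=cells,
            drug_ids=drugs,
            values=self.values[np.ix_(ci, di)],
            observed=self.observed[np.ix_(ci, di)],
            provenance={d: self.provenance[d] for d in drugs if d in self.provenance},
        )


@dataclass
class ExpressionMatrix:
    """Gene x cell line expression matrix, raw TPM or log2(TPM+1)."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # genes x cells
    transformed: bool = False

    def __post_init__(self):
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.gene_ids), len(self.cell_ids))
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != {shape}")
        if not self.transformed and np.any(self.values < 0):
            raise ValueError("raw TPM values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class FingerprintTable:
    """Fixed-length binary structural fingerprints (MACCS keys, 166 bits)."""

    drug_ids: list[str]
    bits: np.ndarray  # drugs x n_bits, values strictly {0,1}

    def __post_init__(self):
        self.drug_ids = _check_unique(self.drug_ids, "drug")
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.drug_ids):
            raise ValueError("bits must be (n_drugs, n_bits)")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("fingerprint bits must be strictly 0/1")

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def vector(self, drug_id: str) -> np.ndarray:
        return self.bits[self.drug_ids.index(str(drug_id))]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    """Guess the delimiter from the header line (tab, comma or semicolon)."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                for cand in ("\t", ",", ";"):
                    if cand in line:
                        return cand
                break
    return ","


def _to_pic50(values: np.ndarray, unit: str) -> np.ndarray:
    if unit == "pIC50_molar":
        return values
    if unit == "IC50_micromolar":
        # 1 uM = 1e-6 M, so pIC50 = 6 - log10(IC50[uM])
        with np.errstate(divide="ignore", invalid="ignore"):
            return 6.0 - np.log10(values)
    raise ValueError(f"unknown unit {unit!r}; expected one of {UNITS}")


def read_response_table(path, layout: str = "wide", unit: str = "pIC50_molar",
                        sep: str | None = None) -> ResponseMatrix:
    """Read a delimited response table into a :class:`ResponseMatrix`.

    Wide layout: first column cell ids, header row of drug ids, empty field =
    unobserved.  Long layout: columns (cell_id, drug_id, value).  The delimiter
    is sniffed unless given.
    """
    if unit not in UNITS:
        raise ValueError(f"unknown unit {unit!r}; expected one of {UNITS}")
    kwargs = dict(sep=sep or _sniff_sep(path), float_precision="round_trip")
    if layout == "wide":
        df = pd.read_csv(path, index_col=0, comment="#", **kwargs)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        try:
            vals = df.to_numpy(dtype=float)
        except ValueError as e:
            raise ValueError(f"non-numeric value in wide table {path}: {e}") from e
        obs = np.isfinite(vals)
        vals = np.where(obs, _to_pic50(vals, unit), np.nan)
        return ResponseMatrix(list(df.index), list(df.columns), vals, obs)
    if layout == "long":
        df = pd.read_csv(path, comment="#", **kwargs)
        if df.shape[1] < 3:
            raise ValueError("long layout requires columns (cell_id, drug_id, value)")
        df = df.iloc[:, :3]
        df.columns = ["cell_id", "drug_id", "value"]
        df["cell_id"] = df["cell_id"].astype(str)
        df["drug_id"] = df["drug_id"].astype(str)
        for rownum, v in zip(df.index, df["value"]):
            if not (pd.isna(v) or isinstance(v, (int, float, np.number))):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {v!r} at row {rownum + 2} of {path}"
                    ) from None
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        dup = df.duplicated(subset=["cell_id", "drug_id"], keep=False)
        if dup.any():
            pair = df.loc[dup, ["cell_id", "drug_id"]].iloc[0]
            raise ValueError(
                f"duplicate (cell, drug) pair ({pair.cell_id}, {pair.drug_id}) in {path}"
            )
        cells = list(dict.fromkeys(df["cell_id"]))
        drugs = list(dict.fromkeys(df["drug_id"]))
        vals = np.full((len(cells), len(drugs)), np.nan)
        ci = {c: i for i, c in enumerate(cells)}
        di = {d: j for j, d in enumerate(drugs)}
        for _, row in df.iterrows():
            if pd.notna(row.value):
                vals[ci[row.cell_id], di[row.drug_id]] = row.value
        obs = np.isfinite(vals)
        vals = np.where(obs, _to_pic50(vals, unit), np.nan)
        return ResponseMatrix(cells, drugs, vals, obs)
    raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def write_response_table(m: ResponseMatrix, path, layout: str = "wide",
                         sep: str = "\t") -> None:
    """Write a response matrix (pIC50) back to delimited text."""
    if layout == "wide":
        m.to_frame().to_csv(path, sep=sep, na_rep="")
    elif layout == "long":
        rows = []
        for i, c in enumerate(m.cell_ids):
            for j, d in enumerate(m.drug_ids):
                if m.observed[i, j]:
                    rows.append((c, d, repr(float(m.values[i, j]))))
        pd.DataFrame(rows, columns=["cell_id", "drug_id", "value"]).to_csv(
            path, sep=sep, index=False
        )
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_expression_table(path, sep: str | None = None,
                          transformed: bool = False) -> ExpressionMatrix:
    """Read a gene x cell-line expression table (rows = genes)."""
    kwargs = dict(sep=sep or _sniff_sep(path), float_precision="round_trip")
    df = pd.read_csv(path, index_col=0, comment="#", **kwargs)
    return ExpressionMatrix(
        gene_ids=list(df.index.astype(str)),
        cell_ids=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        transformed=transformed,
    )


def write_expression_table(x: ExpressionMatrix, path, sep: str = "\t") -> None:
    x.to_frame().to_csv(path, sep=sep)


def read_smiles_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a (drug_id, smiles) table."""
    kwargs = dict(sep=sep or _sniff_sep(path), float_precision="round_trip")
    df = pd.read_csv(path, comment="#", **kwargs)
    df = df.iloc[:, :2]
    df.columns = ["drug_id", "smiles"]
    df["drug_id"] = df["drug_id"].astype(str)
    return df


def read_fingerprint_table(path, sep: str = "\t") -> FingerprintTable:
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    return FingerprintTable(list(df.index.astype(str)), df.to_numpy())


def write_fingerprint_table(fp: FingerprintTable, path, sep: str = "\t") -> None:
    pd.DataFrame(
        fp.bits, index=fp.drug_ids,
        columns=[f"bit{i}" for i in range(fp.n_bits)],
    ).to_csv(path, sep=sep, index_label="drug_id")


# ---------------------------------------------------------------------------
# consolidation filters
# ---------------------------------------------------------------------------

def dedupe_by_fingerprint(fp: FingerprintTable, names: list[str]) -> dict[str, str]:
    """Map drug ids with bit-identical fingerprints to one canonical id.

    Drugs whose fingerprints are exactly identical (Tanimoto 1.0) map to the
    first member of the group in a stable sort of ids; all others map to
    themselves.  Every name must have a fingerprint.
    """
    names = [str(n) for n in names]
    missing = [n for n in names if n not in fp.drug_ids]
    if missing:
        raise ValueError(f"drugs without fingerprints: {sorted(missing)}")
    groups: dict[bytes, list[str]] = {}
    for n in names:
        groups.setdefault(fp.vector(n).tobytes(), []).append(n)
    mapping = {}
    for members in groups.values():
        canonical = sorted(members)[0]
        for n in members:
            mapping[n] = canonical
    return mapping


def coverage_filter(m: ResponseMatrix, drug_cov: float = 0.9,
                    line_cov: float = 0.9) -> ResponseMatrix:
    """Two-pass coverage filter on a response matrix.

    Pass 1 keeps drugs observed in strictly more than ``drug_cov`` of cell
    lines ("over 90% coverage"); pass 2 keeps cell lines observed for at least
    ``line_cov`` of the retained drugs ("at least 90%").  Order preserved.
    """
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("empty response matrix")
    drug_frac = m.observed.mean(axis=0)
    keep_drugs = [d for d, f in zip(m.drug_ids, drug_frac) if f > drug_cov]
    if not keep_drugs:
        raise ValueError(
            f"drug coverage pass (> {drug_cov:.0%}) removed every drug"
        )
    sub = m.subset(drugs=keep_drugs)
    line_frac = sub.observed.mean(axis=1)
    keep_cells = [c for c, f in zip(sub.cell_ids, line_frac) if f >= line_cov]
    if not keep_cells:
        raise ValueError(
            f"cell-line coverage pass (>= {line_cov:.0%}) removed every cell line"
        )
    return sub.subset(cells=keep_cells)


def _resolve_aliases(alias_map: dict[str, str]) -> dict[str, str]:
    """Resolve alias chains to final targets, rejecting cycles."""
    resolved = {}
    for src in alias_map:
        cur, seen = src, {src}
        while cur in alias_map:
            cur = alias_map[cur]
            if cur in seen:
                raise ValueError(f"alias cycle involving {src!r}")
            seen.add(cur)
        resolved[src] = cur
    return resolved


def merge_sources(matrices: list[ResponseMatrix],
                  alias_map: dict[str, str] | None = None,
                  canonical_drugs: dict[str, str] | None = None,
                  source_names: list[str] | None = None) -> ResponseMatrix:
    """Merge response matrices from several sources into one.

    Cell ids are renamed through ``alias_map`` and drug ids through
    ``canonical_drugs`` (from :func:`dedupe_by_fingerprint`).  When the same
    (cell, canonical drug) pair is observed in several sources, the
    earliest-listed source wins; the number of such conflicts is logged.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    alias = _resolve_aliases(alias_map or {})
    cdrug = canonical_drugs or {}
    if source_names is None:
        source_names = [f"source{i}" for i in range(len(matrices))]

    cells: list[str] = []
    drugs: list[str] = []
    for m in matrices:
        for c in m.cell_ids:
            c2 = alias.get(c, c)
            if c2 not in cells:
                cells.append(c2)
        for d in m.drug_ids:
            d2 = cdrug.get(d, d)
            if d2 not in drugs:
                drugs.append(d2)

    vals = np.full((len(cells), len(drugs)), np.nan)
    obs = np.zeros_like(vals, dtype=bool)
    prov: dict[str, str] = {}
    ci = {c: i for i, c in enumerate(cells)}
    di = {d: j for j, d in enumerate(drugs)}
    conflicts = 0
    for m, sname in zip(matrices, source_names):
        for jj, d in enumerate(m.drug_ids):
            d2 = cdrug.get(d, d)
            prov.setdefault(d2, sname)
            j = di[d2]
            for ii, c in enumerate(m.cell_ids):
                if not m.observed[ii, jj]:
                    continue
                i = ci[alias.get(c, c)]
                if obs[i, j]:
                    conflicts += 1  # earliest source keeps precedence
                else:
                    vals[i, j] = m.values[ii, jj]
                    obs[i, j] = True
    if conflicts:
        logger.info("merge_sources: %d multiply-observed pairs resolved by "
                    "source precedence", conflicts)
    out = ResponseMatrix(cells, drugs, vals, obs, provenance=prov)
    out.conflict_count = conflicts
    return out
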