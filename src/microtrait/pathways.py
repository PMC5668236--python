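"""Association of predicted functional-pathway relative abundances with
serum traits by univariate linear regression, with the standard presence/
abundance filters and the same permutation-FDR calibration used for OTUs.

The pathway table is the output of a 16S-based function predictor (e.g.
PICRUSt); prediction itself is upstream of this package.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_design, ols_last_coefficient, orth_basis
from .tables import ParseError, ValidationError, _check_unique
from .twopart import P_FLOOR, FdrResult, permutation_fdr

__all__ = [
    "PathwayTable",
    "read_pathway_table",
    "filter_pathways",
    "pathway_regression",
    "PathwayAssociation",
    "PathwayResults",
]

UNCLASSIFIED = "unclassified"


class PathwayTable:
    """Pathways x samples relative abundances with an optional KEGG category
    label per pathway."""

    def __init__(self, data: pd.DataFrame, categories: pd.Series | None = None):
        frame = pd.DataFrame(data)
        _check_unique(frame.index, "pathway")
        _check_unique(frame.columns, "sample")
        vals = frame.to_numpy(dtype=float)
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise ValidationError("pathway abundances must be finite and >= 0")
        self.data = frame
        if categories is not None:
            categories = pd.Series(categories).reindex(frame.index)
        self.categories = categories

    @property
    def pathway_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids) -> "PathwayTable":
        return PathwayTable(self.data.loc[:, list(sample_ids)], self.categories)


def read_pathway_table(path) -> PathwayTable:
    """TSV with pathway id in the first column, an optional ``category``
    second column, then per-sample abundances."""
    raw = pd.read_csv(path, sep="\t")
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected pathway id plus data columns")
    raw = raw.set_index(raw.columns[0])
    categories = None
    if str(raw.columns[0]).strip().lower() == "category":
        categories = raw.iloc[:, 0].astype(str)
        raw = raw.iloc[:, 1:]
    return PathwayTable(raw.astype(float), categories)


def _is_unclassified(label: str) -> bool:
    return UNCLASSIFIED in str(label).strip().lower()


def filter_pathways(table: PathwayTable, min_presence: float = 0.8,
                    min_abund: float = 1e-4) -> tuple[PathwayTable, pd.DataFrame]:
    """Keep pathways present in strictly more than ``min_presence`` of
    samples with mean relative abundance strictly above ``min_abund``;
    unclassified terms are dropped regardless."""
    for name, thr in (("min_presence", min_presence), ("min_abund", min_abund)):
        if not 0.0 < thr < 1.0:
            raise ValidationError(f"{name} must lie in (0, 1), got {thr}")
    vals = table.data.to_numpy(dtype=float)
    presence = (vals > 0).mean(axis=1)
    mean_abund = vals.mean(axis=1)
    unclassified = np.array([_is_unclassified(p) for p in table.pathway_ids])
    if table.categories is not None:
        unclassified |= np.array([_is_unclassified(c) for c in table.categories])
    kept = (presence > min_presence) & (mean_abund > min_abund) & ~unclassified
    report = pd.DataFrame({
        "pathway_id": table.pathway_ids,
        "presence": presence,
        "mean_rel_abund": mean_abund,
        "unclassified": unclassified,
        "kept": kept,
    }).set_index("pathway_id")
    cats = table.categories[kept] if table.categories is not None else None
    return PathwayTable(table.data.loc[kept], cats), report


def pathway_regression(trait, abundance, covariates=None):
    """Univariate OLS of trait on a pathway's relative abundance.

    Returns (beta, T, P); T = beta/SE(beta) is the heatmap statistic.
    Covariates default to none (plain univariate regression) but can be
    supplied for adjusted runs. Zero-variance pathways raise.
    """
    trait = np.asarray(trait, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if np.ptp(abundance) == 0:
        raise ValidationError("zero-variance pathway abundance")
    X = np.column_stack([build_design(covariates, len(trait)), abundance])
    beta, se, t, df, p = ols_last_coefficient(trait, X)
    return float(beta), float(t), float(p)


class PathwayAssociation:
    """Univariate pathway-trait regressions across a table, with permutation
    FDR (trait residuals permuted, all pathways rescanned per round)."""

    def __init__(self, trait, table: PathwayTable, covariates=None,
                 trait_name: str = "trait"):
        self.trait = np.asarray(trait, dtype=float)
        if self.trait.shape[0] != table.n_samples:
            raise ValidationError("trait length does not match sample count")
        self.table = table
        self.covariates = covariates
        self.trait_name = trait_name
        A = table.data.to_numpy(dtype=float)
        self.Xc = build_design(covariates, table.n_samples)
        self.Qc = orth_basis(self.Xc)
        R = A - (A @ self.Qc) @ self.Qc.T
        norms = np.linalg.norm(R, axis=1)
        self.ok = norms > 1e-8 * np.sqrt(table.n_samples)
        self.norms = np.where(self.ok, norms, np.nan)
        self.Qx = np.where(self.ok[:, None],
                           R / np.where(norms == 0, 1, norms)[:, None], 0.0)
        self.df = table.n_samples - self.Qc.shape[1] - 1

    def _scan(self, Y: np.ndarray):
        QtY = self.Qc.T @ Y
        rss0 = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", QtY, QtY)
        proj = self.Qx @ Y
        rss = np.maximum(rss0[None, :] - proj**2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = proj / np.sqrt(rss / self.df)
        p = np.maximum(2.0 * stats.t.sf(np.abs(t), self.df), P_FLOOR)
        p[~self.ok] = np.nan
        t[~self.ok] = np.nan
        return t, p, proj / self.norms[:, None]

    def fit(self, n_perm: int = 0, seed=None, alpha: float = 0.05) -> "PathwayResults":
        y = self.trait
        t, p, beta = self._scan(y[:, None])
        frame = pd.DataFrame({
            "pathway_id": self.table.pathway_ids,
            "beta": beta[:, 0],
            "T": t[:, 0],
            "P": p[:, 0],
            "q_value": np.nan,
        }).set_index("pathway_id")
        if self.table.categories is not None:
            frame.insert(0, "category", self.table.categories.to_numpy())
        fdr = None
        if n_perm:
            yhat = self.Qc @ (self.Qc.T @ y)
            resid = y - yhat
            rng = np.random.default_rng(seed)
            Y = np.empty((len(y), n_perm))
            for b in range(n_perm):
                Y[:, b] = yhat + resid[rng.permutation(len(y))]
            _, p_perm, _ = self._scan(Y)
            fdr = permutation_fdr(frame["P"].to_numpy(), p_perm, alpha=alpha)
            frame["q_value"] = fdr.q_values
        return PathwayResults(frame, self.trait_name, fdr)


class PathwayResults:
    def __init__(self, frame: pd.DataFrame, trait_name: str,
                 fdr: FdrResult | None):
        self.frame = frame
        self.trait_name = trait_name
        self.fdr = fdr

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        if self.fdr is None:
            raise ValidationError("fit with n_perm > 0 to obtain q-values")
        alpha = self.fdr.alpha if alpha is None else alpha
        return self.frame[self.frame["q_value"] < alpha]

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    def summary(self) -> str:
        lines = [f"Pathway association: {self.trait_name}",
                 "=" * 40,
                 f"pathways tested: {int(self.frame['P'].notna().sum())}"]
        if self.fdr is not None:
            lines.append(f"permutations: {self.fdr.n_perm}   "
                         f"significant at FDR<{self.fdr.alpha}: "
                         f"{len(self.significant())}")
        top = self.frame.nsmallest(min(5, len(self.frame)), "P")
        lines.append(top.to_string())
        return "\n".join(lines)
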