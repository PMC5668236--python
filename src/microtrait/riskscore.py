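"""Microbial risk score and cross-validated trait variance explained.

The fraction of serum-trait variance attributable to the gut microbiome is
estimated by repeated 70/30 discovery/validation splits: the two-part
association is fitted on the discovery set, the features passing a P-value
threshold enter an additive risk score

    r_m = sum_j ( beta1_j * b_j + beta2_j * q_j )

where b_j is presence of feature j in a validation sample and q_j its
discovery-standardised log10 relative abundance (term omitted when absent).
The score's incremental (partial) R^2 over sex and batch on the validation
samples, averaged over repeats, is the variance explained; sweeping the
threshold grid traces how it grows as weaker associations join the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import build_design, ols_r2
from .tables import OtuTable, PhenotypeTable, ValidationError
from .twopart import TwoPartAssociation

__all__ = [
    "DEFAULT_GRID",
    "RiskFeature",
    "RiskModel",
    "split_discovery_validation",
    "fit_risk_model",
    "risk_score",
    "explained_variance",
    "MicrobiomeVarianceExplained",
    "VarianceExplainedResults",
]

DEFAULT_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.1)


@dataclass
class RiskFeature:
    """Per-feature risk-score weights; a part that was not computable in the
    discovery set contributes nothing (its beta is None)."""

    feature_id: str
    beta1: float | None
    beta2: float | None
    transform_mean: float = np.nan
    transform_sd: float = np.nan
    p_final: float = np.nan


@dataclass
class RiskModel:
    """Additive microbial risk score fitted on a discovery set."""

    trait: str
    threshold: float
    features: list = field(default_factory=list)
    discovery_ids: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def score(self, table: OtuTable) -> pd.Series:
        """r_m per sample of ``table`` (relative abundance is taken
        internally). An empty model scores 0 everywhere."""
        rel = table.relative_abundance() if table.kind == "counts" else table
        out = np.zeros(rel.n_samples)
        index = rel.data.index
        for feat in self.features:
            if feat.feature_id not in index:
                continue  # absent feature: b_j = 0 and no abundance term
            a = rel.data.loc[feat.feature_id].to_numpy(dtype=float)
            present = a > 0
            if feat.beta1 is not None:
                out += feat.beta1 * present
            if feat.beta2 is not None and feat.transform_sd > 0:
                q = np.zeros_like(a)
                q[present] = (np.log10(a[present]) - feat.transform_mean) \
                    / feat.transform_sd
                out += feat.beta2 * q
        return pd.Series(out, index=rel.sample_ids, name="r_m")


def split_discovery_validation(sample_ids, fraction: float = 0.7, seed=None):
    """Random disjoint, exhaustive split; discovery size = round(fraction*N).

    Deterministic per seed (also accepts a Generator). Either side smaller
    than 10 samples is an error.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"split fraction must lie in (0, 1), got {fraction}")
    ids = list(sample_ids)
    n = len(ids)
    n_disc = int(round(fraction * n))
    if min(n_disc, n - n_disc) < 10:
        raise ValidationError(
            f"split of {n} at {fraction} leaves a set below 10 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    discovery = [ids[i] for i in sorted(perm[:n_disc])]
    validation = [ids[i] for i in sorted(perm[n_disc:])]
    return discovery, validation


def fit_risk_model(results_frame: pd.DataFrame, threshold: float,
                   trait: str = "trait", discovery_ids=()) -> RiskModel:
    """Build a RiskModel from a discovery two-part results frame, selecting
    features with final P <= threshold."""
    sel = results_frame[results_frame["P_final"].notna()
                        & (results_frame["P_final"] <= threshold)]
    feats = []
    for fid, row in sel.iterrows():
        feats.append(RiskFeature(
            feature_id=fid,
            beta1=float(row["beta1"]) if np.isfinite(row["beta1"]) else None,
            beta2=float(row["beta2"]) if np.isfinite(row["beta2"]) else None,
            transform_mean=float(row["transform_mean"]),
            transform_sd=float(row["transform_sd"]),
            p_final=float(row["P_final"]),
        ))
    return RiskModel(trait=trait, threshold=threshold, features=feats,
                     discovery_ids=list(discovery_ids))


def risk_score(model: RiskModel, table: OtuTable) -> pd.Series:
    return model.score(table)


def explained_variance(scores, trait, covariates=None) -> float:
    """Incremental R^2 of the risk score over the covariates.

    R^2(trait ~ covariates + r_m) - R^2(trait ~ covariates), floored at 0.
    A constant score returns 0 with a warning.
    """
    y = np.asarray(trait, dtype=float)
    r = np.asarray(scores, dtype=float)
    if len(y) < 10:
        raise ValidationError("need at least 10 validation samples")
    X0 = build_design(covariates, len(y))
    if np.ptp(r) == 0:
        warnings.warn("constant risk score; explained variance is 0", stacklevel=2)
        return 0.0
    r2_0 = ols_r2(y, X0)
    r2_1 = ols_r2(y, np.column_stack([X0, r]))
    return max(r2_1 - r2_0, 0.0)


class MicrobiomeVarianceExplained:
    """Cross-validated estimate of the trait variance explained by the
    microbiome over a threshold grid.

    Parameters
    ----------
    table, pheno : aligned feature table and phenotypes.
    trait : trait column name.
    covariates : covariate names used both in the discovery association and
        in the validation partial-R^2 (default sex + batch).
    grid : P-value thresholds to sweep (default 1e-5 ... 0.1).
    split_fraction : discovery fraction per repeat (default 0.7).
    """

    def __init__(self, table: OtuTable, pheno: PhenotypeTable, trait: str,
                 covariates=("sex", "batch"), grid=DEFAULT_GRID,
                 split_fraction: float = 0.7, min_present: int = 10,
                 association_covariates: bool = True):
        grid = tuple(sorted(float(g) for g in grid))
        if any(not 0.0 < g <= 1.0 for g in grid):
            raise ValidationError("grid thresholds must lie in (0, 1]")
        shared = [s for s in table.sample_ids if s in set(pheno.sample_ids)]
        self.table = table.select_samples(shared).relative_abundance()
        self.pheno = pheno
        self.trait = trait
        self.covariate_names = tuple(covariates) if covariates else ()
        self.grid = grid
        self.split_fraction = split_fraction
        self.min_present = min_present
        self.association_covariates = association_covariates
        self.sample_ids = shared

    def _one_repeat(self, rng: np.random.Generator):
        disc_ids, valid_ids = split_discovery_validation(
            self.sample_ids, self.split_fraction, seed=rng)
        disc_tab = self.table.select_samples(disc_ids)
        y_disc = self.pheno.trait(self.trait).loc[disc_ids].to_numpy(dtype=float)
        cov_disc = (self.pheno.covariates(self.covariate_names).loc[disc_ids]
                    if (self.covariate_names and self.association_covariates)
                    else None)
        assoc = TwoPartAssociation(
            y_disc, disc_tab, covariates=cov_disc,
            min_present=self.min_present, trait_name=self.trait).fit()

        valid_tab = self.table.select_samples(valid_ids)
        y_valid = self.pheno.trait(self.trait).loc[valid_ids].to_numpy(dtype=float)
        cov_valid = (self.pheno.covariates(self.covariate_names).loc[valid_ids]
                     if self.covariate_names else None)
        row = []
        for thr in self.grid:
            model = fit_risk_model(assoc.frame, thr, trait=self.trait,
                                   discovery_ids=disc_ids)
            if model.n_features == 0:
                row.append((0.0, 0))
                continue
            scores = model.score(valid_tab).to_numpy()
            if np.ptp(scores) == 0:
                row.append((0.0, model.n_features))
                continue
            r2 = explained_variance(scores, y_valid, cov_valid)
            row.append((r2, model.n_features))
        return row

    def fit(self, repeats: int = 100, seed=None) -> "VarianceExplainedResults":
        if repeats < 2:
            raise ValidationError("need at least 2 cross-validation repeats")
        children = np.random.SeedSequence(seed).spawn(repeats)
        r2 = np.full((repeats, len(self.grid)), np.nan)
        nsel = np.full((repeats, len(self.grid)), np.nan)
        failures = []
        for rep, child in enumerate(children):
            try:
                row = self._one_repeat(np.random.default_rng(child))
            except Exception as exc:  # pragma: no cover - defensive
                failures.append((rep, repr(exc)))
                continue
            r2[rep] = [v for v, _ in row]
            nsel[rep] = [k for _, k in row]
        if failures:
            warnings.warn(f"{len(failures)} repeats failed: {failures[:3]}",
                          stacklevel=2)
            if len(failures) > 0.2 * repeats:
                raise RuntimeError(
                    f"{len(failures)}/{repeats} cross-validation repeats failed")
        ok = np.isfinite(r2).all(axis=1)
        curve = pd.DataFrame({
            "trait": self.trait,
            "threshold": self.grid,
            "mean_R2": r2[ok].mean(axis=0),
            "sd_R2": r2[ok].std(axis=0, ddof=1),
            "mean_n_selected": nsel[ok].mean(axis=0),
            "repeats": int(ok.sum()),
        })
        return VarianceExplainedResults(curve, r2[ok], trait=self.trait,
                                        seed=seed)


class VarianceExplainedResults:
    """CV curve of mean R^2 per threshold plus the per-repeat matrix."""

    def __init__(self, curve: pd.DataFrame, r2_matrix: np.ndarray, trait: str,
                 seed=None):
        self.curve = curve
        self.r2_matrix = r2_matrix
        self.trait = trait
        self.seed = seed

    @property
    def max_mean_r2(self) -> float:
        return float(self.curve["mean_R2"].max())

    @property
    def best_threshold(self) -> float:
        return float(self.curve.loc[self.curve["mean_R2"].idxmax(), "threshold"])

    def write_tsv(self, path) -> None:
        self.curve.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [f"Microbiome variance explained: {self.trait}",
                 "=" * 44,
                 self.curve.to_string(index=False),
                 f"\nmax mean R^2 = {self.max_mean_r2:.4f} at threshold "
                 f"{self.best_threshold:g}"]
        return "\n".join(lines)
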