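"""Two-part microbe-trait association with permutation-based FDR.

A zero-inflated feature is decomposed into a presence/absence indicator and
an abundance-given-presence value. Three association tests are run per
feature against a serum trait:

* binary part — OLS of the trait on the 0/1 presence indicator (plus
  covariates), giving beta1 and a two-tailed P;
* quantitative part — OLS of the trait on the z-standardised log10 relative
  abundance among the samples where the feature is present, giving beta2;
* meta part — the two signed normal scores combined with the unweighted
  Z-score (Stouffer) method, Z_meta = (Z_b + Z_q)/sqrt(2).

The per-feature final P is the minimum over the parts actually computed and
its source labels which part won. Because the min-P statistic is
anti-conservative, significance is calibrated by permuting covariate-adjusted
trait residuals (Freedman-Lane) and recomputing all final P values per
permutation; q-values are plug-in FDR estimates against that null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import build_design, ols_last_coefficient, orth_basis
from .tables import OtuTable, PhenotypeTable, ValidationError, UNASSIGNED

__all__ = [
    "PartResult",
    "AssociationResult",
    "FdrResult",
    "binary_test",
    "quantitative_test",
    "meta_combine",
    "two_part_test",
    "permutation_fdr",
    "summarize_sources",
    "TwoPartAssociation",
    "TwoPartResults",
]

P_FLOOR = 1e-300
# tie-break priority when parts share the minimal P: meta > quantitative > binary
SOURCE_ORDER = ("meta", "quantitative", "binary")
DEFAULT_PREVALENCE_BOUNDS = (0.05, 0.95)
DEFAULT_MIN_PRESENT = 10


def signed_z(p, sign):
    """Signed normal score: |z| solves the two-tailed P, the sign follows the
    effect direction. P is floored at 1e-300 before inversion."""
    p = np.maximum(np.asarray(p, dtype=float), P_FLOOR)
    return -special.ndtri(p / 2.0) * np.sign(np.where(sign == 0, 1.0, sign))


def meta_combine(z_binary, z_quant):
    """Unweighted Stouffer combination of two signed Z scores.

    Returns (Z_meta, P_meta) with Z_meta = (Z_b + Z_q)/sqrt(2) and P_meta the
    two-tailed normal tail probability. Symmetric and monotone in each
    argument.
    """
    zb = np.asarray(z_binary, dtype=float)
    zq = np.asarray(z_quant, dtype=float)
    z = (zb + zq) / np.sqrt(2.0)
    p = 2.0 * special.ndtr(-np.abs(z))
    return z, np.maximum(p, P_FLOOR)


@dataclass
class PartResult:
    """One part of the two-part test (binary or quantitative)."""

    computed: bool
    reason: str | None = None
    beta: float = np.nan
    se: float = np.nan
    t: float = np.nan
    df: float = np.nan
    p: float = np.nan
    z: float = np.nan
    n: int = 0
    transform_mean: float = np.nan
    transform_sd: float = np.nan


def _finish_part(beta, se, t, df, p, n, **extra) -> PartResult:
    if not np.isfinite(p):
        return PartResult(False, reason="degenerate regression", n=n, **extra)
    p = max(p, P_FLOOR)
    z = float(signed_z(p, np.sign(beta) if beta != 0 else 1.0))
    return PartResult(True, beta=beta, se=se, t=t, df=df, p=p, z=z, n=n, **extra)


def binary_test(trait, presence, covariates=None) -> PartResult:
    """OLS of trait on the 0/1 presence indicator plus covariates.

    A constant indicator marks the part not-computed (never P = 1).
    """
    trait = np.asarray(trait, dtype=float)
    presence = np.asarray(presence, dtype=float)
    if set(np.unique(presence)) - {0.0, 1.0}:
        raise ValidationError("presence must be coded 0/1")
    if len(np.unique(presence)) < 2:
        return PartResult(False, reason="presence constant", n=len(trait))
    X = np.column_stack([build_design(covariates, len(trait)), presence])
    beta, se, t, df, p = ols_last_coefficient(trait, X)
    return _finish_part(beta, se, t, df, p, n=len(trait))


def quantitative_test(trait, abundance, covariates=None,
                      min_present: int = DEFAULT_MIN_PRESENT) -> PartResult:
    """OLS of trait on z-standardised log10 relative abundance, restricted to
    the samples where the feature is present.

    The transform parameters (mean/SD of log10 abundance among present
    samples, SD with ddof=1) are stored for reuse when scoring new samples.
    """
    trait = np.asarray(trait, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    mask = abundance > 0
    n_present = int(mask.sum())
    if n_present < min_present:
        return PartResult(False, reason=f"only {n_present} present samples",
                          n=n_present)
    la = np.log10(abundance[mask])
    mu, sd = float(la.mean()), float(la.std(ddof=1))
    if sd == 0.0:
        return PartResult(False, reason="zero abundance variance",
                          n=n_present, transform_mean=mu, transform_sd=sd)
    q = (la - mu) / sd
    # build the full-cohort design once, then subset rows: keeps dummy coding
    # identical whether or not a covariate level drops out of the subset
    Xfull = build_design(covariates, len(trait))
    X = np.column_stack([Xfull[mask], q])
    beta, se, t, df, p = ols_last_coefficient(trait[mask], X)
    return _finish_part(beta, se, t, df, p, n=n_present,
                        transform_mean=mu, transform_sd=sd)


@dataclass
class AssociationResult:
    """Per-feature association record across the three parts."""

    feature_id: str
    prevalence: float
    n_present: int
    binary: PartResult
    quantitative: PartResult
    z_meta: float = np.nan
    p_meta: float = np.nan
    p_final: float = np.nan
    source: str | None = None
    q_value: float = np.nan

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "prevalence": self.prevalence,
            "n_present": self.n_present,
            "beta1": self.binary.beta,
            "Z_binary": self.binary.z,
            "P_binary": self.binary.p,
            "beta2": self.quantitative.beta,
            "Z_quant": self.quantitative.z,
            "P_quant": self.quantitative.p,
            "transform_mean": self.quantitative.transform_mean,
            "transform_sd": self.quantitative.transform_sd,
            "Z_meta": self.z_meta,
            "P_meta": self.p_meta,
            "P_final": self.p_final,
            "source": self.source,
            "q_value": self.q_value,
        }


def _min_p_source(p_binary, p_quant, p_meta):
    """Minimum over computed parts with tie-break meta > quantitative > binary."""
    parts = {"meta": p_meta, "quantitative": p_quant, "binary": p_binary}
    best, label = np.inf, None
    for name in SOURCE_ORDER:
        p = parts[name]
        if np.isfinite(p) and p < best:
            best, label = p, name
    if label is None:
        return np.nan, None
    return best, label


def two_part_test(trait, abundance, covariates=None, feature_id: str = "",
                  min_present: int = DEFAULT_MIN_PRESENT,
                  prevalence_bounds=DEFAULT_PREVALENCE_BOUNDS) -> AssociationResult:
    """Run binary, quantitative and meta parts for one feature.

    The binary part is skipped at extreme prevalence (outside
    ``prevalence_bounds``) where the indicator is near-constant; the meta part
    requires both single parts. The final P is the minimum over computed
    parts; if no part is computable P_final is NaN and source None.
    """
    abundance = np.asarray(abundance, dtype=float)
    presence = (abundance > 0).astype(float)
    prevalence = float(presence.mean())
    lo, hi = prevalence_bounds
    if lo <= prevalence <= hi:
        b = binary_test(trait, presence, covariates)
    else:
        b = PartResult(False, reason=f"prevalence {prevalence:.3f} outside "
                                     f"[{lo}, {hi}]", n=len(presence))
    q = quantitative_test(trait, abundance, covariates, min_present=min_present)
    res = AssociationResult(feature_id=feature_id, prevalence=prevalence,
                            n_present=int(presence.sum()), binary=b,
                            quantitative=q)
    if b.computed and q.computed:
        zm, pm = meta_combine(b.z, q.z)
        res.z_meta, res.p_meta = float(zm), float(pm)
    res.p_final, res.source = _min_p_source(
        b.p if b.computed else np.nan,
        q.p if q.computed else np.nan,
        res.p_meta,
    )
    return res


# ---------------------------------------------------------------------------
# vectorised engine: many trait vectors (observed + permutations) at once


class _TwoPartEngine:
    """Precomputes per-feature projections so the full two-part scan can be
    applied to a whole matrix of trait vectors (columns = observed trait or
    residual permutations) with one pass of dense linear algebra.

    Identical statistics to the per-feature functions (checked in tests);
    exists because the permutation FDR needs hundreds of full scans.
    """

    def __init__(self, abundance: np.ndarray, covariate_frame=None,
                 min_present: int = DEFAULT_MIN_PRESENT,
                 prevalence_bounds=DEFAULT_PREVALENCE_BOUNDS):
        A = np.asarray(abundance, dtype=float)
        self.F, self.n = A.shape
        self.Xc = build_design(covariate_frame, self.n)
        self.Qc = orth_basis(self.Xc)
        r = self.Qc.shape[1]
        self.df_binary = self.n - r - 1

        presence = A > 0
        self.prevalence = presence.mean(axis=1)
        self.n_present = presence.sum(axis=1)
        lo, hi = prevalence_bounds
        bin_ok = (self.prevalence >= lo) & (self.prevalence <= hi)
        bin_ok &= self.df_binary > 0
        B = presence.astype(float)
        Rb = B - (B @ self.Qc) @ self.Qc.T
        norms = np.linalg.norm(Rb, axis=1)
        bin_ok &= norms > 1e-8 * np.sqrt(self.n)
        self.bin_ok = bin_ok
        self.bin_norm = np.where(bin_ok, norms, np.nan)
        self.Qb = np.where(bin_ok[:, None], Rb / np.where(norms == 0, 1, norms)[:, None], 0.0)

        # quantitative part: per-feature present-sample subset
        self.quant = []  # (f, idx, Qs, qvec, norm, df)
        self.quant_ok = np.zeros(self.F, dtype=bool)
        self.transform_mean = np.full(self.F, np.nan)
        self.transform_sd = np.full(self.F, np.nan)
        for f in range(self.F):
            idx = np.flatnonzero(presence[f])
            if len(idx) < min_present:
                continue
            la = np.log10(A[f, idx])
            mu, sd = float(la.mean()), float(la.std(ddof=1))
            self.transform_mean[f], self.transform_sd[f] = mu, sd
            if sd == 0.0:
                continue
            qv = (la - mu) / sd
            Qs = orth_basis(self.Xc[idx])
            df = len(idx) - Qs.shape[1] - 1
            if df <= 0:
                continue
            resid = qv - Qs @ (Qs.T @ qv)
            norm = float(np.linalg.norm(resid))
            if norm <= 1e-8 * np.sqrt(len(idx)):
                continue
            self.quant.append((f, idx, Qs, resid / norm, norm, df))
            self.quant_ok[f] = True

    def scan(self, Y: np.ndarray) -> dict:
        """Compute all part P values for trait matrix Y (n x m).

        Returns F x m arrays: p_binary, beta1, z_binary, p_quant, beta2,
        z_quant, z_meta, p_meta, p_final (NaN where a part is not computed).
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        m = Y.shape[1]
        nan = np.full((self.F, m), np.nan)
        out = {k: nan.copy() for k in
               ("p_binary", "beta1", "z_binary", "p_quant", "beta2", "z_quant",
                "z_meta", "p_meta", "p_final")}

        QtY = self.Qc.T @ Y
        rss0 = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", QtY, QtY)

        if self.bin_ok.any():
            rows = np.flatnonzero(self.bin_ok)
            proj = self.Qb[rows] @ Y                        # (Fb, m)
            rss = np.maximum(rss0[None, :] - proj**2, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = proj / np.sqrt(rss / self.df_binary)
            p = np.maximum(2.0 * stats.t.sf(np.abs(t), self.df_binary), P_FLOOR)
            out["p_binary"][rows] = p
            out["beta1"][rows] = proj / self.bin_norm[rows, None]
            out["z_binary"][rows] = signed_z(p, np.sign(t))

        for f, idx, Qs, qv, norm, df in self.quant:
            Ys = Y[idx]
            QtYs = Qs.T @ Ys
            rss0f = np.einsum("ij,ij->j", Ys, Ys) - np.einsum("ij,ij->j", QtYs, QtYs)
            proj = qv @ Ys
            rss = np.maximum(rss0f - proj**2, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = proj / np.sqrt(rss / df)
            p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), P_FLOOR)
            out["p_quant"][f] = p
            out["beta2"][f] = proj / norm
            out["z_quant"][f] = signed_z(p, np.sign(t))

        both = self.bin_ok & self.quant_ok
        if both.any():
            zm, pm = meta_combine(out["z_binary"][both], out["z_quant"][both])
            out["z_meta"][both] = zm
            out["p_meta"][both] = pm

        stacked = np.stack([out["p_meta"], out["p_quant"], out["p_binary"]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out["p_final"] = np.nanmin(stacked, axis=0)
        return out


# ---------------------------------------------------------------------------
# permutation FDR


@dataclass
class FdrResult:
    """Plug-in permutation FDR estimate over a set of final P values."""

    q_values: np.ndarray
    threshold: float
    alpha: float
    n_perm: int

    def significant(self) -> np.ndarray:
        return self.q_values < self.alpha


def permutation_fdr(p_obs: np.ndarray, p_perm: np.ndarray,
                    alpha: float = 0.05, min_perm: int = 100) -> FdrResult:
    """Estimate q-values from observed final P values and a permutation null.

    For a threshold t, FDR(t) = mean over permutations of #{P_perm <= t}
    divided by max(1, #{P_obs <= t}). Each feature's q-value is the minimum
    FDR(t) over thresholds t >= its own P, monotonised to be non-decreasing
    in P and capped at 1. The returned ``threshold`` is the largest observed
    P with FDR(t) < alpha (NaN if none).

    Parameters
    ----------
    p_obs : (F,) observed final P values (NaN = feature not testable).
    p_perm : (F, n_perm) final P values under the permuted traits.
    """
    p_obs = np.asarray(p_obs, dtype=float)
    p_perm = np.asarray(p_perm, dtype=float)
    if p_perm.ndim != 2 or p_perm.shape[0] != p_obs.shape[0]:
        raise ValidationError("p_perm must be (n_features, n_perm)")
    n_perm = p_perm.shape[1]
    if n_perm < min_perm:
        raise ValidationError(
            f"need at least {min_perm} permutations for stable FDR, got {n_perm}"
        )
    finite = np.isfinite(p_obs)
    q = np.full(p_obs.shape, np.nan)
    if not finite.any():
        return FdrResult(q, np.nan, alpha, n_perm)

    ps = np.sort(p_obs[finite])
    pooled = np.sort(p_perm[np.isfinite(p_perm)])
    cnt_obs = np.searchsorted(ps, ps, side="right").astype(float)
    cnt_perm = np.searchsorted(pooled, ps, side="right") / n_perm
    fdr = cnt_perm / cnt_obs
    # q: running minimum from the right, capped at 1
    q_sorted = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)
    pos = np.searchsorted(ps, p_obs[finite], side="right") - 1
    q[finite] = q_sorted[pos]
    passing = ps[fdr < alpha]
    threshold = float(passing.max()) if passing.size else np.nan
    return FdrResult(q, threshold, alpha, n_perm)


def summarize_sources(sources, significant=None) -> pd.DataFrame:
    """Counts and one-decimal percentages of final-P sources.

    ``sources`` is an iterable of labels in {binary, quantitative, meta}, or
    a results frame with a ``source`` column (optionally pre-filtered to the
    significant set via ``significant``, a boolean mask).
    """
    if isinstance(sources, pd.DataFrame):
        col = sources["source"]
        if significant is not None:
            col = col[np.asarray(significant, dtype=bool)]
        labels = col.dropna().tolist()
    else:
        labels = [s for s in sources if s is not None]
    if not labels:
        raise ValidationError("no sources to summarise")
    counts = pd.Series(labels).value_counts()
    total = int(counts.sum())
    rows = []
    for name in ("binary", "quantitative", "meta"):
        c = int(counts.get(name, 0))
        rows.append({"source": name, "count": c,
                     "percent": round(100.0 * c / total, 1)})
    return pd.DataFrame(rows).set_index("source")


# ---------------------------------------------------------------------------
# Model / Results


class TwoPartAssociation:
    """Two-part association of one serum trait with every feature of a table.

    Parameters
    ----------
    trait : (n,) trait values aligned with ``table`` samples.
    table : OtuTable (converted to relative abundance internally).
    covariates : DataFrame of covariates (e.g. sex, batch) or None.
    min_present : minimum present samples for the quantitative part.
    prevalence_bounds : binary part skipped outside these bounds.
    exclude_unassigned : drop the 'unassigned' aggregate feature.

    ``fit(n_perm=..., seed=...)`` returns a :class:`TwoPartResults`; with
    ``n_perm`` > 0 the permutation FDR is run and q-values attached.
    """

    def __init__(self, trait, table: OtuTable, covariates=None,
                 min_present: int = DEFAULT_MIN_PRESENT,
                 prevalence_bounds=DEFAULT_PREVALENCE_BOUNDS,
                 exclude_unassigned: bool = True, trait_name: str = "trait"):
        rel = table.relative_abundance()
        if exclude_unassigned and UNASSIGNED in rel.data.index:
            rel = OtuTable(rel.data.drop(index=UNASSIGNED), kind="counts")
            # note: dropping a row breaks the sum-to-1 invariant, so re-wrap
            # as counts; the per-sample log10 values are unchanged.
        self.feature_ids = rel.feature_ids
        self.abundance = rel.values
        self.trait = np.asarray(trait, dtype=float)
        if self.trait.shape[0] != rel.n_samples:
            raise ValidationError("trait length does not match sample count")
        if not np.isfinite(self.trait).all():
            raise ValidationError("trait contains missing values; drop them first")
        self.covariates = covariates
        self.trait_name = trait_name
        self.min_present = min_present
        self.prevalence_bounds = prevalence_bounds
        self._engine = None

    @classmethod
    def from_tables(cls, table: OtuTable, pheno: PhenotypeTable, trait: str,
                    covariates=("sex", "batch"), **kwargs) -> "TwoPartAssociation":
        """Align a table with a phenotype table on shared samples and build
        the model for one named trait."""
        shared = [s for s in table.sample_ids if s in set(pheno.sample_ids)]
        if len(shared) < len(table.sample_ids):
            warnings.warn(
                f"dropping {len(table.sample_ids) - len(shared)} samples absent "
                "from the phenotype table", stacklevel=2)
        sub = table.select_samples(shared)
        y = pheno.trait(trait).loc[shared]
        keep = y.notna().to_numpy()
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} samples with missing "
                          f"{trait}", stacklevel=2)
            shared = [s for s, k in zip(shared, keep) if k]
            sub = table.select_samples(shared)
            y = y[keep]
        cov = pheno.covariates(covariates).loc[shared] if covariates else None
        return cls(y.to_numpy(), sub, covariates=cov, trait_name=trait, **kwargs)

    @property
    def engine(self) -> _TwoPartEngine:
        if self._engine is None:
            self._engine = _TwoPartEngine(
                self.abundance, self.covariates,
                min_present=self.min_present,
                prevalence_bounds=self.prevalence_bounds)
        return self._engine

    def fit(self, n_perm: int = 0, seed=None, alpha: float = 0.05,
            min_perm: int = 100) -> "TwoPartResults":
        eng = self.engine
        obs = eng.scan(self.trait)
        frame = pd.DataFrame({
            "feature_id": self.feature_ids,
            "prevalence": eng.prevalence,
            "n_present": eng.n_present,
            "beta1": obs["beta1"][:, 0],
            "Z_binary": obs["z_binary"][:, 0],
            "P_binary": obs["p_binary"][:, 0],
            "beta2": obs["beta2"][:, 0],
            "Z_quant": obs["z_quant"][:, 0],
            "P_quant": obs["p_quant"][:, 0],
            "transform_mean": eng.transform_mean,
            "transform_sd": eng.transform_sd,
            "Z_meta": obs["z_meta"][:, 0],
            "P_meta": obs["p_meta"][:, 0],
            "P_final": obs["p_final"][:, 0],
        }).set_index("feature_id")
        src = [
            _min_p_source(pb, pq, pm)[1]
            for pb, pq, pm in zip(frame["P_binary"], frame["P_quant"],
                                  frame["P_meta"])
        ]
        frame["source"] = src
        frame["q_value"] = np.nan

        fdr = None
        if n_perm:
            p_perm = self._permutation_scan(n_perm, seed)
            fdr = permutation_fdr(frame["P_final"].to_numpy(), p_perm,
                                  alpha=alpha, min_perm=min_perm)
            frame["q_value"] = fdr.q_values
        return TwoPartResults(frame, trait_name=self.trait_name, fdr=fdr,
                              n_samples=len(self.trait))

    def _permutation_scan(self, n_perm: int, seed) -> np.ndarray:
        """Freedman-Lane residual permutations -> (F, n_perm) final P matrix.

        The trait is regressed on the covariates once; the residuals are
        permuted with one shared sample permutation per round (preserving
        across-feature correlation) and re-attached to the fitted values.
        """
        eng = self.engine
        y = self.trait
        yhat = eng.Qc @ (eng.Qc.T @ y)
        resid = y - yhat
        rng = np.random.default_rng(seed)
        Y = np.empty((len(y), n_perm))
        for b in range(n_perm):
            Y[:, b] = yhat + resid[rng.permutation(len(y))]
        return eng.scan(Y)["p_final"]


class TwoPartResults:
    """Results of a two-part association scan: a tidy per-feature frame,
    the FDR calibration, and summary helpers."""

    def __init__(self, frame: pd.DataFrame, trait_name: str,
                 fdr: FdrResult | None, n_samples: int):
        self.frame = frame
        self.trait_name = trait_name
        self.fdr = fdr
        self.n_samples = n_samples

    @property
    def p_final(self) -> pd.Series:
        return self.frame["P_final"]

    @property
    def threshold(self) -> float:
        return self.fdr.threshold if self.fdr is not None else np.nan

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        """Features passing the permutation FDR at ``alpha`` (default: the
        alpha the FDR was run at)."""
        if self.fdr is None:
            raise ValidationError("fit with n_perm > 0 to obtain q-values")
        alpha = self.fdr.alpha if alpha is None else alpha
        return self.frame[self.frame["q_value"] < alpha]

    def source_summary(self, significant_only: bool = True) -> pd.DataFrame:
        frame = self.significant() if (significant_only and self.fdr) else self.frame
        return summarize_sources(frame["source"])

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    def summary(self) -> str:
        f = self.frame
        n_tested = int(f["P_final"].notna().sum())
        lines = [
            f"Two-part association: {self.trait_name}",
            "=" * 40,
            f"samples: {self.n_samples}   features tested: {n_tested} / {len(f)}",
        ]
        if self.fdr is not None:
            sig = self.significant()
            lines.append(
                f"permutations: {self.fdr.n_perm}   FDR alpha: {self.fdr.alpha}"
            )
            thr = self.threshold
            lines.append(f"significant features: {len(sig)}   "
                         f"P threshold: {thr:.3g}" if np.isfinite(thr)
                         else f"significant features: {len(sig)}")
            if len(sig):
                lines.append("\nsource attribution among significant:")
                lines.append(self.source_summary().to_string())
        top = f.nsmallest(min(5, len(f)), "P_final")[
            ["prevalence", "P_binary", "P_quant", "P_meta", "P_final", "source"]]
        lines.append("\ntop associations:")
        lines.append(top.to_string())
        return "\n".join(lines)
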