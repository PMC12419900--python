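"""Clade-wise log-log allometry between stylopodial indices and centre of mass.

The central object is :class:`AllometricModel`, a simple-regression model of
log10(relative centre of mass) on log10(index), fitted either by ordinary
least squares (OLS) or by phylogenetic generalized least squares (PGLS) with
a Brownian-motion correlation structure.  ``fit()`` returns an
:class:`AllometricFit` carrying the slope, intercept, their uncertainty, fit
statistics (slope p-value, adjusted R^2 for OLS, small-sample AICc) and the
per-taxon residuals, with a ``summary()`` table.

Outlier screening follows a deliberately conservative dual-convention
boxplot rule: residual quartiles are computed under both the inclusive-
median (Tukey hinge) and exclusive-median definitions, and a taxon is
flagged only if it falls outside the 1.5 x IQR fences under *both*.
:func:`fit_suite` wires the whole protocol: per-(subset x predictor x
method) primary fits, automatic outlier-removed refits, and ratite-excluded
bird variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phylo import PhyloTree, brownian_vcv

__all__ = [
    "TraitTable",
    "AllometricModel",
    "AllometricFit",
    "OutlierReport",
    "SuiteResult",
    "ols_fit",
    "pgls_fit",
    "aicc",
    "quartiles",
    "flag_outliers",
    "fit_suite",
    "DEFAULT_PREDICTORS",
]

DEFAULT_PREDICTORS = ("W1_index", "W2_index", "C_index", "L_index")


@dataclass
class TraitTable:
    """Per-taxon predictor/response pairs for one regression.

    ``data`` columns: taxon, clade, x (predictor), y (response), ratite.
    ``transformed`` records whether x and y are already on the log10 scale.
    """

    data: pd.DataFrame
    predictor: str
    response: str = "relative_com"
    transformed: bool = False

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        predictor: str,
        response: str = "relative_com",
    ) -> "TraitTable":
        """Build from a measurement/index DataFrame, dropping incomplete taxa."""
        cols = {"taxon": df["taxon"], "clade": df["clade"]}
        cols["x"] = pd.to_numeric(df[predictor], errors="coerce")
        cols["y"] = pd.to_numeric(df[response], errors="coerce")
        cols["ratite"] = df["ratite"].fillna(False).astype(bool) if "ratite" in df else False
        out = pd.DataFrame(cols).dropna(subset=["x", "y"]).reset_index(drop=True)
        if out["taxon"].duplicated().any():
            raise ValueError("duplicate taxa in trait table")
        return cls(data=out, predictor=predictor, response=response)

    def log10(self) -> "TraitTable":
        if self.transformed:
            return self
        if (self.data["x"] <= 0).any() or (self.data["y"] <= 0).any():
            bad = self.data.loc[(self.data["x"] <= 0) | (self.data["y"] <= 0), "taxon"]
            raise ValueError(
                f"non-positive values cannot be log10-transformed: {list(bad)}"
            )
        data = self.data.copy()
        data["x"] = np.log10(data["x"])
        data["y"] = np.log10(data["y"])
        return TraitTable(data, self.predictor, self.response, transformed=True)

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "TraitTable":
        return TraitTable(
            self.data[mask].reset_index(drop=True),
            self.predictor,
            self.response,
            self.transformed,
        )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); k counts slope, intercept and
    the residual variance (k = 3 for a simple regression).
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class AllometricFit:
    """Results of one allometric regression."""

    method: str
    subset: str
    variant: str
    predictor: str
    response: str
    n: int
    slope: float
    intercept: float
    slope_se: float
    slope_p: float
    slope_ci95: tuple[float, float]
    adj_R2: float | None
    loglik: float
    AICc: float
    sigma2_ml: float
    residuals: pd.Series
    mean_abs_error: float

    def predict(self, index_value) -> np.ndarray:
        """Predicted relative CoM (back-transformed) at raw index values."""
        x = np.asarray(index_value, dtype=float)
        return 10.0 ** (self.slope * np.log10(x) + self.intercept)

    @property
    def significant(self) -> bool:
        return self.slope_p < 0.05

    def summary(self) -> str:
        lines = [
            f"Allometric {self.method.upper()} fit: "
            f"log10({self.response}) ~ log10({self.predictor})",
            f"  subset: {self.subset}   variant: {self.variant}   n = {self.n}",
            f"  slope     {self.slope: .4f}  (SE {self.slope_se:.4f}, "
            f"95% CI [{self.slope_ci95[0]:.4f}, {self.slope_ci95[1]:.4f}])",
            f"  intercept {self.intercept: .4f}",
            f"  slope p   {self.slope_p:.4g}",
        ]
        if self.adj_R2 is not None:
            lines.append(f"  adj. R^2  {self.adj_R2:.4f}")
        lines.append(f"  AICc      {self.AICc:.2f}")
        lines.append(f"  mean |pred - obs| (relative CoM): {self.mean_abs_error:.4f}")
        return "\n".join(lines)

    def to_record(self) -> dict:
        return {
            "subset": self.subset,
            "variant": self.variant,
            "predictor": self.predictor,
            "method": self.method,
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "slope_p": self.slope_p,
            "slope_ci_lo": self.slope_ci95[0],
            "slope_ci_hi": self.slope_ci95[1],
            "adj_R2": self.adj_R2,
            "AICc": self.AICc,
            "mean_abs_error": self.mean_abs_error,
        }


class AllometricModel:
    """Log-log simple regression of relative CoM on a stylopodial index.

    Parameters
    ----------
    table : TraitTable
        Predictor/response pairs; transformed to log10 on construction if
        still raw.
    method : {"ols", "pgls"}
        Ordinary least squares, or generalized least squares with a
        Brownian phylogenetic correlation structure (requires ``tree``).
    tree : PhyloTree, optional
        Tree covering the table's taxa (pruned automatically); PGLS only.
    """

    def __init__(
        self,
        table: TraitTable,
        method: str = "ols",
        tree: PhyloTree | None = None,
        subset: str = "all",
        variant: str = "all",
    ):
        if method not in ("ols", "pgls"):
            raise ValueError(f"unknown method {method!r}")
        if method == "pgls" and tree is None:
            raise ValueError("PGLS requires a tree")
        self.table = table.log10()
        if self.table.n < 3:
            raise ValueError(f"need n >= 3 taxa, got {self.table.n}")
        self.method = method
        self.tree = tree
        self.subset = subset
        self.variant = variant

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        predictor: str,
        response: str = "relative_com",
        method: str = "ols",
        tree: PhyloTree | None = None,
        **kw,
    ) -> "AllometricModel":
        return cls(TraitTable.from_frame(df, predictor, response), method, tree, **kw)

    def fit(self) -> AllometricFit:
        t = self.table
        x = t.data["x"].to_numpy()
        y = t.data["y"].to_numpy()
        taxa = list(t.data["taxon"])
        n = len(y)
        if np.ptp(x) == 0:
            raise ValueError("zero predictor variance")

        if self.method == "ols":
            X = sm.add_constant(x)
            res = sm.OLS(y, X).fit()
            intercept, slope = res.params
            se = res.bse[1]
            p = res.pvalues[1]
            ci = tuple(res.conf_int(alpha=0.05)[1])
            adj_r2 = res.rsquared_adj
            loglik = res.llf
            resid = y - res.fittedvalues
            sigma2 = float(resid @ resid) / n
        else:
            (slope, intercept, se, p, ci, loglik, resid, sigma2) = _pgls(
                x, y, taxa, self.tree
            )
            adj_r2 = None

        fitted_rel = 10.0 ** (intercept + slope * x)
        observed_rel = 10.0 ** y
        mae = float(np.mean(np.abs(fitted_rel - observed_rel)))
        return AllometricFit(
            method=self.method,
            subset=self.subset,
            variant=self.variant,
            predictor=t.predictor,
            response=t.response,
            n=n,
            slope=float(slope),
            intercept=float(intercept),
            slope_se=float(se),
            slope_p=float(p),
            slope_ci95=(float(ci[0]), float(ci[1])),
            adj_R2=None if adj_r2 is None else float(adj_r2),
            loglik=float(loglik),
            AICc=aicc(float(loglik), 3, n) if n > 4 else float("nan"),
            sigma2_ml=float(sigma2),
            residuals=pd.Series(resid, index=taxa, name="residual"),
            mean_abs_error=mae,
        )


def _pgls(x, y, taxa, tree: PhyloTree):
    """Brownian GLS with the rate sigma^2 profiled out by ML.

    beta = (X' C^-1 X)^-1 X' C^-1 y with C the shared-path matrix; the ML
    rate is r' C^-1 r / n.  Standard errors use the n-2 denominator so the
    slope t-test matches OLS conventions; the log-likelihood uses the ML
    rate so AICc is comparable across OLS and PGLS.
    """
    sub = tree.prune_to(taxa)
    C = brownian_vcv(sub, taxa=taxa).matrix
    n = len(y)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        dup = _near_duplicate_taxa(C, taxa)
        raise ValueError(
            f"singular Brownian covariance (offending taxa: {dup})"
        ) from exc
    X = np.column_stack([np.ones(n), x])
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    XtX = Xi.T @ Xi
    beta = np.linalg.solve(XtX, Xi.T @ yi)
    resid = y - X @ beta
    ri = yi - Xi @ beta
    rss = float(ri @ ri)
    sigma2_ml = rss / n
    logdetC = 2.0 * float(np.log(np.diag(L)).sum())
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdetC + n)
    sigma2_unb = rss / (n - 2)
    cov = sigma2_unb * np.linalg.inv(XtX)
    se = float(np.sqrt(cov[1, 1]))
    tstat = beta[1] / se
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    tq = stats.t.ppf(0.975, df=n - 2)
    ci = (beta[1] - tq * se, beta[1] + tq * se)
    return beta[1], beta[0], se, p, ci, loglik, resid, sigma2_ml


def _near_duplicate_taxa(C: np.ndarray, taxa: list[str]) -> list[str]:
    bad = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if abs(C[i, i] - C[i, j]) < 1e-12 and abs(C[j, j] - C[i, j]) < 1e-12:
                bad.extend([taxa[i], taxa[j]])
    return sorted(set(bad))


def ols_fit(table: TraitTable, **kw) -> AllometricFit:
    return AllometricModel(table, method="ols", **kw).fit()


def pgls_fit(table: TraitTable, tree: PhyloTree, **kw) -> AllometricFit:
    return AllometricModel(table, method="pgls", tree=tree, **kw).fit()


# ---------------------------------------------------------------------------
# Dual-convention boxplot outlier protocol


def quartiles(values, convention: str) -> tuple[float, float]:
    """First and third quartiles under a median-handling convention.

    ``inclusive``: with n odd, the median joins both halves (Tukey hinges);
    ``exclusive``: with n odd, the median joins neither half.  With n even
    the halves — and hence the quartiles — coincide.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values for quartiles")
    half = n // 2
    if n % 2 == 0:
        lower, upper = v[:half], v[half:]
    elif convention == "inclusive":
        lower, upper = v[: half + 1], v[half:]
    elif convention == "exclusive":
        lower, upper = v[:half], v[half + 1:]
    else:
        raise ValueError(f"unknown quartile convention {convention!r}")
    return float(np.median(lower)), float(np.median(upper))


@dataclass
class OutlierReport:
    """Residual boxplot screen under both quartile conventions."""

    residuals: pd.Series
    fences: dict[str, tuple[float, float]] = field(default_factory=dict)
    flagged_by: dict[str, list[str]] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)


def flag_outliers(fit: AllometricFit, k: float = 1.5) -> OutlierReport:
    """Taxa outside the k x IQR fences under BOTH quartile conventions.

    Requiring agreement between the inclusive- and exclusive-median quartile
    calculations avoids over-filtering small subsets, where the two
    conventions can disagree about borderline residuals.  With n < 5 the
    screen is skipped (warning) and an empty report returned.
    """
    resid = fit.residuals
    if len(resid) < 5:
        warnings.warn(f"n={len(resid)} < 5: outlier screen skipped", stacklevel=2)
        return OutlierReport(residuals=resid)
    report = OutlierReport(residuals=resid)
    flag_sets = []
    for conv in ("inclusive", "exclusive"):
        q1, q3 = quartiles(resid.to_numpy(), conv)
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        report.fences[conv] = (lo, hi)
        flagged = resid.index[(resid < lo) | (resid > hi)].tolist()
        report.flagged_by[conv] = flagged
        flag_sets.append(set(flagged))
    both = flag_sets[0] & flag_sets[1]
    report.flagged = [t for t in resid.index if t in both]
    return report


# ---------------------------------------------------------------------------
# Full fitting protocol


@dataclass
class SuiteResult:
    """All fits and outlier reports from one run of the protocol."""

    fits: list[AllometricFit]
    outliers: dict[tuple, OutlierReport]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records([f.to_record() for f in self.fits])

    def get(self, subset=None, predictor=None, method=None, variant=None) -> list[AllometricFit]:
        out = self.fits
        if subset is not None:
            out = [f for f in out if f.subset == subset]
        if predictor is not None:
            out = [f for f in out if f.predictor == predictor]
        if method is not None:
            out = [f for f in out if f.method == method]
        if variant is not None:
            out = [f for f in out if f.variant == variant]
        return out

    def significant_equations(self, alpha: float = 0.05, method: str = "ols") -> list:
        """Predictive equations from significant primary fits (export rule)."""
        from .prediction import PredictiveEquation

        eqs = []
        for f in self.fits:
            if f.method == method and f.variant == "all" and f.slope_p < alpha:
                eqs.append(
                    PredictiveEquation(
                        name=f"{f.subset}_{f.predictor.replace('_index', '')}",
                        predictor=f.predictor,
                        slope=f.slope,
                        intercept=f.intercept,
                        mean_error=f.mean_abs_error,
                        source="fitted",
                        clade=f.subset,
                    )
                )
        return eqs


def fit_suite(
    df: pd.DataFrame,
    tree: PhyloTree | None = None,
    subsets: dict[str, list[str]] | None = None,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    methods: tuple[str, ...] = ("ols", "pgls"),
    response: str = "relative_com",
    min_n: int = 3,
) -> SuiteResult:
    """Run every (subset x predictor x method) regression with variants.

    ``df`` is a per-taxon frame with clade, index and response columns (see
    :func:`stylocom.indices.measurements_frame`).  For each primary fit the
    dual-convention outlier screen runs automatically; flagged taxa trigger
    an ``outliers_removed`` refit.  Subsets containing ratite-flagged taxa
    additionally get a ``ratites_removed`` variant.  Subsets with fewer than
    ``min_n`` usable taxa are skipped with a warning.
    """
    if subsets is None:
        subsets = {c: [c] for c in df["clade"].dropna().unique()}
    methods = tuple(m for m in methods if m != "pgls" or tree is not None)

    fits: list[AllometricFit] = []
    reports: dict[tuple, OutlierReport] = {}
    for subset_name, clades in subsets.items():
        sub_df = df[df["clade"].isin(clades)]
        for predictor in predictors:
            if predictor not in df.columns:
                continue
            table = TraitTable.from_frame(sub_df, predictor, response)
            if table.n < min_n:
                warnings.warn(
                    f"subset {subset_name!r} has n={table.n} < {min_n} for "
                    f"{predictor}; skipped",
                    stacklevel=2,
                )
                continue
            variants: list[tuple[str, TraitTable]] = [("all", table)]
            ratite_mask = table.data["ratite"].to_numpy(dtype=bool)
            if ratite_mask.any() and (~ratite_mask).sum() >= min_n:
                variants.append(("ratites_removed", table.subset(~ratite_mask)))
            for method in methods:
                for variant_name, vtable in variants:
                    model = AllometricModel(
                        vtable, method=method, tree=tree,
                        subset=subset_name, variant=variant_name,
                    )
                    fit = model.fit()
                    fits.append(fit)
                    if variant_name != "all":
                        continue
                    report = flag_outliers(fit)
                    reports[(subset_name, predictor, method)] = report
                    if report.flagged and vtable.n - len(report.flagged) >= min_n:
                        keep = ~vtable.data["taxon"].isin(report.flagged)
                        refit = AllometricModel(
                            vtable.subset(keep.to_numpy()), method=method, tree=tree,
                            subset=subset_name, variant="outliers_removed",
                        ).fit()
                        fits.append(refit)
    return SuiteResult(fits=fits, outliers=reports)
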