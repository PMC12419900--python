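"""Fossil centre-of-mass prediction from stylopodial indices.

A predictive equation is a log10-linear relation

    log10(relative CoM) = slope * log10(index) + intercept

fitted on extant taxa (or taken from the built-in printed set) and applied
to the equivalent index in fossil taxa.  Agreement with independent
volumetric reference estimates is quantified as the per-clade mean absolute
difference (on the glenoacetabular-fraction scale) and Spearman rank-order
concordance.  Uncertainty bands are prediction +/- the extant mean error;
predictions outside [0, 1] are flagged, never clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .indices import StylopodMeasurements, measurements_frame

__all__ = [
    "PredictiveEquation",
    "PredictionReport",
    "PRINTED_EQUATIONS",
    "predict_relcom",
    "mean_abs_error",
    "spearman_rho",
    "build_report",
    "load_equations",
    "save_equations",
]


@dataclass(frozen=True)
class PredictiveEquation:
    """One log10-linear relative-CoM predictor.

    ``mean_error`` is the mean absolute prediction error of the equation on
    its extant calibration set, in glenoacetabular fractions; it is the
    half-width of the reported uncertainty band.
    """

    name: str
    predictor: str  # index column, e.g. "W1_index"
    slope: float
    intercept: float
    mean_error: float
    source: str = "fitted"  # "fitted" | "printed"
    clade: str | None = None

    def __post_init__(self):
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError(f"equation {self.name}: non-finite coefficients")
        if self.mean_error < 0:
            raise ValueError(f"equation {self.name}: mean_error must be >= 0")


#: Published extant equations (significant OLS fits), usable without refitting.
PRINTED_EQUATIONS: tuple[PredictiveEquation, ...] = (
    PredictiveEquation("mammal_W1", "W1_index", 0.866, -0.294, 0.0198, "printed", "mammal"),
    PredictiveEquation("mammal_C", "C_index", 0.519, -0.271, 0.0288, "printed", "mammal"),
    PredictiveEquation(
        "nonavian_sauropsid_W1", "W1_index", 1.240, -0.355, 0.0618, "printed", "nonavian_sauropsid"
    ),
    PredictiveEquation(
        "nonavian_sauropsid_C", "C_index", 1.375, -0.374, 0.0621, "printed", "nonavian_sauropsid"
    ),
    PredictiveEquation("bird_W1", "W1_index", 0.656, -0.229, 0.0757, "printed", "bird"),
    PredictiveEquation("bird_W2", "W2_index", 0.609, -0.257, 0.0843, "printed", "bird"),
    PredictiveEquation("bird_C", "C_index", 0.652, -0.245, 0.0750, "printed", "bird"),
)


def predict_relcom(index_value, eq: PredictiveEquation):
    """Apply one equation to a (positive) index value, back-transformed."""
    x = np.asarray(index_value, dtype=float)
    if np.any(x <= 0):
        raise ValueError("index value must be > 0")
    out = 10.0 ** (eq.slope * np.log10(x) + eq.intercept)
    return float(out) if np.isscalar(index_value) else out


def mean_abs_error(predicted, reference) -> float:
    """Mean |predicted - reference| on the relative-CoM scale."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {r.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(p - r)))


def spearman_rho(a, b) -> float:
    """Spearman rank-order correlation (average ranks for ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if len(a) < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: rank correlation undefined")
    return float(stats.spearmanr(a, b).statistic)


@dataclass
class PredictionReport:
    """Fossil prediction results.

    ``predictions``: one row per (taxon, equation) with the index value,
    predicted relative CoM, band, reference value and absolute difference.
    ``clade_mae``: per-(clade, equation) mean absolute difference.
    ``rho``: Spearman concordance per equation over taxa with references.
    """

    predictions: pd.DataFrame
    clade_mae: pd.DataFrame
    rho: dict[str, float]

    def summary(self) -> str:
        lines = ["Fossil relative centre of mass predictions"]
        for eq_name, rho in sorted(self.rho.items()):
            lines.append(f"  {eq_name}: Spearman rho vs reference = {rho:.2f}")
        if len(self.clade_mae):
            lines.append("  per-clade mean |prediction - reference|:")
            for _, row in self.clade_mae.iterrows():
                lines.append(
                    f"    {row['clade']:16s} {row['equation']:24s} "
                    f"{row['mean_abs_diff']:.4f}  (n={int(row['n'])})"
                )
        return "\n".join(lines)


def build_report(
    fossil_rows: list[StylopodMeasurements] | pd.DataFrame,
    equations: list[PredictiveEquation],
    reference: dict[str, float] | None = None,
) -> PredictionReport:
    """Predict relative CoM for every fossil taxon under every equation.

    Rows lacking the index an equation needs are skipped for that equation
    only.  ``reference`` maps taxon to an independent (volumetric) relative
    CoM estimate; concordance statistics cover only taxa with both values.
    """
    if isinstance(fossil_rows, pd.DataFrame):
        df = fossil_rows
    else:
        df = measurements_frame(fossil_rows)
    reference = reference or {}

    records = []
    rho: dict[str, float] = {}
    for eq in equations:
        if eq.predictor not in df.columns or df[eq.predictor].dropna().empty:
            warnings.warn(
                f"equation {eq.name}: no fossil row has {eq.predictor}; skipped",
                stacklevel=2,
            )
            continue
        usable = df.dropna(subset=[eq.predictor])
        preds = predict_relcom(usable[eq.predictor].to_numpy(), eq)
        for (_, row), pred in zip(usable.iterrows(), preds):
            ref = reference.get(row["taxon"])
            records.append(
                {
                    "taxon": row["taxon"],
                    "clade": row["clade"],
                    "equation": eq.name,
                    "index_value": row[eq.predictor],
                    "predicted": pred,
                    "band_lo": pred - eq.mean_error,
                    "band_hi": pred + eq.mean_error,
                    "out_of_unit_interval": not (0.0 <= pred <= 1.0),
                    "reference": ref,
                    "abs_diff": abs(pred - ref) if ref is not None else np.nan,
                    "in_band": (abs(pred - ref) <= eq.mean_error) if ref is not None else None,
                }
            )
        matched = [r for r in records if r["equation"] == eq.name and r["reference"] is not None]
        if len(matched) >= 3:
            try:
                rho[eq.name] = spearman_rho(
                    [r["predicted"] for r in matched], [r["reference"] for r in matched]
                )
            except ValueError as exc:  # e.g. constant reference values
                warnings.warn(f"equation {eq.name}: rho omitted ({exc})", stacklevel=2)
        elif reference:
            warnings.warn(
                f"equation {eq.name}: fewer than 3 taxa overlap the reference; "
                "rho omitted",
                stacklevel=2,
            )

    pred_df = pd.DataFrame.from_records(records)
    if len(pred_df) and pred_df["abs_diff"].notna().any():
        clade_mae = (
            pred_df.dropna(subset=["abs_diff"])
            .groupby(["clade", "equation"], as_index=False)
            .agg(mean_abs_diff=("abs_diff", "mean"), n=("abs_diff", "size"))
        )
    else:
        clade_mae = pd.DataFrame(columns=["clade", "equation", "mean_abs_diff", "n"])
    return PredictionReport(predictions=pred_df, clade_mae=clade_mae, rho=rho)


# ---------------------------------------------------------------------------
# Equation file I/O (CSV or YAML)


def save_equations(equations: list[PredictiveEquation], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "name": e.name,
            "predictor": e.predictor,
            "slope": e.slope,
            "intercept": e.intercept,
            "mean_error": e.mean_error,
            "source": e.source,
            "clade": e.clade,
        }
        for e in equations
    ]
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(rows, sort_keys=False))
    else:
        pd.DataFrame.from_records(rows).to_csv(path, index=False)


def load_equations(path: str | Path) -> list[PredictiveEquation]:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        rows = yaml.safe_load(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    return [
        PredictiveEquation(
            name=r["name"],
            predictor=r["predictor"],
            slope=float(r["slope"]),
            intercept=float(r["intercept"]),
            mean_error=float(r["mean_error"]),
            source=str(r.get("source", "fitted")),
            clade=r.get("clade"),
        )
        for r in rows
    ]
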