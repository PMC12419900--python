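"""Stylopodial indices from linear limb-bone measurements.

Eight measurements per taxon: minimum humeral and femoral shaft
circumferences (HC, FC), shaft widths at the level of minimum circumference
parallel (HW1, FW1) and perpendicular (HW2, FW2) to the elbow/knee extensor
plane, and bone lengths (HL, FL).  Humeral-to-femoral ratios give the four
stylopodial indices:

    C index  = HC / FC        W1 index = HW1 / FW1
    W2 index = HW2 / FW2      L index  = HL / FL

Mass-relative dimensions divide each measurement by body_mass ** (1/3);
limb-intrinsic robusticity divides each humeral shaft dimension by HL and
each femoral one by FL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CLADES",
    "MEASUREMENTS",
    "StylopodMeasurements",
    "IndexSet",
    "compute_indices",
    "mass_relative_dimensions",
    "intrinsic_robusticity",
    "load_measurement_table",
    "measurements_frame",
]

CLADES = frozenset(
    {"mammal", "nonavian_sauropsid", "bird", "theropod", "sauropodomorph", "ornithischian"}
)
MEASUREMENTS = ("HC", "FC", "HW1", "FW1", "HW2", "FW2", "HL", "FL")
#: index name -> (humeral measurement, femoral measurement)
INDEX_PAIRS = {"C": ("HC", "FC"), "W1": ("HW1", "FW1"), "W2": ("HW2", "FW2"), "L": ("HL", "FL")}

_CSV_COLUMNS = [
    "taxon", "clade", "HC", "FC", "HW1", "FW1", "HW2", "FW2", "HL", "FL",
    "body_mass", "relative_com", "ratite", "notes",
]


@dataclass
class StylopodMeasurements:
    """Linear stylopodial measurements and metadata for one taxon.

    Missing measurements are ``None``; all present values must be > 0.
    ``clade`` comes from the closed vocabulary in :data:`CLADES`.
    """

    taxon: str
    clade: str
    HC: float | None = None
    FC: float | None = None
    HW1: float | None = None
    FW1: float | None = None
    HW2: float | None = None
    FW2: float | None = None
    HL: float | None = None
    FL: float | None = None
    body_mass: float | None = None
    relative_com: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(
                f"taxon {self.taxon!r}: unknown clade {self.clade!r}; "
                f"expected one of {sorted(CLADES)}"
            )
        for name in MEASUREMENTS + ("body_mass",):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"taxon {self.taxon!r}: {name} must be > 0, got {value}")


@dataclass(frozen=True)
class IndexSet:
    """Stylopodial index values for one taxon; missing inputs yield None."""

    C_index: float | None
    W1_index: float | None
    W2_index: float | None
    L_index: float | None
    mass_relative: dict[str, float] | None = None
    intrinsic: dict[str, float] | None = None


def _ratio(m: StylopodMeasurements, hum: str, fem: str) -> float | None:
    a, b = getattr(m, hum), getattr(m, fem)
    if a is None or b is None:
        return None
    return a / b


def compute_indices(
    m: StylopodMeasurements,
    with_mass_relative: bool = True,
    with_intrinsic: bool = True,
) -> IndexSet:
    """All computable indices for one taxon; no imputation of missing input."""
    return IndexSet(
        C_index=_ratio(m, "HC", "FC"),
        W1_index=_ratio(m, "HW1", "FW1"),
        W2_index=_ratio(m, "HW2", "FW2"),
        L_index=_ratio(m, "HL", "FL"),
        mass_relative=(
            mass_relative_dimensions(m) if with_mass_relative and m.body_mass is not None else None
        ),
        intrinsic=intrinsic_robusticity(m, warn=False) if with_intrinsic else None,
    )


def mass_relative_dimensions(m: StylopodMeasurements) -> dict[str, float]:
    """Each present measurement divided by body_mass ** (1/3)."""
    if m.body_mass is None:
        raise ValueError(f"taxon {m.taxon!r}: body_mass required for mass-relative dimensions")
    root = m.body_mass ** (1.0 / 3.0)
    return {
        name: getattr(m, name) / root
        for name in MEASUREMENTS
        if getattr(m, name) is not None
    }


def intrinsic_robusticity(m: StylopodMeasurements, warn: bool = True) -> dict[str, float]:
    """Limb-intrinsic ratios: HW1/HL, HW2/HL, HC/HL, FW1/FL, FW2/FL, FC/FL.

    Ratios whose bone length is missing are omitted (with a warning).
    """
    out: dict[str, float] = {}
    for length, dims in (("HL", ("HW1", "HW2", "HC")), ("FL", ("FW1", "FW2", "FC"))):
        bone_len = getattr(m, length)
        if bone_len is None:
            if warn:
                warnings.warn(
                    f"taxon {m.taxon!r}: {length} missing; "
                    f"omitting intrinsic ratios {[f'{d}/{length}' for d in dims]}",
                    stacklevel=2,
                )
            continue
        for dim in dims:
            value = getattr(m, dim)
            if value is not None:
                out[f"{dim}/{length}"] = value / bone_len
    return out


def load_measurement_table(path: str | Path) -> list[StylopodMeasurements]:
    """Read and validate a measurement CSV (one row per taxon).

    Schema: taxon, clade, HC, FC, HW1, FW1, HW2, FW2, HL, FL, body_mass,
    relative_com, ratite, notes.  Empty cells are missing values; ratite is
    parsed into the row's flag set.  Errors are collected per row/column and
    reported together.
    """
    df = pd.read_csv(path)
    required = {"taxon", "clade"}.union(MEASUREMENTS)
    missing_cols = sorted(required - set(df.columns))
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    dupes = df["taxon"][df["taxon"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate taxon names {dupes}")

    rows: list[StylopodMeasurements] = []
    errors: list[str] = []
    for i, rec in df.iterrows():
        kwargs: dict = {"taxon": str(rec["taxon"]), "clade": str(rec["clade"])}
        for col in MEASUREMENTS + ("body_mass", "relative_com"):
            if col not in df.columns:
                continue
            raw = rec[col]
            if pd.isna(raw):
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                errors.append(f"row {i} ({rec['taxon']}): unparseable {col}={raw!r}")
                continue
            if col != "relative_com" and not value > 0:
                errors.append(f"row {i} ({rec['taxon']}): {col} must be > 0, got {value}")
                continue
            kwargs[col] = value
        flags = set()
        if "ratite" in df.columns and not pd.isna(rec["ratite"]):
            if str(rec["ratite"]).strip().lower() in ("1", "1.0", "true", "yes", "ratite"):
                flags.add("ratite")
        try:
            rows.append(StylopodMeasurements(flags=flags, **kwargs))
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError(f"{path}: invalid measurement table:\n  " + "\n  ".join(errors))
    return rows


def measurements_frame(rows: list[StylopodMeasurements]) -> pd.DataFrame:
    """Per-taxon DataFrame of raw measurements, indices and metadata."""
    records = []
    for m in rows:
        idx = compute_indices(m, with_mass_relative=False, with_intrinsic=False)
        rec = {
            "taxon": m.taxon,
            "clade": m.clade,
            "ratite": "ratite" in m.flags,
            **{name: getattr(m, name) for name in MEASUREMENTS},
            "body_mass": m.body_mass,
            "relative_com": m.relative_com,
            "C_index": idx.C_index,
            "W1_index": idx.W1_index,
            "W2_index": idx.W2_index,
            "L_index": idx.L_index,
        }
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df.astype({"ratite": bool}) if len(df) else df
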