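"""Preparation of record-level natality data for mediation analysis.

A birth record carries the mother's race class (1 = non-Black, 2 = Black),
the anthropometric fields needed to derive prepregnancy body mass index
(BMI) and gestational weight gain (GWG), and five binary maternal outcomes.
This module derives the two mediators, classifies each as optimal or
non-optimal against IOM-style cutoffs, applies the deletion rules for
missing data, and aggregates retained records into the eight-cell
(race x BMI-class x GWG-class) count table that the Bayesian model consumes.

Deletion rules, applied in order:

1. drop any record missing one or more of the five outcomes;
2. drop any record missing (or carrying a non-positive) height, delivery
   weight, prepregnancy weight, or obstetric gestation estimate.

GWG is corrected to 40 weeks by proportional scaling,
``(delivery - prepregnancy weight) * 40 / gestation_weeks``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five maternal outcomes, in canonical column order.
OUTCOMES = (
    "gestational_hypertension",
    "hypertension_eclampsia",
    "parturition_induction",
    "cesarean_delivery",
    "icu_admission",
)

#: Fields required to derive BMI and adjusted GWG.
ANTHRO_FIELDS = (
    "height_cm",
    "prepreg_weight_kg",
    "delivery_weight_kg",
    "gestation_weeks",
)

#: Mediator combinations (m1, m2) in published-table display order:
#: (optimal BMI, optimal GWG), (non-opt, opt), (opt, non-opt), (non-opt, non-opt).
MEDIATOR_COMBOS = ((1, 1), (2, 1), (1, 2), (2, 2))

RACE_LABELS = {1: "non_black", 2: "black"}

CM_PER_INCH = 2.54
KG_PER_LB = 0.45359237

CANONICAL_COLUMNS = ("race_class",) + ANTHRO_FIELDS + OUTCOMES


@dataclass(frozen=True)
class ClassificationRules:
    """Cutoffs that map continuous BMI / adjusted GWG to binary classes.

    Optimal BMI is the half-open interval [bmi_lower, bmi_upper) by default
    (18.5 to 25 kg/m^2, upper bound exclusive, matching the IOM normal range
    whose last listed value is 24.9); set ``bmi_upper_inclusive`` to close it.
    Optimal adjusted GWG is the closed interval [gwg_lower, gwg_upper]
    (11.5 to 16 kg at 40 weeks). Negative adjusted GWG is allowed and
    classifies as non-optimal.
    """

    bmi_lower: float = 18.5
    bmi_upper: float = 25.0
    bmi_upper_inclusive: bool = False
    gwg_lower: float = 11.5
    gwg_upper: float = 16.0

    def classify_bmi(self, bmi):
        bmi = np.asarray(bmi, dtype=float)
        if self.bmi_upper_inclusive:
            optimal = (bmi >= self.bmi_lower) & (bmi <= self.bmi_upper)
        else:
            optimal = (bmi >= self.bmi_lower) & (bmi < self.bmi_upper)
        return np.where(optimal, 1, 2)

    def classify_gwg(self, gwg_adj):
        gwg_adj = np.asarray(gwg_adj, dtype=float)
        optimal = (gwg_adj >= self.gwg_lower) & (gwg_adj <= self.gwg_upper)
        return np.where(optimal, 1, 2)


DEFAULT_RULES = ClassificationRules()


def derive_bmi(height_cm, prepreg_weight_kg):
    """Prepregnancy BMI in kg/m^2 from height (cm) and weight (kg)."""
    height_m = np.asarray(height_cm, dtype=float) / 100.0
    out = np.asarray(prepreg_weight_kg, dtype=float) / height_m**2
    return float(out) if out.ndim == 0 else out


def adjust_gwg(prepreg_weight_kg, delivery_weight_kg, gestation_weeks):
    """Gestational weight gain (kg) corrected to 40 weeks.

    Proportional correction: gain scales linearly with gestation length,
    so the 40-week-equivalent gain is ``gain * 40 / weeks``.
    """
    gain = np.asarray(delivery_weight_kg, dtype=float) - np.asarray(
        prepreg_weight_kg, dtype=float
    )
    out = gain * 40.0 / np.asarray(gestation_weeks, dtype=float)
    return float(out) if out.ndim == 0 else out


def classify_mediators(bmi, gwg_adj, rules: ClassificationRules = DEFAULT_RULES):
    """Return (m1, m2): 1 = optimal, 2 = non-optimal, per mediator."""
    m1 = rules.classify_bmi(bmi)
    m2 = rules.classify_gwg(gwg_adj)
    if m1.ndim == 0:
        return int(m1), int(m2)
    return m1, m2


@dataclass
class BirthRecord:
    """One singleton birth. Any field but race_class may be missing (None)."""

    race_class: int
    height_cm: float | None = None
    prepreg_weight_kg: float | None = None
    delivery_weight_kg: float | None = None
    gestation_weeks: float | None = None
    outcomes: Mapping[str, int | None] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "race_class": self.race_class,
            "height_cm": self.height_cm,
            "prepreg_weight_kg": self.prepreg_weight_kg,
            "delivery_weight_kg": self.delivery_weight_kg,
            "gestation_weeks": self.gestation_weeks,
        }
        for name in OUTCOMES:
            row[name] = self.outcomes.get(name)
        return row


def records_to_frame(records: Iterable[BirthRecord]) -> pd.DataFrame:
    """Stack BirthRecord objects into the canonical record DataFrame."""
    rows = [rec.to_row() for rec in records]
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    return frame.astype(float)


@dataclass(frozen=True)
class DeletionLog:
    """Audit counts for the two-stage missing-data deletion."""

    n_input: int
    n_missing_outcome: int
    n_missing_anthro: int
    n_retained: int

    def __post_init__(self):
        if self.n_input != self.n_retained + self.n_missing_outcome + self.n_missing_anthro:
            raise ValueError("deletion log does not conserve records")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_missing_outcome": self.n_missing_outcome,
            "n_missing_anthro": self.n_missing_anthro,
            "n_retained": self.n_retained,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def filter_records(
    records,
    rules: ClassificationRules = DEFAULT_RULES,
    outcomes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, DeletionLog]:
    """Apply deletion rules and derive mediators for the survivors.

    Parameters
    ----------
    records
        A DataFrame with the canonical columns, or an iterable of
        :class:`BirthRecord`.
    rules
        Classification cutoffs for the two mediators.
    outcomes
        Outcome columns that must be complete. Defaults to whichever of the
        five canonical outcomes are present in the input.

    Returns
    -------
    (derived, log)
        ``derived`` has columns race_class, bmi, gwg_adj, m1, m2 plus the
        outcome columns as integers; ``log`` is the :class:`DeletionLog`.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
    if "race_class" not in df.columns:
        raise ValueError("records are missing the race_class column")
    race = df["race_class"]
    bad_race = ~race.isin([1, 2])
    if bad_race.any():
        raise ValueError(
            f"row {int(np.flatnonzero(bad_race.to_numpy())[0])}: "
            f"race_class must be 1 or 2"
        )
    if outcomes is None:
        outcomes = [c for c in OUTCOMES if c in df.columns]
    if not outcomes:
        raise ValueError("no outcome columns present in records")
    missing_cols = [c for c in ANTHRO_FIELDS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"records are missing columns: {missing_cols}")

    n_input = len(df)
    outcome_missing = df[list(outcomes)].isna().any(axis=1).to_numpy()
    anthro = df[list(ANTHRO_FIELDS)].to_numpy(dtype=float)
    anthro_bad = (np.isnan(anthro) | (anthro <= 0) | ~np.isfinite(anthro)).any(axis=1)
    # outcome deletion takes precedence, matching the reported deletion order
    anthro_only = anthro_bad & ~outcome_missing
    keep = ~outcome_missing & ~anthro_bad

    log = DeletionLog(
        n_input=n_input,
        n_missing_outcome=int(outcome_missing.sum()),
        n_missing_anthro=int(anthro_only.sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "filter_records: %d input, %d missing-outcome, %d missing-anthropometrics, %d retained",
        log.n_input, log.n_missing_outcome, log.n_missing_anthro, log.n_retained,
    )

    kept = df.loc[keep]
    bmi = derive_bmi(kept["height_cm"].to_numpy(), kept["prepreg_weight_kg"].to_numpy())
    gwg = adjust_gwg(
        kept["prepreg_weight_kg"].to_numpy(),
        kept["delivery_weight_kg"].to_numpy(),
        kept["gestation_weeks"].to_numpy(),
    )
    m1, m2 = classify_mediators(bmi, gwg, rules)
    derived = pd.DataFrame(
        {
            "race_class": kept["race_class"].to_numpy(dtype=np.int64),
            "bmi": bmi,
            "gwg_adj": gwg,
            "m1": m1.astype(np.int64),
            "m2": m2.astype(np.int64),
        },
        index=kept.index,
    )
    for name in outcomes:
        derived[name] = kept[name].to_numpy(dtype=np.int64)
    return derived.reset_index(drop=True), log


class CellCounts:
    """Cases r and births n for the 8 (race, BMI-class, GWG-class) cells.

    Arrays are indexed ``[x-1, m1-1, m2-1]`` with x the race class and
    m1/m2 the mediator classes (1 = optimal, 2 = non-optimal).
    """

    __slots__ = ("r", "n", "outcome")

    def __init__(self, r, n, outcome: str = "outcome"):
        r = np.asarray(r, dtype=np.int64).reshape(2, 2, 2)
        n = np.asarray(n, dtype=np.int64).reshape(2, 2, 2)
        if (n < 0).any() or (r < 0).any() or (r > n).any():
            raise ValueError("cell counts must satisfy 0 <= r <= n")
        self.r = r
        self.n = n
        self.outcome = outcome

    def cell(self, x: int, m1: int, m2: int) -> tuple[int, int]:
        return int(self.r[x - 1, m1 - 1, m2 - 1]), int(self.n[x - 1, m1 - 1, m2 - 1])

    def collapse(self, x: int, m1: int | None = None, m2: int | None = None) -> tuple[int, int]:
        """Pooled (r, n) with each ``None`` index summed out."""
        r = self.r[x - 1]
        n = self.n[x - 1]
        if m1 is not None:
            r, n = r[m1 - 1], n[m1 - 1]
        else:
            r, n = r.sum(axis=0), n.sum(axis=0)
        if m2 is not None:
            r, n = r[m2 - 1], n[m2 - 1]
        else:
            r, n = r.sum(), n.sum()
        return int(np.asarray(r).sum()), int(np.asarray(n).sum())

    def race_total(self, x: int) -> int:
        return int(self.n[x - 1].sum())

    def total_births(self) -> int:
        return int(self.n.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for x in (1, 2):
            for m1 in (1, 2):
                for m2 in (1, 2):
                    r, n = self.cell(x, m1, m2)
                    rows.append(
                        {"outcome": self.outcome, "x": x, "m1": m1, "m2": m2, "r": r, "n": n}
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, outcome: str = "outcome") -> "CellCounts":
        r = np.zeros((2, 2, 2), dtype=np.int64)
        n = np.zeros((2, 2, 2), dtype=np.int64)
        for _, row in frame.iterrows():
            r[int(row["x"]) - 1, int(row["m1"]) - 1, int(row["m2"]) - 1] = int(row["r"])
            n[int(row["x"]) - 1, int(row["m1"]) - 1, int(row["m2"]) - 1] = int(row["n"])
        return cls(r, n, outcome=outcome)

    def __eq__(self, other):
        return (
            isinstance(other, CellCounts)
            and np.array_equal(self.r, other.r)
            and np.array_equal(self.n, other.n)
            and self.outcome == other.outcome
        )

    def __repr__(self):
        return f"CellCounts(outcome={self.outcome!r}, total={self.total_births()})"


def aggregate(derived: pd.DataFrame, outcome: str) -> CellCounts:
    """Aggregate derived records into the eight-cell count table for one outcome.

    Empty cells are zero-filled; the eight cell denominators partition the
    retained records.
    """
    if len(derived) == 0:
        return CellCounts(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), outcome=outcome)
    idx = (
        (derived["race_class"].to_numpy() - 1) * 4
        + (derived["m1"].to_numpy() - 1) * 2
        + (derived["m2"].to_numpy() - 1)
    )
    n = np.bincount(idx, minlength=8).reshape(2, 2, 2)
    r = np.bincount(idx, weights=derived[outcome].to_numpy(dtype=float), minlength=8)
    return CellCounts(np.rint(r).reshape(2, 2, 2), n, outcome=outcome)


class PrevalenceTable:
    """Joint prevalence P(M1, M2 | X) as percentages, per race.

    Stored as a (2, 2, 2) percent array indexed ``[x-1, m1-1, m2-1]``;
    each race's four entries sum to 100.
    """

    def __init__(self, percent):
        percent = np.asarray(percent, dtype=float).reshape(2, 2, 2)
        if (percent < 0).any():
            raise ValueError("prevalence percentages must be non-negative")
        sums = percent.reshape(2, 4).sum(axis=1)
        if not np.allclose(sums, 100.0, rtol=0, atol=1e-7):
            raise ValueError(
                f"each race's prevalence must sum to 100%, got {sums.tolist()}"
            )
        self.percent = percent

    def fractions(self) -> np.ndarray:
        return self.percent / 100.0

    def combo_percent(self, x: int, m1: int, m2: int) -> float:
        return float(self.percent[x - 1, m1 - 1, m2 - 1])

    @classmethod
    def from_percentages(cls, non_black, black, normalize: bool = False) -> "PrevalenceTable":
        """Build from two 4-vectors in display order (see MEDIATOR_COMBOS).

        With ``normalize=True`` each race's vector is rescaled to sum to
        exactly 100 (printed tables are rounded and may sum to e.g. 99.9).
        """
        percent = np.zeros((2, 2, 2))
        for x, vec in ((1, non_black), (2, black)):
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (4,):
                raise ValueError("each race needs exactly 4 prevalence entries")
            if normalize:
                vec = vec * (100.0 / vec.sum())
            for (m1, m2), v in zip(MEDIATOR_COMBOS, vec):
                percent[x - 1, m1 - 1, m2 - 1] = v
        return cls(percent)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m1, m2 in MEDIATOR_COMBOS:
            rows.append(
                {
                    "bmi": "optimal" if m1 == 1 else "non_optimal",
                    "gwg": "optimal" if m2 == 1 else "non_optimal",
                    "non_black": self.combo_percent(1, m1, m2),
                    "black": self.combo_percent(2, m1, m2),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def __repr__(self):
        return f"PrevalenceTable({self.percent.tolist()})"


def prevalence_table(cells: CellCounts) -> PrevalenceTable:
    """Observed joint mediator prevalence per race, from cell denominators."""
    percent = np.zeros((2, 2, 2))
    for x in (1, 2):
        total = cells.race_total(x)
        if total == 0:
            raise ValueError(f"race class {x} has zero births; prevalence undefined")
        percent[x - 1] = 100.0 * cells.n[x - 1] / total
    return PrevalenceTable(percent)


# ---------------------------------------------------------------------------
# Delimited-text readers


def _coerce_numeric(series: pd.Series, col: str) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    as_str = series.astype("string").str.strip()
    bad = numeric.isna() & as_str.notna() & (as_str != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"row {row}: cannot parse {col!r} value {series.iloc[row]!r}")
    return numeric


def read_records(
    path,
    column_map: Mapping[str, str] | None = None,
    units: str = "metric",
    sentinels: Sequence[float] = (),
    sep: str = ",",
) -> pd.DataFrame:
    """Read record-level births from delimited text into the canonical frame.

    Parameters
    ----------
    column_map
        Maps canonical names (see CANONICAL_COLUMNS) to the file's column
        names; identity for columns not listed.
    units
        ``metric`` (cm / kg) or ``imperial`` (inches / pounds, converted
        at read time).
    sentinels
        Numeric codes (e.g. 999-style unknowns) mapped to missing in the
        anthropometric and outcome fields.
    """
    if units not in ("metric", "imperial"):
        raise ValueError("units must be 'metric' or 'imperial'")
    raw = pd.read_csv(path, sep=sep, dtype="string")
    rename = {}
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in ("race_class",) + ANTHRO_FIELDS if c not in raw.columns]
    if missing:
        raise ValueError(f"input is missing required columns: {missing}")
    present_outcomes = [c for c in OUTCOMES if c in raw.columns]
    if not present_outcomes:
        raise ValueError("input has none of the five outcome columns")

    frame = pd.DataFrame(index=raw.index)
    for col in ("race_class",) + ANTHRO_FIELDS + tuple(present_outcomes):
        frame[col] = _coerce_numeric(raw[col], col)
    if sentinels:
        sentinel_arr = np.asarray(list(sentinels), dtype=float)
        for col in ANTHRO_FIELDS + tuple(present_outcomes):
            vals = frame[col].to_numpy(dtype=float)
            frame[col] = np.where(np.isin(vals, sentinel_arr), np.nan, vals)
    bad_race = ~frame["race_class"].isin([1, 2])
    if bad_race.any():
        row = int(np.flatnonzero(bad_race.to_numpy())[0])
        raise ValueError(f"row {row}: race_class must be 1 or 2")
    if units == "imperial":
        frame["height_cm"] = frame["height_cm"] * CM_PER_INCH
        for col in ("prepreg_weight_kg", "delivery_weight_kg"):
            frame[col] = frame[col] * KG_PER_LB
    return frame


def read_cell_counts(path, sep: str = ",") -> dict[str, CellCounts]:
    """Read pre-aggregated counts (columns outcome, x, m1, m2, r, n)."""
    frame = pd.read_csv(path, sep=sep)
    required = {"outcome", "x", "m1", "m2", "r", "n"}
    if not required.issubset(frame.columns):
        raise ValueError(f"cell-count input needs columns {sorted(required)}")
    out = {}
    for outcome, grp in frame.groupby("outcome", sort=False):
        out[str(outcome)] = CellCounts.from_frame(grp, outcome=str(outcome))
    return out


def write_cell_counts(cells_by_outcome: Mapping[str, CellCounts], path) -> None:
    frames = [c.to_frame() for c in cells_by_outcome.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
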