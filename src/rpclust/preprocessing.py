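"""Dietary preprocessing: recall averaging, tertile categorization,
eligibility filtering and cardiovascular risk-factor flags.

Continuous per-food consumption amounts (cup- or ounce-equivalents averaged
over up to two 24-hour recalls) are mapped to four ordered levels: 1 = no
consumption, then the lower / middle / upper tertile of the *positive*
consumption distribution pooled over the whole analytic population.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ConsumptionMatrix, DataError

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """An expected column or setting is missing."""


# ---------------------------------------------------------------------------
# Recall averaging
# ---------------------------------------------------------------------------

def average_recalls(records: pd.DataFrame, amount_cols: list[str] | None = None,
                    id_col: str = "person_id", day_col: str = "day_index",
                    expected_ids=None) -> pd.DataFrame:
    """Average per-food amounts over a person's available recall days.

    ``records`` is tidy: one row per (person, day) with nonnegative amount
    columns.  A person with two complete recalls gets the day mean; a person
    with one keeps that day unchanged.  Persons listed in ``expected_ids``
    but absent from ``records`` are excluded with a logged reason rather
    than raising.

    Returns a DataFrame indexed by person id with the amount columns.
    """
    if id_col not in records.columns:
        raise ConfigurationError(f"missing id column {id_col!r}")
    if amount_cols is None:
        amount_cols = [c for c in records.columns
                       if c not in (id_col, day_col)]
    amounts = records[amount_cols]
    if (amounts.to_numpy(dtype=float) < 0).any():
        raise DataError("negative consumption amount in recall records")
    out = records.groupby(id_col, sort=False)[amount_cols].mean()
    if expected_ids is not None:
        missing = [i for i in expected_ids if i not in out.index]
        for pid in missing:
            logger.warning("person %r excluded: no complete dietary recall",
                           pid)
    return out


# ---------------------------------------------------------------------------
# Tertile categorization
# ---------------------------------------------------------------------------

@dataclass
class CategorizationRule:
    """Per-food tertile cutpoints of the positive-consumption distribution.

    ``cutpoints[food] = (t1, t2)`` with 0 < t1 <= t2, computed over the whole
    analytic population (never within subgroup).  Foods with fewer than three
    distinct positive values are flagged degenerate: all positive amounts map
    to a single "consumed" level (2).
    """

    cutpoints: dict = field(default_factory=dict)
    degenerate: set = field(default_factory=set)
    d: int = 4

    def columns(self) -> list:
        return list(self.cutpoints)

    def to_json(self, path) -> None:
        payload = {
            "schema": "rpclust-categorization-rule-v1",
            "d": self.d,
            "cutpoints": {str(k): (None if v is None else list(v))
                          for k, v in self.cutpoints.items()},
            "degenerate": sorted(str(c) for c in self.degenerate),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CategorizationRule":
        with open(path) as fh:
            payload = json.load(fh)
        cut = {k: (None if v is None else tuple(v))
               for k, v in payload["cutpoints"].items()}
        return cls(cutpoints=cut, degenerate=set(payload["degenerate"]),
                   d=payload["d"])


def fit_categorization(amounts: pd.DataFrame, d: int = 4,
                       weights=None) -> CategorizationRule:
    """Fit tertile cutpoints on the positive part of each food column.

    The quantile convention is the inverse empirical CDF (type 1): the 1/3
    and 2/3 quantiles are order statistics of the sorted positive values,
    so ties at a cutpoint are resolved deterministically.  ``weights``
    switches to weighted quantiles of the positive distribution.
    """
    amounts = pd.DataFrame(amounts)
    rule = CategorizationRule(d=d)
    for col in amounts.columns:
        x = amounts[col].to_numpy(dtype=float)
        if (x < 0).any():
            i = int(np.argmax(x < 0))
            raise DataError(f"negative amount at row {i}, column {col!r}")
        pos_mask = x > 0
        pos = x[pos_mask]
        if len(np.unique(pos)) < 3:
            rule.cutpoints[col] = None
            rule.degenerate.add(col)
            logger.warning(
                "column %r degenerate (<3 distinct positive values); "
                "positive amounts map to a single consumed level", col)
            continue
        if weights is None:
            t1, t2 = np.quantile(pos, [1 / 3, 2 / 3], method="inverted_cdf")
        else:
            w = np.asarray(weights, dtype=float)[pos_mask]
            t1, t2 = _weighted_quantile(pos, w, [1 / 3, 2 / 3])
        rule.cutpoints[col] = (float(t1), float(t2))
    return rule


def _weighted_quantile(x: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cw = np.cumsum(w) / w.sum()
    # inverse weighted CDF: smallest x with cumulative weight >= q
    return np.array([x[np.searchsorted(cw, q, side="left")] for q in qs])


def categorize(amounts: pd.DataFrame, rule: CategorizationRule,
               subgroup=None, d: int | None = None,
               subgroup_names=None) -> ConsumptionMatrix:
    """Map amounts to ordered levels 1..d under a fitted rule.

    0 maps to level 1; positive amounts map by half-open intervals
    (0, t1] -> 2, (t1, t2] -> 3, (t2, inf) -> 4, so a tie at a cutpoint goes
    to the lower level.  Degenerate columns map every positive amount to 2.
    """
    amounts = pd.DataFrame(amounts)
    d = d or rule.d
    cols = list(amounts.columns)
    missing = [c for c in cols if c not in rule.cutpoints]
    if missing:
        raise ConfigurationError(
            f"rule was not fitted for columns {missing}")
    n = len(amounts)
    y = np.ones((n, len(cols)), dtype=np.int64)
    for jc, col in enumerate(cols):
        x = amounts[col].to_numpy(dtype=float)
        if (x < 0).any():
            i = int(np.argmax(x < 0))
            raise DataError(f"negative amount at row {i}, column {col!r}")
        pos = x > 0
        if col in rule.degenerate:
            y[pos, jc] = 2
            continue
        t1, t2 = rule.cutpoints[col]
        y[pos, jc] = 2
        y[x > t1, jc] = 3
        y[x > t2, jc] = 4
    if subgroup is None:
        subgroup = np.ones(n, dtype=np.int64)
    return ConsumptionMatrix(
        y=y, subgroup=np.asarray(subgroup), d=d, item_names=[str(c) for c in cols],
        subgroup_names=list(subgroup_names) if subgroup_names else [],
        person_ids=list(amounts.index),
    )


# ---------------------------------------------------------------------------
# Eligibility filtering
# ---------------------------------------------------------------------------

@dataclass
class EligibilityCriteria:
    """Inclusion filters of the low-income female analytic sample.

    Defaults: female sex, age 20-80 inclusive (80 is the survey's top code),
    family income at or below 130% of the poverty threshold, five named
    race/ethnicity groups, pregnant/lactating excluded, at least one
    complete dietary recall.
    """

    sex: str | None = "female"
    age_min: float = 20.0
    age_max: float = 80.0
    income_ratio_max: float = 1.30
    allowed_race_codes: tuple = (1, 2, 3, 4, 6)
    exclude_pregnant: bool = True
    min_recalls: int = 1

    def __post_init__(self) -> None:
        if self.income_ratio_max <= 0:
            raise ConfigurationError("income_ratio_max must be positive")
        if self.age_min > self.age_max:
            raise ConfigurationError("empty age range")


#: Fixed application order of the exclusion tally.
ELIGIBILITY_ORDER = ("sex", "age", "race", "income", "pregnancy", "diet")

_REQUIRED_COLS = {
    "sex": "sex", "age": "age", "race": "race",
    "income": "income_ratio", "pregnancy": "pregnant", "diet": "n_recalls",
}


def apply_eligibility(table: pd.DataFrame, criteria: EligibilityCriteria,
                      columns: dict | None = None):
    """Filter a covariate table and tally exclusions per criterion.

    Criteria are applied in the fixed order sex -> age -> race/ethnicity ->
    income ratio -> pregnancy/lactation -> diet completeness; each person is
    counted once, under the first criterion that removes them.  Returns
    ``(retained_ids, tally)`` where ``tally`` is an ordered dict
    criterion -> count removed.
    """
    colmap = dict(_REQUIRED_COLS)
    if columns:
        colmap.update(columns)
    needed = [colmap[k] for k in ELIGIBILITY_ORDER
              if not (k == "sex" and criteria.sex is None)
              and not (k == "pregnancy" and not criteria.exclude_pregnant)]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")

    keep = pd.Series(True, index=table.index)
    tally: dict[str, int] = {}
    for crit in ELIGIBILITY_ORDER:
        col = colmap[crit]
        if crit == "sex":
            if criteria.sex is None:
                continue
            ok = (table[col].astype(str).str.lower()
                  == criteria.sex.lower())
        elif crit == "age":
            ok = ((table[col] >= criteria.age_min)
                  & (table[col] <= criteria.age_max))
        elif crit == "race":
            ok = table[col].isin(criteria.allowed_race_codes)
        elif crit == "income":
            ok = table[col] <= criteria.income_ratio_max
        elif crit == "pregnancy":
            if not criteria.exclude_pregnant:
                continue
            ok = ~table[col].fillna(False).astype(bool)
        else:  # diet completeness
            ok = table[col] >= criteria.min_recalls
        ok = ok.fillna(False)
        removed = keep & ~ok
        tally[crit] = int(removed.sum())
        keep &= ok
    return list(table.index[keep]), tally


# ---------------------------------------------------------------------------
# Cardiovascular risk-factor flags
# ---------------------------------------------------------------------------

def _or_flags(disjuncts: list[pd.Series]) -> pd.Series:
    """Three-valued OR: 1 if any disjunct is 1; 0 if all known and 0;
    missing (pd.NA) otherwise."""
    stacked = pd.concat(disjuncts, axis=1)
    any_true = (stacked == 1).any(axis=1)
    all_known = stacked.notna().all(axis=1)
    out = pd.Series(pd.NA, index=stacked.index, dtype="Int64")
    out[any_true] = 1
    out[~any_true & all_known] = 0
    return out


def derive_risk_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Binary cardiovascular risk flags from biomarker/questionnaire columns.

    Definitions (boundary behavior deliberate):

    - ``high_cholesterol``: total cholesterol > 200 mg/dL (strict), or LDL
      > 150 mg/dL, or cholesterol-lowering medication.
    - ``obesity``: BMI >= 30 kg/m^2 (inclusive).
    - ``hypertension``: mean systolic BP > 140 mm Hg, or diastolic > 90,
      or blood-pressure medication.
    - ``diabetes``: fasting glucose > 126 mg/dL, or diabetes medication.
    - ``smoker``: current cigarette smoking reported.

    Missing inputs leave a flag missing (person kept; excluded from that
    flag's summaries downstream).  Expected columns (all optional):
    total_chol, ldl, chol_meds, bmi, sbp, dbp, bp_meds, glucose,
    diabetes_meds, current_smoker.
    """
    idx = table.index

    def col(name):
        if name in table.columns:
            return pd.to_numeric(table[name], errors="coerce")
        return pd.Series(pd.NA, index=idx, dtype="Float64")

    def gt(name, cut):
        x = col(name)
        out = pd.Series(pd.NA, index=idx, dtype="Int64")
        out[x > cut] = 1
        out[x.notna() & ~(x > cut)] = 0
        return out

    def ge(name, cut):
        x = col(name)
        out = pd.Series(pd.NA, index=idx, dtype="Int64")
        out[x >= cut] = 1
        out[x.notna() & ~(x >= cut)] = 0
        return out

    def yes(name):
        x = col(name)
        out = pd.Series(pd.NA, index=idx, dtype="Int64")
        out[x == 1] = 1
        out[x.notna() & (x != 1)] = 0
        return out

    flags = pd.DataFrame(index=idx)
    flags["high_cholesterol"] = _or_flags(
        [gt("total_chol", 200), gt("ldl", 150), yes("chol_meds")])
    flags["obesity"] = ge("bmi", 30)
    flags["hypertension"] = _or_flags(
        [gt("sbp", 140), gt("dbp", 90), yes("bp_meds")])
    flags["diabetes"] = _or_flags(
        [gt("glucose", 126), yes("diabetes_meds")])
    flags["smoker"] = yes("current_smoker")
    return flags
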