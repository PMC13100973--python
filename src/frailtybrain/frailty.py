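"""Deficit-accumulation frailty index construction.

A frailty index is the fraction of health deficits a person carries out
of the health variables observed for them: each of >= 30 health
variables is rescored to 0 (no deficit) / 1 (deficit), items failing
standard screening rules are removed, and the index is the deficit sum
divided by the number of observed items, computed only for participants
with at least 80% of items observed.

Screening rules (applied in the fixed order missingness -> prevalence ->
pairwise correlation -> variance inflation):

* missingness: items with more than 15% missing values are dropped;
* prevalence: deficits reported by fewer than 1% or more than 80% of
  participants are dropped (too rare / too common to be informative);
* correlation: of any pair with Pearson |r| >= 0.8 (pairwise-complete,
  on the binarized items) one member is dropped — the one with more
  missing values, ties broken by spec order;
* multicollinearity: variance inflation factors are computed on complete
  cases and the max-VIF item dropped iteratively while any VIF > 10.

Every decision is recorded in a :class:`ScreeningLedger` so the retained
item set is reproducible from the recorded statistics alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .exceptions import ConfigurationError, DegenerateDataError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "HealthItemSpec",
    "ScreeningLedger",
    "default_item_specs",
    "binarize_items",
    "screen_items",
    "compute_frailty_index",
    "variant_index",
    "SENSITIVITY_VARIANTS",
]

DOMAINS = ("physical", "behavior", "global_status", "neuropsychiatric",
           "cognition", "function")
SENSITIVITY_TAGS = ("CDR", "MMSE", "GAD7", "GDS_SF")

#: The three index variants used for circularity control: each excludes
#: the items carrying the listed sensitivity tags.
SENSITIVITY_VARIANTS: dict[str, tuple[str, ...]] = {
    "no_cdr": ("CDR",),
    "no_cdr_mmse": ("CDR", "MMSE"),
    "no_cdr_mmse_gad7_gds": ("CDR", "MMSE", "GAD7", "GDS_SF"),
}


@dataclass(frozen=True)
class HealthItemSpec:
    """Declarative description of one health variable.

    ``rule`` maps the raw value to {0 no deficit, 1 deficit, missing}:

    * ``{"kind": "identity"}`` — value already 0/1; anything else -> missing;
    * ``{"kind": "ge", "cut": c}`` — deficit iff value >= c (cut on the
      deficit side);
    * ``{"kind": "le", "cut": c}`` — deficit iff value <= c;
    * ``{"kind": "lt", "cut": c}`` — deficit iff value < c (used when the
      deficit region is an open lower tail, e.g. MMSE < 24);
    * ``{"kind": "outside", "low": a, "high": b}`` — deficit iff
      value < a or value >= b (healthy band [a, b), upper cut on the
      deficit side).
    """

    name: str
    domain: str
    kind: str = "binary"  # binary | continuous | ordinal
    rule: dict = field(default_factory=lambda: {"kind": "identity"})
    sensitivity_tag: str | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ConfigurationError(f"item {self.name!r}: unknown domain {self.domain!r}")
        if self.sensitivity_tag is not None and self.sensitivity_tag not in SENSITIVITY_TAGS:
            raise ConfigurationError(
                f"item {self.name!r}: unknown sensitivity tag {self.sensitivity_tag!r}"
            )
        if self.rule.get("kind") not in ("identity", "ge", "le", "lt", "outside"):
            raise ConfigurationError(
                f"item {self.name!r}: unknown rule kind {self.rule.get('kind')!r}"
            )


def default_item_specs() -> list[HealthItemSpec]:
    """The 32-item default layout with conventional cut-points.

    Cut-points are conveniences from standard clinical usage (e.g. BMI
    deficit outside [18.5, 30), SBP >= 140, GDS-SF >= 5, MMSE < 24); a
    study fixing different cut-points should supply its own spec list.
    """
    P, B, G, N, C, F = DOMAINS

    def spec(name, domain, rule=None, kind="binary", tag=None):
        return HealthItemSpec(name, domain, kind,
                              rule or {"kind": "identity"}, tag)

    items = [
        # physical: 7 cardiometabolic + 2 sensory + medications/diagnoses
        spec("bmi", P, {"kind": "outside", "low": 18.5, "high": 30.0}, "continuous"),
        spec("sbp", P, {"kind": "ge", "cut": 140.0}, "continuous"),
        spec("dbp", P, {"kind": "ge", "cut": 90.0}, "continuous"),
        spec("resting_hr", P, {"kind": "outside", "low": 60.0, "high": 100.0}, "continuous"),
        spec("hypertension", P),
        spec("diabetes", P),
        spec("dyslipidemia", P),
        spec("visual_impairment", P, {"kind": "ge", "cut": 1.0}, "ordinal"),
        spec("auditory_impairment", P, {"kind": "ge", "cut": 1.0}, "ordinal"),
        spec("n_medications", P, {"kind": "ge", "cut": 5.0}, "continuous"),
        spec("n_diagnoses", P, {"kind": "ge", "cut": 2.0}, "continuous"),
        # behavior
        spec("ever_smoked", B),
        spec("currently_smoking", B),
        spec("cigarettes_per_day", B, {"kind": "ge", "cut": 10.0}, "continuous"),
        spec("substance_abuse", B),
        spec("alcohol_abuse", B),
        # global clinical status: eight CDR items (six domains, global, sum of boxes)
        *[spec(n, G, {"kind": "ge", "cut": 0.5}, "ordinal", "CDR")
          for n in ("cdr_memory", "cdr_orientation", "cdr_judgment",
                    "cdr_community", "cdr_home", "cdr_personal_care",
                    "cdr_global", "cdr_sum_boxes")],
        # neuropsychiatric / depression / anxiety
        spec("npi_q", N, {"kind": "ge", "cut": 1.0}, "continuous"),
        spec("gds_sf", N, {"kind": "ge", "cut": 5.0}, "continuous", "GDS_SF"),
        spec("gad_7", N, {"kind": "ge", "cut": 5.0}, "continuous", "GAD7"),
        # cognition
        spec("mmse", C, {"kind": "lt", "cut": 24.0}, "continuous", "MMSE"),
        # function
        spec("pfaq", F, {"kind": "ge", "cut": 6.0}, "continuous"),
        spec("adlq_basic", F, {"kind": "ge", "cut": 1.0}, "continuous"),
        spec("adlq_instrumental", F, {"kind": "ge", "cut": 7.0}, "continuous"),
        spec("adlq_advanced", F, {"kind": "ge", "cut": 3.0}, "continuous"),
    ]
    assert len(items) == 32
    return items


# ----------------------------------------------------------------------
def _apply_rule(values: pd.Series, rule: dict, name: str) -> pd.Series:
    v = pd.to_numeric(values, errors="coerce")
    kind = rule["kind"]
    if kind == "identity":
        out = v.where(v.isin([0.0, 1.0]))
        bad = v.notna() & ~v.isin([0.0, 1.0])
    elif kind == "ge":
        out = (v >= rule["cut"]).astype(float).where(v.notna())
        bad = pd.Series(False, index=v.index)
    elif kind == "le":
        out = (v <= rule["cut"]).astype(float).where(v.notna())
        bad = pd.Series(False, index=v.index)
    elif kind == "lt":
        out = (v < rule["cut"]).astype(float).where(v.notna())
        bad = pd.Series(False, index=v.index)
    elif kind == "outside":
        out = ((v < rule["low"]) | (v >= rule["high"])).astype(float).where(v.notna())
        bad = pd.Series(False, index=v.index)
    else:  # pragma: no cover - guarded in spec validation
        raise ConfigurationError(f"unknown rule kind {kind!r}")
    bad = bad | (values.notna() & v.isna())
    if bad.any():
        logger.warning("item %s: %d unmappable value(s) set to missing",
                       name, int(bad.sum()))
    return out


def binarize_items(raw: pd.DataFrame,
                   specs: list[HealthItemSpec]) -> pd.DataFrame:
    """Rescore a raw item table to 0/1/NaN deficits per the item rules.

    Every raw column must have a spec; unmapped or out-of-range values
    become missing with a logged warning.
    """
    by_name = {s.name: s for s in specs}
    missing = [c for c in raw.columns if c not in by_name]
    if missing:
        raise SchemaError(f"columns without an item spec: {missing}")
    out = {c: _apply_rule(raw[c], by_name[c].rule, c) for c in raw.columns}
    return pd.DataFrame(out, index=raw.index)


# ----------------------------------------------------------------------
@dataclass
class ScreeningLedger:
    """Per-item screening statistics and the decision taken."""

    table: pd.DataFrame  # index: item; columns: prevalence, missing_frac,
    #                      max_abs_corr, corr_partner, vif, decision
    thresholds: dict = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == "kept"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="item")


def _pairwise_corr(deficits: pd.DataFrame) -> pd.DataFrame:
    with warnings.catch_warnings():
        # constant columns yield NaN correlations; handled downstream
        warnings.simplefilter("ignore", RuntimeWarning)
        return deficits.corr(method="pearson", min_periods=2)


def screen_items(deficits: pd.DataFrame, *,
                 max_missing: float = 0.15,
                 min_prevalence: float = 0.01,
                 max_prevalence: float = 0.80,
                 max_corr: float = 0.8,
                 max_vif: float = 10.0) -> ScreeningLedger:
    """Screen binarized items; returns the full decision ledger.

    Order: missingness, prevalence, pairwise correlation, iterative VIF.
    Prevalence is the deficit rate among observed values. Raises if every
    item is dropped.
    """
    if deficits.shape[1] < 2:
        raise ConfigurationError("screening requires at least 2 items")
    items = list(deficits.columns)
    stats = pd.DataFrame(index=pd.Index(items, name="item"))
    stats["missing_frac"] = deficits.isna().mean()
    stats["prevalence"] = deficits.mean(skipna=True)
    stats["max_abs_corr"] = np.nan
    stats["corr_partner"] = ""
    stats["vif"] = np.nan
    stats["decision"] = "kept"

    stats.loc[stats["missing_frac"] > max_missing, "decision"] = "dropped_missing"
    alive = stats["decision"] == "kept"
    stats.loc[alive & (stats["prevalence"] < min_prevalence), "decision"] = "dropped_rare"
    alive = stats["decision"] == "kept"
    stats.loc[alive & (stats["prevalence"] > max_prevalence), "decision"] = "dropped_common"

    # pairwise correlation screen
    retained = list(stats.index[stats["decision"] == "kept"])
    corr = _pairwise_corr(deficits[retained]).abs()
    np.fill_diagonal(corr.values, 0.0)
    for it in retained:
        if corr.loc[it].notna().any():
            stats.loc[it, "max_abs_corr"] = corr.loc[it].max()
            stats.loc[it, "corr_partner"] = corr.loc[it].idxmax()
    while True:
        sub = corr.loc[retained, retained]
        if sub.size == 0 or not (sub.to_numpy() >= max_corr).any():
            break
        flat = sub.stack()
        a, b = flat.idxmax()
        # drop the member with more missing values; tie -> later spec order
        ma, mb = stats.loc[a, "missing_frac"], stats.loc[b, "missing_frac"]
        if ma > mb:
            drop = a
        elif mb > ma:
            drop = b
        else:
            drop = a if items.index(a) > items.index(b) else b
        partner = b if drop == a else a
        stats.loc[drop, ["decision", "corr_partner", "max_abs_corr"]] = (
            "dropped_correlated", partner, sub.loc[a, b])
        retained.remove(drop)

    # iterative VIF on complete cases
    while len(retained) >= 2:
        cc = deficits[retained].dropna()
        if len(cc) <= len(retained) + 1:
            logger.warning("too few complete cases (%d) for VIF on %d items; "
                           "VIF screen skipped", len(cc), len(retained))
            break
        X = np.column_stack([np.ones(len(cc)), cc.to_numpy(float)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vifs = np.array([variance_inflation_factor(X, j + 1)
                             for j in range(len(retained))])
        for it, v in zip(retained, vifs):
            stats.loc[it, "vif"] = v
        if np.nanmax(vifs) <= max_vif:
            break
        drop = retained[int(np.nanargmax(vifs))]
        stats.loc[drop, "decision"] = "dropped_vif"
        retained.remove(drop)

    if not retained:
        raise DegenerateDataError("screening dropped every item")
    thresholds = dict(max_missing=max_missing, min_prevalence=min_prevalence,
                      max_prevalence=max_prevalence, max_corr=max_corr,
                      max_vif=max_vif)
    return ScreeningLedger(table=stats, thresholds=thresholds)


# ----------------------------------------------------------------------
def compute_frailty_index(deficits: pd.DataFrame,
                          items: list[str] | None = None,
                          variant: str = "full",
                          min_completeness: float = 0.8) -> pd.DataFrame:
    """Observed-denominator frailty index per participant.

    index = (sum of observed deficits) / (number of observed items),
    reported only for participants with at least ``min_completeness`` of
    the item set observed (default 80%); others get ``included = False``
    and a missing index. Returns columns
    ``index, n_observed, n_items, included, variant``.
    """
    if items is not None:
        unknown = [i for i in items if i not in deficits.columns]
        if unknown:
            raise SchemaError(f"unknown items: {unknown}")
        deficits = deficits[items]
    if deficits.shape[1] < 1:
        raise ConfigurationError("at least one retained item is required")
    n_items = deficits.shape[1]
    n_obs = deficits.notna().sum(axis=1)
    included = (n_obs / n_items) >= min_completeness
    index = deficits.sum(axis=1, skipna=True) / n_obs.replace(0, np.nan)
    index = index.where(included)
    return pd.DataFrame({
        "index": index,
        "n_observed": n_obs,
        "n_items": n_items,
        "included": included,
        "variant": variant,
    })


def variant_index(deficits: pd.DataFrame,
                  specs: list[HealthItemSpec],
                  exclude_tags: tuple[str, ...] = (),
                  retained: list[str] | None = None,
                  variant: str | None = None,
                  min_completeness: float = 0.8) -> pd.DataFrame:
    """Frailty index over the item set with the tagged items removed.

    ``exclude_tags`` are sensitivity tags (CDR, MMSE, GAD7, GDS_SF); the
    completeness gate applies to the reduced denominator. With an empty
    exclusion set this is exactly :func:`compute_frailty_index`.
    """
    unknown = set(exclude_tags) - set(SENSITIVITY_TAGS)
    if unknown:
        raise ConfigurationError(f"unknown sensitivity tags: {sorted(unknown)}")
    by_name = {s.name: s for s in specs}
    pool = retained if retained is not None else list(deficits.columns)
    keep = [c for c in pool
            if by_name.get(c) is None or by_name[c].sensitivity_tag not in exclude_tags]
    if not keep:
        raise DegenerateDataError("exclusion set removes every item")
    if variant is None:
        variant = "-".join(exclude_tags) if exclude_tags else "full"
    return compute_frailty_index(deficits, items=keep, variant=variant,
                                 min_completeness=min_completeness)
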