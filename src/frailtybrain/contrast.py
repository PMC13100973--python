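"""Subsampling-based contrasts of frailty-brain associations between groups.

Within each diagnostic group, the per-unit OLS of outcome on frailty
(+ scanner dummies) is refitted on many random subsamples drawn without
replacement, yielding an empirical distribution of the frailty
t-statistic per unit. Two groups' distributions are then contrasted per
unit with Welch independent-sample t-tests, restricted to units whose
full-sample association was significant in at least one of the two
groups, with Benjamini-Hochberg FDR across the restricted set.

The subsample fraction is a design choice (default 0.8 without
replacement) recorded in the output metadata; the magnitude of the
contrast t grows with ``n_draws``, which is therefore reported alongside
every contrast. Draw-level random streams are derived from the master
seed and the draw index, so results are independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import CollinearityError, ConfigurationError, DegenerateDataError
from .neuro import MassUnivariateOLS

logger = logging.getLogger(__name__)

__all__ = ["SubsampleConfig", "subsample_t_distribution", "contrast_groups",
           "ContrastResults"]


@dataclass(frozen=True)
class SubsampleConfig:
    n_draws: int = 1000
    fraction: float = 0.8
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ConfigurationError(f"n_draws must be >= 2, got {self.n_draws}")
        if not 0.0 < self.fraction < 1.0:
            raise ConfigurationError(
                f"fraction must lie strictly in (0, 1), got {self.fraction}; "
                "fraction 1.0 would make every draw identical")


def _draw_t(outcomes: pd.DataFrame, frailty: pd.Series,
            scanner: pd.Series | None, idx: np.ndarray) -> np.ndarray:
    sub_out = outcomes.iloc[idx]
    sub_fr = frailty.iloc[idx]
    sub_sc = scanner.iloc[idx] if scanner is not None else None
    res = MassUnivariateOLS(sub_out, sub_fr, sub_sc).fit()
    if res.table["degenerate"].any():
        raise DegenerateDataError("constant outcome in subsample")
    return res.table["t"].to_numpy()


def subsample_t_distribution(outcomes: pd.DataFrame, frailty: pd.Series,
                             scanner: pd.Series | None,
                             config: SubsampleConfig,
                             group_mask=None) -> pd.DataFrame:
    """Empirical frailty-t distributions from repeated subsampling.

    Returns a (n_draws x units) frame: row d holds the per-unit frailty
    t-statistics of the OLS refit on draw d's subsample (drawn without
    replacement at ``config.fraction``). Degenerate draws (constant
    outcome or rank-deficient design) are resampled up to
    ``config.max_retries`` times, then raise.
    """
    if group_mask is not None:
        mask = np.asarray(group_mask, bool)
        outcomes, frailty = outcomes[mask], frailty[mask]
        scanner = scanner[mask] if scanner is not None else None
    n = len(outcomes)
    m = int(round(config.fraction * n))
    if m < 3:
        raise ConfigurationError(f"subsample size {m} too small (n = {n})")
    rows = np.empty((config.n_draws, outcomes.shape[1]))
    for d in range(config.n_draws):
        for retry in range(config.max_retries + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, d, retry]))
            idx = rng.choice(n, size=m, replace=False)
            try:
                rows[d] = _draw_t(outcomes, frailty, scanner, idx)
                break
            except (DegenerateDataError, CollinearityError) as err:
                if retry == config.max_retries:
                    raise DegenerateDataError(
                        f"draw {d} degenerate after {config.max_retries} retries"
                    ) from err
                logger.warning("draw %d degenerate (retry %d)", d, retry + 1)
    return pd.DataFrame(rows, columns=outcomes.columns,
                        index=pd.RangeIndex(config.n_draws, name="draw"))


@dataclass
class ContrastResults:
    """Per-unit between-group contrast of empirical t distributions."""

    table: pd.DataFrame
    n_draws: int
    fraction: float
    group_a: str
    group_b: str
    alpha: float = 0.05

    @property
    def significant_units(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def summary(self, top: int = 10) -> str:
        sig = self.table[self.table["significant"]]
        lines = [
            f"Subsampling contrast {self.group_a} vs {self.group_b} "
            f"(n_draws = {self.n_draws}, fraction = {self.fraction}): "
            f"{len(sig)}/{len(self.table)} units significant at FDR {self.alpha}",
            sig.head(top).to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="unit")


def contrast_groups(t_samples_a: pd.DataFrame, t_samples_b: pd.DataFrame,
                    restriction_set: list[str] | None = None,
                    group_a: str = "A", group_b: str = "B",
                    alpha: float = 0.05,
                    fraction: float = np.nan) -> ContrastResults:
    """Welch t-test per unit between two groups' empirical t distributions.

    ``restriction_set`` is the units significant in at least one group's
    full-sample analysis; an empty set yields an empty result with a log
    entry. The dominant group per unit is the one with the larger mean
    |t| (its association is stronger); ``direction`` is the sign of the
    dominant group's mean t.
    """
    if t_samples_a.shape[0] != t_samples_b.shape[0]:
        raise ConfigurationError("both groups need the same n_draws")
    units = list(t_samples_a.columns)
    if list(t_samples_b.columns) != units:
        raise ConfigurationError("groups must cover identical units")
    if restriction_set is not None:
        missing = set(restriction_set) - set(units)
        if missing:
            raise ConfigurationError(f"restriction set not in units: {sorted(missing)}")
        units = [u for u in units if u in set(restriction_set)]
    n_draws = t_samples_a.shape[0]
    if not units:
        logger.warning("empty restriction set: no units to contrast")
        empty = pd.DataFrame(columns=["mean_a", "sd_a", "mean_b", "sd_b", "t",
                                      "p", "q", "dominant", "direction",
                                      "significant"])
        return ContrastResults(empty, n_draws, fraction, group_a, group_b, alpha)

    a = t_samples_a[units].to_numpy()
    b = t_samples_b[units].to_numpy()
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    sd_a = a.std(axis=0, ddof=1)
    sd_b = b.std(axis=0, ddof=1)
    identical = np.all(a == b, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t_stat = np.where(identical, 0.0, t_stat)
    p = np.where(identical, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    dom_is_a = np.abs(mean_a) >= np.abs(mean_b)
    dominant = np.where(dom_is_a, group_a, group_b)
    direction = np.sign(np.where(dom_is_a, mean_a, mean_b))
    table = pd.DataFrame({
        "mean_a": mean_a, "sd_a": sd_a, "mean_b": mean_b, "sd_b": sd_b,
        "t": t_stat, "p": p, "q": q, "dominant": dominant,
        "direction": direction, "significant": q < alpha,
    }, index=pd.Index(units, name="unit"))
    return ContrastResults(table, n_draws, fraction, group_a, group_b, alpha)
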