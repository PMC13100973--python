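"""Mass-univariate frailty-brain association models.

For every unit — an atlas region's gray-matter volume or a Fisher-z
ROI-to-ROI connectivity edge — a separate ordinary least-squares model
is fitted with the frailty index as the main predictor and scanner type
as dummy-coded covariates (reference level = most frequent scanner).
Per unit the model adjusted R^2 and p value and the frailty t and p are
extracted; model p values are Benjamini-Hochberg FDR corrected across
the family of non-degenerate units within one group's analysis, and a
unit is flagged significant when BOTH the FDR-adjusted model p and the
raw frailty-predictor p are below alpha (the dual criterion).
FDR-adjusted predictor p values are emitted as well for transparency,
but do not feed the flag.

The family of models shares one design matrix, so the whole family is
solved with a single QR decomposition; on small fixtures the results
match statsmodels OLS to high precision (tested).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import CollinearityError, ConfigurationError, DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = ["fisher_z", "MassUnivariateOLS", "MassUnivariateResults",
           "fit_region_models", "fit_edge_models", "node_degree_summary"]


def fisher_z(r):
    """Fisher z-transformation atanh(r) of a correlation.

    Values with |r| >= 1 - 1e-7 are clipped with a warning; |r| > 1 is a
    domain error.
    """
    r = np.asarray(r, float)
    if np.any(np.abs(r) > 1):
        raise ConfigurationError("correlations must satisfy |r| <= 1")
    lim = 1.0 - 1e-7
    if np.any(np.abs(r) >= lim):
        warnings.warn("correlations with |r| >= 1 - 1e-7 clipped before atanh",
                      UserWarning, stacklevel=2)
        r = np.clip(r, -lim, lim)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _scanner_dummies(scanner: pd.Series) -> pd.DataFrame:
    """Dummy-code scanner labels, dropping the most frequent level as
    reference (maximal stability of the reference column)."""
    scanner = scanner.astype(str)
    counts = scanner.value_counts()
    ref = counts.index[0]
    levels = [l for l in counts.index if l != ref]
    return pd.DataFrame(
        {f"scanner[{l}]": (scanner == l).astype(float) for l in levels},
        index=scanner.index)


class MassUnivariateOLS:
    """One OLS model per outcome column, sharing a single design matrix.

    Parameters
    ----------
    outcomes : DataFrame (participants x units)
        Regional volumes or connectivity edges.
    frailty : Series
        The frailty index (main predictor).
    scanner : Series, optional
        Scanner labels, entered as dummy covariates.
    covariates : DataFrame, optional
        Extra covariates (e.g. CDR total, structural/temporal SNR) for
        sensitivity re-runs.
    """

    def __init__(self, outcomes: pd.DataFrame, frailty: pd.Series,
                 scanner: pd.Series | None = None,
                 covariates: pd.DataFrame | None = None):
        outcomes = pd.DataFrame(outcomes)
        frailty = pd.Series(frailty)
        if not outcomes.index.equals(frailty.index):
            raise ConfigurationError("outcomes and frailty must share an index")
        parts = [pd.Series(1.0, index=outcomes.index, name="const"),
                 frailty.rename("frailty").astype(float)]
        if scanner is not None:
            scanner = pd.Series(scanner).reindex(outcomes.index)
            dums = _scanner_dummies(scanner)
            if not dums.empty:
                parts.append(dums)
        if covariates is not None:
            covariates = pd.DataFrame(covariates).reindex(outcomes.index)
            parts.append(covariates.astype(float))
        design = pd.concat(parts, axis=1)
        ok = design.notna().all(axis=1) & outcomes.notna().all(axis=1)
        self.design = design[ok]
        self.outcomes = outcomes[ok]
        n, p = self.design.shape
        if n <= p + 2:
            raise DegenerateDataError(
                f"n = {n} too small for {p} predictors (need n > p + 2)")
        X = self.design.to_numpy(float)
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            bad = _collinear_columns(self.design)
            raise CollinearityError(f"design matrix rank deficient; "
                                    f"collinear columns: {bad}")

    def fit(self, alpha: float = 0.05) -> "MassUnivariateResults":
        X = self.design.to_numpy(float)
        Y = self.outcomes.to_numpy(float)
        n, p = X.shape
        dof = n - p
        Q, R = np.linalg.qr(X)
        beta = np.linalg.solve(R, Q.T @ Y)           # (p, n_units)
        resid = Y - X @ beta
        ssr = np.einsum("ij,ij->j", resid, resid)
        sst = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
        degenerate = sst <= 1e-30
        if degenerate.any():
            logger.warning("%d unit(s) have constant outcome; excluded from "
                           "the FDR family", int(degenerate.sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2 = ssr / dof
            Rinv = np.linalg.inv(R)
            xtx_inv_diag = np.sum(Rinv ** 2, axis=1)   # diag of (X'X)^-1
            j = list(self.design.columns).index("frailty")
            se = np.sqrt(sigma2 * xtx_inv_diag[j])
            t = beta[j] / se
            p_frailty = 2 * stats.t.sf(np.abs(t), dof)
            r2 = 1.0 - ssr / sst
            r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
            f_model = ((sst - ssr) / (p - 1)) / (ssr / dof)
            p_model = stats.f.sf(f_model, p - 1, dof)

        table = pd.DataFrame({
            "unit": self.outcomes.columns,
            "slope": beta[j],
            "t": t,
            "p_frailty": p_frailty,
            "r2_adj": r2_adj,
            "f_model": f_model,
            "p_model": p_model,
            "degenerate": degenerate,
        }).set_index("unit")

        fam = ~table["degenerate"]
        table["q_model"] = np.nan
        table["q_frailty"] = np.nan
        if fam.any():
            table.loc[fam, "q_model"] = multipletests(
                table.loc[fam, "p_model"], method="fdr_bh")[1]
            table.loc[fam, "q_frailty"] = multipletests(
                table.loc[fam, "p_frailty"], method="fdr_bh")[1]
        table["significant"] = (fam & (table["q_model"] < alpha)
                                & (table["p_frailty"] < alpha))
        return MassUnivariateResults(
            table=table, alpha=alpha, n=n,
            covariates=[c for c in self.design.columns
                        if c not in ("const", "frailty")])


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    cols = list(design.columns)
    bad = []
    base = design.iloc[:, :1].to_numpy(float)
    for j in range(1, len(cols)):
        cand = design.iloc[:, :j + 1].to_numpy(float)
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            bad.append(cols[j])
    return bad


@dataclass
class MassUnivariateResults:
    """Per-unit association table with the dual significance criterion."""

    table: pd.DataFrame
    alpha: float
    n: int
    covariates: list[str] = field(default_factory=list)

    @property
    def significant_units(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def summary(self, top: int = 10) -> str:
        sig = self.table[self.table["significant"]]
        ordered = sig.reindex(sig["t"].abs().sort_values(ascending=False).index)
        lines = [
            f"Mass-univariate OLS: {len(self.table)} units, n = {self.n}, "
            f"covariates = {self.covariates or 'none'}",
            f"significant (model q < {self.alpha} & frailty p < {self.alpha}): "
            f"{len(sig)}",
            ordered.head(top)[["r2_adj", "q_model", "t", "p_frailty"]]
            .to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="unit")


# ----------------------------------------------------------------------
def _apply_mask(objs, mask):
    if mask is None:
        return objs
    return [o[np.asarray(mask, bool)] if o is not None else None for o in objs]


def fit_region_models(roi_table: pd.DataFrame, frailty: pd.Series,
                      scanner: pd.Series | None = None,
                      group_mask=None, covariates: pd.DataFrame | None = None,
                      alpha: float = 0.05) -> MassUnivariateResults:
    """Per-region OLS of volume on frailty (+ scanner dummies) within one
    group; FDR family = that group's non-degenerate regions."""
    roi_table, frailty, scanner, covariates = _apply_mask(
        [roi_table, frailty, scanner, covariates], group_mask)
    return MassUnivariateOLS(roi_table, frailty, scanner, covariates).fit(alpha)


def fit_edge_models(edge_table: pd.DataFrame, frailty: pd.Series,
                    scanner: pd.Series | None = None,
                    group_mask=None, covariates: pd.DataFrame | None = None,
                    alpha: float = 0.05) -> MassUnivariateResults:
    """Per-edge OLS over the strict upper triangle (self-edges rejected)."""
    for name in edge_table.columns:
        i, j = name.split("|")
        if i == j:
            raise ConfigurationError(f"self-edge {name!r}: the diagonal is "
                                     "excluded from edge analysis")
    edge_table, frailty, scanner, covariates = _apply_mask(
        [edge_table, frailty, scanner, covariates], group_mask)
    return MassUnivariateOLS(edge_table, frailty, scanner, covariates).fit(alpha)


def node_degree_summary(edge_results: MassUnivariateResults,
                        regions: list[str] | None = None) -> pd.DataFrame:
    """Count each region's significant edges, split by sign of t.

    Returns a frame indexed by region with columns ``n_negative``,
    ``n_positive``, ``n_total``, sorted by total descending with a
    deterministic tie-break by region name.
    """
    tab = edge_results.table
    if regions is None:
        regions = sorted({r for e in tab.index for r in e.split("|")})
    counts = pd.DataFrame(0, index=pd.Index(regions, name="region"),
                          columns=["n_negative", "n_positive"])
    sig = tab[tab["significant"]]
    for edge, row in sig.iterrows():
        a, b = edge.split("|")
        col = "n_negative" if row["t"] < 0 else "n_positive"
        counts.loc[a, col] += 1
        counts.loc[b, col] += 1
    counts["n_total"] = counts.sum(axis=1)
    counts = counts.reset_index()
    counts = counts.sort_values(["n_total", "region"], ascending=[False, True])
    return counts.set_index("region")
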