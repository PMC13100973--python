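"""Synthetic cohort generation.

Emulates the statistical structure of a three-group dementia cohort
(cognitively unimpaired, Alzheimer's disease, frontotemporal lobar
degeneration) so that every downstream stage — frailty-index scoring,
group statistics, classification, mass-univariate brain associations and
subsampling contrasts — can be exercised and calibrated without access
to the original consortium data.

The generative model, per participant:

* latent frailty drawn from a group-specific normal, truncated to [0, 1]
  by rejection sampling (clipping would pile mass on the boundaries and
  distort both moments and downstream AUCs);
* binary health-deficit items drawn per item with group-specific
  probabilities, optionally coupled to latent frailty through a logistic
  link; missingness injected completely at random;
* regional gray-matter volumes ``intercept + slope_group * frailty +
  scanner_offset + noise``;
* ROI-to-ROI connectivity edges (Fisher-z scale)
  ``baseline + slope_group * frailty + noise``, stored on the strict
  upper triangle and expanded to symmetric matrices on demand.

Ground-truth parameters are returned alongside the data so recovery
tests never need to re-derive them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import region_labels
from .exceptions import ConfigurationError

__all__ = [
    "GroupSpec",
    "ItemSpec",
    "CohortConfig",
    "GeneratedCohort",
    "generate_frailty_scores",
    "generate_item_table",
    "generate_roi_volumes",
    "generate_connectivity",
    "simulate_cohort",
    "edge_index",
    "edge_names",
]

#: Published group parameters: (label, n, frailty mean, frailty SD).
TABLE1_GROUPS = (
    ("CU", 1924, 0.14, 0.065),
    ("AD", 1126, 0.24, 0.075),
    ("FTLD", 411, 0.27, 0.10),
)

#: Item domains of the 32-variable deficit-accumulation index.
ITEM_DOMAINS = (
    "physical",
    "behavior",
    "global_status",
    "neuropsychiatric",
    "cognition",
    "function",
)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    frailty_mean: float
    frailty_sd: float

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if not self.frailty_sd > 0:
            raise ConfigurationError(
                f"group {self.label!r}: frailty_sd must be > 0, got {self.frailty_sd}"
            )
        if not 0.0 <= self.frailty_mean <= 1.0:
            raise ConfigurationError(
                f"group {self.label!r}: frailty_mean must lie in [0, 1], got {self.frailty_mean}"
            )


@dataclass(frozen=True)
class ItemSpec:
    """One binary health-deficit item with per-group deficit probabilities."""

    name: str
    domain: str
    prob: dict[str, float]  # group label -> deficit probability

    def validate(self, group_labels: tuple[str, ...]) -> None:
        if self.domain not in ITEM_DOMAINS:
            raise ConfigurationError(
                f"item {self.name!r}: unknown domain {self.domain!r}"
            )
        for g in group_labels:
            p = self.prob.get(g)
            if p is None:
                raise ConfigurationError(f"item {self.name!r}: missing probability for group {g!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"item {self.name!r}: probability for {g!r} must be in [0, 1], got {p}"
                )


def _default_items(group_specs: tuple[GroupSpec, ...]) -> tuple[ItemSpec, ...]:
    """32 items across the six domains; each item's per-group deficit
    probability defaults to the group's configured mean frailty, so the
    expected deficit-accumulation index equals the configured mean."""
    layout = (
        [("physical", f"physical_{i:02d}") for i in range(1, 12)]
        + [("behavior", f"behavior_{i:02d}") for i in range(1, 6)]
        + [("global_status", f"cdr_{i:02d}") for i in range(1, 9)]
        + [("neuropsychiatric", "npi_q"), ("neuropsychiatric", "gds_sf"),
           ("neuropsychiatric", "gad_7")]
        + [("cognition", "mmse")]
        + [("function", "pfaq"), ("function", "adlq_basic"),
           ("function", "adlq_instrumental"), ("function", "adlq_advanced")]
    )
    probs = {g.label: g.frailty_mean for g in group_specs}
    return tuple(ItemSpec(name, domain, dict(probs)) for domain, name in layout)


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    Defaults reproduce the published three-group structure: CU n=1924
    (frailty 0.14 +/- 0.065), AD n=1126 (0.24 +/- 0.075), FTLD n=411
    (0.27 +/- 0.10); 32 binary items whose per-group prevalence equals
    the group mean frailty; 116 AAL regions; 2 scanners.
    """

    groups: tuple[GroupSpec, ...] = tuple(GroupSpec(*g) for g in TABLE1_GROUPS)
    items: tuple[ItemSpec, ...] | None = None  # None -> 32-item default layout
    missing_rate: float = 0.0
    item_frailty_coupling: float = 0.0  # logit-scale slope on standardised latent frailty
    n_regions: int = 116
    roi_intercepts: np.ndarray | None = None        # (n_regions,)
    roi_slopes: dict[str, np.ndarray] | None = None  # group -> (n_regions,)
    roi_noise_sd: float | np.ndarray = 0.5
    scanner_offsets: np.ndarray | None = None        # (n_scanners, n_regions)
    edge_baseline: np.ndarray | None = None          # (n_edges,)
    edge_slopes: dict[str, np.ndarray] | None = None
    edge_noise_sd: float | np.ndarray = 0.3
    n_scanners: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("groups: at least one group is required")
        for g in self.groups:
            g.validate()
        labels = self.group_labels
        if len(set(labels)) != len(labels):
            raise ConfigurationError("groups: labels must be unique")
        if self.items is None:
            self.items = _default_items(self.groups)
        for it in self.items:
            it.validate(labels)
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(
                f"missing_rate must lie in [0, 1), got {self.missing_rate}"
            )
        if self.n_scanners < 1:
            raise ConfigurationError(f"n_scanners must be >= 1, got {self.n_scanners}")
        if self.n_regions < 2:
            raise ConfigurationError(f"n_regions must be >= 2, got {self.n_regions}")

    # ------------------------------------------------------------------
    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.groups)

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)

    @property
    def n_edges(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    def resolved_roi_params(self) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray, np.ndarray]:
        """Fill unspecified ROI parameters with reproducible defaults drawn
        from a config-seeded stream (so ground truth is well defined)."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        p = self.n_regions
        intercepts = (
            np.asarray(self.roi_intercepts, float)
            if self.roi_intercepts is not None
            else rng.uniform(5.0, 10.0, size=p)
        )
        if intercepts.shape != (p,):
            raise ConfigurationError("roi_intercepts: shape must be (n_regions,)")
        if self.roi_slopes is not None:
            slopes = {g: np.asarray(s, float) for g, s in self.roi_slopes.items()}
            for g in self.group_labels:
                if g not in slopes:
                    raise ConfigurationError(f"roi_slopes: missing group {g!r}")
                if slopes[g].shape != (p,):
                    raise ConfigurationError(f"roi_slopes[{g!r}]: shape must be (n_regions,)")
        else:
            slopes = {g: rng.uniform(-3.0, -1.0, size=p) for g in self.group_labels}
        noise = np.broadcast_to(np.asarray(self.roi_noise_sd, float), (p,)).copy()
        if np.any(noise < 0):
            raise ConfigurationError("roi_noise_sd must be >= 0")
        if self.scanner_offsets is not None:
            offsets = np.asarray(self.scanner_offsets, float)
            if offsets.shape != (self.n_scanners, p):
                raise ConfigurationError("scanner_offsets: shape must be (n_scanners, n_regions)")
        else:
            offsets = rng.normal(0.0, 0.2, size=(self.n_scanners, p))
            offsets[0] = 0.0  # reference scanner
        return intercepts, slopes, noise, offsets

    def resolved_edge_params(self) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 202]))
        m = self.n_edges
        baseline = (
            np.asarray(self.edge_baseline, float)
            if self.edge_baseline is not None
            else rng.normal(0.3, 0.15, size=m)
        )
        if baseline.shape != (m,):
            raise ConfigurationError("edge_baseline: shape must be (n_edges,) over the upper triangle")
        if self.edge_slopes is not None:
            slopes = {g: np.asarray(s, float) for g, s in self.edge_slopes.items()}
            for g in self.group_labels:
                if g not in slopes:
                    raise ConfigurationError(f"edge_slopes: missing group {g!r}")
                if slopes[g].shape != (m,):
                    raise ConfigurationError(f"edge_slopes[{g!r}]: shape must be (n_edges,)")
        else:
            slopes = {g: np.zeros(m) for g in self.group_labels}
        noise = np.broadcast_to(np.asarray(self.edge_noise_sd, float), (m,)).copy()
        if np.any(noise < 0):
            raise ConfigurationError("edge_noise_sd must be >= 0")
        return baseline, slopes, noise


# ----------------------------------------------------------------------
# Edge bookkeeping: strict upper triangle in canonical (i < j) order.

def edge_index(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle in canonical order."""
    return np.triu_indices(n_regions, k=1)


def edge_names(regions: list[str]) -> list[str]:
    ii, jj = edge_index(len(regions))
    return [f"{regions[i]}|{regions[j]}" for i, j in zip(ii, jj)]


# ----------------------------------------------------------------------
@dataclass
class GeneratedCohort:
    """A simulated cohort plus its generative ground truth.

    ``connectivity`` is stored edge-major (participants x upper-triangle
    edges); :meth:`connectivity_matrix` expands one participant's row to
    the full symmetric matrix (zero diagonal, excluded from analysis).
    """

    config: CohortConfig
    group: pd.Series                 # participant -> group label
    frailty_truth: pd.Series         # latent frailty in [0, 1]
    item_table: pd.DataFrame         # participants x items (0/1/NaN)
    roi_volumes: pd.DataFrame        # participants x region names
    connectivity: pd.DataFrame       # participants x edge names (Fisher z)
    scanner: pd.Series               # participant -> scanner label
    demographics: pd.DataFrame | None = None  # age, sex, education
    ground_truth: dict = field(default_factory=dict)

    @property
    def regions(self) -> list[str]:
        return list(self.roi_volumes.columns)

    def connectivity_matrix(self, participant) -> pd.DataFrame:
        regions = self.regions
        n = len(regions)
        mat = np.zeros((n, n))
        ii, jj = edge_index(n)
        vals = self.connectivity.loc[participant].to_numpy()
        mat[ii, jj] = vals
        mat[jj, ii] = vals
        return pd.DataFrame(mat, index=regions, columns=regions)

    # -- serialisation ---------------------------------------------------
    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write all cohort tables as CSV (connectivity in long format)
        and ground truth as a JSON sidecar; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        items = self.item_table.copy()
        items.insert(0, "group", self.group)
        items.insert(1, "frailty_truth", self.frailty_truth)
        paths["item_table"] = str(outdir / "item_table.csv")
        items.to_csv(paths["item_table"], index_label="participant")

        paths["roi_volumes"] = str(outdir / "roi_volumes.csv")
        self.roi_volumes.to_csv(paths["roi_volumes"], index_label="participant")

        long = self.connectivity.stack().rename("z").reset_index()
        long.columns = ["participant", "edge", "z"]
        long[["region_i", "region_j"]] = long["edge"].str.split("|", expand=True)
        paths["connectivity"] = str(outdir / "connectivity_long.csv")
        long[["participant", "region_i", "region_j", "z"]].to_csv(
            paths["connectivity"], index=False
        )

        if self.demographics is not None:
            paths["demographics"] = str(outdir / "demographics.csv")
            self.demographics.to_csv(paths["demographics"],
                                     index_label="participant")

        paths["scanner"] = str(outdir / "scanner.csv")
        self.scanner.rename("scanner").to_csv(paths["scanner"], index_label="participant")

        paths["ground_truth"] = str(outdir / "ground_truth.json")
        with open(paths["ground_truth"], "w") as fh:
            json.dump(_jsonable(self.ground_truth), fh, indent=1)
        return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ----------------------------------------------------------------------
def _truncnorm_rejection(rng: np.random.Generator, mean: float, sd: float, n: int,
                         lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Normal(mean, sd) truncated to [lo, hi] by rejection sampling."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def generate_frailty_scores(config: CohortConfig,
                            rng: np.random.Generator | None = None
                            ) -> tuple[pd.Series, pd.Series]:
    """Draw per-participant latent frailty from group-specific truncated
    normals; returns (frailty, group label), indexed by participant id."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scores, labels = [], []
    for g in config.groups:
        scores.append(_truncnorm_rejection(rng, g.frailty_mean, g.frailty_sd, g.n))
        labels.extend([g.label] * g.n)
    idx = pd.RangeIndex(config.n_total, name="participant")
    return (pd.Series(np.concatenate(scores), index=idx, name="frailty_truth"),
            pd.Series(labels, index=idx, name="group"))


def generate_item_table(config: CohortConfig, frailty_truth: pd.Series,
                        group: pd.Series,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the binary deficit-item table.

    With ``item_frailty_coupling == 0`` items are independent Bernoulli
    given group. A positive coupling tilts each item's logit by
    ``coupling * (frailty - group_mean) / group_sd`` so the computed
    index correlates with latent frailty within group.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if len(config.items) < 30:
        warnings.warn(
            f"only {len(config.items)} items configured; deficit-accumulation "
            "indices are typically built from >= 30 items for reliability",
            UserWarning, stacklevel=2,
        )
    n = len(frailty_truth)
    group_arr = group.to_numpy()
    means = {g.label: g.frailty_mean for g in config.groups}
    sds = {g.label: g.frailty_sd for g in config.groups}
    z = np.zeros(n)
    if config.item_frailty_coupling != 0.0:
        mu = np.vectorize(means.get)(group_arr)
        sd = np.vectorize(sds.get)(group_arr)
        z = (frailty_truth.to_numpy() - mu) / sd

    cols = {}
    for item in config.items:
        p = np.vectorize(item.prob.get)(group_arr).astype(float)
        if config.item_frailty_coupling != 0.0:
            eps = 1e-9
            logit = np.log(np.clip(p, eps, 1 - eps) / np.clip(1 - p, eps, 1 - eps))
            p = 1.0 / (1.0 + np.exp(-(logit + config.item_frailty_coupling * z)))
            p[np.isclose(np.vectorize(item.prob.get)(group_arr).astype(float), 0.0)] = 0.0
        vals = (rng.random(n) < p).astype(float)
        cols[item.name] = vals
    table = pd.DataFrame(cols, index=frailty_truth.index)
    if config.missing_rate > 0:
        mask = rng.random(table.shape) < config.missing_rate
        table = table.mask(mask)
    return table


def generate_roi_volumes(config: CohortConfig, frailty_truth: pd.Series,
                         group: pd.Series, scanner: pd.Series,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Regional volumes: intercept + group slope * frailty + scanner offset + noise."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    intercepts, slopes, noise_sd, offsets = config.resolved_roi_params()
    n, p = len(frailty_truth), config.n_regions
    f = frailty_truth.to_numpy()[:, None]
    slope_mat = np.vstack([slopes[g] for g in group.to_numpy()])
    scan_idx = scanner.str.replace("scanner_", "", regex=False).astype(int).to_numpy()
    vols = intercepts[None, :] + slope_mat * f + offsets[scan_idx, :]
    vols = vols + rng.normal(0.0, 1.0, size=(n, p)) * noise_sd[None, :]
    if np.any(vols <= 0):
        warnings.warn(
            "generated ROI volumes contain non-positive values; intercepts do "
            "not dominate the configured noise/slopes", UserWarning, stacklevel=2,
        )
    return pd.DataFrame(vols, index=frailty_truth.index,
                        columns=region_labels(p))


def generate_connectivity(config: CohortConfig, frailty_truth: pd.Series,
                          group: pd.Series,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fisher-z edge table on the strict upper triangle:
    baseline + group slope * frailty + noise."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    baseline, slopes, noise_sd, = config.resolved_edge_params()
    n, m = len(frailty_truth), config.n_edges
    f = frailty_truth.to_numpy()[:, None]
    slope_mat = np.vstack([slopes[g] for g in group.to_numpy()])
    z = baseline[None, :] + slope_mat * f
    z = z + rng.normal(0.0, 1.0, size=(n, m)) * noise_sd[None, :]
    return pd.DataFrame(z, index=frailty_truth.index,
                        columns=edge_names(region_labels(config.n_regions)))


#: Published demographic parameters per group:
#: (age mean, age SD, female fraction, education mean, education SD).
_DEMOGRAPHICS = {
    "CU": (58.50, 13.58, 1338 / 1911, 15.71, 2.97),
    "AD": (70.91, 8.24, 733 / 1123, 13.63, 3.50),
    "FTLD": (66.31, 8.23, 206 / 409, 14.14, 3.56),
}
_DEMOGRAPHICS_DEFAULT = (65.0, 10.0, 0.5, 14.0, 3.0)


def generate_demographics(config: CohortConfig, group: pd.Series,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Age, sex (1 = female) and years of education per participant, drawn
    from published group-specific distributions where the group label is
    one of CU/AD/FTLD, else from neutral defaults. Used as ANCOVA
    covariates in the sensitivity analysis."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    n = len(group)
    age = np.empty(n)
    sex = np.empty(n)
    edu = np.empty(n)
    for g in config.group_labels:
        mask = (group == g).to_numpy()
        a_mu, a_sd, p_f, e_mu, e_sd = _DEMOGRAPHICS.get(g, _DEMOGRAPHICS_DEFAULT)
        k = int(mask.sum())
        age[mask] = rng.normal(a_mu, a_sd, size=k)
        sex[mask] = (rng.random(k) < p_f).astype(float)
        edu[mask] = np.clip(rng.normal(e_mu, e_sd, size=k), 0, None)
    return pd.DataFrame({"age": age, "sex": sex, "education": edu},
                        index=group.index)


def _assign_scanners(config: CohortConfig, n: int,
                     rng: np.random.Generator) -> pd.Series:
    idx = rng.integers(0, config.n_scanners, size=n)
    return pd.Series([f"scanner_{i}" for i in idx],
                     index=pd.RangeIndex(n, name="participant"), name="scanner")


def simulate_cohort(config: CohortConfig) -> GeneratedCohort:
    """Generate a full cohort (frailty, items, volumes, connectivity,
    scanners) reproducibly from ``config.seed``."""
    frailty, group = generate_frailty_scores(config)
    scanner = _assign_scanners(
        config, config.n_total,
        np.random.default_rng(np.random.SeedSequence([config.seed, 5])))
    items = generate_item_table(config, frailty, group)
    vols = generate_roi_volumes(config, frailty, group, scanner)
    conn = generate_connectivity(config, frailty, group)
    demo = generate_demographics(config, group)
    intercepts, roi_slopes, roi_noise, offsets = config.resolved_roi_params()
    baseline, edge_slopes, edge_noise = config.resolved_edge_params()
    truth = {
        "groups": [(g.label, g.n, g.frailty_mean, g.frailty_sd) for g in config.groups],
        "roi_intercepts": intercepts,
        "roi_slopes": roi_slopes,
        "roi_noise_sd": roi_noise,
        "scanner_offsets": offsets,
        "edge_baseline": baseline,
        "edge_slopes": edge_slopes,
        "edge_noise_sd": edge_noise,
        "missing_rate": config.missing_rate,
        "seed": config.seed,
    }
    return GeneratedCohort(config=config, group=group, frailty_truth=frailty,
                           item_table=items, roi_volumes=vols,
                           connectivity=conn, scanner=scanner,
                           demographics=demo, ground_truth=truth)
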