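"""Image-quality covariates: spatial SNR and segmented temporal SNR.

Spatial SNR of a structural image is the mean intensity of (already
masked) brain voxels divided by the standard deviation of those
intensities. Temporal SNR of an fMRI time series is computed by
splitting the series into consecutive non-overlapping 20-timepoint
segments anchored at the first sample, taking each complete segment's
mean over its standard deviation, and averaging across segments; a
trailing remainder shorter than one segment is discarded. Both are
dimensionless. Spatial SNR is scale-invariant; tSNR is not
shift-invariant (adding a constant offset raises the mean but not the
SD). Correlating these metrics with frailty per group supports the
"quality unrelated to frailty" sensitivity check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError

logger = logging.getLogger(__name__)

__all__ = ["QualityRecord", "spatial_snr", "temporal_snr",
           "quality_frailty_association"]


@dataclass(frozen=True)
class QualityRecord:
    participant: object
    spatial_snr: float
    temporal_snr: float
    n_segments: int


def spatial_snr(intensities) -> float:
    """mean / SD of masked brain-voxel intensities (sample SD, ddof=1)."""
    x = np.asarray(intensities, float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ConfigurationError("spatial SNR needs at least 2 voxel values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero standard deviation: SNR undefined")
    return float(x.mean() / sd)


def temporal_snr(series, segment_length: int = 20,
                 bias_correction: bool = True) -> tuple[float, int]:
    """Segmented temporal SNR of a time series.

    Returns ``(tsnr, n_segments)`` with n_segments = floor(T / L) for a
    series of T points and segment length L; the trailing remainder is
    discarded with a log entry. Segments with zero SD are skipped with a
    warning. Requires T >= L.

    With 20-point segments the raw mean-of-ratios estimator is biased
    upward by E[sigma/S] ~ 4% (Jensen's inequality on 1/S); by default
    each segment ratio is divided by the normal-theory factor
    ``sqrt((L-1)/2) * Gamma((L-2)/2) / Gamma((L-1)/2)`` so the estimator
    is unbiased for mu/sigma on stationary Gaussian data. Disable with
    ``bias_correction=False`` to get the raw ratio mean.
    """
    x = np.asarray(series, float)
    T = len(x)
    if segment_length < 2:
        raise ConfigurationError("segment_length must be >= 2")
    if T < segment_length:
        raise ConfigurationError(
            f"series length {T} shorter than one segment ({segment_length})")
    n_seg = T // segment_length
    rem = T - n_seg * segment_length
    if rem:
        logger.info("discarding trailing %d point(s) (< one segment)", rem)
    segs = x[:n_seg * segment_length].reshape(n_seg, segment_length)
    sds = segs.std(axis=1, ddof=1)
    ok = sds > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-SD segment(s) skipped",
                      UserWarning, stacklevel=2)
    if not ok.any():
        raise DegenerateDataError("every segment has zero SD: tSNR undefined")
    ratios = segs[ok].mean(axis=1) / sds[ok]
    if bias_correction and segment_length >= 4:
        from scipy.special import gammaln

        nu = segment_length - 1
        kappa = np.exp(0.5 * np.log(nu / 2)
                       + gammaln((nu - 1) / 2) - gammaln(nu / 2))
        ratios = ratios / kappa
    return float(ratios.mean()), int(n_seg)


def quality_frailty_association(quality: pd.Series, frailty: pd.Series,
                                group: pd.Series | None = None) -> pd.DataFrame:
    """Per-group Pearson correlation of a quality metric with frailty.

    Returns a frame with columns ``r, p, n`` indexed by group (one row
    'all' when no grouping is given). Requires n >= 3 per group.
    """
    quality = pd.Series(quality)
    frailty = pd.Series(frailty).reindex(quality.index)
    if group is None:
        group = pd.Series("all", index=quality.index)
    else:
        group = pd.Series(group).reindex(quality.index)
    rows = {}
    for g, idx in quality.groupby(group).groups.items():
        q, f = quality.loc[idx], frailty.loc[idx]
        ok = q.notna() & f.notna()
        if ok.sum() < 3:
            raise DegenerateDataError(f"group {g!r}: n < 3 for correlation")
        r, p = stats.pearsonr(q[ok], f[ok])
        rows[g] = {"r": float(r), "p": float(p), "n": int(ok.sum())}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("group")
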