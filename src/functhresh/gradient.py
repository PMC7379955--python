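"""Compound drought-intensity index from covarying physical stressors.

During stream drying the primary stressors (shrinking wetted area, falling
water volume and flow, widening temperature range) covary strongly, so a
single latent axis captures most of their variance. The drought intensity
(DI) of each channel is the first-axis score of a centred covariance PCA of
the four stressors, oriented so that DI rises as flow falls, and min-max
rescaled so 0 is the least and 1 the most disturbed channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .synthetic import STRESSORS

#: DI band edges: < 0.2 low, 0.2-0.7 moderate (bounds inclusive), > 0.7 high.
BAND_EDGES = (0.2, 0.7)


@dataclass
class DroughtIndex:
    """Per-channel drought intensity with PCA diagnostics."""

    frame: pd.DataFrame  # columns: di, band
    explained_variance: float
    loadings: pd.Series

    @property
    def di(self) -> pd.Series:
        return self.frame["di"]


def compute_drought_index(env: pd.DataFrame, standardize: bool = False) -> DroughtIndex:
    """Collapse the stressor table to a 0-1 drought-intensity axis.

    Parameters
    ----------
    env : DataFrame
        Channel x stressor table with the four columns ``wetted_area``,
        ``water_volume``, ``flow`` and ``max_temp_range``, in native units.
    standardize : bool
        If True, stressors are scaled to unit variance before the PCA
        (correlation rather than covariance PCA). Default off: stressor
        units are taken at face value.

    Raises
    ------
    ValueError
        If fewer than 3 channels are supplied or no stressor varies.
    """
    missing = [c for c in STRESSORS if c not in env.columns]
    if missing:
        raise KeyError(f"stressor columns missing: {missing}")
    X = env[list(STRESSORS)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("stressor table contains missing values")
    if len(X) < 3:
        raise ValueError("drought index needs at least 3 channels")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate gradient: all channels have identical stressors")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)

    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(X)[:, 0]
    loadings = pd.Series(pca.components_[0], index=list(STRESSORS))
    explained = float(pca.explained_variance_ratio_[0])

    # Orient severity upward: DI must correlate negatively with flow.
    flow = env["flow"].to_numpy(dtype=float)
    corr = np.corrcoef(scores, flow)[0, 1] if np.std(flow) > 0 else -loadings["flow"]
    if corr > 0:
        scores = -scores
        loadings = -loadings

    lo, hi = scores.min(), scores.max()
    di = (scores - lo) / (hi - lo)
    frame = pd.DataFrame({"di": di}, index=env.index)
    frame["band"] = classify_intensity(frame["di"])
    return DroughtIndex(frame=frame, explained_variance=explained, loadings=loadings)


def classify_intensity(di: pd.Series | np.ndarray) -> pd.Series:
    """Label DI values as low (< 0.2), moderate (0.2-0.7) or high (> 0.7).

    Both printed band bounds are assigned to the moderate band.
    """
    di = pd.Series(di)
    bands = pd.Series("moderate", index=di.index, dtype=object)
    bands[di < BAND_EDGES[0]] = "low"
    bands[di > BAND_EDGES[1]] = "high"
    return bands
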