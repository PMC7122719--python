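"""Plotting helpers: t-SNE scatter with Gaussian-mixture contours.

Requires matplotlib (optional dependency, ``pip install psychembed[plot]``).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler


def plot_tsne_gmm(
    coords: np.ndarray,
    groups: Sequence[str],
    seed: int = 0,
    ax=None,
):
    """Scatter of 2-D projected patients colored by group, with contours of
    a 2-component GMM refit in the projected space."""
    import matplotlib.pyplot as plt

    coords = np.asarray(coords, dtype=np.float64)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    Z = StandardScaler().fit_transform(coords)
    gmm = GaussianMixture(n_components=2, covariance_type="full", random_state=seed)
    gmm.fit(Z)
    xx, yy = np.meshgrid(
        np.linspace(Z[:, 0].min() - 1, Z[:, 0].max() + 1, 200),
        np.linspace(Z[:, 1].min() - 1, Z[:, 1].max() + 1, 200),
    )
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    dens = -gmm.score_samples(grid).reshape(xx.shape)
    ax.contour(xx, yy, dens, levels=10, cmap="coolwarm", alpha=0.5)
    for grp, marker in zip(sorted(set(groups)), "ov^sD"):
        mask = np.array([g == grp for g in groups])
        ax.scatter(Z[mask, 0], Z[mask, 1], s=14, marker=marker, label=grp, alpha=0.8)
    ax.legend(frameon=False)
    ax.set_xlabel("tSNE 1")
    ax.set_ylabel("tSNE 2")
    return ax
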