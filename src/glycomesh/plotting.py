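"""Histogram helpers for re-plotting the measured distributions."""

from __future__ import annotations

import numpy as np

from .datatypes import MorphometryResult, NNResult

__all__ = ["histogram_with_gaussian"]


def histogram_with_gaussian(result, ax=None, bins=20, **hist_kw):
    """Histogram of a result's samples with a Gaussian overlay at the
    sample mean/sd — the conventional presentation of spacing, pore-size
    and diameter distributions."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if isinstance(result, NNResult):
        samples, mu, sd = result.nn_distances, result.gaussian_mu, result.gaussian_sigma
        label = "nearest-neighbor distance (nm)"
    elif isinstance(result, MorphometryResult):
        samples, mu, sd = result.samples, result.mean, result.sd
        label = f"{result.measurement_kind} (nm)"
    else:
        samples = np.asarray(result, dtype=float)
        mu, sd = samples.mean(), samples.std(ddof=1)
        label = "value"
    ax.hist(samples, bins=bins, density=True, alpha=0.6, **hist_kw)
    if sd > 0:
        x = np.linspace(samples.min(), samples.max(), 200)
        ax.plot(x, np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi)))
    ax.set_xlabel(label)
    ax.set_ylabel("density")
    return ax
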