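"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: the ACF here is the
direct O(n^2) summation (the package uses FFT), and Fleiss' kappa is the
textbook category-proportion formula written out by hand (the package
delegates to statsmodels).
"""

from __future__ import annotations

import numpy as np


def acf_direct(x: np.ndarray) -> np.ndarray:
    """Biased sample ACF by direct summation: c_k = (1/n) sum (x_t-m)(x_{t+k}-m)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = x.mean()
    d = x - m
    c = np.array([np.dot(d[: n - k], d[k:]) / n for k in range(n)])
    return c / c[0]


def first_1e_crossing_direct(x: np.ndarray) -> float:
    """First 1/e crossing of the direct-summation ACF, linearly interpolated."""
    r = acf_direct(x)
    thresh = 1.0 / np.e
    for k in range(1, len(r)):
        if r[k] < thresh:
            return (k - 1) + (thresh - r[k - 1]) / (r[k] - r[k - 1])
    return float(len(x) - 1)


def fleiss_kappa_direct(labels: np.ndarray) -> float:
    """Fleiss' kappa from an (n_subjects, n_raters) label matrix, by hand.

    P_i = (sum_j n_ij^2 - r) / (r (r-1)); kappa = (mean P_i - P_e)/(1 - P_e)
    with P_e = sum_j p_j^2.
    """
    labels = np.asarray(labels, dtype=object)
    n, r = labels.shape
    cats = sorted({v for row in labels for v in row})
    counts = np.zeros((n, len(cats)))
    for i in range(n):
        for v in labels[i]:
            counts[i, cats.index(v)] += 1
    p_i = ((counts**2).sum(axis=1) - r) / (r * (r - 1))
    p_j = counts.sum(axis=0) / (n * r)
    p_e = (p_j**2).sum()
    if p_e == 1.0:
        return float("nan")
    return float((p_i.mean() - p_e) / (1 - p_e))
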