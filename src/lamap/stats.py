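"""Agreement and correlation statistics.

Spearman rank correlation, ordinary least-squares regression, Bland-Altman
limits of agreement (bias ± 1.96 SD of the paired differences) and the
Hotelling–Steiger test for the difference of two dependent correlations
sharing one variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Tuple

import numpy as np
from scipy import stats as sps


def _paired(x, y, n_min: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < n_min:
        raise ValueError(f"need at least {n_min} pairs")
    return x, y


def spearman(x, y, exact: bool = False) -> Tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the t approximation with n − 2 degrees of freedom;
    ``exact=True`` computes the two-sided permutation p instead (all n!
    permutations; intended for n ≤ 9).
    """
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant variable")
    r, p = sps.spearmanr(x, y)
    r, p = float(r), float(p)
    if exact:
        if x.size > 9:
            raise ValueError("exact permutation p supported for n <= 9 only")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        perms = np.array(list(permutations(range(x.size))))
        ry_p = ry[perms]
        rx_c = rx - rx.mean()
        ry_c = ry_p - ry_p.mean(axis=1, keepdims=True)
        rs = (ry_c @ rx_c) / np.sqrt((rx_c @ rx_c) * (ry_c * ry_c).sum(axis=1))
        p = float(np.mean(np.abs(rs) >= abs(r) - 1e-12))
    return r, p


def linear_regression(x, y) -> Tuple[float, float, float]:
    """Ordinary least squares y = slope·x + intercept, with Pearson r.

    A constant y yields slope 0 but an undefined correlation → error on r
    (the slope/intercept are still well defined and reported in the message).
    """
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0:
        raise ValueError("linear regression undefined for constant x")
    if np.ptp(y) == 0:
        slope = 0.0
        intercept = float(y[0])
        raise ValueError(
            f"pearson r undefined for constant y (slope={slope}, "
            f"intercept={intercept})")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def bland_altman(x, y) -> Tuple[float, float, float]:
    """Bland-Altman agreement: bias and ±1.96 SD limits of the differences.

    Differences d = x − y; bias = mean(d); limits = bias ± 1.96·SD(d) with
    the sample (n − 1) standard deviation.
    """
    x, y = _paired(x, y, 3)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def _check_correlation_triple(r12: float, r13: float, r23: float) -> None:
    for r in (r12, r13, r23):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
        if abs(r) == 1.0:
            raise ValueError("|r| = 1 diverges under the Fisher transform")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det < -1e-12:
        raise ValueError("inconsistent correlation triple (not PSD)")


def steiger_test(r12: float, r13: float, r23: float, n: int,
                 variant: str = "steiger-z") -> Tuple[float, float]:
    """Test the difference of two dependent correlations sharing variable 1.

    ``variant="steiger-z"`` (default) computes Steiger's Z̄* for the
    common-index case: Fisher-transformed correlations compared with the
    shared-variable covariance term, two-sided p from the normal law.
    ``variant="hotelling-t"`` computes Hotelling's t with n − 3 degrees of
    freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    _check_correlation_triple(r12, r13, r23)
    if variant == "steiger-z":
        z12 = math.atanh(r12)
        z13 = math.atanh(r13)
        rbar = 0.5 * (r12 + r13)
        num = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (
            1 - 2 * rbar**2 - r23**2)
        cov = num / (1 - rbar**2) ** 2
        stat = (z12 - z13) * math.sqrt((n - 3) / (2.0 * (1.0 - cov)))
        p = 2.0 * sps.norm.sf(abs(stat))
    elif variant == "hotelling-t":
        det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
        stat = (r12 - r13) * math.sqrt(
            (n - 3) * (1 + r23) / (2.0 * det))
        p = 2.0 * sps.t.sf(abs(stat), df=n - 3)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(stat), float(p)


@dataclass
class AgreementStats:
    """Agreement summary between two paired measurements."""

    spearman_r: float
    spearman_p: float
    slope: float
    intercept: float
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


def agreement(x, y) -> AgreementStats:
    """All agreement statistics for one paired comparison."""
    x, y = _paired(x, y, 3)
    r, p = spearman(x, y)
    slope, intercept, pr = linear_regression(x, y)
    bias, lo, hi = bland_altman(x, y)
    return AgreementStats(
        spearman_r=r, spearman_p=p, slope=slope, intercept=intercept,
        pearson_r=pr, bias=bias, loa_low=lo, loa_high=hi, n=int(x.size))


def fwhm(sigma) -> np.ndarray:
    """Full width at half maximum of a Gaussian: 2·sqrt(2 ln 2)·σ."""
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * np.asarray(sigma, dtype=float)
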