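"""Rank correlation and tests for comparing two dependent correlations.

The comparison of interest: is variable j (mean laterality RT) more
strongly correlated with k (phantom motor control) than with h (age at
amputation)?  The two correlations r_jk and r_jh share variable j, so the
comparison must account for their dependence through r_kh.  The default
statistic is Steiger's Z1* (Fisher-z difference with a pooled-correlation
covariance term); the Hotelling-Williams t is available as an
alternative.  When applied to Spearman rhos the rhos are passed through
the same machinery, a common-practice approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Literal, NamedTuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrPair",
    "spearman",
    "dependent_corr_test",
    "dependent_corr_from_samples",
]

#: largest n for which the exact permutation p-value is enumerated
EXACT_N_MAX = 8


@dataclass(frozen=True)
class CorrPair:
    """Two dependent correlations sharing variable j.

    r_jk and r_jh share j; r_kh correlates the two non-shared variables;
    n is the common sample size.
    """

    r_jk: float
    r_jh: float
    r_kh: float
    n: int

    def __post_init__(self) -> None:
        for name in ("r_jk", "r_jh", "r_kh"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [-1, 1]")
        if self.n < 4:
            raise ValueError("need n >= 4")


class TestResult(NamedTuple):
    statistic: float
    p_value: float


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman(x, y) -> TestResult:
    """Average-rank Spearman correlation with exact or t-approximate p.

    Exact two-sided permutation p for n <= 8 (full enumeration over rank
    permutations); the usual t approximation otherwise.  Constant input is
    an error: rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d samples")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; Spearman correlation undefined")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N_MAX:
        # exact null: permute one rank vector over all n! orderings
        perms = np.array(list(permutations(ry)))
        rhos = np.corrcoef(rx, perms)[0, 1:]
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(rho, p)


def _fisher_z(r: float) -> float:
    if abs(r) >= 1.0:
        raise ValueError("|r| = 1; Fisher z transform undefined")
    return math.atanh(r)


def _steiger(pair: CorrPair) -> float:
    """Steiger's Z1* with the pooled correlation rbar = (r_jk + r_jh)/2."""
    z1 = _fisher_z(pair.r_jk)
    z2 = _fisher_z(pair.r_jh)
    rbar = (pair.r_jk + pair.r_jh) / 2.0
    rm2 = rbar * rbar
    # covariance factor for two correlations sharing one variable
    psi = pair.r_kh * (1.0 - 2.0 * rm2) - 0.5 * rm2 * (1.0 - 2.0 * rm2 - pair.r_kh**2)
    sbar = psi / (1.0 - rm2) ** 2
    return (z1 - z2) * math.sqrt((pair.n - 3) / (2.0 - 2.0 * sbar))


def _williams(pair: CorrPair) -> tuple[float, int]:
    """Hotelling-Williams t with n-3 degrees of freedom."""
    r12, r13, r23, n = pair.r_jk, pair.r_jh, pair.r_kh, pair.n
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    rbar = (r12 + r13) / 2.0
    denom = 2.0 * detR * (n - 1) / (n - 3) + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * math.sqrt((n - 1) * (1.0 + r23) / denom)
    return t, n - 3


def dependent_corr_test(
    pair: CorrPair,
    tail: Literal["one", "two"] = "two",
    method: Literal["steiger", "williams"] = "steiger",
) -> TestResult:
    """Test the difference between two dependent correlations sharing j.

    ``tail="one"`` tests the directional hypothesis r_jk > r_jh (p is the
    upper-tail probability of the signed statistic); ``"two"`` is
    two-sided.  Equal input correlations give a statistic of exactly 0 and
    a one-tailed p of 0.5.
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if method == "steiger":
        stat = _steiger(pair)
        sf = sps.norm.sf(stat)
    elif method == "williams":
        stat, df = _williams(pair)
        sf = sps.t.sf(stat, df=df)
    else:
        raise ValueError("method must be 'steiger' or 'williams'")
    p = float(sf) if tail == "one" else float(2.0 * min(sf, 1.0 - sf))
    return TestResult(float(stat), p)


def dependent_corr_from_samples(
    j, k, h,
    tail: Literal["one", "two"] = "one",
    method: Literal["steiger", "williams"] = "steiger",
    corr: Literal["spearman", "pearson"] = "spearman",
) -> tuple[TestResult, CorrPair]:
    """Compare corr(j, k) against corr(j, h) from raw paired samples.

    With ``corr="spearman"`` all three correlations are computed on ranks
    before entering the dependent-correlation machinery.
    """
    j = np.asarray(j, dtype=float)
    k = np.asarray(k, dtype=float)
    h = np.asarray(h, dtype=float)
    if not (j.shape == k.shape == h.shape) or j.ndim != 1:
        raise ValueError("j, k, h must be paired 1-d samples")
    if corr == "spearman":
        j, k, h = _rank(j), _rank(k), _rank(h)
    r = np.corrcoef(np.vstack([j, k, h]))
    pair = CorrPair(r_jk=float(r[0, 1]), r_jh=float(r[0, 2]), r_kh=float(r[1, 2]), n=j.size)
    return dependent_corr_test(pair, tail=tail, method=method), pair
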