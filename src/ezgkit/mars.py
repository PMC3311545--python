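"""MA-plot-based random-sampling significance test for unreplicated counts.

Two libraries with totals n1, n2 are modelled as binomial samples with a
common per-transcript proportion p under the null. With X = log2(k1'),
Y = log2(k2') (pseudocounted), M = X - Y and A = (X + Y)/2, the
delta-method normal approximation gives

    mu_X = log2(n1 p),  var_X = (1 - p) / (n1 p ln^2 2)

and likewise for Y. The test replaces the unknown p by the per-transcript
estimate p_hat = 2^a / sqrt(n1 n2) and refers

    z = |m - E(M|a)| / sqrt(Var(M|a))

to a standard normal. With the geometric p_hat, a - E(A) vanishes
identically, so E(M|a) reduces to log2(n1/n2) while Var(M|a) keeps the
bivariate-normal reduction Var(M) - Cov(M,A)^2/Var(A); this reproduces the
reference implementation's statistic. The reduction is anticonservative
when n1 and n2 differ appreciably; ``variance="unconditional"`` keeps the
full Var(M) instead, which restores type-I calibration at unequal totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .quantify import BIN_LABELS, TimeCourseCounts

_LN2_SQ = math.log(2) ** 2
_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-12


class MarsError(ValueError):
    """Raised for invalid test inputs."""


@dataclass
class MarsResult:
    """Per-transcript outcome of the random-sampling test for one pair."""

    transcript_id: str
    k1: float  # pseudocounted count, library 1
    k2: float  # pseudocounted count, library 2
    m: float
    a: float
    z: float
    p_value: float
    q_value: float | None = None
    e_m_given_a: float = 0.0
    saturated: bool = False  # p_hat clamp hit the upper bound

    @property
    def delta(self) -> float:
        """Signed departure of M from its null conditional expectation."""
        return self.m - self.e_m_given_a


def conditional_moments(
    mu_x: float,
    var_x: float,
    mu_y: float,
    var_y: float,
    a: float,
) -> tuple[float, float]:
    """Conditional mean and variance of M = X - Y given A = a.

    X and Y are independent normals; (M, A) with A = (X + Y)/2 is then
    bivariate normal and the standard conditional formulas apply.
    """
    e_m = mu_x - mu_y
    var_m = var_x + var_y
    e_a = (mu_x + mu_y) / 2.0
    var_a = var_m / 4.0
    cov_ma = (var_x - var_y) / 2.0
    e_m_given_a = e_m + cov_ma / var_a * (a - e_a)
    var_m_given_a = var_m - cov_ma**2 / var_a
    return e_m_given_a, var_m_given_a


def _mars_arrays(
    k1: np.ndarray,
    k2: np.ndarray,
    n1: float,
    n2: float,
    pseudocount: float = 1.0,
    variance: str = "conditional",
) -> dict[str, np.ndarray]:
    if n1 <= 0 or n2 <= 0:
        raise MarsError("library sizes must be positive")
    if variance not in ("conditional", "unconditional"):
        raise MarsError(f"unknown variance mode {variance!r}")
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if (k1 < 0).any() or (k2 < 0).any():
        raise MarsError("counts must be non-negative")
    k1p = k1 + pseudocount
    k2p = k2 + pseudocount
    if (k1p <= 0).any() or (k2p <= 0).any():
        raise MarsError("pseudocounted counts must be positive")
    x = np.log2(k1p)
    y = np.log2(k2p)
    m = x - y
    a = (x + y) / 2.0
    p_raw = np.exp2(a) / math.sqrt(n1 * n2)
    saturated = p_raw >= _P_CEIL
    p_hat = np.clip(p_raw, _P_FLOOR, _P_CEIL)
    var_x = (1.0 - p_hat) / (n1 * p_hat * _LN2_SQ)
    var_y = (1.0 - p_hat) / (n2 * p_hat * _LN2_SQ)
    e_m = math.log2(n1 / n2)
    var_m = var_x + var_y
    cov_ma = (var_x - var_y) / 2.0
    var_a = var_m / 4.0
    # a - E(A) == 0 identically for the geometric p_hat, so the
    # conditional mean reduces to E(M).
    e_m_given_a = np.full_like(m, e_m)
    if variance == "conditional":
        var_used = var_m - cov_ma**2 / var_a
    else:
        var_used = var_m
    z = np.abs(m - e_m_given_a) / np.sqrt(var_used)
    p_value = 2.0 * norm.sf(z)
    return {
        "k1": k1p,
        "k2": k2p,
        "m": m,
        "a": a,
        "z": z,
        "p_value": p_value,
        "e_m_given_a": e_m_given_a,
        "saturated": saturated,
    }


def mars_test(
    k1: float,
    k2: float,
    n1: float,
    n2: float,
    pseudocount: float = 1.0,
    variance: str = "conditional",
    transcript_id: str = "",
) -> MarsResult:
    """Test a single count pair for a difference in sampling proportion."""
    r = _mars_arrays(
        np.array([k1]), np.array([k2]), n1, n2, pseudocount, variance
    )
    return MarsResult(
        transcript_id=transcript_id,
        k1=float(r["k1"][0]),
        k2=float(r["k2"][0]),
        m=float(r["m"][0]),
        a=float(r["a"][0]),
        z=float(r["z"][0]),
        p_value=float(r["p_value"][0]),
        e_m_given_a=float(r["e_m_given_a"][0]),
        saturated=bool(r["saturated"][0]),
    )


def mars_table(
    counts: TimeCourseCounts,
    bin_pair: tuple[str, str] = ("0-2", "2-4"),
    pseudocount: float = 1.0,
    variance: str = "conditional",
    qvalue_lambda: float = 0.5,
) -> list[MarsResult]:
    """Run the test for every transcript on one pair of time bins.

    k1/n1 come from the first bin of the pair, k2/n2 from the second;
    q-values are Storey estimates over the whole table.
    """
    if bin_pair[0] == bin_pair[1]:
        raise MarsError("bin pair must name two distinct bins")
    i = counts.bin_index(bin_pair[0])
    j = counts.bin_index(bin_pair[1])
    r = _mars_arrays(
        counts.counts[:, i],
        counts.counts[:, j],
        float(counts.library_sizes[i]),
        float(counts.library_sizes[j]),
        pseudocount,
        variance,
    )
    q_values = (
        compute_qvalues(r["p_value"], lam=qvalue_lambda)
        if counts.n_transcripts
        else np.array([])
    )
    return [
        MarsResult(
            transcript_id=tid,
            k1=float(r["k1"][t]),
            k2=float(r["k2"][t]),
            m=float(r["m"][t]),
            a=float(r["a"][t]),
            z=float(r["z"][t]),
            p_value=float(r["p_value"][t]),
            q_value=float(q_values[t]),
            e_m_given_a=float(r["e_m_given_a"][t]),
            saturated=bool(r["saturated"][t]),
        )
        for t, tid in enumerate(counts.transcript_ids)
    ]


def compute_qvalues(p_values, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    pi0_hat = #{p > lam} / (m (1 - lam)), clamped to [1/m, 1];
    q(p_(i)) = min_{j >= i} pi0_hat * m * p_(j) / j over sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise MarsError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise MarsError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = np.count_nonzero(p > lam) / (m * (1.0 - lam))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def results_to_frame(
    results: list[MarsResult], thresholds: tuple[float, ...] = (0.001, 0.05)
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "k1": [r.k1 for r in results],
            "k2": [r.k2 for r in results],
            "m": [r.m for r in results],
            "a": [r.a for r in results],
            "z": [r.z for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
    for thr in thresholds:
        df[f"significant_{thr}"] = df["p_value"] < thr
    return df


def write_mars_table(
    results: list[MarsResult],
    path,
    thresholds: tuple[float, ...] = (0.001, 0.05),
) -> None:
    results_to_frame(results, thresholds).to_csv(path, sep="\t", index=False)


__all__ = [
    "MarsError",
    "MarsResult",
    "conditional_moments",
    "mars_test",
    "mars_table",
    "compute_qvalues",
    "results_to_frame",
    "write_mars_table",
    "BIN_LABELS",
]
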