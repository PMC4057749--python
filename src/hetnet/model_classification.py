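"""Network-model classification: random vs scale-free vs hierarchical.

Random networks have a Poisson-like P(k) and a degree-independent C(k);
scale-free networks follow P(k) ~ k^−γ; hierarchical networks additionally
show C(k) ~ k^−1.  Following common PPI practice, both distributions are fit
twice — an ordinary least-squares line on the raw (k, y) points and a line
on the log10–log10 points (the power law) — and the R² of the competing
fits drives a three-way decision rule.  Fits are on raw unique-k points, no
logarithmic binning or CCDF; maximum-likelihood power-law estimation is
deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: Minimum R² advantage of the power-law fit over the linear fit on P(k)
#: before the network is called non-random.
DEFAULT_DELTA = 0.1
#: How far the C(k) power-law exponent may sit from −1 for "hierarchical".
DEFAULT_GAMMA_TOLERANCE = 0.3
#: Minimum C(k) power-law R² required for "hierarchical".
DEFAULT_CK_R2_THRESHOLD = 0.7


@dataclass(frozen=True)
class FitResult:
    """A least-squares fit of one model to one distribution.

    ``r_squared`` is clamped to [0, 1] for reporting; ``r_squared_raw``
    keeps the unclamped value (negative for fits worse than the mean).
    ``degenerate`` flags zero-variance inputs, which are reported with
    R² = 1 but excluded from classification.
    """

    model: str  # "linear" | "power-law"
    slope: float
    intercept: float
    r_squared: float
    r_squared_raw: float
    degenerate: bool = False

    @property
    def gamma(self) -> float:
        """Power-law exponent γ in y ~ k^−γ (meaningful for power-law fits)."""
        return -self.slope


def _least_squares(x: np.ndarray, y: np.ndarray, model: str) -> FitResult:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return FitResult(model, float(slope), float(intercept),
                         r_squared=1.0, r_squared_raw=1.0, degenerate=True)
    raw = 1.0 - ss_res / ss_tot
    return FitResult(model, float(slope), float(intercept),
                     r_squared=min(max(raw, 0.0), 1.0), r_squared_raw=raw)


def fit_powerlaw(distribution: Mapping[int, float]) -> FitResult:
    """Fit y ~ k^−γ by least squares on (log10 k, log10 y).

    Points with k ≤ 0 or y ≤ 0 are excluded before the log transform;
    at least three must survive.
    """
    pts = [(k, y) for k, y in distribution.items() if k > 0 and y > 0]
    if len(pts) < 3:
        raise ValueError("insufficient support: need >=3 positive (k, y) points")
    k = np.log10([p[0] for p in pts])
    y = np.log10([p[1] for p in pts])
    return _least_squares(k, y, "power-law")


def fit_linear(distribution: Mapping[int, float]) -> FitResult:
    """Fit y = a·k + b by least squares on the untransformed points."""
    pts = sorted(distribution.items())
    if len(pts) < 3:
        raise ValueError("insufficient support: need >=3 (k, y) points")
    k = np.asarray([p[0] for p in pts], dtype=float)
    y = np.asarray([p[1] for p in pts], dtype=float)
    return _least_squares(k, y, "linear")


@dataclass(frozen=True)
class NetworkClassification:
    label: str  # "random" | "scale-free" | "hierarchical"
    pk_linear: FitResult
    pk_powerlaw: FitResult
    ck_linear: FitResult | None
    ck_powerlaw: FitResult | None


def classify(pk_linear: FitResult, pk_powerlaw: FitResult,
             ck_linear: FitResult | None = None,
             ck_powerlaw: FitResult | None = None,
             delta: float = DEFAULT_DELTA,
             gamma_tolerance: float = DEFAULT_GAMMA_TOLERANCE,
             ck_r2_threshold: float = DEFAULT_CK_R2_THRESHOLD,
             ) -> NetworkClassification:
    """Three-way decision rule over the four competing fits.

    random        — the P(k) power law does not beat the linear fit by
                    more than ``delta`` in R²;
    hierarchical  — non-random, and the C(k) power-law exponent lies within
                    ``gamma_tolerance`` of −1 with R² ≥ ``ck_r2_threshold``;
    scale-free    — everything else.

    Deterministic given the fits and thresholds.  Degenerate fits cannot be
    scored and raise.
    """
    if pk_linear.degenerate or pk_powerlaw.degenerate:
        raise ValueError("degenerate (zero-variance) P(k): cannot classify")
    if pk_powerlaw.r_squared <= pk_linear.r_squared + delta:
        label = "random"
    elif (ck_powerlaw is not None and not ck_powerlaw.degenerate
          and abs(ck_powerlaw.slope - (-1.0)) <= gamma_tolerance
          and ck_powerlaw.r_squared >= ck_r2_threshold):
        label = "hierarchical"
    else:
        label = "scale-free"
    return NetworkClassification(label, pk_linear, pk_powerlaw,
                                 ck_linear, ck_powerlaw)


def classify_graph(graph, delta: float = DEFAULT_DELTA,
                   gamma_tolerance: float = DEFAULT_GAMMA_TOLERANCE,
                   ck_r2_threshold: float = DEFAULT_CK_R2_THRESHOLD,
                   ) -> NetworkClassification:
    """Convenience wrapper: compute P(k)/C(k) and classify the graph.

    When C(k) has fewer than three positive points the hierarchical test is
    simply unavailable and the C(k) fits are reported as ``None``.
    """
    from . import topology

    pk = topology.degree_distribution(graph)
    ck = topology.clustering_distribution(graph)
    pk_lin = fit_linear(pk)
    pk_pow = fit_powerlaw(pk)
    try:
        ck_lin = fit_linear(ck)
        ck_pow = fit_powerlaw(ck)
    except ValueError:
        ck_lin = ck_pow = None
    return classify(pk_lin, pk_pow, ck_lin, ck_pow, delta=delta,
                    gamma_tolerance=gamma_tolerance,
                    ck_r2_threshold=ck_r2_threshold)
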