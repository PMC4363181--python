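"""Adaptive decision threshold from the mixture of positive scores.

The positive site scores typically form a mixture: a large null bump of
noise-driven sites near zero and a separated component of true variants
further right.  The marginal density of scores S > 0 is estimated by
Lindsey's method — the histogram counts are modelled as Poisson with a
log-mean that is a natural cubic spline in the bin midpoint — and the
cutoff S* is placed at the leftmost strict interior local minimum of the
fitted density.  When no minimum exists (fit failed, too few scores, or
a unimodal score distribution) the upper 95% quantile of the positive
scores is used instead; in that regime the score model does not suffice
to reliably call the variants and calling is conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import patsy
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "DensityFitError",
    "ThresholdResult",
    "fit_score_density",
    "find_cutoff",
    "determine_threshold",
    "plot_threshold",
]

DEFAULT_BINS = 100
DEFAULT_DF = 7
DEFAULT_MIN_SCORES = 200
DEFAULT_FALLBACK_QUANTILE = 0.95

RULE_MINIMUM = "leftmost_local_minimum"
RULE_FALLBACK = "quantile_fallback"


class DensityFitError(RuntimeError):
    """The spline density fit could not be obtained."""


@dataclass
class ThresholdResult:
    """Outcome of the adaptive cutoff determination."""

    s_star: float
    rule: str                       # RULE_MINIMUM or RULE_FALLBACK
    bin_edges: Optional[np.ndarray]   # histogram over S > 0 (None if no fit)
    counts: Optional[np.ndarray]
    density: Optional[np.ndarray]     # fitted Poisson means per bin
    df: int
    n_positive: int
    fallback_quantile: float
    minima_bins: list = field(default_factory=list)

    @property
    def midpoints(self) -> Optional[np.ndarray]:
        if self.bin_edges is None:
            return None
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_dict(self) -> dict:
        return {
            "s_star": self.s_star,
            "rule": self.rule,
            "df": self.df,
            "n_positive": self.n_positive,
            "fallback_quantile": self.fallback_quantile,
            "minima_bins": [int(i) for i in self.minima_bins],
            "bin_edges": None if self.bin_edges is None else self.bin_edges.tolist(),
            "counts": None if self.counts is None else self.counts.tolist(),
            "density": None if self.density is None else self.density.tolist(),
        }


def fit_score_density(
    scores: Sequence[float],
    n_bins: int = DEFAULT_BINS,
    df: int = DEFAULT_DF,
):
    """Lindsey-method density fit to the histogram of positive scores.

    Returns ``(bin_edges, counts, fitted)`` where ``fitted`` holds the
    exponentiated fitted log-means per bin; their sum approximates the
    total score count.  Raises :class:`DensityFitError` when the Poisson
    regression does not converge or is degenerate.
    """
    s = np.asarray(scores, dtype=np.float64)
    s = s[s > 0]
    if s.size == 0:
        raise DensityFitError("no positive scores to fit")
    edges = np.linspace(0.0, float(s.max()), n_bins + 1)
    counts, _ = np.histogram(s, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    try:
        # cr() spans the constant function, so no separate intercept.
        basis = np.asarray(patsy.dmatrix(
            "cr(x, df=df) - 1", {"x": mids, "df": df}, return_type="dataframe"
        ))
        model = sm.GLM(counts, basis, family=sm.families.Poisson())
        # Long zero runs between the two score populations make plain
        # IRLS overflow (quasi-separation); L-BFGS on the concave
        # log-likelihood from a log-linear least-squares start is stable.
        start, *_ = np.linalg.lstsq(basis, np.log(counts + 0.5), rcond=None)
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            res = model.fit(start_params=start, method="lbfgs", maxiter=500,
                            disp=False)
    except Exception as exc:  # singular basis, separation, ...
        raise DensityFitError(f"Poisson spline regression failed: {exc}") from exc
    if not np.all(np.isfinite(res.mu)):
        raise DensityFitError("Poisson spline regression did not converge")
    return edges, counts, np.asarray(res.mu, dtype=np.float64)


#: A dip in the fitted density only separates two score populations if
#: the upper population actually contains sites: at least this many
#: observed scores must lie to the right of the dip.  A natural spline
#: on the log scale can chase a single extreme score into a boundary
#: spike, which is an outlier artifact, not a second component.
MIN_COMPONENT_SITES = 5


def _strict_local_minima(density: np.ndarray,
                         counts: Optional[np.ndarray] = None,
                         min_component: int = MIN_COMPONENT_SITES) -> list:
    """Interior bins whose fitted value is strictly below both neighbours.

    Plateaus are not minima and boundary bins are never minima.  When
    the observed ``counts`` are given, a minimum additionally requires
    at least ``min_component`` observed scores to its right, so that the
    dip separates two populations rather than isolating stray outliers.
    """
    d = np.asarray(density, dtype=np.float64)
    right_mass = None
    if counts is not None:
        right_mass = np.concatenate(
            (np.cumsum(np.asarray(counts)[::-1])[::-1][1:], [0])
        )
    return [
        i for i in range(1, d.size - 1)
        if d[i] < d[i - 1] and d[i] < d[i + 1]
        and (right_mass is None or right_mass[i] >= min_component)
    ]


def find_cutoff(
    density: Optional[np.ndarray],
    scores: Sequence[float],
    bin_edges: Optional[np.ndarray] = None,
    counts: Optional[np.ndarray] = None,
    df: int = DEFAULT_DF,
    fallback_quantile: float = DEFAULT_FALLBACK_QUANTILE,
) -> ThresholdResult:
    """Locate S* on a fitted density, or fall back to the score quantile.

    ``density=None`` signals that no fit is available and forces the
    fallback.  With a fitted density, S* is the midpoint of the leftmost
    strict interior local minimum; if none exists the upper
    ``fallback_quantile`` of the positive scores is used and a warning
    notes that the score model does not suffice for a reliable cutoff.
    """
    s = np.asarray(scores, dtype=np.float64)
    pos = np.sort(s[s > 0])
    if pos.size == 0:
        raise ValueError("empty score set: no positive scores")
    minima: list = []
    if density is not None:
        minima = _strict_local_minima(density, counts=counts)
    if minima:
        mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])
        s_star = float(mids[minima[0]])
        rule = RULE_MINIMUM
    else:
        s_star = float(np.quantile(pos, fallback_quantile))
        rule = RULE_FALLBACK
        logger.warning(
            "no interior density minimum: the score model does not suffice to "
            "reliably call the variants; using the upper %.0f%% quantile %.4f "
            "as threshold", 100 * fallback_quantile, s_star,
        )
    return ThresholdResult(
        s_star=s_star,
        rule=rule,
        bin_edges=None if bin_edges is None else np.asarray(bin_edges),
        counts=None if counts is None else np.asarray(counts),
        density=None if density is None else np.asarray(density),
        df=df,
        n_positive=int(pos.size),
        fallback_quantile=fallback_quantile,
        minima_bins=minima,
    )


def determine_threshold(
    scores: Sequence[float],
    n_bins: int = DEFAULT_BINS,
    df: int = DEFAULT_DF,
    min_scores: int = DEFAULT_MIN_SCORES,
    fallback_quantile: float = DEFAULT_FALLBACK_QUANTILE,
) -> ThresholdResult:
    """Full adaptive-threshold procedure on a set of site scores.

    Fits the spline density to the positive scores when there are at
    least ``min_scores`` of them, then applies the leftmost-minimum /
    quantile-fallback rule.  The result depends only on the multiset of
    scores, not on their order.
    """
    s = np.asarray(scores, dtype=np.float64)
    pos = s[s > 0]
    if pos.size == 0:
        raise ValueError("empty score set: no positive scores")
    edges = counts = density = None
    if pos.size < min_scores:
        logger.warning(
            "only %d positive scores (< %d): skipping the density fit",
            pos.size, min_scores,
        )
    else:
        try:
            edges, counts, density = fit_score_density(pos, n_bins=n_bins, df=df)
        except DensityFitError as exc:
            logger.warning("density fit failed (%s); falling back", exc)
    return find_cutoff(
        density, pos, bin_edges=edges, counts=counts, df=df,
        fallback_quantile=fallback_quantile,
    )


def plot_threshold(result: ThresholdResult, ax=None):
    """Diagnostic plot: histogram of S > 0, fitted density, and S*."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if result.bin_edges is not None:
        widths = np.diff(result.bin_edges)
        ax.bar(result.midpoints, result.counts, width=widths,
               color="0.8", edgecolor="0.6", label="scores > 0")
        if result.density is not None:
            ax.plot(result.midpoints, result.density, "r-", lw=2,
                    label="fitted density")
    ax.axvline(result.s_star, color="b", ls=":", lw=2,
               label=f"S* = {result.s_star:.2f} ({result.rule})")
    ax.set_xlabel("site score S")
    ax.set_ylabel("sites per bin")
    ax.legend()
    return ax
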