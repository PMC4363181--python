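"""Per-site variant scores.

A site with at least one mismatching base receives the total score

    S = Δ_Q + Δ_P + Δ_R + Δ_H + log q(δ)

where each Δ component averages, over the *mismatch* bases of the
cross-section and normalised by the full coverage |C|, an empirical
log-odds of that base's characteristic under the background model:

    Δ_Q = (1/|C|) Σ_{x∈M̄} log[ Q_x / (1 − Q_x) ]
    Δ_P = (1/|C|) Σ_{x∈M̄} ( log[ Pr(M|P_x) / (1 − Pr(M|P_x)) ]
                             + log[ P_M̄ / P_M ] )
    Δ_R = (1/|C|) Σ_{x∈M̄} log[ Pr(M|R_x) / (1 − Pr(M|R_x)) ]
    Δ_H = (1/|C|) Σ_{x∈M̄} log[ Pr(M|H_x) / (1 − Pr(M|H_x)) ]

and q(δ) is the empirical quantile of the site's mismatch rate.  All
logs are natural.  Sites with no mismatching base (|M̄| = 0) do not
enter any component of the model and receive no score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .background import BackgroundModel, ConditionalTable
from .pileup import CrossSection

__all__ = [
    "Q_CLAMP",
    "SiteScore",
    "delta_Q",
    "delta_P",
    "delta_R",
    "delta_H",
    "score_site",
    "score_stream",
    "scores_to_frame",
    "SITE_TABLE_COLUMNS",
]

# Base qualities are clamped into this open interval before the log-odds
# so that phred-0 / phred-40+ calls cannot produce infinities.
Q_CLAMP = (1e-3, 0.9999)

_BASE_ORDER = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SiteScore:
    """Score decomposition for one site with >= 1 mismatching base."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str       # modal mismatch nucleotide, alphabetical tie-break
    coverage: int
    n_mismatch: int
    delta: float
    d_q: float
    d_p: float
    d_r: float
    d_h: float
    log_q: float
    total: float


def _logodds(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def delta_Q(cs: CrossSection) -> float:
    """Base-quality component Δ_Q."""
    q = np.clip(cs.quality[cs.mismatch_mask], Q_CLAMP[0], Q_CLAMP[1])
    return float(_logodds(q).sum() / cs.coverage)


def delta_P(cs: CrossSection, table: ConditionalTable) -> float:
    """Read-position component Δ_P, rescaled by the maxima P_M and P_M̄."""
    mm = cs.mismatch_mask
    p = cs.read_pos[mm] / cs.read_len[mm]
    rescale = math.log(table.p_mismatch_max) - math.log(table.p_match_max)
    return float((table.log_odds(p).sum() + mm.sum() * rescale) / cs.coverage)


def delta_R(cs: CrossSection, table: ConditionalTable) -> float:
    """Alignment-error component Δ_R."""
    return float(table.log_odds(cs.read_errors[cs.mismatch_mask]).sum() / cs.coverage)


def delta_H(cs: CrossSection, table: ConditionalTable) -> float:
    """Alignment-multiplicity component Δ_H."""
    return float(table.log_odds(cs.read_hits[cs.mismatch_mask]).sum() / cs.coverage)


def _modal_alt(cs: CrossSection) -> str:
    counts = np.array(
        [(cs.base_codes[cs.mismatch_mask] == b).sum() for b in _BASE_ORDER]
    )
    return chr(_BASE_ORDER[int(np.argmax(counts))])  # argmax: first max = alphabetical


def score_site(cs: CrossSection, model: BackgroundModel) -> Optional[SiteScore]:
    """Total score S for one cross-section, or ``None`` if |M̄| = 0."""
    if cs.n_mismatch == 0:
        return None
    d_q = delta_Q(cs)
    d_p = delta_P(cs, model.tables["P"])
    d_r = delta_R(cs, model.tables["R"])
    d_h = delta_H(cs, model.tables["H"])
    log_q = math.log(model.q(cs.delta))
    return SiteScore(
        chrom=cs.chrom,
        pos=cs.pos,
        ref_base=cs.ref_base,
        alt_base=_modal_alt(cs),
        coverage=cs.coverage,
        n_mismatch=cs.n_mismatch,
        delta=cs.delta,
        d_q=d_q,
        d_p=d_p,
        d_r=d_r,
        d_h=d_h,
        log_q=log_q,
        total=d_q + d_p + d_r + d_h + log_q,
    )


def score_stream(
    cross_sections: Iterable[CrossSection], model: BackgroundModel
) -> Iterator[SiteScore]:
    """Score every cross-section with at least one mismatch."""
    for cs in cross_sections:
        s = score_site(cs, model)
        if s is not None:
            yield s


SITE_TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "coverage", "n_mismatch",
    "delta", "d_Q", "d_P", "d_R", "d_H", "log_q", "S",
]


def scores_to_frame(scores: Iterable[SiteScore]) -> pd.DataFrame:
    """Tabulate site scores for the audit table (one row per scored site)."""
    rows = [
        (s.chrom, s.pos, s.ref_base, s.alt_base, s.coverage, s.n_mismatch,
         s.delta, s.d_q, s.d_p, s.d_r, s.d_h, s.log_q, s.total)
        for s in scores
    ]
    return pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)
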