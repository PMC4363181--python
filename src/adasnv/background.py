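"""Empirical background model of the sequencing-error process.

The caller's null model is estimated from the data itself, exploiting
the fact that the overwhelming majority of genomic sites carry no
biological variation, so their mismatches reflect only technical error.
Two ingredients are estimated:

* the empirical cumulative distribution (ECDF) of the per-site mismatch
  rate δ across all tabulated sites, giving the quantile ``q(δ)``;
* conditional match probabilities ``Pr(M | P)``, ``Pr(M | R)`` and
  ``Pr(M | H)`` over relative read position, alignment edit distance and
  alignment multiplicity, tabulated from a uniform random sample of
  low-mismatch sites (``0 < δ < 0.5``).

Smoothing uses an additive (Jeffreys, α = 0.5) pseudocount so that every
log-odds downstream stays finite even for empty bins.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .pileup import CrossSection, mismatch_rate

logger = logging.getLogger(__name__)

__all__ = [
    "DeltaECDF",
    "ConditionalTable",
    "BackgroundModel",
    "build_delta_ecdf",
    "sample_background_sites",
    "estimate_conditional_tables",
    "build_background_model",
]

MODEL_FORMAT_VERSION = "1"

DEFAULT_SAMPLE_SIZE = 100_000
DEFAULT_P_BINS = 50
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_R_MAX = 20
DEFAULT_H_MAX = 50


@dataclass
class DeltaECDF:
    """Inclusive empirical CDF of the per-site mismatch rate δ.

    ``q(δ)`` is the fraction of tabulated sites with mismatch rate
    ``<= δ``; it is non-decreasing, equals 1 at (and above) the largest
    observed δ, and is floored at ``1 / (n_sites + 1)`` below the
    smallest observed value so that ``log q`` is always finite.
    """

    support: np.ndarray      # sorted unique δ values
    cum_counts: np.ndarray   # cumulative site counts, same length
    n_sites: int

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=np.float64)
        self.cum_counts = np.asarray(self.cum_counts, dtype=np.int64)
        if self.support.size == 0:
            raise ValueError("empty ECDF")

    @classmethod
    def from_counts(cls, counts: Dict[float, int]) -> "DeltaECDF":
        if not counts:
            raise ValueError("cannot build ECDF from an empty site stream")
        support = np.array(sorted(counts), dtype=np.float64)
        c = np.array([counts[v] for v in support], dtype=np.int64)
        return cls(support=support, cum_counts=np.cumsum(c), n_sites=int(c.sum()))

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "DeltaECDF":
        return cls.from_counts(Counter(float(v) for v in values))

    def q(self, delta):
        """Quantile of δ: fraction of sites with mismatch rate <= δ."""
        idx = np.searchsorted(self.support, np.asarray(delta, dtype=np.float64),
                              side="right")
        floor = 1.0 / (self.n_sites + 1)
        out = np.where(idx > 0,
                       self.cum_counts[np.maximum(idx, 1) - 1] / self.n_sites,
                       floor)
        if np.ndim(delta) == 0:
            return float(out)
        return out

    def to_dict(self) -> dict:
        return {
            "support": self.support.tolist(),
            "cum_counts": self.cum_counts.tolist(),
            "n_sites": int(self.n_sites),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeltaECDF":
        return cls(support=np.array(d["support"], dtype=np.float64),
                   cum_counts=np.array(d["cum_counts"], dtype=np.int64),
                   n_sites=int(d["n_sites"]))


def build_delta_ecdf(cross_sections: Iterable[CrossSection],
                     include_zero: bool = True) -> DeltaECDF:
    """Tabulate the mismatch-rate ECDF over a stream of cross-sections.

    All sites with coverage >= 1 are tabulated, including δ = 0 sites by
    default, so that any site with a mismatch already lands above the
    bulk of the distribution.  Set ``include_zero=False`` to restrict the
    tabulation to sites with at least one mismatch.
    """
    counts: Counter = Counter()
    for cs in cross_sections:
        d = mismatch_rate(cs)
        if d == 0.0 and not include_zero:
            continue
        counts[d] += 1
    if not counts:
        raise ValueError("cannot build ECDF: no sites tabulated")
    return DeltaECDF.from_counts(counts)


def sample_background_sites(
    cross_sections: Iterable[CrossSection],
    n: int = DEFAULT_SAMPLE_SIZE,
    seed: Optional[int] = None,
) -> List[CrossSection]:
    """Uniform sample (without replacement) of low-mismatch sites.

    Qualifying sites satisfy ``0 < δ < 0.5``: they carry at least one
    mismatch (so the error process is observable) but are unlikely to be
    variant.  Reservoir sampling keeps the pass single; if fewer than
    ``n`` sites qualify, all of them are returned with a warning.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    reservoir: List[CrossSection] = []
    t = 0
    for cs in cross_sections:
        d = mismatch_rate(cs)
        if not (0.0 < d < 0.5):
            continue
        t += 1
        if len(reservoir) < n:
            reservoir.append(cs)
        else:
            j = int(rng.integers(0, t))
            if j < n:
                reservoir[j] = cs
    if t == 0:
        raise ValueError(
            "no background estimable: no sites with 0 < delta < 0.5"
        )
    if t < n:
        logger.warning(
            "only %d sites qualify for the background sample (requested %d); "
            "using all of them", t, n,
        )
    return reservoir


@dataclass
class ConditionalTable:
    """Binned empirical match probabilities for one site characteristic.

    ``kind`` is one of ``"P"`` (relative read position, ``n_bins``
    equal-width bins over (0, 1]), ``"R"`` (edit distance, identity bins
    ``0..r_max`` plus an overflow bin) or ``"H"`` (hit count, identity
    bins ``1..h_max`` plus an overflow bin).  ``Pr(M | bin)`` is the
    additively smoothed match fraction; for the P table the maxima
    ``P_M = max_P Pr(M|P)`` and ``P_M̄ = max_P Pr(M̄|P)`` over occupied
    bins are kept for the rescaling term of the position score.
    """

    kind: str
    match_counts: np.ndarray
    mismatch_counts: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    n_bins: Optional[int] = None    # P only: number of bins over (0, 1]
    r_max: Optional[int] = None     # R only
    h_max: Optional[int] = None     # H only
    pr_match: np.ndarray = field(init=False)
    p_match_max: Optional[float] = field(init=False, default=None)
    p_mismatch_max: Optional[float] = field(init=False, default=None)

    def __post_init__(self):
        self.match_counts = np.asarray(self.match_counts, dtype=np.int64)
        self.mismatch_counts = np.asarray(self.mismatch_counts, dtype=np.int64)
        if self.kind not in ("P", "R", "H"):
            raise ValueError(f"unknown characteristic kind {self.kind!r}")
        a = self.pseudocount
        total = self.match_counts + self.mismatch_counts
        self.pr_match = (self.match_counts + a) / (total + 2.0 * a)
        occupied = total > 0
        if self.kind == "P":
            if not occupied.any():
                raise ValueError("P table has no occupied bins")
            self.p_match_max = float(self.pr_match[occupied].max())
            self.p_mismatch_max = float((1.0 - self.pr_match[occupied]).max())

    def bin_index(self, values) -> np.ndarray:
        """Map raw characteristic values to bin indices."""
        v = np.asarray(values)
        if self.kind == "P":
            # equal-width bins over (0, 1]: bin b covers (b/n, (b+1)/n]
            idx = np.ceil(v * self.n_bins).astype(np.int64) - 1
            return np.clip(idx, 0, self.n_bins - 1)
        if self.kind == "R":
            return np.minimum(v.astype(np.int64), self.r_max + 1)
        return np.minimum(v.astype(np.int64), self.h_max + 1) - 1

    def log_odds(self, values) -> np.ndarray:
        """log[ Pr(M|x) / (1 - Pr(M|x)) ] for raw characteristic values."""
        p = self.pr_match[self.bin_index(values)]
        return np.log(p) - np.log1p(-p)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "match_counts": self.match_counts.tolist(),
            "mismatch_counts": self.mismatch_counts.tolist(),
            "pseudocount": self.pseudocount,
            "n_bins": self.n_bins,
            "r_max": self.r_max,
            "h_max": self.h_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalTable":
        return cls(
            kind=d["kind"],
            match_counts=np.array(d["match_counts"], dtype=np.int64),
            mismatch_counts=np.array(d["mismatch_counts"], dtype=np.int64),
            pseudocount=float(d["pseudocount"]),
            n_bins=d["n_bins"],
            r_max=d["r_max"],
            h_max=d["h_max"],
        )


def estimate_conditional_tables(
    sample: Sequence[CrossSection],
    p_bins: int = DEFAULT_P_BINS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    r_max: int = DEFAULT_R_MAX,
    h_max: int = DEFAULT_H_MAX,
) -> Dict[str, ConditionalTable]:
    """Tabulate Pr(M | P), Pr(M | R) and Pr(M | H) from a background sample.

    Every base — match and mismatch — of every sampled cross-section
    contributes one count to its bin in each of the three tables.
    """
    if not sample:
        raise ValueError("background sample is empty")
    n_p, n_r, n_h = p_bins, r_max + 2, h_max + 1
    pm = np.zeros(n_p, np.int64)
    pmm = np.zeros(n_p, np.int64)
    rm = np.zeros(n_r, np.int64)
    rmm = np.zeros(n_r, np.int64)
    hm = np.zeros(n_h, np.int64)
    hmm = np.zeros(n_h, np.int64)
    for cs in sample:
        mm = cs.mismatch_mask
        p_idx = np.clip(np.ceil(cs.rel_pos * p_bins).astype(np.int64) - 1, 0, n_p - 1)
        r_idx = np.minimum(cs.read_errors.astype(np.int64), r_max + 1)
        h_idx = np.minimum(cs.read_hits.astype(np.int64), h_max + 1) - 1
        for idx, cm, cmm in ((p_idx, pm, pmm), (r_idx, rm, rmm), (h_idx, hm, hmm)):
            cm += np.bincount(idx[~mm], minlength=cm.size)
            cmm += np.bincount(idx[mm], minlength=cm.size)
    return {
        "P": ConditionalTable("P", pm, pmm, pseudocount, n_bins=p_bins),
        "R": ConditionalTable("R", rm, rmm, pseudocount, r_max=r_max),
        "H": ConditionalTable("H", hm, hmm, pseudocount, h_max=h_max),
    }


@dataclass
class BackgroundModel:
    """The empirical reference model: δ-ECDF plus conditional tables."""

    ecdf: DeltaECDF
    tables: Dict[str, ConditionalTable]
    sample_size: int                 # requested background sample size
    n_sampled: int                   # sites actually in the sample
    n_qualifying: int                # sites with 0 < δ < 0.5 seen
    seed: Optional[int]
    contigs: List[str]
    version: str = MODEL_FORMAT_VERSION

    def q(self, delta):
        return self.ecdf.q(delta)

    def to_dict(self) -> dict:
        return {
            "format": "adasnv-background-model",
            "version": self.version,
            "ecdf": self.ecdf.to_dict(),
            "tables": {k: t.to_dict() for k, t in self.tables.items()},
            "sample_size": self.sample_size,
            "n_sampled": self.n_sampled,
            "n_qualifying": self.n_qualifying,
            "seed": self.seed,
            "contigs": list(self.contigs),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundModel":
        if d.get("format") != "adasnv-background-model":
            raise ValueError("not a background-model file")
        if d.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model version {d.get('version')!r}")
        return cls(
            ecdf=DeltaECDF.from_dict(d["ecdf"]),
            tables={k: ConditionalTable.from_dict(t) for k, t in d["tables"].items()},
            sample_size=int(d["sample_size"]),
            n_sampled=int(d["n_sampled"]),
            n_qualifying=int(d["n_qualifying"]),
            seed=d["seed"],
            contigs=list(d["contigs"]),
            version=d["version"],
        )

    @classmethod
    def load(cls, path) -> "BackgroundModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_background_model(
    cross_sections: Iterable[CrossSection],
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    seed: Optional[int] = None,
    p_bins: int = DEFAULT_P_BINS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    r_max: int = DEFAULT_R_MAX,
    h_max: int = DEFAULT_H_MAX,
    include_zero: bool = True,
    contigs: Optional[Sequence[str]] = None,
) -> BackgroundModel:
    """One-pass build of the full background model.

    The δ-ECDF is tabulated over every emitted site while a reservoir
    keeps a uniform sample of the qualifying (``0 < δ < 0.5``) sites;
    the conditional tables are then estimated from that sample.
    """
    if sample_size < 1:
        raise ValueError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    reservoir: List[CrossSection] = []
    t = 0
    n_sites = 0
    for cs in cross_sections:
        d = mismatch_rate(cs)
        if d != 0.0 or include_zero:
            counts[d] += 1
            n_sites += 1
        if 0.0 < d < 0.5:
            t += 1
            if len(reservoir) < sample_size:
                reservoir.append(cs)
            else:
                j = int(rng.integers(0, t))
                if j < sample_size:
                    reservoir[j] = cs
    if n_sites == 0:
        raise ValueError("no cross-sections: nothing to tabulate")
    if t == 0:
        raise ValueError("no background estimable: no sites with 0 < delta < 0.5")
    if t < sample_size:
        logger.warning(
            "only %d sites qualify for the background sample (requested %d); "
            "using all of them", t, sample_size,
        )
    tables = estimate_conditional_tables(
        reservoir, p_bins=p_bins, pseudocount=pseudocount, r_max=r_max, h_max=h_max
    )
    return BackgroundModel(
        ecdf=DeltaECDF.from_counts(counts),
        tables=tables,
        sample_size=sample_size,
        n_sampled=len(reservoir),
        n_qualifying=t,
        seed=seed,
        contigs=list(contigs) if contigs is not None else [],
    )
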