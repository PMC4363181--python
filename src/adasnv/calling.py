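"""Two-pass pipeline orchestration: build → score → threshold → call.

Pass 1 (``run_build``) streams the alignments once and produces the
:class:`~adasnv.background.BackgroundModel` sidecar: the δ-ECDF over
every emitted site plus conditional match tables from a reservoir
sample of low-mismatch sites.  Pass 2 (``run_call``) streams the
alignments again, scores every site with at least one mismatch,
determines the adaptive threshold S* and emits a VCF of the calls,
the full site table and a threshold report.  ``evaluate_calls``
compares a call set with a simulated truth set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pysam

from .background import (
    DEFAULT_H_MAX,
    DEFAULT_P_BINS,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_R_MAX,
    DEFAULT_SAMPLE_SIZE,
    BackgroundModel,
    build_background_model,
)
from .pileup import PileupConfig, iterate_cross_sections
from .scoring import SiteScore, score_stream, scores_to_frame
from .threshold import (
    DEFAULT_BINS,
    DEFAULT_DF,
    DEFAULT_FALLBACK_QUANTILE,
    DEFAULT_MIN_SCORES,
    ThresholdResult,
    determine_threshold,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "CallResult",
    "run_build",
    "run_call",
    "evaluate_calls",
    "write_vcf",
    "read_vcf_positions",
]


@dataclass(frozen=True)
class VariantCall:
    """One called site (score exceeding the adaptive threshold)."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    score: float
    delta: float
    coverage: int
    n_mismatch: int
    d_q: float
    d_p: float
    d_r: float
    d_h: float
    log_q: float


@dataclass
class CallResult:
    """Everything pass 2 produced."""

    calls: List[VariantCall]
    threshold: ThresholdResult
    scores: List[SiteScore]

    @property
    def n_scored(self) -> int:
        return len(self.scores)

    def scored_positions(self) -> Set[Tuple[str, int]]:
        return {(s.chrom, s.pos) for s in self.scores}

    def called_positions(self) -> Set[Tuple[str, int]]:
        return {(c.chrom, c.pos) for c in self.calls}


def run_build(
    bam: Union[str, Path],
    fasta: Union[str, Path],
    out: Optional[Union[str, Path]] = None,
    *,
    region: Optional[str] = None,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    seed: Optional[int] = 0,
    p_bins: int = DEFAULT_P_BINS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    r_max: int = DEFAULT_R_MAX,
    h_max: int = DEFAULT_H_MAX,
    pileup_config: Optional[PileupConfig] = None,
) -> BackgroundModel:
    """Build the background model from alignments and serialize it.

    Raises ``ValueError`` with "no cross-sections" on empty input and
    with "no background estimable" when no site has 0 < δ < 0.5.
    """
    with pysam.AlignmentFile(str(bam)) as af:
        contigs = list(af.references)
    stream = iterate_cross_sections(bam, fasta, region=region, config=pileup_config)
    model = build_background_model(
        stream,
        sample_size=sample_size,
        seed=seed,
        p_bins=p_bins,
        pseudocount=pseudocount,
        r_max=r_max,
        h_max=h_max,
        contigs=contigs,
    )
    logger.info(
        "background model: %d sites tabulated, %d qualifying, %d sampled (seed=%s)",
        model.ecdf.n_sites, model.n_qualifying, model.n_sampled, seed,
    )
    if out is not None:
        model.save(out)
    return model


def run_call(
    bam: Union[str, Path],
    fasta: Union[str, Path],
    model: Union[BackgroundModel, str, Path],
    *,
    region: Optional[str] = None,
    out_vcf: Optional[Union[str, Path]] = None,
    site_table: Optional[Union[str, Path]] = None,
    report: Optional[Union[str, Path]] = None,
    n_bins: int = DEFAULT_BINS,
    df: int = DEFAULT_DF,
    min_scores: int = DEFAULT_MIN_SCORES,
    fallback_quantile: float = DEFAULT_FALLBACK_QUANTILE,
    ge: bool = False,
    pileup_config: Optional[PileupConfig] = None,
) -> CallResult:
    """Score all sites, pick the adaptive threshold, and call variants.

    The call rule is strict ``S > S*`` by default; ``ge=True`` switches
    to ``S >= S*``.
    """
    if not isinstance(model, BackgroundModel):
        model = BackgroundModel.load(model)
    with pysam.AlignmentFile(str(bam)) as af:
        bam_contigs = list(af.references)
    if model.contigs:
        missing = [c for c in bam_contigs if c not in model.contigs]
        if missing:
            raise ValueError(
                f"model/BAM contig mismatch: BAM contigs {bam_contigs} vs "
                f"model contigs {model.contigs}"
            )
    stream = iterate_cross_sections(bam, fasta, region=region, config=pileup_config)
    scores = list(score_stream(stream, model))
    if not scores:
        raise ValueError("no scorable sites: every cross-section is all-match")
    threshold = determine_threshold(
        [s.total for s in scores],
        n_bins=n_bins, df=df, min_scores=min_scores,
        fallback_quantile=fallback_quantile,
    )
    s_star = threshold.s_star
    calls = [
        VariantCall(
            chrom=s.chrom, pos=s.pos, ref_base=s.ref_base, alt_base=s.alt_base,
            score=s.total, delta=s.delta, coverage=s.coverage,
            n_mismatch=s.n_mismatch, d_q=s.d_q, d_p=s.d_p, d_r=s.d_r,
            d_h=s.d_h, log_q=s.log_q,
        )
        for s in scores
        if (s.total >= s_star if ge else s.total > s_star)
    ]
    logger.info(
        "threshold S*=%.4f via %s; %d of %d scored sites called",
        s_star, threshold.rule, len(calls), len(scores),
    )
    if site_table is not None:
        scores_to_frame(scores).to_csv(site_table, sep="\t", index=False)
    if report is not None:
        import json

        Path(report).write_text(json.dumps(threshold.to_dict()) + "\n")
    if out_vcf is not None:
        write_vcf(out_vcf, calls, fasta, s_star=s_star, rule=threshold.rule,
                  model_seed=model.seed)
    return CallResult(calls=calls, threshold=threshold, scores=scores)


def write_vcf(
    path: Union[str, Path],
    calls: Sequence[VariantCall],
    fasta: Union[str, Path],
    *,
    s_star: float,
    rule: str,
    model_seed=None,
) -> None:
    """Write calls as VCFv4.2.

    QUAL carries the score rescaled to a non-negative value
    (``S - S*``, floored at 0); the raw score and its components go to
    INFO fields (HZS, HZQ, HZP, HZR, HZH, HZLQ).
    """
    header = pysam.VariantHeader()
    header.add_line('##source=adasnv')
    header.add_line(f'##adasnv_threshold={s_star:.6g}')
    header.add_line(f'##adasnv_threshold_rule={rule}')
    if model_seed is not None:
        header.add_line(f'##adasnv_model_seed={model_seed}')
    with pysam.FastaFile(str(fasta)) as fa:
        for name, length in zip(fa.references, fa.lengths):
            header.contigs.add(name, length=length)
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage">')
    header.add_line('##INFO=<ID=NMM,Number=1,Type=Integer,'
                    'Description="Mismatching bases">')
    header.add_line('##INFO=<ID=DELTA,Number=1,Type=Float,'
                    'Description="Mismatch rate">')
    header.add_line('##INFO=<ID=HZS,Number=1,Type=Float,Description="Total score S">')
    header.add_line('##INFO=<ID=HZQ,Number=1,Type=Float,'
                    'Description="Base-quality component">')
    header.add_line('##INFO=<ID=HZP,Number=1,Type=Float,'
                    'Description="Read-position component">')
    header.add_line('##INFO=<ID=HZR,Number=1,Type=Float,'
                    'Description="Alignment-error component">')
    header.add_line('##INFO=<ID=HZH,Number=1,Type=Float,'
                    'Description="Hit-count component">')
    header.add_line('##INFO=<ID=HZLQ,Number=1,Type=Float,'
                    'Description="Log quantile of the mismatch rate">')
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = vcf.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos,
                alleles=(c.ref_base, c.alt_base),
                qual=max(c.score - s_star, 0.0),
            )
            rec.info["DP"] = c.coverage
            rec.info["NMM"] = c.n_mismatch
            rec.info["DELTA"] = c.delta
            rec.info["HZS"] = c.score
            rec.info["HZQ"] = c.d_q
            rec.info["HZP"] = c.d_p
            rec.info["HZR"] = c.d_r
            rec.info["HZH"] = c.d_h
            rec.info["HZLQ"] = c.log_q
            vcf.write(rec)


def read_vcf_positions(path: Union[str, Path]) -> Set[Tuple[str, int]]:
    """Set of (chrom, 1-based pos) records in a VCF."""
    out: Set[Tuple[str, int]] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.add((rec.chrom, rec.pos))
    return out


def evaluate_calls(
    calls: Union[Iterable[Tuple[str, int]], Sequence[VariantCall]],
    truth: Union[Set[Tuple[str, int]], "object"],
    scored: Optional[Iterable[Tuple[str, int]]] = None,
) -> Dict[str, object]:
    """Confusion counts, sensitivity and positive predictive value.

    ``calls`` may be VariantCall records or (chrom, pos) pairs; ``truth``
    a TruthSet or a set of (chrom, pos) pairs.  SENS = TP / (TP + FN),
    PPV = TP / (TP + FP); PPV is ``None`` ("NA") when nothing was
    called.  TN counts scored non-truth sites that were not called and
    requires ``scored``.
    """
    call_set = {
        (c.chrom, c.pos) if isinstance(c, VariantCall) else (c[0], int(c[1]))
        for c in calls
    }
    truth_set = truth if isinstance(truth, set) else truth.position_set()
    tp = len(call_set & truth_set)
    fp = len(call_set - truth_set)
    fn = len(truth_set - call_set)
    tn = None
    if scored is not None:
        scored_set = set(scored)
        tn = len(scored_set - truth_set - call_set)
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn, "SENS": sens, "PPV": ppv}
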