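"""Independent straight-line recomputation of the site score.

Everything here is deliberately written with plain Python loops and
``math`` so the score pipeline can be checked against an implementation
that shares no code with the package internals.
"""

import math


def clamp(q, lo=1e-3, hi=0.9999):
    return min(max(q, lo), hi)


def smoothed_pr_match(match, mismatch, alpha):
    return (match + alpha) / (match + mismatch + 2.0 * alpha)


def p_bin(p, n_bins):
    """Bin index for relative read position over (0, 1]."""
    b = math.ceil(p * n_bins) - 1
    return min(max(b, 0), n_bins - 1)


def r_bin(r, r_max):
    return min(r, r_max + 1)


def h_bin(h, h_max):
    return min(h, h_max + 1) - 1


def table_probs(table):
    """Per-bin smoothed match probabilities recomputed from raw counts."""
    a = table.pseudocount
    return [
        smoothed_pr_match(int(m), int(mm), a)
        for m, mm in zip(table.match_counts, table.mismatch_counts)
    ]


def ecdf_q(support, cum_counts, n_sites, delta):
    """Inclusive ECDF by direct counting over the tabulated support."""
    best = None
    for v, c in zip(support, cum_counts):
        if v <= delta + 1e-15:
            best = c
    if best is None:
        return 1.0 / (n_sites + 1)
    return best / n_sites


def score_components(bases, ref_base, model):
    """Recompute (d_Q, d_P, d_R, d_H, log_q, total) for one cross-section.

    ``bases`` is a list of AlignedBase records; the model's tables are
    consulted only through their raw counts and parameters.
    """
    cov = len(bases)
    mism = [b for b in bases if b.base != ref_base]
    assert mism, "score undefined for all-match cross-sections"

    d_q = 0.0
    for b in mism:
        q = clamp(b.quality)
        d_q += math.log(q / (1.0 - q))
    d_q /= cov

    pt = model.tables["P"]
    probs_p = table_probs(pt)
    occupied = [
        i for i in range(len(probs_p))
        if pt.match_counts[i] + pt.mismatch_counts[i] > 0
    ]
    p_m = max(probs_p[i] for i in occupied)
    p_mbar = max(1.0 - probs_p[i] for i in occupied)
    d_p = 0.0
    for b in mism:
        pr = probs_p[p_bin(b.read_pos / b.read_len, pt.n_bins)]
        d_p += math.log(pr / (1.0 - pr)) + math.log(p_mbar / p_m)
    d_p /= cov

    rt = model.tables["R"]
    probs_r = table_probs(rt)
    d_r = 0.0
    for b in mism:
        pr = probs_r[r_bin(b.read_errors, rt.r_max)]
        d_r += math.log(pr / (1.0 - pr))
    d_r /= cov

    ht = model.tables["H"]
    probs_h = table_probs(ht)
    d_h = 0.0
    for b in mism:
        pr = probs_h[h_bin(b.read_hits, ht.h_max)]
        d_h += math.log(pr / (1.0 - pr))
    d_h /= cov

    delta = len(mism) / cov
    log_q = math.log(
        ecdf_q(model.ecdf.support.tolist(), model.ecdf.cum_counts.tolist(),
               model.ecdf.n_sites, delta)
    )
    total = d_q + d_p + d_r + d_h + log_q
    return d_q, d_p, d_r, d_h, log_q, total
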