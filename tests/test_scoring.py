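"""Score components against independent straight-line recomputation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adasnv import (
    BackgroundModel,
    DeltaECDF,
    delta_H,
    delta_P,
    delta_Q,
    delta_R,
    score_site,
    score_stream,
    scores_to_frame,
)

import _oracle
from conftest import make_cross_section, make_table


def _cs(mism, match=0, quality=0.9, k=1, m=8, r=0, h=1, ref="A"):
    bases = [("C", quality, k, m, r, h)] * mism
    bases += [("A", quality, k, m, r, h)] * match
    return make_cross_section(bases, ref_base=ref)


class TestDeltaQ:
    def test_neutral_quality_scores_zero(self):
        assert delta_Q(_cs(1, quality=0.5)) == 0.0

    def test_single_mismatch(self):
        cs = _cs(1, match=9, quality=0.99)
        assert delta_Q(cs) == pytest.approx(math.log(99) / 10, abs=1e-12)

    def test_two_mismatches(self):
        cs = _cs(2, match=2, quality=0.9)
        assert delta_Q(cs) == pytest.approx(2 * math.log(9) / 4, abs=1e-12)

    def test_extreme_qualities_stay_finite(self):
        assert np.isfinite(delta_Q(_cs(1, quality=1.0)))
        assert np.isfinite(delta_Q(_cs(1, quality=0.0)))


class TestDeltaP:
    def test_vanishes_for_symmetric_table(self):
        # single occupied bin with equal counts: Pr(M|bin)=0.5 and
        # P_M = P_M̄, so both terms are exactly zero
        t = make_table("P", [10, 0], [10, 0], n_bins=2)
        assert delta_P(_cs(1, k=1, m=8), t) == 0.0

    def test_rescaled_value(self):
        # bin 0: 148/1 -> Pr=0.99; bin 1: 9/0 -> Pr=0.95, so P_M=0.99
        # and P_M̄=0.05; a single mismatch in bin 0 at coverage 1
        t = make_table("P", [148, 9], [1, 0], n_bins=2)
        cs = _cs(1, k=1, m=8)  # P = 1/8 -> bin 0
        expected = math.log(99) + math.log(0.05 / 0.99)
        assert delta_P(cs, t) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(1.606, abs=5e-3)

    def test_linearity_within_one_bin(self):
        t = make_table("P", [148, 9], [1, 0], n_bins=2)
        one = delta_P(_cs(1, match=5, k=1, m=8), t)
        three = delta_P(_cs(3, match=3, k=1, m=8), t)
        # same coverage: three identical mismatches contribute three times
        # the per-base term of one
        assert three == pytest.approx(3 * one, abs=1e-12)


class TestDeltaRH:
    def test_neutral_probability_contributes_nothing(self):
        t = make_table("R", [0, 0], [0, 0], r_max=0)  # all bins empty -> 0.5
        assert delta_R(_cs(2, r=0), t) == 0.0

    def test_overflow_bin_used(self):
        t = make_table("R", [100, 50, 10], [1, 5, 9], r_max=1)
        cs = _cs(1, r=7)  # beyond r_max -> overflow bin (index 2)
        pr = 10.5 / 20
        assert delta_R(cs, t) == pytest.approx(math.log(pr / (1 - pr)), abs=1e-12)

    def test_h_mirrors_r(self):
        t = make_table("H", [100, 10], [1, 9], h_max=1)
        cs = _cs(1, h=60)
        pr = 10.5 / 20
        assert delta_H(cs, t) == pytest.approx(math.log(pr / (1 - pr)), abs=1e-12)


class TestScoreSite:
    def test_all_match_site_excluded(self, toy_model):
        assert score_site(_cs(0, match=5), toy_model) is None

    def test_total_is_component_sum(self, toy_model):
        cs = _cs(2, match=6, r=1, h=2, k=3)
        s = score_site(cs, toy_model)
        assert s.total == pytest.approx(
            s.d_q + s.d_p + s.d_r + s.d_h + s.log_q, abs=1e-12
        )
        assert s.log_q <= 0

    def test_log_q_zero_at_maximal_delta(self, toy_model):
        cs = _cs(10)  # δ = 1 is the ECDF maximum of toy_model
        s = score_site(cs, toy_model)
        assert s.log_q == 0.0
        assert s.total == pytest.approx(s.d_q + s.d_p + s.d_r + s.d_h)

    def test_modal_alt_with_alphabetical_ties(self):
        cs = make_cross_section(
            [("T", 0.9, 1, 8, 0, 1), ("G", 0.9, 1, 8, 0, 1),
             ("G", 0.9, 1, 8, 0, 1), ("A", 0.9, 1, 8, 0, 1)],
            ref_base="A",
        )
        assert score_site(cs, _toy()).alt_base == "G"
        tie = make_cross_section(
            [("T", 0.9, 1, 8, 0, 1), ("C", 0.9, 1, 8, 0, 1)], ref_base="A"
        )
        assert score_site(tie, _toy()).alt_base == "C"

    def test_duplicating_reads_leaves_score_unchanged(self, toy_model):
        cs = _cs(2, match=6, r=1, h=2, k=3)
        dup = make_cross_section(
            [(chr(b), q, k, m, r, h) for b, q, k, m, r, h in zip(
                np.concatenate([cs.base_codes] * 2),
                np.concatenate([cs.quality] * 2),
                np.concatenate([cs.read_pos] * 2),
                np.concatenate([cs.read_len] * 2),
                np.concatenate([cs.read_errors] * 2),
                np.concatenate([cs.read_hits] * 2),
            )],
            ref_base="A",
        )
        s, sd = score_site(cs, toy_model), score_site(dup, toy_model)
        assert sd.delta == s.delta
        for f in ("d_q", "d_p", "d_r", "d_h", "total"):
            assert getattr(sd, f) == pytest.approx(getattr(s, f), abs=1e-12)


def _toy():
    return BackgroundModel(
        ecdf=DeltaECDF.from_values([0.0, 0.1, 0.5, 1.0]),
        tables={
            "P": make_table("P", [50] * 4, [5] * 4, n_bins=4),
            "R": make_table("R", [50, 20], [2, 4], r_max=0),
            "H": make_table("H", [50, 10], [2, 3], h_max=0),
        },
        sample_size=10, n_sampled=4, n_qualifying=4, seed=0, contigs=["chr1"],
    )


@given(st.data())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_random_cross_sections_match_oracle(data):
    """Brute-force per-base recomputation agrees with the vectorised path."""
    model = _toy()
    cov = data.draw(st.integers(1, 12))
    rng_seed = data.draw(st.integers(0, 10_000))
    rng = np.random.default_rng(rng_seed)
    bases = []
    for _ in range(cov):
        m = int(rng.integers(5, 20))
        bases.append((
            "ACGT"[rng.integers(0, 4)],
            float(rng.uniform(0, 1)),
            int(rng.integers(1, m + 1)),
            m,
            int(rng.integers(0, 5)),
            int(rng.integers(1, 4)),
        ))
    cs = make_cross_section(bases, ref_base="A")
    s = score_site(cs, model)
    if cs.n_mismatch == 0:
        assert s is None
        return
    d_q, d_p, d_r, d_h, log_q, total = _oracle.score_components(
        cs.bases, "A", model
    )
    assert s.d_q == pytest.approx(d_q, abs=1e-10)
    assert s.d_p == pytest.approx(d_p, abs=1e-10)
    assert s.d_r == pytest.approx(d_r, abs=1e-10)
    assert s.d_h == pytest.approx(d_h, abs=1e-10)
    assert s.log_q == pytest.approx(log_q, abs=1e-10)
    assert s.total == pytest.approx(total, abs=1e-10)


def test_monotone_in_mismatch_quality(toy_model):
    totals = []
    for q in np.linspace(0.05, 0.999, 12):
        cs = _cs(1, match=5, quality=float(q))
        totals.append(score_site(cs, toy_model).total)
    assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))


def test_score_stream_filters_and_frames(toy_model):
    css = [_cs(0, match=3), _cs(1, match=3), _cs(2, match=2)]
    scores = list(score_stream(css, toy_model))
    assert [s.n_mismatch for s in scores] == [1, 2]
    df = scores_to_frame(scores)
    assert list(df["n_mismatch"]) == [1, 2]
    assert df.shape == (2, 13)
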