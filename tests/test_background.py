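"""Background model estimation: δ-ECDF, sampling rule, conditional tables."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adasnv import (
    BackgroundModel,
    DeltaECDF,
    SimConfig,
    build_background_model,
    build_delta_ecdf,
    estimate_conditional_tables,
    iterate_cross_sections,
    sample_background_sites,
    simulate_dataset,
)

from conftest import make_cross_section, make_table


def _cs_with_delta(n_mismatch, coverage, **kw):
    bases = [("C", 0.9, 1, 8, 0, 1)] * n_mismatch
    bases += [("A", 0.9, 1, 8, 0, 1)] * (coverage - n_mismatch)
    return make_cross_section(bases, ref_base="A", **kw)


class TestDeltaECDF:
    def test_direct_counting_examples(self):
        ecdf = DeltaECDF.from_values([0.0, 0.0, 0.1, 0.5])
        assert ecdf.q(0.5) == 1.0
        assert ecdf.q(0.1) == 0.75
        assert ecdf.q(0.0) == 0.5

    def test_floor_below_smallest_value(self):
        ecdf = DeltaECDF.from_values([0.1, 0.2])
        assert ecdf.q(0.05) == pytest.approx(1 / 3)
        assert ecdf.q(0.9) == 1.0

    @given(st.lists(st.sampled_from([0.0, 0.02, 0.1, 0.25, 0.5, 1.0]),
                    min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_and_is_monotone(self, deltas):
        ecdf = DeltaECDF.from_values(deltas)
        grid = np.linspace(0, 1, 21)
        qs = [ecdf.q(g) for g in grid]
        assert all(b >= a for a, b in zip(qs, qs[1:]))
        for g in grid:
            brute = sum(1 for d in deltas if d <= g) / len(deltas)
            if brute > 0:
                assert ecdf.q(g) == pytest.approx(brute, abs=1e-12)
            else:
                assert 0 < ecdf.q(g) <= 1 / len(deltas)

    def test_build_from_stream(self):
        css = [_cs_with_delta(m, 10) for m in (0, 0, 1, 5)]
        ecdf = build_delta_ecdf(css)
        assert ecdf.q(0.1) == 0.75
        ecdf_nz = build_delta_ecdf(css, include_zero=False)
        assert ecdf_nz.n_sites == 2

    def test_empty_stream_fails(self):
        with pytest.raises(ValueError):
            build_delta_ecdf([])


class TestBackgroundSampling:
    def test_delta_window_enforced(self):
        css = (
            [_cs_with_delta(0, 10)] * 5       # δ = 0: excluded
            + [_cs_with_delta(6, 10)] * 5     # δ = 0.6: excluded
            + [_cs_with_delta(5, 10)] * 5     # δ = 0.5: excluded (open interval)
            + [_cs_with_delta(1, 10, pos=p) for p in range(1, 8)]
        )
        sample = sample_background_sites(css, n=100, seed=0)
        assert len(sample) == 7
        assert all(0 < cs.delta < 0.5 for cs in sample)

    def test_exhaustion_warns(self, caplog):
        css = [_cs_with_delta(1, 10, pos=p) for p in range(1, 11)]
        with caplog.at_level("WARNING"):
            sample = sample_background_sites(css, n=100_000, seed=0)
        assert len(sample) == 10
        assert any("qualify" in r.message for r in caplog.records)

    def test_no_qualifying_sites_fails(self):
        with pytest.raises(ValueError, match="no background estimable"):
            sample_background_sites([_cs_with_delta(0, 10)], n=10, seed=0)

    def test_reservoir_reproducible_and_uniform_ish(self):
        css = [_cs_with_delta(1, 10, pos=p) for p in range(1, 2001)]
        s1 = sample_background_sites(css, n=50, seed=7)
        s2 = sample_background_sites(css, n=50, seed=7)
        assert [c.pos for c in s1] == [c.pos for c in s2]
        s3 = sample_background_sites(css, n=50, seed=8)
        assert [c.pos for c in s3] != [c.pos for c in s1]
        # positions from a different seed still span the stream
        assert np.mean([c.pos for c in s3]) == pytest.approx(1000, rel=0.35)


class TestConditionalTables:
    def test_smoothing_arithmetic(self):
        t = make_table("R", [99, 0], [1, 0], r_max=0)
        assert t.pr_match[0] == pytest.approx(99.5 / 101)
        assert t.pr_match[1] == 0.5  # empty bin -> uninformative prior

    def test_counting_over_sample(self):
        cs = make_cross_section(
            [("A", 0.9, 1, 10, 0, 1),    # match, P=0.1
             ("C", 0.9, 10, 10, 3, 1),   # mismatch, P=1.0, R overflow
             ("A", 0.9, 5, 10, 1, 60)],  # match, P=0.5, H overflow
            ref_base="A",
        )
        tabs = estimate_conditional_tables([cs], p_bins=10, r_max=2, h_max=50)
        p = tabs["P"]
        assert p.match_counts[0] == 1 and p.match_counts[4] == 1
        assert p.mismatch_counts[9] == 1
        r = tabs["R"]
        assert r.mismatch_counts[3] == 1     # R=3 > r_max=2 -> overflow bin
        h = tabs["H"]
        assert h.match_counts[50] == 1       # H=60 > h_max=50 -> overflow bin
        assert h.match_counts[0] == 1 and h.mismatch_counts[0] == 1

    def test_p_maxima_over_occupied_bins(self):
        t = make_table("P", [148, 9, 0], [1, 0, 0], n_bins=3)
        assert t.p_match_max == pytest.approx(148.5 / 150)   # = 0.99
        assert t.p_mismatch_max == pytest.approx(1 - 9.5 / 10)  # = 0.05

    def test_bin_edges_inclusive_right(self):
        t = make_table("P", [1] * 50, [1] * 50, n_bins=50)
        assert t.bin_index(np.array([1.0]))[0] == 49
        assert t.bin_index(np.array([0.02]))[0] == 0
        assert t.bin_index(np.array([0.021]))[0] == 1

    def test_flat_error_process_gives_flat_table(self, tmp_path):
        cfg = SimConfig(genome_length=30_000, coverage=30, n_variants=0,
                        beta=0.5, error_rate=0.02, profile="flat", seed=3)
        sim = simulate_dataset(cfg, tmp_path / "flat")
        model = build_background_model(
            iterate_cross_sections(sim.alignments, sim.fasta),
            sample_size=50_000, seed=3,
        )
        t = model.tables["P"]
        occ = (t.match_counts + t.mismatch_counts) > 0
        mism_frac = t.mismatch_counts[occ] / (t.match_counts + t.mismatch_counts)[occ]
        # flat profile: per-bin mismatch fraction varies only by sampling noise
        assert mism_frac.std() / mism_frac.mean() < 0.5
        assert t.p_match_max == pytest.approx(
            np.mean(t.pr_match[occ]), abs=0.02
        )

    def test_ramp_error_process_degrades_toward_read_end(self, small_model):
        t = small_model.tables["P"]
        pr = t.pr_match
        # monotone trend: mean match probability over the first half of the
        # read exceeds the mean over the last half
        assert pr[:25].mean() > pr[25:].mean()
        assert pr[:5].mean() > pr[-5:].mean()


class TestModelSerialization:
    def test_roundtrip_bit_identical(self, small_model, tmp_path):
        p = tmp_path / "model.json"
        small_model.save(p)
        re = BackgroundModel.load(p)
        assert re.to_dict() == small_model.to_dict()
        grid = np.linspace(0, 1, 101)
        assert np.array_equal(re.ecdf.q(grid), small_model.ecdf.q(grid))
        for k in "PRH":
            assert np.array_equal(re.tables[k].pr_match,
                                  small_model.tables[k].pr_match)
        p2 = tmp_path / "model2.json"
        re.save(p2)
        assert p.read_text() == p2.read_text()

    def test_version_checked(self, small_model, tmp_path):
        p = tmp_path / "model.json"
        small_model.save(p)
        d = json.loads(p.read_text())
        d["version"] = "999"
        p.write_text(json.dumps(d))
        with pytest.raises(ValueError, match="version"):
            BackgroundModel.load(p)
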