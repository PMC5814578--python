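"""Pooled-group window similarity: windowing, pooling, scoring,
unique-window assignment and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolscan import similarity as S
from poolscan.snv_matrix import GroupSpec


class TestMakeWindows:
    def test_overlapping_slide(self):
        w = S.make_windows({"c": 1_000_000}, size=500_000, step=250_000)
        assert w[["start", "end"]].values.tolist() == [
            [0, 500_000], [250_000, 750_000], [500_000, 1_000_000],
        ]

    def test_short_chromosome_truncates(self):
        w = S.make_windows({"c": 400_000})
        assert w[["start", "end"]].values.tolist() == [[0, 400_000]]

    def test_step_equals_size_tiles(self):
        w = S.make_windows({"c": 1_100_000}, size=500_000, step=500_000)
        assert len(w) == 3  # ceil(length / size)
        assert w["end"].iloc[-1] == 1_100_000

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            S.make_windows({"c": 100}, size=0)
        with pytest.raises(ValueError):
            S.make_windows({"c": 100}, size=10, step=20)


class TestPooling:
    def test_fixed_and_half_frequencies(self, tiny_matrix, tiny_spec):
        freqs = S.pool_allele_frequencies(tiny_matrix, tiny_spec)
        # group A rows: [0,0,1,1,0,1] and [0,1,1,1,0,1]
        assert freqs.freq("A").tolist() == [0, 0.5, 1, 1, 0, 1]
        assert freqs.n == {"A": 2, "B": 2}

    def test_unknown_group_raises(self, tiny_matrix, tiny_spec):
        freqs = S.pool_allele_frequencies(tiny_matrix, tiny_spec)
        with pytest.raises(KeyError):
            freqs.freq("nope")

    def test_pooled_frequency_estimates_truth(self, small_truth, small_matrix):
        """Pooled frequencies sit within binomial sampling error of the
        generating frequencies (5 sigma on the mean absolute error)."""
        spec = small_truth.config.group_spec()
        freqs = S.pool_allele_frequencies(small_matrix, spec)
        for g, n in spec.sizes().items():
            p = small_truth.frequencies[small_truth.groups.index(g)]
            err = np.abs(freqs.freq(g) - p)
            bound = np.sqrt(p * (1 - p) / n)
            assert err.mean() < bound.mean() + 5 * bound.std() / np.sqrt(len(p))


class TestSiteSimilarity:
    @pytest.mark.parametrize(
        "p1,p2,expected", [(1.0, 1.0, 1.0), (1.0, 0.0, 0.0), (0.8, 0.6, 0.8)]
    )
    def test_values(self, p1, p2, expected):
        assert S.site_similarity(p1, p2) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            S.site_similarity(1.2, 0.5)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0, 1), st.floats(0, 1),
           st.sampled_from(S.SIMILARITY_METHODS))
    def test_symmetric_and_bounded(self, p1, p2, method):
        a = S.site_similarity(p1, p2, method=method)
        b = S.site_similarity(p2, p1, method=method)
        assert a == b and 0 <= a <= 1

    def test_major_allele_variant(self):
        assert S.site_similarity(0.9, 0.6, method="major") == 1.0
        assert S.site_similarity(0.9, 0.1, method="major") == 0.0
        assert S.site_similarity(0.5, 0.9, method="major") == 0.5


def _freqs_from(p_by_group: dict, positions, chrom="c1"):
    groups = list(p_by_group)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"}
    )
    return S.PoolFrequencies(
        groups=groups,
        n={g: 10 for g in groups},
        p=np.array([p_by_group[g] for g in groups], dtype=float),
        sites=sites,
    )


class TestWindowScan:
    def test_mean_of_site_similarities(self):
        # sims vs focal: 1 - |dp| = {1.0, 0.9, 0.95}
        freqs = _freqs_from(
            {"F": [0.5, 0.5, 0.5], "G": [0.5, 0.6, 0.45]}, [10, 20, 30]
        )
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]})
        out = S.window_scan(freqs, w, "F", ["G"])
        assert out["sim_G"].iloc[0] == pytest.approx(0.95)
        assert out["n_snvs"].iloc[0] == 3

    def test_empty_window_flagged_undefined(self):
        freqs = _freqs_from({"F": [0.5], "G": [0.5]}, [10])
        w = pd.DataFrame({"chrom": ["c1"], "start": [100], "end": [200]})
        out = S.window_scan(freqs, w, "F", ["G"])
        assert out["n_snvs"].iloc[0] == 0 and np.isnan(out["sim_G"].iloc[0])

    def test_identical_pools_give_one(self):
        p = list(np.linspace(0, 1, 7))
        freqs = _freqs_from({"F": p, "G": p}, list(range(10, 80, 10)))
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]})
        out = S.window_scan(freqs, w, "F", ["G"])
        assert out["sim_G"].iloc[0] == pytest.approx(1.0)

    def test_symmetry_between_groups(self):
        rng = np.random.default_rng(0)
        freqs = _freqs_from(
            {"F": rng.random(20), "G": rng.random(20)},
            sorted(rng.choice(1000, 20, replace=False)),
        )
        w = S.make_windows({"c1": 1000}, size=500, step=250)
        ab = S.window_scan(freqs, w, "F", ["G"])["sim_G"]
        ba = S.window_scan(freqs, w, "G", ["F"])["sim_F"]
        assert np.allclose(ab, ba, equal_nan=True)

    def test_focal_in_others_rejected(self):
        freqs = _freqs_from({"F": [0.5], "G": [0.5]}, [10])
        w = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]})
        with pytest.raises(ValueError):
            S.window_scan(freqs, w, "F", ["F", "G"])


def _records(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snvs",
                       "sim_QK", "sim_Wb-T", "sim_Wb-NE"]
    )


class TestAssignment:
    def test_argmax_assignment(self):
        rec = _records([("c1", 0, 500, 30, 0.97, 0.96, 0.90)])
        out = S.assign_unique_windows(rec)
        assert out["assigned_to"].iloc[0] == "QK"

    def test_snv_floor_excludes(self):
        rec = _records([("c1", 0, 500, 24, 0.99, 0.1, 0.1)])
        out = S.assign_unique_windows(rec)
        assert not out["qualifies"].iloc[0]
        assert out["assigned_to"].iloc[0] is None

    def test_exact_tie_excluded_and_counted(self):
        rec = _records([("c1", 0, 500, 30, 0.97, 0.97, 0.90)])
        out = S.assign_unique_windows(rec)
        assert out["tie"].iloc[0] and out["assigned_to"].iloc[0] is None
        assert out["qualifies"].iloc[0]

    def test_partition_identity(self):
        rng = np.random.default_rng(1)
        rows = [
            ("c1", i * 250, i * 250 + 500, int(rng.integers(0, 60)),
             *rng.uniform(0.8, 1.0, 3))
            for i in range(200)
        ]
        out = S.assign_unique_windows(_records(rows))
        assert out["qualifies"].sum() == (
            out["assigned_to"].notna().sum() + out["tie"].sum()
        )

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        rows = [
            ("c1", i * 250, i * 250 + 500, int(rng.integers(0, 60)),
             *rng.uniform(0.8, 1.0, 3))
            for i in range(200)
        ]
        rec = _records(rows)
        counts_sim = [
            S.assign_unique_windows(rec, min_sim=s)["qualifies"].sum()
            for s in (0.85, 0.90, 0.95, 0.99)
        ]
        counts_snv = [
            S.assign_unique_windows(rec, min_snvs=n)["qualifies"].sum()
            for n in (5, 25, 50)
        ]
        assert counts_sim == sorted(counts_sim, reverse=True)
        assert counts_snv == sorted(counts_snv, reverse=True)

    def test_matches_exhaustive_enumeration_on_toy_input(self):
        """Brute-force oracle: enumerate every window x pair by hand on a
        <=10-site input and compare assignments."""
        rng = np.random.default_rng(3)
        positions = sorted(rng.choice(2000, 8, replace=False))
        p = {g: rng.random(8) for g in ("F", "G1", "G2")}
        freqs = _freqs_from(p, positions)
        windows = S.make_windows({"c1": 2000}, size=1000, step=500)
        scan = S.window_scan(freqs, windows, "F", ["G1", "G2"])
        out = S.assign_unique_windows(scan, min_snvs=2, min_sim=0.5)
        for wi, (_, start, end) in enumerate(
            windows[["chrom", "start", "end"]].itertuples(index=False)
        ):
            idx = [i for i, x in enumerate(positions) if start <= x < end]
            expect = None
            if len(idx) >= 2:
                sims = {
                    g: np.mean([1 - abs(p["F"][i] - p[g][i]) for i in idx])
                    for g in ("G1", "G2")
                }
                best = max(sims, key=sims.get)
                if sims[best] >= 0.5 and len(
                    [g for g in sims if sims[g] == sims[best]]
                ) == 1:
                    expect = best
            assert out["assigned_to"].iloc[wi] == expect


class TestSummaries:
    def test_printed_count_split(self):
        """334/226/154 equal-length windows -> 46.78/31.65/21.57 percent."""
        rows = []
        start = 0
        for g, n in [("QK", 334), ("Wb-T", 226), ("Wb-NE", 154)]:
            for _ in range(n):
                rows.append(("c1", start, start + 500_000, g, 0.99))
                start += 250_000
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "assigned_to", "best_sim"]
        )
        out = S.summarize_similarity(df, per_chrom=False)
        pct = dict(zip(out["group"], out["percent"]))
        assert pct["QK"] == pytest.approx(46.78, abs=0.005)
        assert pct["Wb-T"] == pytest.approx(31.65, abs=0.005)
        assert pct["Wb-NE"] == pytest.approx(21.57, abs=0.005)
        assert sum(pct.values()) == pytest.approx(100)

    def test_single_window_is_hundred_percent(self):
        df = pd.DataFrame(
            [("c1", 0, 500_000, "QK", 0.99)],
            columns=["chrom", "start", "end", "assigned_to", "best_sim"],
        )
        out = S.summarize_similarity(df)
        assert (out["percent"] == 100.0).all()

    def test_chromosomes_without_assignments_absent(self):
        df = pd.DataFrame(
            [("c1", 0, 500_000, "QK", 0.99), ("c2", 0, 500_000, None, np.nan)],
            columns=["chrom", "start", "end", "assigned_to", "best_sim"],
        )
        out = S.summarize_similarity(df)
        assert set(out["chrom"]) == {"c1", "genome"}

    def test_empty_input_gives_empty_summary(self):
        df = pd.DataFrame(
            columns=["chrom", "start", "end", "assigned_to", "best_sim"]
        )
        assert S.summarize_similarity(df).empty


class TestLinks:
    def test_round_trip_and_ordering(self, tmp_path):
        df = pd.DataFrame(
            [
                ("c2", 0, 500_000, "QK", 0.97),
                ("c1", 250_000, 750_000, "Wb-T", 0.96),
                ("c1", 0, 500_000, "QK", 0.99),
            ],
            columns=["chrom", "start", "end", "assigned_to", "best_sim"],
        )
        p = tmp_path / "links.bed"
        S.export_links(df, p)
        back = S.read_links(p)
        assert back["chrom"].tolist() == ["c1", "c1", "c2"]
        assert back["start"].tolist() == [0, 250_000, 0]
        assert back["best_sim"].tolist() == [0.99, 0.96, 0.97]

    def test_empty_export_rejected(self, tmp_path):
        df = pd.DataFrame(
            columns=["chrom", "start", "end", "assigned_to", "best_sim"]
        )
        with pytest.raises(ValueError):
            S.export_links(df, tmp_path / "x.bed")
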