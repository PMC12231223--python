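"""Prey volume, composition table, IRI ranking and size summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import geckodiet as gd
from conftest import make_dataset, random_small_dataset


class TestPreyVolume:
    @pytest.mark.parametrize(
        "length,width,pi_mode,expected",
        [
            (10.0, 2.0, "exact", 20.944),       # (4*pi/3) * 5 * 1^2
            (2.0, 2.0, "exact", 4.18879),       # sphere of diameter 2
            (10.0, 2.0, "paper_3_14", 20.933),  # pi fixed at 3.14
        ],
    )
    def test_known_volumes(self, length, width, pi_mode, expected):
        assert gd.prey_volume(length, width, pi_mode) == pytest.approx(
            expected, abs=5e-4)

    def test_sphere_limit_matches_closed_form(self):
        # L = W = 2r reduces the spheroid to a sphere of radius r
        r = 1.7
        assert gd.prey_volume(2 * r, 2 * r) == pytest.approx(4 / 3 * math.pi * r**3)

    @given(
        length=st.floats(0.1, 100.0),
        width=st.floats(0.1, 100.0),
        bump=st.floats(0.01, 10.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing_in_both_dimensions(self, length, width, bump):
        base = gd.prey_volume(length, width)
        assert gd.prey_volume(length + bump, width) > base
        assert gd.prey_volume(length, width + bump) > base

    def test_nonpositive_dimension_is_domain_error(self):
        with pytest.raises(gd.GeckodietError):
            gd.prey_volume(0.0, 1.0)
        with pytest.raises(gd.GeckodietError):
            gd.prey_volume(1.0, -2.0)


def brute_force_composition(items, freq_denominator="sum_of_F", n_stomachs=None):
    """Independent tally: items is a list of (stomach_id, category, volume)."""
    cats = sorted({c for _, c, _ in items})
    tallies = {}
    for c in cats:
        stomachs = {s for s, cc, _ in items if cc == c}
        n = sum(1 for _, cc, _ in items if cc == c)
        v = sum(vol for _, cc, vol in items if cc == c)
        tallies[c] = (len(stomachs), n, v)
    sum_f = sum(t[0] for t in tallies.values())
    sum_n = sum(t[1] for t in tallies.values())
    sum_v = sum(t[2] for t in tallies.values())
    denom_f = sum_f if freq_denominator == "sum_of_F" else n_stomachs
    out = {}
    for c, (f, n, v) in tallies.items():
        pf = 100 * f / denom_f
        pn = 100 * n / sum_n
        pv = 100 * v / sum_v
        out[c] = (f, pf, n, pn, v, pv, (pf + pn + pv) / 3)
    return out


class TestCompositionTable:
    @pytest.mark.parametrize("freq_denominator", ["sum_of_F", "n_stomachs"])
    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_tally(self, seed, freq_denominator):
        rng = np.random.default_rng(seed)
        ds = random_small_dataset(rng)
        ds = gd.compute_volumes(ds)
        table = gd.composition_table(ds, freq_denominator=freq_denominator)
        oracle = brute_force_composition(
            [(p.specimen_id, p.category, p.volume_mm3) for p in ds.prey_items],
            freq_denominator, n_stomachs=len(ds),
        )
        assert set(table.categories) == set(oracle)
        for row in table.rows:
            f, pf, n, pn, v, pv, iri = oracle[row.category]
            assert (row.F, row.N) == (f, n)
            assert row.V == pytest.approx(v, rel=1e-9)
            assert row.pctF == pytest.approx(pf, rel=1e-9)
            assert row.pctN == pytest.approx(pn, rel=1e-9)
            assert row.pctV == pytest.approx(pv, rel=1e-9)
            assert row.iri == pytest.approx(iri, rel=1e-9)

    def test_reproduces_published_rows(self, reference_table):
        araneae = reference_table.row("Araneae")
        assert gd.round_half_away(araneae.pctF) == 26.67
        assert gd.round_half_away(araneae.pctN) == 35.87
        assert gd.round_half_away(araneae.pctV) == 10.44
        assert gd.round_half_away(araneae.iri) == 24.33
        assert gd.round_half_away(reference_table.row("Achatinidae").iri) == 10.67

    def test_single_category_normalizes_to_100(self):
        ds = gd.compute_volumes(make_dataset({"s1": [("Araneae", 5.0, 1.0)],
                                              "s2": [("Araneae", 7.0, 2.0)]}))
        (row,) = gd.composition_table(ds).rows
        assert row.pctF == row.pctN == row.pctV == row.iri == 100.0

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation_and_normalization_invariants(self, seed):
        rng = np.random.default_rng(100 + seed)
        ds = gd.compute_volumes(random_small_dataset(rng))
        table = gd.composition_table(ds)
        assert table.total_N == sum(r.N for r in table.rows) == len(ds.prey_items)
        assert table.total_V == pytest.approx(
            sum(p.volume_mm3 for p in ds.prey_items), rel=1e-6)
        for col in ("pctF", "pctN", "pctV", "iri"):
            assert sum(getattr(r, col) for r in table.rows) == pytest.approx(
                100.0, abs=0.05)

    def test_pct_volume_invariant_to_pi_mode(self):
        rng = np.random.default_rng(42)
        ds = random_small_dataset(rng)
        exact = gd.composition_table(gd.compute_volumes(ds, "exact"))
        approx = gd.composition_table(gd.compute_volumes(ds, "paper_3_14"))
        for re, ra in zip(exact.rows, approx.rows):
            assert re.pctV == pytest.approx(ra.pctV, rel=1e-12)
            assert re.iri == pytest.approx(ra.iri, rel=1e-12)

    def test_adding_item_never_decreases_its_share(self):
        base = {"s1": [("Araneae", 5.0, 1.0), ("Blattidae", 8.0, 2.0)],
                "s2": [("Opiliones", 4.0, 1.5)]}
        t0 = gd.composition_table(gd.compute_volumes(make_dataset(base)))
        grown = {k: list(v) for k, v in base.items()}
        grown["s2"].append(("Araneae", 3.0, 1.0))
        t1 = gd.composition_table(gd.compute_volumes(make_dataset(grown)))
        assert t1.row("Araneae").pctN > t0.row("Araneae").pctN
        assert t1.row("Araneae").iri > t0.row("Araneae").iri

    def test_empty_after_filter_is_error(self, default_dataset):
        with pytest.raises(gd.GeckodietError):
            gd.composition_table(default_dataset, group_filter="juvenile")

    def test_n_stomachs_denominator_uses_stomach_count(self):
        ds = gd.compute_volumes(make_dataset({
            "s1": [("Araneae", 5.0, 1.0)],
            "s2": [("Araneae", 6.0, 1.0), ("Blattidae", 4.0, 1.0)],
        }))
        table = gd.composition_table(ds, freq_denominator="n_stomachs")
        assert table.row("Araneae").pctF == pytest.approx(100.0)  # 2 of 2 stomachs
        assert table.row("Blattidae").pctF == pytest.approx(50.0)


class TestRanking:
    def test_strict_iri_order_is_non_increasing(self, reference_table):
        ranked = gd.rank_by_iri(reference_table)
        iris = [reference_table.row(c).iri for c in ranked]
        assert iris == sorted(iris, reverse=True)

    def test_narrative_six_reproduced_with_occurrence_filter(self, reference_table):
        assert gd.rank_by_iri(reference_table, top_k=6, min_stomachs=2) == [
            "Araneae", "Opiliones", "Achatinidae", "Blattidae",
            "Scolopendridae", "Acrididae",
        ]

    def test_named_six_keep_relative_order_in_strict_ranking(self, reference_table):
        full = gd.rank_by_iri(reference_table)
        six = ["Araneae", "Opiliones", "Achatinidae", "Blattidae",
               "Scolopendridae", "Acrididae"]
        positions = [full.index(c) for c in six]
        assert positions == sorted(positions)

    def test_single_category_table(self):
        ds = gd.compute_volumes(make_dataset({"s1": [("Araneae", 5.0, 1.0)]}))
        assert gd.rank_by_iri(gd.composition_table(ds)) == ["Araneae"]

    def test_exact_tie_breaks_lexicographically(self):
        # identical F, N and volume in both categories -> identical IRI and N
        ds = gd.compute_volumes(make_dataset({
            "s1": [("Zygoptera", 5.0, 1.0), ("Acrididae", 5.0, 1.0)],
        }))
        assert gd.rank_by_iri(gd.composition_table(ds)) == ["Acrididae",
                                                            "Zygoptera"]


class TestSizeSummary:
    def test_hand_computable_pair(self):
        ds = make_dataset({"s1": [("Araneae", 2.0, 1.0), ("Araneae", 4.0, 1.0)]})
        s = gd.size_summary(ds, "length")
        assert (s.n, s.mean, s.min, s.max) == (2, 3.0, 2.0, 4.0)
        assert s.sd == pytest.approx(math.sqrt(2), abs=1e-4)

    def test_single_item_reports_zero_sd(self):
        ds = make_dataset({"s1": [("Araneae", 2.0, 1.0)]})
        s = gd.size_summary(ds, "length")
        assert (s.n, s.sd) == (1, 0.0)

    def test_default_generator_matches_study_mean_length(self, default_dataset):
        s = gd.size_summary(default_dataset, "length")
        assert s.n > 100
        assert s.mean == pytest.approx(7.53, abs=0.7)  # ~bootstrap SE at n≈400

    def test_count_per_stomach_aggregates_first(self):
        ds = make_dataset({"s1": [("Araneae", 2.0, 1.0)] * 3,
                           "s2": [("Blattidae", 4.0, 1.0)]})
        s = gd.size_summary(ds, "count_per_stomach")
        assert (s.n, s.mean, s.min, s.max) == (2, 2.0, 1.0, 3.0)

    def test_empty_selection_is_error(self):
        ds = make_dataset({"s1": [("Araneae", 2.0, 1.0)]})
        with pytest.raises(gd.GeckodietError):
            gd.size_summary(ds, "length", group_filter="male")


class TestTrophicSpectrum:
    def test_overall_count_on_default_dataset(self, default_dataset):
        spectrum = gd.trophic_spectrum(default_dataset, by=None)
        assert spectrum["all"] == len({p.category
                                       for p in default_dataset.prey_items})

    def test_single_shared_category_counts_once_per_group(self):
        ds = make_dataset(
            {"m1": [("Araneae", 5.0, 1.0)], "f1": [("Araneae", 4.0, 1.0)]},
            groups={"m1": "male", "f1": "female"},
        )
        assert gd.trophic_spectrum(ds) == {"male": 1, "female": 1}

    def test_group_without_items_counts_zero(self):
        ds = gd.assemble_dataset(
            [gd.Specimen("m1", "male", 100.0, 20.0, 19.0),
             gd.Specimen("f1", "female", 100.0, 20.0, 19.0)],
            [gd.PreyItem("f1", "Araneae", 4.0, 1.0)],
        )
        assert gd.trophic_spectrum(ds) == {"male": 0, "female": 1}
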