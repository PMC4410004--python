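"""Correction factors, hotspot calling, and reference-model round trips."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import somdriver as sd
from somdriver.reference import GeneMutationProfile, aggregate_profiles


def make_profile(n_sil=0, n_og=0, n_tsg=0, cds_length=1000, position_counts=None):
    return GeneMutationProfile(
        gene="G",
        cds_length=cds_length,
        n_sil=n_sil,
        n_og=n_og,
        n_tsg=n_tsg,
        position_counts=position_counts or {},
    )


class TestCorrectionFactors:
    @pytest.mark.parametrize(
        "n_sil, n_og, expected",
        [
            (0, 10, 1.0),  # no silent load at all
            (134, 392, 0.0),  # observed ratio equals the neutral 134/392
            (67, 392, 0.5),  # observed ratio at half the neutral ratio
            (300, 100, 0.0),  # negative factor clamps to zero
            (0, 0, 1.0),  # no data: no evidence of elevated background
            (5, 0, 0.0),  # silent only: background dominated
        ],
    )
    def test_f_og(self, code_table, n_sil, n_og, expected):
        factors = sd.compute_correction_factors(
            make_profile(n_sil=n_sil, n_og=n_og), code_table
        )
        assert factors.f_og == pytest.approx(expected)

    @pytest.mark.parametrize(
        "n_sil, n_tsg, expected",
        [(134, 23, 0.0), (0, 23, 1.0), (67, 23, 0.5), (1000, 23, 0.0)],
    )
    def test_f_tsg(self, code_table, n_sil, n_tsg, expected):
        factors = sd.compute_correction_factors(
            make_profile(n_sil=n_sil, n_tsg=n_tsg), code_table
        )
        assert factors.f_tsg == pytest.approx(expected)

    @given(
        n_og=st.integers(0, 500),
        n_tsg=st.integers(0, 100),
        sil_a=st.integers(0, 300),
        sil_b=st.integers(0, 300),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_non_increasing_in_silent_load(self, n_og, n_tsg, sil_a, sil_b):
        lo, hi = sorted([sil_a, sil_b])
        f_lo = sd.compute_correction_factors(make_profile(n_sil=lo, n_og=n_og, n_tsg=n_tsg))
        f_hi = sd.compute_correction_factors(make_profile(n_sil=hi, n_og=n_og, n_tsg=n_tsg))
        assert f_hi.f_og <= f_lo.f_og + 1e-12
        assert f_hi.f_tsg <= f_lo.f_tsg + 1e-12
        assert 0.0 <= f_hi.f_og <= 1.0 and 0.0 <= f_hi.f_tsg <= 1.0


class TestDetectHotspots:
    def test_zero_factor_silences_all_positions(self):
        profile = make_profile(n_sil=500, n_og=100, position_counts={10: 50, 20: 30})
        factors = sd.compute_correction_factors(profile)
        assert factors.f_og == 0.0
        assert sd.detect_hotspots(profile, factors) == ()

    def test_recurrent_position_is_called(self):
        # binomial tail(3, 10, 1/1000) ~ 1.2e-7 << 0.05
        profile = make_profile(n_og=10, cds_length=1000, position_counts={42: 3})
        factors = sd.CorrectionFactors(f_og=1.0, f_tsg=1.0)
        hotspots = sd.detect_hotspots(profile, factors)
        assert [h.cds_pos for h in hotspots] == [42]
        assert hotspots[0].p_value == pytest.approx(1.1948e-7, rel=1e-3)

    def test_singleton_never_a_hotspot(self):
        profile = make_profile(n_og=2, cds_length=30, position_counts={5: 1, 7: 1})
        factors = sd.CorrectionFactors(f_og=1.0, f_tsg=1.0)
        assert sd.detect_hotspots(profile, factors) == ()

    def test_matches_exhaustive_integer_scan(self):
        """With f_og = 1 hotspot calls equal a brute-force per-position scan."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            length = int(rng.integers(60, 3000))
            n_positions = int(rng.integers(1, 12))
            positions = rng.choice(length, size=n_positions, replace=False) + 1
            counts = rng.integers(1, 8, size=n_positions)
            n_og = int(counts.sum()) + int(rng.integers(0, 5))
            profile = make_profile(
                n_og=n_og,
                cds_length=length,
                position_counts={int(p): int(c) for p, c in zip(positions, counts)},
            )
            got = {h.cds_pos for h in sd.detect_hotspots(profile, sd.CorrectionFactors(1.0, 1.0))}
            p_l = 1.0 / length
            expected = {
                int(pos)
                for pos, c in profile.position_counts.items()
                if c >= 2
                and sum(
                    comb(n_og, x) * p_l**x * (1 - p_l) ** (n_og - x)
                    for x in range(c, n_og + 1)
                )
                <= 0.05
            }
            assert got == expected

    def test_hotspot_count_bounded_by_distinct_positions(self, planted_dataset):
        for gene in planted_dataset["model"].genes.values():
            assert all(h.raw_count >= 2 for h in gene.hotspots)


class TestBuildReference:
    def test_planted_og_gene_has_hotspots_and_high_factor(self, planted_dataset):
        model = planted_dataset["model"]
        factors = []
        for i in range(1, 6):
            entry = model.get(f"OG{i:02d}")
            assert len(entry.hotspots) >= 1
            assert entry.f_og > 0.2  # well above background-dominated
            factors.append(entry.f_og)
        assert np.median(factors) > 0.7

    def test_constructed_og_like_gene(self):
        """40% of 50 missense on 3 positions, 2 silent: hotspots, f_og near 1."""
        rows = [("OG", f"S{i}", 300 + (i % 3), "Missense_Mutation") for i in range(20)]
        rows += [("OG", f"T{i}", 10 * i + 1, "Missense_Mutation") for i in range(30)]
        rows += [("OG", f"U{i}", 50 * i + 7, "Silent") for i in range(2)]
        df, _ = _table_for(rows)
        model = sd.build_reference(df, {"OG": 1500})
        entry = model.get("OG")
        assert entry.f_og > 0.85
        assert {h.cds_pos for h in entry.hotspots} >= {300, 301, 302}

    def test_neutral_ratio_gene_yields_zero_factor_and_no_hotspots(self):
        df, _ = _table_for(
            [("NEU", f"S{i}", (i % 500) + 1, "Silent") for i in range(134)]
            + [("NEU", f"T{i}", (i % 500) + 1, "Missense_Mutation") for i in range(392)]
        )
        model = sd.build_reference(df, {"NEU": 600})
        entry = model.get("NEU")
        assert entry.f_og == pytest.approx(0.0)
        assert entry.hotspots == ()

    def test_gene_without_cds_length_is_dropped(self):
        df, _ = _table_for([("KNOWN", "S1", 5, "Missense_Mutation"),
                            ("UNKNOWN", "S1", 5, "Missense_Mutation")])
        model = sd.build_reference(df, {"KNOWN": 300})
        assert model.get("UNKNOWN") is None and model.get("KNOWN") is not None

    def test_unmutated_gene_gets_neutral_defaults(self):
        df, _ = _table_for([("A", "S1", 5, "Missense_Mutation")])
        model = sd.build_reference(df, {"A": 300, "B": 900})
        entry = model.get("B")
        assert entry.f_og == 1.0 and entry.f_tsg == 1.0 and entry.hotspots == ()

    def test_empty_table_is_fatal(self):
        import pandas as pd

        with pytest.raises(ValueError):
            sd.build_reference(pd.DataFrame(), {"A": 300})

    def test_serialization_round_trip(self, tmp_path, planted_dataset):
        model = planted_dataset["model"]
        model.save(tmp_path / "model")
        loaded = sd.ReferenceModel.load(tmp_path / "model")
        assert loaded.alpha == model.alpha
        assert set(loaded.genes) == set(model.genes)
        for gene, entry in model.genes.items():
            other = loaded.genes[gene]
            assert other == entry  # dataclass equality, bit-identical floats


def _table_for(rows):
    """Build an internal mutation table from (gene, sample, pos, class) tuples."""
    import pandas as pd

    from somdriver.io import LoadReport, _finalize_table

    df = pd.DataFrame(rows, columns=["gene", "sample", "cds_pos", "source_class"])
    report = LoadReport()
    return _finalize_table(df, None, report), report


def test_aggregate_profiles_counts(planted_dataset):
    """Per-gene category totals partition the table rows."""
    cohort = planted_dataset["cohort"]
    profiles, dropped = aggregate_profiles(cohort, planted_dataset["lengths"])
    assert dropped == 0
    n_counted = sum(p.n_sil + p.n_og + p.n_tsg for p in profiles.values())
    n_expected = (cohort["category"] != "EXCLUDED").sum()
    assert n_counted == n_expected
    for p in profiles.values():
        assert sum(p.position_counts.values()) <= p.n_og
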