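"""Filter semantics: thresholds, PON, population AF, plasma pool, and methods."""

import numpy as np
import pytest

from ctdnasignal import (
    FilterConfig,
    Observation,
    PonSites,
    VariantKey,
    apply_method,
    apply_plasma_pool_filter,
    apply_pon_filter,
    apply_population_af_filter,
    build_pon,
    build_pon_from_tables,
    evaluate_basic_filters,
    filter_ladder,
    merge_pons,
    read_pon,
    write_pon,
)
from ctdnasignal.filters import method_verdict_frame

from conftest import rec, table_of, random_table

CFG = FilterConfig()


def kept_keys(table):
    return set(table.keys())


class TestBasicThresholds:
    def test_boundary_values_pass(self):
        r = rec(100, tumor=(12, 8), normal=(10, 0))
        assert evaluate_basic_filters(r, CFG) == set()

    def test_tumor_ad_below_threshold(self):
        r = rec(100, tumor=(24, 7), normal=(17, 0))
        assert evaluate_basic_filters(r, CFG) == {"ADt"}

    def test_any_normal_alt_read_fails(self):
        r = rec(100, tumor=(24, 12), normal=(17, 1))
        assert evaluate_basic_filters(r, CFG) == {"ADn"}

    def test_low_tumor_vaf_fails(self):
        # AD 8 of DP 48 -> VAF 1/6 < 0.2 but AD/DP thresholds pass
        r = rec(100, tumor=(48, 8), normal=(17, 0))
        assert evaluate_basic_filters(r, CFG) == {"VAFt"}

    def test_scalar_and_vectorized_paths_agree(self):
        rng = np.random.default_rng(3)
        from ctdnasignal.filters import basic_failed_frame

        for _ in range(20):
            table = random_table(rng)
            frame = basic_failed_frame(table, CFG)
            for i, r in enumerate(table.records()):
                expected = evaluate_basic_filters(r, CFG)
                got = {lab for lab in frame.columns if frame.iloc[i][lab]}
                assert got == expected


class TestPopulationAfFilter:
    def test_inclusive_boundary(self):
        table = table_of([
            rec(100, pop_af=2e-5),   # above -> removed
            rec(200, pop_af=1e-5),   # at cutoff -> kept (<=)
            rec(300, pop_af=None),   # absent -> kept
        ])
        kept, verdicts = apply_population_af_filter(table, 1e-5)
        assert [k.pos for k in kept.keys()] == [200, 300]
        assert [v.failed for v in verdicts] == [frozenset({"gnomAD"}), frozenset(), frozenset()]


class TestPanelOfNormals:
    def normals(self, counts):
        """counts: list of per-sample {pos: ad}."""
        return {
            f"N{j}": [(VariantKey("1", pos, "A", "C"), Observation(20, ad))
                      for pos, ad in sample.items()]
            for j, sample in enumerate(counts)
        }

    def test_site_in_two_normals_enters(self):
        pon = build_pon(self.normals([{100: 1}, {100: 1}] + [{}] * 8), CFG)
        assert VariantKey("1", 100, "A", "C") in pon

    def test_site_in_one_normal_stays_out(self):
        pon = build_pon(self.normals([{100: 3}] + [{}] * 9), CFG)
        assert len(pon) == 0

    def test_degenerate_single_sample_rule(self):
        cfg = CFG.with_(pon_min_samples=1)
        pon = build_pon(self.normals([{100: 1}, {}]), cfg)
        assert VariantKey("1", 100, "A", "C") in pon

    def test_build_from_tables_uses_normal_column(self):
        t1 = table_of([rec(100, normal=(17, 1)), rec(200, normal=(17, 0))], patient_id="A")
        t2 = table_of([rec(100, normal=(17, 2))], patient_id="B")
        pon = build_pon_from_tables([t1, t2], CFG)
        assert pon.sites == {VariantKey("1", 100, "A", "C")}

    def test_merge_is_set_union(self):
        k1, k2 = VariantKey("1", 1, "A", "C"), VariantKey("1", 2, "A", "C")
        a = PonSites(frozenset({k1}), "a")
        b = PonSites(frozenset({k2}), "b")
        assert merge_pons(a, b).sites == {k1, k2}
        assert merge_pons(a, PonSites.empty()).sites == a.sites
        assert merge_pons(a, a).sites == a.sites

    def test_pon_filter_membership(self):
        table = table_of([rec(100), rec(200)])
        pon = PonSites(frozenset({VariantKey("1", 100, "A", "C")}))
        kept, _ = apply_pon_filter(table, pon)
        assert [k.pos for k in kept.keys()] == [200]
        kept_all, _ = apply_pon_filter(table, PonSites.empty())
        assert kept_all == table

    def test_pon_tsv_round_trip(self, tmp_path):
        pon = PonSites(frozenset({VariantKey("1", 5, "A", "G"), VariantKey("2", 9, "C", "T")}), "x")
        path = tmp_path / "pon.tsv"
        write_pon(pon, path)
        assert read_pon(path).sites == pon.sites


class TestPlasmaPoolFilter:
    def test_strict_inequality_boundary(self):
        pool_ads = [(50, a) for a in (0, 1, 1, 0, 0, 0, 0, 0, 0)]
        table = table_of([rec(100, pool=tuple(pool_ads))], n_pool=9)
        kept, _ = apply_plasma_pool_filter(table)
        assert len(kept) == 1  # no pool AD exceeds 1 strictly

    def test_ad_two_in_any_pool_sample_removes(self):
        pool_ads = [(50, a) for a in (0, 2, 0, 0, 0, 0, 0, 0, 0)]
        table = table_of([rec(100, pool=tuple(pool_ads))], n_pool=9)
        kept, verdicts = apply_plasma_pool_filter(table)
        assert len(kept) == 0
        assert verdicts[0].failed == {"pool"}

    def test_empty_pool_is_identity(self):
        table = table_of([rec(100), rec(200)], n_pool=0)
        kept, _ = apply_plasma_pool_filter(table)
        assert kept == table

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            table = random_table(rng)
            once, _ = apply_plasma_pool_filter(table)
            twice, _ = apply_plasma_pool_filter(once)
            assert twice == once


class TestMethods:
    def test_pool_only_failure_separates_method3(self, toy_table):
        for method in (1, 2):
            kept, _ = apply_method(toy_table, method, CFG)
            assert 400 in {k.pos for k in kept.keys()}
        kept3, _ = apply_method(toy_table, 3, CFG)
        assert 400 not in {k.pos for k in kept3.keys()}
        assert 100 in {k.pos for k in kept3.keys()}  # clean variant kept by all

    def test_unknown_method_rejected(self, toy_table):
        with pytest.raises(ValueError):
            apply_method(toy_table, 4, CFG)

    def test_method_nesting_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            table = random_table(rng)
            pon = PonSites(frozenset(k for k in table.keys() if rng.random() < 0.1), "p1")
            pon_self = PonSites(frozenset(k for k in table.keys() if rng.random() < 0.1), "p2")
            k1, _ = apply_method(table, 1, CFG, pon, pon_self)
            k2, _ = apply_method(table, 2, CFG, pon, pon_self)
            k3, _ = apply_method(table, 3, CFG, pon, pon_self)
            assert kept_keys(k3) <= kept_keys(k2) <= kept_keys(k1)

    def test_verdict_completeness(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, n_variants=30)
        kept, verdicts = apply_method(table, 3, CFG)
        kept_set = kept_keys(kept)
        for v in verdicts:
            assert (v.key in kept_set) == v.passes

    def test_pool_and_pon_order_independence(self):
        """Method 3 survivors are the same whether the pool filter runs before or after the PON."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            table = random_table(rng)
            pon = PonSites(frozenset(k for k in table.keys() if rng.random() < 0.2), "pon")
            pool_first, _ = apply_plasma_pool_filter(table, CFG.pool_ad_gt)
            a, _ = apply_pon_filter(pool_first, pon)
            pon_first, _ = apply_pon_filter(table, pon)
            b, _ = apply_plasma_pool_filter(pon_first, CFG.pool_ad_gt)
            assert a == b

    def test_monotone_thresholds_never_add_survivors(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            table = random_table(rng)
            base = FilterConfig(
                ad_t_min=int(rng.integers(0, 10)),
                dp_t_min=int(rng.integers(0, 15)),
                vaf_t_min=float(rng.uniform(0, 0.4)),
                ad_n_max=int(rng.integers(0, 3)),
                dp_n_min=int(rng.integers(0, 12)),
            )
            tighter = base.with_(
                ad_t_min=base.ad_t_min + 1,
                vaf_t_min=min(1.0, base.vaf_t_min + 0.05),
                ad_n_max=max(0, base.ad_n_max - 1),
            )
            kb, _ = apply_method(table, 1, base)
            kt, _ = apply_method(table, 1, tighter)
            assert kept_keys(kt) <= kept_keys(kb)


class TestFilterLadder:
    def test_singleton_matches_apply_method(self, toy_table):
        rungs = filter_ladder(toy_table, [CFG])
        kept, _ = apply_method(toy_table, 1, CFG)
        assert rungs[0].n_kept == len(kept)
        assert rungs[0].kept == kept

    def test_monotone_ladder_non_increasing(self):
        rng = np.random.default_rng(19)
        table = random_table(rng, n_variants=60)
        ladder = [
            FilterConfig(ad_t_min=a, dp_t_min=d, vaf_t_min=v, ad_n_max=2 - i // 2, dp_n_min=n)
            for i, (a, d, v, n) in enumerate(
                [(0, 0, 0.0, 0), (2, 4, 0.05, 4), (4, 8, 0.1, 6), (6, 10, 0.15, 8),
                 (8, 12, 0.2, 10)]
            )
        ]
        counts = [r.n_kept for r in filter_ladder(table, ladder)]
        assert counts == sorted(counts, reverse=True)

    def test_vacuous_thresholds_keep_all_pon_gnomad_survivors(self):
        rng = np.random.default_rng(23)
        table = random_table(rng, n_variants=40)
        zero = FilterConfig(ad_t_min=0, dp_t_min=0, vaf_t_min=0.0,
                            ad_n_max=10**9, dp_n_min=0)
        rungs = filter_ladder(table, [zero])
        survivors_gnomad, _ = apply_population_af_filter(table, zero.pop_af_max)
        assert rungs[0].n_kept == len(survivors_gnomad)

    def test_empty_ladder_rejected(self, toy_table):
        with pytest.raises(ValueError):
            filter_ladder(toy_table, [])


def test_verdict_frame_columns_cover_all_labels(toy_table):
    frame = method_verdict_frame(toy_table, 3, CFG)
    assert list(frame.columns) == list(
        ("ADt", "DPt", "VAFt", "ADn", "DPn", "gnomAD", "PON", "pool")
    )
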