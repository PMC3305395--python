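import pytest

from gonadprime import (
    find_primed,
    interstromal_removal_set,
    make_gene_list,
    normalize_symbol,
    primed_overlap_report,
    restrict_by_enrichment,
    restrict_by_removal,
    start_point_stability,
    symbol_map,
)

ST = "E12.5"


def somatic_rows(levels: dict) -> dict:
    rows = {}
    for lin in ("supporting", "interstitial_stromal"):
        for sex in ("XX", "XY"):
            m = levels.get((lin, sex), 7.0)
            rows[(lin, sex, ST)] = [m - 0.05, m, m + 0.05]
    return rows


@pytest.fixture(scope="module")
def reference_study():
    from conftest import build_study

    genes = {
        # dimorphic only in the interstitium -> removed
        "int_only": somatic_rows({("interstitial_stromal", "XY"): 10.0}),
        # dimorphic in both, higher in supporting cells -> kept
        "both_supp_higher": somatic_rows(
            {
                ("supporting", "XY"): 11.0,
                ("interstitial_stromal", "XY"): 9.0,
            }
        ),
        # dimorphic in both, higher in the interstitium -> removed
        "both_int_higher": somatic_rows(
            {
                ("supporting", "XY"): 9.0,
                ("interstitial_stromal", "XY"): 11.0,
            }
        ),
        # dimorphic only in supporting cells -> kept
        "supp_only": somatic_rows({("supporting", "XY"): 10.0}),
        "flat": somatic_rows({}),
    }
    return build_study(genes)


class TestSymbolHandling:
    def test_normalisation_is_case_insensitive_mouse_style(self):
        assert normalize_symbol("SOX9") == "Sox9"
        assert normalize_symbol(" sox9 ") == "Sox9"
        assert normalize_symbol("") == ""

    def test_symbol_map_groups_clusters(self, sim_small):
        _, truth, f = sim_small
        mapping = symbol_map(f)
        dup_counts = [len(v) for v in mapping.values()]
        assert max(dup_counts) >= 2  # duplicate transcript clusters exist
        for sym, ids in list(mapping.items())[:50]:
            assert all(
                normalize_symbol(f.clusters.at[c, "gene_symbol"]) == sym for c in ids
            )


class TestRestriction:
    def test_universe_and_empty_reference(self, reference_study):
        primed = make_gene_list(reference_study, "primed", {"int_only", "supp_only"})
        universe = make_gene_list(
            reference_study, "all", set(reference_study.matrix.index)
        )
        empty = make_gene_list(reference_study, "none", set())
        assert (
            restrict_by_enrichment(reference_study, primed, universe).cluster_ids
            == primed.cluster_ids
        )
        assert not restrict_by_enrichment(reference_study, primed, empty).cluster_ids

    def test_partial_overlap_keeps_exactly_matching_symbols(self, reference_study):
        primed = make_gene_list(
            reference_study, "primed", {"int_only", "supp_only", "flat"}
        )
        ref = make_gene_list(reference_study, "ref", {"supp_only", "both_int_higher"})
        kept = restrict_by_enrichment(reference_study, primed, ref)
        assert kept.cluster_ids == {"supp_only"}


class TestInterstromalRemoval:
    def test_three_step_semantics(self, reference_study, cfg):
        removal = interstromal_removal_set(reference_study, ST, "XY", cfg)
        assert "int_only" in removal
        assert "both_int_higher" in removal
        assert "both_supp_higher" not in removal
        assert "supp_only" not in removal
        assert "flat" not in removal

    def test_removal_applied_by_symbol(self, reference_study, cfg):
        removal = interstromal_removal_set(reference_study, ST, "XY", cfg)
        primed = make_gene_list(
            reference_study, "primed", {"int_only", "supp_only"}
        )
        cleaned = restrict_by_removal(reference_study, primed, removal)
        assert cleaned.cluster_ids == {"supp_only"}

    def test_stable_under_unrelated_genes(self, cfg):
        from conftest import build_study

        genes = {
            "int_only": somatic_rows({("interstitial_stromal", "XY"): 10.0}),
            "noise1": somatic_rows({}),
            "noise2": somatic_rows({("supporting", "XX"): 10.0}),
        }
        study = build_study(genes)
        removal = interstromal_removal_set(study, ST, "XY", cfg)
        assert removal.cluster_ids == {"int_only"}


class TestOverlapReport:
    def test_identical_primed_sets(self, reference_study):
        primed = make_gene_list(reference_study, "p", {"supp_only", "flat"})
        dimorphic = make_gene_list(reference_study, "d", set())
        rep = primed_overlap_report(primed, primed, dimorphic)
        assert rep["counts"]["primed_in_both"] == rep["total"] == 2

    def test_categories_partition_and_priority(self, reference_study):
        primed_b = make_gene_list(
            reference_study,
            "b",
            {"supp_only", "int_only", "both_int_higher", "flat"},
        )
        primed_a = make_gene_list(reference_study, "a", {"supp_only"})
        dimorphic = make_gene_list(
            reference_study, "d", {"int_only", "both_int_higher"}
        )
        signature = make_gene_list(reference_study, "s", {"int_only"})
        rep = primed_overlap_report(primed_a, primed_b, dimorphic, signature)
        counts = rep["counts"]
        assert sum(counts.values()) == rep["total"] == 4
        assert counts["primed_in_both"] == 1
        assert counts["dimorphic_with_signature"] == 1
        assert counts["dimorphic_without_signature"] == 1
        assert counts["not_detected"] == 1


def test_start_point_stability_reports_fractions(sim_small, cfg):
    _, _, f = sim_small
    rep = start_point_stability(f, "germ", "E11.5", "E12.5", "E13.5", cfg)
    assert rep["n_primed"] > 0
    assert 0.0 <= rep["fraction_identical_both_starts"] <= 1.0
    if rep["fraction_concordant_shift"] is not None:
        assert 0.0 <= rep["fraction_concordant_shift"] <= 1.0


def test_mixed_population_priming_runs_without_other_lineages(cfg):
    """A single-population study (no other lineages) supports the basic
    priming method, as needed for mixed-sort time courses."""
    from conftest import build_study

    rows = {}
    for i, (xx, xy) in enumerate([((9, 7), (9, 9)), ((8, 8), (8, 8))]):
        rows[f"g{i}"] = {
            ("other", "XX", "E11.0"): [xx[0] - 0.05, xx[0], xx[0] + 0.05],
            ("other", "XX", "E12.5"): [xx[1] - 0.05, xx[1], xx[1] + 0.05],
            ("other", "XY", "E11.0"): [xy[0] - 0.05, xy[0], xy[0] + 0.05],
            ("other", "XY", "E12.5"): [xy[1] - 0.05, xy[1], xy[1] + 0.05],
        }
    study = build_study(rows)
    gl = find_primed(study, "other", "E11.0", "E12.5", "male", cfg, "all")
    assert "g0" in gl and "g1" not in gl
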