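import pytest

from gonadprime import (
    bias_report,
    classify_level,
    find_primed,
    gene_level_tags,
    marker_denominator,
    priming_analysis,
)

START, MID, END = "E11.5", "E12.5", "E13.5"
LINS = ("supporting", "interstitial_stromal", "germ", "endothelial")


def germ_course(xx, xy, background=7.0):
    """Replicate values for all germ/other groups over three stages.

    ``xx``/``xy`` are (start, mid, end) germ-cell means; every other
    lineage sits at ``background`` throughout.
    """
    rows = {}
    stages = (START, MID, END)
    for lin in LINS:
        for sex in ("XX", "XY"):
            for i, stage in enumerate(stages):
                if lin == "germ":
                    m = (xx if sex == "XX" else xy)[i]
                else:
                    m = background
                rows[(lin, sex, stage)] = [m - 0.05, m, m + 0.05]
    return rows


@pytest.fixture(scope="module")
def priming_study():
    from conftest import build_study

    genes = {
        # classic male priming: equal at start, retained in XY, repressed in XX
        "male_primed": germ_course(xx=(9, 8, 7), xy=(9, 9, 9)),
        # repressed identically in both sexes: differential repression fails
        "both_fall": germ_course(xx=(9, 8, 7), xy=(9, 8, 7)),
        # constant gene: no repression anywhere
        "constant": germ_course(xx=(9, 9, 9), xy=(9, 9, 9)),
        # intermediate male priming: progenitor between the final levels
        "male_primed_mid": germ_course(xx=(9, 8, 7), xy=(9, 10, 11)),
        # female priming (mirror)
        "female_primed": germ_course(xx=(9, 9, 9), xy=(9, 8, 7)),
    }
    return build_study(genes)


class TestFindPrimed:
    def test_primed_pattern_detected(self, priming_study, cfg):
        gl = find_primed(priming_study, "germ", START, END, "male", cfg, "all")
        assert "male_primed" in gl
        assert "male_primed_mid" in gl
        assert "female_primed" not in gl

    def test_differential_repression_required(self, priming_study, cfg):
        gl = find_primed(priming_study, "germ", START, END, "male", cfg, "all")
        assert "both_fall" not in gl

    def test_constant_gene_excluded(self, priming_study, cfg):
        gl = find_primed(priming_study, "germ", START, END, "male", cfg, "all")
        assert "constant" not in gl

    def test_sexes_never_share_a_primed_cluster(self, priming_study, cfg):
        male = find_primed(priming_study, "germ", START, END, "male", cfg, "all")
        female = find_primed(priming_study, "germ", START, END, "female", cfg, "all")
        assert not (male.cluster_ids & female.cluster_ids)
        assert "female_primed" in female

    def test_relaxed_start_accepts_early_divergence(self, cfg):
        from conftest import build_study

        study = build_study(
            {"early": germ_course(xx=(8, 7.5, 7), xy=(9, 9, 9))}
        )
        strict = find_primed(study, "germ", START, END, "male", cfg, "all")
        relaxed = find_primed(
            study, "germ", START, END, "male", cfg, "all", relaxed_start=True
        )
        assert "early" not in strict
        assert "early" in relaxed


class TestLevels:
    def test_similar_and_intermediate_tags(self, priming_study, cfg):
        gl = find_primed(priming_study, "germ", START, END, "male", cfg, "all")
        tags = classify_level(
            priming_study, gl, "germ", "male", START, END, cfg, "enriched"
        )
        assert tags["male_primed"] == "similar"
        assert tags["male_primed_mid"] == "intermediate"

    def test_conflicting_clusters_count_as_other(self, cfg):
        from conftest import build_study

        rows = {
            "tc_sim": germ_course(xx=(9, 8, 7), xy=(9, 9, 9)),
            "tc_mid": germ_course(xx=(9, 8, 7), xy=(9, 10, 11)),
            "tc_unc": germ_course(xx=(9, 8, 7), xy=(9, 9, 9)),
        }
        study = build_study(
            rows, symbols={"tc_sim": "Gene1", "tc_mid": "Gene1", "tc_unc": "Gene2"}
        )
        cluster_tags = {"tc_sim": "similar", "tc_mid": "intermediate", "tc_unc": "other"}
        tags = gene_level_tags(study, cluster_tags)
        assert tags["Gene1"] == "other"
        cluster_tags2 = {"tc_sim": "similar", "tc_unc": "other"}
        study2 = build_study(
            rows, symbols={"tc_sim": "Gene1", "tc_mid": "Gene3", "tc_unc": "Gene1"}
        )
        assert gene_level_tags(study2, cluster_tags2)["Gene1"] == "similar"


class TestAgainstPlantedTruth:
    @pytest.mark.parametrize("method", ["all", "enriched", "depleted"])
    def test_recovery_and_specificity(self, sim_small, cfg, method):
        _, truth, f = sim_small
        result = priming_analysis(f, "germ", START, END, cfg, method)
        for sex_for in ("male", "female"):
            gl = result.primed(sex_for)
            expected = truth.expected_members(gl.recipe, cfg)
            assert expected
            tp = len(gl.symbols & expected)
            fp = len(gl.symbols - expected)
            assert tp >= 0.75 * len(expected)
            assert fp <= 0.02 * (len(truth.symbols) - len(expected))

    def test_enriched_method_is_a_restriction(self, sim_small, cfg):
        _, _, f = sim_small
        allp = find_primed(f, "germ", START, END, "male", cfg, "all")
        enr = find_primed(f, "germ", START, END, "male", cfg, "enriched")
        assert enr.cluster_ids <= allp.cluster_ids

    def test_primed_within_markers_and_tags_sum(self, sim_small, cfg):
        _, _, f = sim_small
        result = priming_analysis(f, "germ", START, END, cfg, "all")
        for sex_for in ("male", "female"):
            assert result.primed(sex_for).cluster_ids <= result.markers(sex_for).cluster_ids
            counts = result.tag_counts(sex_for)
            assert sum(counts.values()) == result.primed(sex_for).gene_level_count

    def test_label_swap_swaps_sexes(self, sim_small, cfg):
        _, _, f = sim_small
        swapped = f.with_sexes_swapped()
        male = find_primed(f, "germ", START, END, "male", cfg, "all")
        female_sw = find_primed(swapped, "germ", START, END, "female", cfg, "all")
        assert male.cluster_ids == female_sw.cluster_ids

    def test_marker_denominators_nest(self, sim_small, cfg):
        _, _, f = sim_small
        allm = marker_denominator(f, "germ", END, "male", cfg, "all")
        enrm = marker_denominator(f, "germ", END, "male", cfg, "enriched")
        assert enrm.cluster_ids <= allm.cluster_ids

    def test_bias_report_counts_and_probabilities(self, sim_small, cfg):
        _, _, f = sim_small
        result = priming_analysis(f, "germ", START, END, cfg, "all")
        report = bias_report(result, cfg)
        assert report.n_male_primed == result.male_primed.gene_level_count
        assert report.denominators[0] >= report.n_male_primed
        assert 0.0 <= report.p_independence <= 1.0
        for p in (report.p_female_model, report.p_male_model, report.p_balanced):
            assert 0.0 <= p <= 1.0
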