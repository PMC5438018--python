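"""Variant, gene-burden and window tests; thresholds; the suite wrapper."""

import numpy as np
import pandas as pd
import pytest

from hemiassoc import (
    bonferroni_threshold,
    build_carrier_matrix,
    gene_burden_test,
    magnitude_threshold,
    run_association_suite,
    variant_test,
    window_test,
)
from hemiassoc.annotate import GeneModel, annotate_variants
from hemiassoc.association import fisher_exact, results_to_frame, suite_minima, TwoByTwo
from tests.conftest import make_call


def five_sample_manifest():
    return pd.DataFrame(
        {
            "sample_id": ["a", "b", "c", "d", "e"],
            "group": ["case", "case", "case", "control", "control"],
            "age": [22.0, 30.0, 18.0, 25.0, 19.0],
        }
    )


def matrix_from(calls, manifest=None):
    return build_carrier_matrix(calls, manifest if manifest is not None else five_sample_manifest())


class TestThresholds:
    @pytest.mark.parametrize(
        "m, exact, magnitude",
        [
            (4_176, 0.05 / 4_176, 1e-5),  # variant / window family scale
            (73, 0.05 / 73, 1e-3),        # gene family scale
        ],
    )
    def test_exact_and_order_of_magnitude(self, m, exact, magnitude):
        assert bonferroni_threshold(0.05, m) == pytest.approx(exact, rel=1e-12)
        assert magnitude_threshold(0.05, m) == magnitude

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestVariantTest:
    def test_counts_and_threshold(self):
        calls = [
            make_call(pos=18_400_500, carriers=("a", "b")),
            make_call(pos=18_400_600, carriers=("a", "d")),
        ]
        res = variant_test(matrix_from(calls))
        assert len(res) == 2
        r = {x.unit_id: x for x in res}
        t = r["chr22:18400500:G>A"].table
        assert (t.a, t.b, t.c, t.d) == (2, 1, 0, 2)
        assert res[0].threshold == pytest.approx(0.05 / 2)
        # p/OR match the scalar Fisher API
        p, orr = fisher_exact(t)
        assert r["chr22:18400500:G>A"].p_value == pytest.approx(p)
        assert r["chr22:18400500:G>A"].odds_ratio == pytest.approx(orr)

    def test_single_group_matrix_rejected(self):
        mf = pd.DataFrame({"sample_id": ["a", "b"], "group": ["case", "case"], "age": [20, 20]})
        m = matrix_from([make_call(carriers=("a", "b"))], mf)
        with pytest.raises(ValueError, match="both cases and controls"):
            variant_test(m)


class TestGeneBurden:
    def gene(self):
        # CDS covers 18_400_450..18_400_650 so both variants below are coding
        return GeneModel(
            "G1", "+",
            exons=((18_400_400, 18_400_700),),
            cds=((18_400_450, 18_400_650),),
        )

    def test_burden_is_union_of_carrier_sets(self):
        """Samples carrying several qualifying variants count once (union, not sum)."""
        calls = [
            make_call(pos=18_400_500, carriers=("a", "b")),
            make_call(pos=18_400_600, carriers=("a", "d")),
        ]
        m = matrix_from(calls)
        ann = annotate_variants(calls, [self.gene()])
        res = gene_burden_test(m, ann)
        (g,) = [r for r in res if r.unit_id == "G1"]
        # union {a,b} | {a,d} = {a,b,d}: 2 case carriers, 1 control carrier
        assert (g.table.a, g.table.c) == (2, 1)

    def test_single_variant_gene_equals_variant_p(self):
        calls = [make_call(pos=18_400_500, carriers=("a", "b", "d"))]
        m = matrix_from(calls)
        ann = annotate_variants(calls, [self.gene()])
        gene_p = gene_burden_test(m, ann)[0].p_value
        var_p = variant_test(m)[0].p_value
        assert gene_p == pytest.approx(var_p, abs=1e-15)

    def test_gene_without_qualifying_variants_untestable(self):
        # variant in the intron-free gene's exon but outside CDS -> "other"
        g = GeneModel("G2", "+", exons=((18_400_400, 18_400_700),), cds=((18_400_650, 18_400_660),))
        calls = [make_call(pos=18_400_500, carriers=("a", "b"))]
        m = matrix_from(calls)
        res = gene_burden_test(m, annotate_variants(calls, [g]))
        assert res[0].testable is False
        assert res[0].p_value == 1.0
        assert res[0].significant is False


class TestWindowTest:
    def test_isolated_variant_reduces_to_variant_test(self):
        calls = [make_call(pos=18_400_500, carriers=("a", "b", "d"))]
        m = matrix_from(calls)
        for w, res in window_test(m, window_sizes=(1_000, 10_000)).items():
            assert res[0].p_value == pytest.approx(variant_test(m)[0].p_value)

    def test_window_span_controls_burden_merging(self):
        """Variants 400 bp apart merge at w=1000 (+-500) and separate at w=500 (+-250)."""
        calls = [
            make_call(pos=18_400_500, carriers=("a", "b")),
            make_call(pos=18_400_900, carriers=("c", "d")),
        ]
        m = matrix_from(calls)
        wide = window_test(m, window_sizes=(1_000,))[1_000]
        # each window spans both variants: burden carriers = union = 4 samples
        for r in wide:
            assert (r.table.a, r.table.c) == (3, 1)
        narrow = window_test(m, window_sizes=(500,))[500]
        tables = {(r.table.a, r.table.c) for r in narrow}
        assert tables == {(2, 0), (1, 1)}

    def test_window_count_equals_variant_count(self):
        calls = [make_call(pos=18_400_000 + 100 * i, carriers=("a", "b")) for i in range(7)]
        m = matrix_from(calls)
        out = window_test(m, window_sizes=(1_000, 5_000))
        for res in out.values():
            assert len(res) == 7
            assert res[0].threshold == pytest.approx(0.05 / 7)

    def test_empty_matrix_rejected(self):
        m = matrix_from([make_call(carriers=("a", "d"))])
        m.variants = []
        m.indicator = np.zeros((5, 0), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            window_test(m)


class TestSuite:
    def suite_inputs(self):
        calls = [
            make_call(pos=18_400_500, carriers=("a", "b")),
            make_call(pos=18_400_600, carriers=("a", "d")),
            make_call(pos=18_402_000, carriers=("b", "e")),
        ]
        m = matrix_from(calls)
        gene = GeneModel(
            "G1", "+", exons=((18_400_400, 18_400_700),), cds=((18_400_450, 18_400_650),)
        )
        return m, annotate_variants(calls, [gene])

    def test_age_subset_drops_only_young_controls(self):
        calls = [
            make_call(pos=18_400_500, carriers=("a", "b")),
            make_call(pos=18_400_600, carriers=("a", "d")),
        ]
        mf = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d", "e", "f"],
                "group": ["case", "case", "case", "control", "control", "control"],
                "age": [22.0, 30.0, 18.0, 25.0, 19.0, 21.0],
            }
        )
        m = build_carrier_matrix(calls, mf)
        gene = GeneModel(
            "G1", "+", exons=((18_400_400, 18_400_700),), cds=((18_400_450, 18_400_650),)
        )
        ann = annotate_variants(calls, [gene])
        bundle = run_association_suite(m, ann, min_control_age=20)
        # controls e (19) dropped, d (25) and f (21) kept; case c (18) untouched
        assert bundle.summary["n_case"] == 3
        assert bundle.summary["n_control"] == 2
        with pytest.raises(ValueError, match="fewer than 2 controls"):
            run_association_suite(m, ann, min_control_age=99)

    def test_bundle_deterministic(self):
        m, ann = self.suite_inputs()
        b1 = run_association_suite(m, ann)
        b2 = run_association_suite(m, ann)
        assert b1.summary == b2.summary
        for fam in b1.families:
            pd.testing.assert_frame_equal(
                results_to_frame(b1.families[fam]), results_to_frame(b2.families[fam])
            )

    def test_track_has_all_families(self):
        m, ann = self.suite_inputs()
        bundle = run_association_suite(
            m, ann, window_sizes=(1_000,),
            gene_spans={"G1": ("chr22", 18_400_400, 18_400_700)},
        )
        assert set(bundle.track["family"]) == {"variant", "gene", "window_1000"}
        assert (bundle.track["minus_log10_p"] >= 0).all()

    def test_fast_minima_match_full_suite(self):
        m, ann = self.suite_inputs()
        mins = suite_minima(m, ann, window_sizes=(1_000, 5_000))
        bundle = run_association_suite(m, ann, window_sizes=(1_000, 5_000))
        for fam, info in mins.items():
            full = bundle.summary["families"][fam]
            assert info["min_p"] == pytest.approx(full["min_p"], abs=1e-15)
            assert info["n_significant"] == full["n_significant"]
            assert info["threshold"] == pytest.approx(full["threshold"])

    def test_results_frame_has_bh_column(self):
        m, ann = self.suite_inputs()
        df = results_to_frame(variant_test(m))
        assert {"p_value", "p_bh", "significant"} <= set(df.columns)
        assert (df["p_bh"] >= df["p_value"] - 1e-12).all()
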