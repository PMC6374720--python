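"""Diagnostic panels, hybrid metrics, classification, sex linkage,
maternal inference, and PCoA."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh
from sklearn.base import clone

from hybridiag import Config, GenotypeMatrix, Sex, TaxonPartition
from hybridiag.hybrid import (
    GenotypePCoA,
    HybridClassifier,
    HybridMetrics,
    build_fixed_panel,
    classify_specimen,
    detect_sex_linked_loci,
    genotypic_distance_matrix,
    hybrid_metrics,
    hybrid_report,
    infer_maternal_parent,
    pcoa_coordinates,
    shared_snp_counts,
)


def _gm(rows: dict[str, list[float]], loci: list[str]) -> GenotypeMatrix:
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    return GenotypeMatrix(frame)


@pytest.fixture
def tiny_panel_data():
    loci = ["L1", "L2", "L3", "L4"]
    gm = _gm(
        {
            "a1": [0, 0, 2, 0], "a2": [0, 0, 2, 0],
            "b1": [2, 2, 0, 1], "b2": [2, 2, 0, 0],
            "h1": [1, 1, 1, 0],
        },
        loci,
    )
    part = TaxonPartition(
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "h1": "hyb"}
    )
    return gm, part


class TestPanel:
    def test_fixed_differences_enter_with_orientation(self, tiny_panel_data):
        gm, part = tiny_panel_data
        panel = build_fixed_panel(gm, part, "A", "B")
        # L4 excluded: one parent-B specimen is heterozygous
        assert panel.loci == ["L1", "L2", "L3"]
        assert panel.a_is_alt == {"L1": False, "L2": False, "L3": True}

    def test_call_rate_requirement_spans_all_specimens(self, tiny_panel_data):
        gm, part = tiny_panel_data
        gm.calls.at["h1", "L1"] = np.nan  # hybrid missing, parents complete
        panel = build_fixed_panel(gm, part, "A", "B")
        assert "L1" not in panel.loci

    def test_empty_parent_errors(self, tiny_panel_data):
        gm, part = tiny_panel_data
        with pytest.raises(ValueError, match="empty parental"):
            build_fixed_panel(gm, part, "A", "nosuch")

    def test_single_parent_specimen_warns(self):
        gm = _gm({"a1": [0.0], "b1": [2.0]}, ["L1"])
        part = TaxonPartition({"a1": "A", "b1": "B"})
        with pytest.warns(UserWarning, match="fewer than 2"):
            build_fixed_panel(gm, part, "A", "B")

    def test_planted_fixed_differences_recovered(self, small_cross):
        panel = build_fixed_panel(
            small_cross.genotypes, small_cross.partition, "taxonA", "taxonB"
        )
        diag = set(
            small_cross.locus_truth.loc[
                small_cross.locus_truth.category != "nondiagnostic", "locus_id"
            ]
        )
        assert diag <= set(panel.loci)


class TestMetricsAndClassification:
    def test_f1_signature(self, tiny_panel_data):
        gm, part = tiny_panel_data
        panel = build_fixed_panel(gm, part, "A", "B")
        m = hybrid_metrics(gm, panel, "h1")
        assert m.index_a == 0.5
        assert m.het_frac == 1.0
        assert classify_specimen(m) == "F1"

    def test_parental_signature(self, tiny_panel_data):
        gm, part = tiny_panel_data
        panel = build_fixed_panel(gm, part, "A", "B")
        m = hybrid_metrics(gm, panel, "a1")
        assert (m.index_a, m.het_frac) == (1.0, 0.0)
        assert classify_specimen(m) == "parental_A"

    def test_mixed_genotypes_arithmetic(self):
        # dosages (2,1,1,0) with the parent-A allele = alt everywhere
        loci = [f"L{i}" for i in range(4)]
        gm = _gm(
            {"a1": [2, 2, 2, 2], "a2": [2, 2, 2, 2],
             "b1": [0, 0, 0, 0], "b2": [0, 0, 0, 0],
             "x": [2, 1, 1, 0]},
            loci,
        )
        part = TaxonPartition(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "x": "hyb"}
        )
        panel = build_fixed_panel(gm, part, "A", "B")
        m = hybrid_metrics(gm, panel, "x")
        assert m.index_a == 0.5
        assert m.het_frac == 0.5
        assert m.hom_a_frac == 0.25
        assert m.hom_b_frac == 0.25

    @pytest.mark.parametrize(
        "index_a,het,hom_a,hom_b,expected",
        [
            (1.0, 0.0, 1.0, 0.0, "parental_A"),
            (0.0, 0.0, 0.0, 1.0, "parental_B"),
            (0.5, 1.0, 0.0, 0.0, "F1"),
            (0.75, 0.5, 0.5, 0.0, "backcross_A"),
            # below the 75% rule but carrying no parent-B homozygote:
            # still the BC1 signature
            (0.65, 0.7, 0.3, 0.0, "backcross_A"),
            (0.35, 0.7, 0.0, 0.3, "backcross_B"),
            (0.5, 0.2, 0.4, 0.4, "later_generation"),
            # F2-like: intermediate index, both homozygote classes present,
            # heterozygosity above the later-generation ceiling
            (0.5, 0.5, 0.25, 0.25, "unresolved"),
        ],
    )
    def test_classification_ladder(self, index_a, het, hom_a, hom_b, expected):
        m = HybridMetrics("s", 20, index_a, het, hom_a, hom_b)
        assert classify_specimen(m) == expected

    def test_ladder_is_total(self):
        rng = np.random.default_rng(3)
        cfg = Config()
        for _ in range(500):
            het = rng.uniform(0, 1)
            hom_a = rng.uniform(0, 1 - het)
            hom_b = 1 - het - hom_a
            index_a = hom_a + het / 2
            m = HybridMetrics("s", 30, index_a, het, hom_a, hom_b)
            label = classify_specimen(m, cfg)
            assert label in (
                "parental_A", "parental_B", "F1", "backcross_A",
                "backcross_B", "later_generation", "unresolved",
            )

    def test_no_called_loci_is_unresolved_with_warning(self, tiny_panel_data):
        gm, part = tiny_panel_data
        panel = build_fixed_panel(gm, part, "A", "B")
        gm.calls.loc["h1", panel.loci] = np.nan
        with pytest.warns(UserWarning, match="no called panel loci"):
            m = hybrid_metrics(gm, panel, "h1")
        assert classify_specimen(m) == "unresolved"

    def test_estimator_api_round_trip(self, small_cross):
        truth = small_cross.specimen_truth
        parents = truth[truth.true_class.isin(["parental_A", "parental_B"])]
        X = small_cross.genotypes.subset(
            specimens=list(parents.specimen_id)
        ).values
        est = HybridClassifier(parent_a="parental_A", parent_b="parental_B")
        assert clone(est).get_params() == est.get_params()
        est.fit(X, parents.true_class.to_numpy())
        preds = est.predict(X)
        assert preds.shape == (len(parents),)
        assert set(preds) <= {"parental_A", "parental_B"}


class TestSexLinkage:
    @staticmethod
    def _setup(male_genotypes, female_genotype, maternal="A"):
        males = [f"m{i}" for i in range(len(male_genotypes))]
        rows = {
            "a1": [0.0], "a2": [0.0], "b1": [2.0], "b2": [2.0],
            **{m: [g] for m, g in zip(males, male_genotypes)},
            "f1": [female_genotype],
        }
        gm = _gm(rows, ["X1"])
        part = TaxonPartition(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
             **{m: "hyb" for m in males}, "f1": "hyb"}
        )
        panel = build_fixed_panel(gm, part, "A", "B")
        sexes = {m: Sex.MALE for m in males} | {"f1": Sex.FEMALE}
        return gm, panel, sexes, males + ["f1"]

    def test_x_linked_pattern_flagged(self):
        gm, panel, sexes, hybrids = self._setup([0.0] * 13, 1.0)
        report = detect_sex_linked_loci(gm, panel, sexes, hybrids, "A")
        assert report.table.at["X1", "status"] == "sex_linked"

    def test_one_heterozygous_male_breaks_the_call(self):
        gm, panel, sexes, hybrids = self._setup([0.0] * 12 + [1.0], 1.0)
        report = detect_sex_linked_loci(gm, panel, sexes, hybrids, "A")
        assert report.table.at["X1", "status"] == "nondiagnostic"

    def test_all_heterozygous_is_autosomal_diagnostic(self):
        gm, panel, sexes, hybrids = self._setup([1.0] * 13, 1.0)
        report = detect_sex_linked_loci(gm, panel, sexes, hybrids, "A")
        assert report.table.at["X1", "status"] == "autosomal_diagnostic"

    def test_requires_sexed_hybrids(self):
        gm, panel, sexes, hybrids = self._setup([0.0] * 3, 1.0)
        with pytest.raises(ValueError, match="no sexed"):
            detect_sex_linked_loci(
                gm, panel, {h: Sex.UNKNOWN for h in hybrids}, hybrids, "A"
            )

    def test_maternal_parent_must_be_in_panel(self):
        gm, panel, sexes, hybrids = self._setup([0.0] * 3, 1.0)
        with pytest.raises(ValueError, match="not a panel parent"):
            detect_sex_linked_loci(gm, panel, sexes, hybrids, "C")


class TestMaternalInference:
    @staticmethod
    def _panel():
        from hybridiag.hybrid import DiagnosticPanel

        return DiagnosticPanel(["L1"], {"L1": True}, "A", "B", 1.0)

    def test_unanimous_assignment(self):
        result = infer_maternal_parent(
            {"h1": "A", "h2": "A"}, self._panel(), ["h1", "h2"]
        )
        assert result.maternal_parent == "A"
        assert "female A" in result.direction

    def test_split_is_bidirectional(self):
        result = infer_maternal_parent(
            {"h1": "A", "h2": "B"}, self._panel(), ["h1", "h2"]
        )
        assert result.maternal_parent == "bidirectional"

    def test_unassigned_hybrids_excluded(self):
        result = infer_maternal_parent(
            {"h1": "A"}, self._panel(), ["h1", "h2"]
        )
        assert result.excluded == ["h2"]
        assert result.maternal_parent == "A"


class TestSharedSnps:
    def test_monomorphic_reference_shares_nothing(self):
        gm = _gm({"f1": [0, 0], "o1": [0, 0]}, ["L1", "L2"])
        part = TaxonPartition({"f1": "F", "o1": "O"})
        assert shared_snp_counts(gm, part, "F", ["O"]) == {"O": 0}

    def test_planted_overlap_counted(self):
        # focal polymorphic at L1+L2, other at L2+L3 -> one shared SNP
        gm = _gm(
            {"f1": [1, 1, 0], "f2": [1, 0, 0],
             "o1": [0, 1, 2], "o2": [0, 0, 2]},
            ["L1", "L2", "L3"],
        )
        part = TaxonPartition({"f1": "F", "f2": "F", "o1": "O", "o2": "O"})
        assert shared_snp_counts(gm, part, "F", ["O"]) == {"O": 1}

    def test_unknown_taxon_errors(self):
        gm = _gm({"f1": [0.0]}, ["L1"])
        part = TaxonPartition({"f1": "F"})
        with pytest.raises(ValueError, match="unknown or empty"):
            shared_snp_counts(gm, part, "F", ["Q"])


class TestPCoA:
    def test_identical_specimens_coincide(self):
        gm = _gm(
            {"s1": [0, 1, 2], "s2": [0, 1, 2], "s3": [2, 1, 0]},
            ["L1", "L2", "L3"],
        )
        coords, _ = pcoa_coordinates(gm)
        np.testing.assert_allclose(
            coords.loc["s1"], coords.loc["s2"], atol=1e-9
        )

    def test_collinear_specimens_have_flat_second_axis(self):
        gm = _gm(
            {"s1": [0] * 8, "s2": [1] * 8, "s3": [2] * 8},
            [f"L{i}" for i in range(8)],
        )
        coords, eig = pcoa_coordinates(gm)
        assert eig[1] == pytest.approx(0.0, abs=1e-9)

    def test_requires_three_specimens(self):
        gm = _gm({"s1": [0.0], "s2": [2.0]}, ["L1"])
        with pytest.raises(ValueError, match="at least 3"):
            pcoa_coordinates(gm)

    def test_f1_centroid_near_parental_midpoint(self, small_cross):
        truth = small_cross.specimen_truth
        keep = truth[truth.true_class.isin(["parental_A", "parental_B", "F1"])]
        coords, _ = pcoa_coordinates(
            small_cross.genotypes, list(keep.specimen_id)
        )
        centroid = {
            cls: coords.loc[
                keep[keep.true_class == cls].specimen_id
            ].mean(axis=0)
            for cls in ("parental_A", "parental_B", "F1")
        }
        midpoint = (centroid["parental_A"] + centroid["parental_B"]) / 2
        span = abs(
            centroid["parental_A"]["axis1"] - centroid["parental_B"]["axis1"]
        )
        assert abs(centroid["F1"]["axis1"] - midpoint["axis1"]) < 0.15 * span

    def test_matches_independent_eigendecomposition(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(12, 30)).astype(float)
        est = GenotypePCoA(n_axes=3).fit(X)
        # independent route: double-centering + scipy.linalg.eigh
        d = genotypic_distance_matrix(X)
        d2 = d**2
        n = d2.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        w, v = eigh(b)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        expected = v[:, :3] * np.sqrt(np.maximum(w[:3], 0))
        for k in range(3):
            got = est.coordinates_[:, k]
            want = expected[:, k]
            if np.sign(got[np.argmax(np.abs(got))]) != np.sign(
                want[np.argmax(np.abs(want))]
            ):
                want = -want
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_sklearn_params(self):
        est = GenotypePCoA(n_axes=4)
        assert clone(est).n_axes == 4


def test_hybrid_report_classifies_all_cohorts(small_cross):
    """End-to-end: panel from parents, autosomal subset, classes match
    planted truth for parental, F1 and BC1 cohorts."""
    gm, part = small_cross.genotypes, small_cross.partition
    truth = small_cross.specimen_truth.set_index("specimen_id")
    panel = build_fixed_panel(gm, part, "taxonA", "taxonB")
    autosomal = set(
        small_cross.locus_truth.loc[
            small_cross.locus_truth.category == "autosomal_diagnostic",
            "locus_id",
        ]
    )
    report = hybrid_report(gm, panel.subset(autosomal))
    merged = report.set_index("specimen_id").join(truth)
    expected = {
        "parental_A": "parental_A", "parental_B": "parental_B",
        "F1": "F1", "BC1A": "backcross_A", "BC1B": "backcross_B",
    }
    for true_class, predicted in expected.items():
        sub = merged[merged.true_class == true_class]
        assert (sub.hybrid_class == predicted).all(), true_class
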