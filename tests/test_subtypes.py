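import numpy as np
import pandas as pd
import pytest

from lncfocal import (
    classify_subtype,
    select_signature,
    split_cohort,
    subtype_t_statistics,
    zscore,
)
from lncfocal.subtypes import SignatureGene, SubtypeError

from oracles import welch_t


class TestSplitCohort:
    def test_disjoint_halves_of_400(self):
        samples = [f"s{i}" for i in range(400)]
        disc, val = split_cohort(samples, n_per_set=200, seed=1)
        assert len(disc) == len(val) == 200
        assert not set(disc) & set(val)
        assert sorted(disc + val) == sorted(samples)

    def test_deterministic_under_seed(self):
        samples = [f"s{i}" for i in range(400)]
        assert split_cohort(samples, seed=9) == split_cohort(samples, seed=9)
        assert split_cohort(samples, seed=9) != split_cohort(samples, seed=10)

    def test_odd_sample_lands_in_validation(self):
        disc, val = split_cohort([f"s{i}" for i in range(401)], n_per_set=200, seed=0)
        assert len(disc) == 200 and len(val) == 201

    def test_too_few_samples_rejected(self):
        with pytest.raises(SubtypeError):
            split_cohort(["a", "b"], n_per_set=2)


class TestZscore:
    def test_arithmetic_on_three_values(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"], columns=["a", "b", "c"])
        z = zscore(expr)
        # population sd of {1,2,3} is sqrt(2/3)
        expected = (np.array([1, 2, 3]) - 2) / np.sqrt(2 / 3)
        assert np.allclose(z.loc["g0"], expected)

    def test_constant_gene_flagged(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g0"], columns=["a", "b", "c"])
        assert zscore(expr).loc["g0"].isna().all()

    def test_row_means_vanish(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(20, 30)))
        z = zscore(expr)
        assert np.abs(z.mean(axis=1)).max() < 1e-9
        assert np.allclose(z.std(axis=1, ddof=0), 1.0)


def labeled_expr(group_values, n_genes=1):
    """Expression frame + labels: dict subtype -> per-sample values."""
    cols, labels, data = [], {}, []
    for subtype, values in group_values.items():
        for i, v in enumerate(values):
            name = f"{subtype}_{i}"
            cols.append(name)
            labels[name] = subtype
    for g in range(n_genes):
        row = []
        for subtype, values in group_values.items():
            row.extend(values)
        data.append(row)
    expr = pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)], columns=cols,
                        dtype=float)
    return expr, pd.Series(labels)


class TestTStatistics:
    def test_strongly_shifted_gene_exceeds_threshold(self):
        rng = np.random.default_rng(0)
        hi = rng.normal(5, 1, 20)   # 5 sd above the rest
        lo = rng.normal(0, 1, 60)
        expr, labels = labeled_expr({"A": hi, "B": lo[:20], "C": lo[20:40], "D": lo[40:]})
        t = subtype_t_statistics(expr, labels)
        assert t.loc["g0", "A"] > 4

    def test_mostly_zero_gene_excluded(self):
        expr, labels = labeled_expr({"A": [1.0, 2.0, 1.5], "B": [0.5, 1.0, 0.7]})
        counts = pd.DataFrame([[0, 0, 0, 0, 5, 3]], index=["g0"], columns=expr.columns)
        t = subtype_t_statistics(expr, labels, counts=counts)
        assert "g0" not in t.index

    def test_matches_welch_formula_on_six_samples(self):
        x, y = [1.0, 2.5, 2.0], [4.0, 5.5, 6.0]
        expr, labels = labeled_expr({"A": x, "B": y})
        t = subtype_t_statistics(expr, labels)
        assert t.loc["g0", "A"] == pytest.approx(welch_t(x, y), abs=1e-12)
        assert t.loc["g0", "B"] == pytest.approx(welch_t(y, x), abs=1e-12)

    def test_pooled_variance_option(self):
        from scipy.stats import ttest_ind

        x, y = [1.0, 2.5, 2.0, 1.7], [4.0, 5.5, 6.0]
        expr, labels = labeled_expr({"A": x, "B": y})
        t = subtype_t_statistics(expr, labels, equal_var=True)
        assert t.loc["g0", "A"] == pytest.approx(
            ttest_ind(x, y, equal_var=True).statistic, abs=1e-12
        )

    def test_tiny_subtype_rejected(self):
        expr, labels = labeled_expr({"A": [1.0], "B": [2.0, 3.0, 4.0]})
        with pytest.raises(SubtypeError, match="A"):
            subtype_t_statistics(expr, labels)


class TestSelectSignature:
    def frame(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=["A", "B", "C", "D"])

    def test_single_subtype_hit_is_kept(self):
        sigs = select_signature(self.frame([[1.0, 4.2, -1.0, 0.0]]))
        assert len(sigs) == 1
        assert sigs[0].subtype == "B" and sigs[0].direction == "induced"

    def test_negative_t_gives_repressed(self):
        sigs = select_signature(self.frame([[0.0, -4.5, 1.0, 0.0]]))
        assert sigs[0].direction == "repressed"

    def test_ambiguous_gene_dropped(self):
        assert select_signature(self.frame([[4.5, -4.2, 0.0, 0.0]])) == []

    def test_threshold_is_strict(self):
        assert select_signature(self.frame([[4.0, 0.0, 0.0, 0.0]])) == []


class TestClassifier:
    def make_z(self):
        # 6 samples; gA induced in subtype A samples, gB induced in B samples
        z = pd.DataFrame(
            {
                "a1": [2.0, -1.0], "a2": [1.8, -0.8],
                "b1": [-1.0, 2.2], "b2": [-0.9, 1.9],
                "x1": [0.1, -0.1], "x2": [-0.2, 0.0],
            },
            index=["gA", "gB"],
        )
        sigs = [
            SignatureGene("gA", "A", "induced", 8.0),
            SignatureGene("gB", "B", "induced", 7.0),
        ]
        return z, sigs

    def test_constructed_samples_predicted_correctly(self):
        z, sigs = self.make_z()
        res = classify_subtype(z, sigs, ["A", "B"])
        assert res.predictions["a1"] == "A"
        assert res.predictions["b2"] == "B"

    def test_exact_tie_takes_first_subtype_and_flags(self):
        z = pd.DataFrame({"s1": [1.0, 1.0]}, index=["gA", "gB"])
        sigs = [
            SignatureGene("gA", "A", "induced", 5.0),
            SignatureGene("gB", "B", "induced", 5.0),
        ]
        res = classify_subtype(z, sigs, ["B", "A"])
        assert res.predictions["s1"] == "B"
        assert res.ties == ["s1"]

    def test_subtype_without_signatures_rejected(self):
        z, sigs = self.make_z()
        with pytest.raises(SubtypeError, match="C"):
            classify_subtype(z, sigs, ["A", "B", "C"])

    def test_accuracy_against_labels(self):
        z, sigs = self.make_z()
        labels = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "A"})
        res = classify_subtype(z, sigs, ["A", "B"], labels=labels)
        assert res.accuracy == pytest.approx(3 / 4)

    def test_relabeling_permutes_predictions(self):
        z, sigs = self.make_z()
        res = classify_subtype(z, sigs, ["A", "B"])
        swapped = [
            SignatureGene(s.gene_id, {"A": "B", "B": "A"}[s.subtype], s.direction, s.t_statistic)
            for s in sigs
        ]
        res2 = classify_subtype(z, swapped, ["A", "B"])
        mapping = {"A": "B", "B": "A"}
        assert (res2.predictions == res.predictions.map(mapping)).all()


class TestEndToEndOnSyntheticCohort:
    def test_permuted_labels_give_chance_accuracy(self, cohort400):
        """With labels shuffled, accuracy falls to roughly the largest
        subtype proportion (chance level)."""
        cohort = cohort400
        ann = cohort.annotation
        lnc = [g.gene_id for g in ann.lncrna_genes]
        rng = np.random.default_rng(123)
        perm = pd.Series(
            rng.permutation(cohort.labels.to_numpy()), index=cohort.labels.index
        )
        disc, val = split_cohort(list(perm.index), n_per_set=200, seed=3)
        # classify with the true signatures and score against permuted labels
        from lncfocal import select_signature

        t_true = subtype_t_statistics(
            cohort.counts.log2_rpkm.loc[lnc], cohort.labels.loc[disc],
            counts=cohort.counts.counts.loc[lnc],
        )
        sigs = select_signature(t_true)
        z = zscore(cohort.counts.log2_rpkm.loc[lnc], val)
        res = classify_subtype(
            z, sigs, list(cohort.config.subtype_names), labels=perm.loc[val]
        )
        chance = max(
            (perm == s).mean() for s in cohort.config.subtype_names
        )
        assert abs(res.accuracy - chance) < 0.12

    def test_discovery_validation_disjoint_and_signatures_from_discovery_only(
        self, cohort400
    ):
        disc, val = split_cohort(list(cohort400.labels.index), n_per_set=200, seed=3)
        assert not set(disc) & set(val)
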