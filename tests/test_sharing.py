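import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from microdna import (
    BinomialNullSpec,
    PresenceMatrix,
    binomial_sharing_probability,
    build_presence_matrix,
    expected_region_frequencies,
    observed_vs_expected_chisq,
    region_probabilities,
    stage_shared_set,
    summarize_sharing,
    venn_partition,
)
from microdna.metrics import SampleProfile

from conftest import make_call, plasma_meta


def brute_force_tail(n, p, k):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def profile_with_genes(pid, stage, genes):
    calls = [make_call(start=i * 1000, end=i * 1000 + 200, call_id=f"{pid}c{i}")
             for i in range(len(genes))]
    return SampleProfile(
        sample_meta=plasma_meta(pid, stage),
        calls=calls,
        gene_of_call={c.call_id: g for c, g in zip(calls, genes)},
    )


class TestPresenceMatrix:
    def test_detection_indicator(self):
        profiles = [
            profile_with_genes("P1", "diagnosis", ["A", "B"]),
            profile_with_genes("P2", "diagnosis", ["B"]),
        ]
        m = build_presence_matrix(profiles)
        df = m.to_frame()
        assert list(df.index) == ["A", "B"]
        assert df.loc["A"].tolist() == [True, False]
        assert df.loc["B"].tolist() == [True, True]

    def test_intergenic_calls_excluded(self):
        p = profile_with_genes("P1", "diagnosis", ["A"])
        q = profile_with_genes("P2", "diagnosis", [None, None])
        m = build_presence_matrix([p, q])
        assert m.genes == ["A"]
        assert m.detected[:, 1].sum() == 0  # all-zero column preserved

    def test_gene_universe_keeps_empty_rows(self):
        p = profile_with_genes("P1", "diagnosis", ["A"])
        m = build_presence_matrix([p], gene_universe=["A", "B"])
        assert m.genes == ["A", "B"]
        assert m.drop_empty_genes().genes == ["A"]


class TestStageSharedSet:
    def _matrix(self, detections):
        """detections: {gene: [(patient, stage)]}, one plasma sample per pair."""
        pairs = sorted({ps for v in detections.values() for ps in v})
        samples = [plasma_meta(p, s) for p, s in pairs]
        genes = sorted(detections)
        det = np.zeros((len(genes), len(samples)), dtype=bool)
        for i, g in enumerate(genes):
            for p, s in detections[g]:
                det[i, pairs.index((p, s))] = True
        return PresenceMatrix(genes=genes, samples=samples, detected=det)

    def test_threshold_boundary(self):
        m = self._matrix({"g": [(f"P{i}", "diagnosis") for i in range(2)]
                          + [(f"Q{i}", "diagnosis") for i in range(23)]})
        assert stage_shared_set(m, "diagnosis", "plasma", k=2) == {"g"}

    def test_patient_distinct_counting(self):
        # same patient observed in two samples does not count twice
        from microdna import SampleMeta
        samples = [
            SampleMeta("s1", "P1", "plasma", "diagnosis", 10**6),
            SampleMeta("s2", "P1", "plasma", "diagnosis", 10**6),
            SampleMeta("s3", "P2", "plasma", "diagnosis", 10**6),
        ]
        det = np.array([[True, True, False]])
        m = PresenceMatrix(genes=["g"], samples=samples, detected=det)
        assert stage_shared_set(m, "diagnosis", "plasma", k=2) == set()

    def test_too_few_patients_warns_empty(self):
        m = self._matrix({"g": [("P1", "relapse")]})
        assert stage_shared_set(m, "relapse", "plasma", k=2) == set()


class TestVennPartition:
    def test_small_example(self):
        assert venn_partition({1, 2}, {2, 3}, set()) == {
            "A": 1, "B": 1, "C": 0, "AB": 1, "AC": 0, "BC": 0, "ABC": 0
        }

    def test_identical_singletons(self):
        out = venn_partition({"x"}, {"x"}, {"x"})
        assert out["ABC"] == 1 and sum(out.values()) == 1

    @given(seed=st.integers(0, 100))
    def test_counts_equal_membership_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(500)]
        sets = [set(np.asarray(universe)[rng.random(500) < 0.3]) for _ in range(3)]
        out = venn_partition(*sets)
        brute = {"A": 0, "B": 0, "C": 0, "AB": 0, "AC": 0, "BC": 0, "ABC": 0}
        for g in universe:
            key = "".join(l for l, s in zip("ABC", sets) if g in s)
            if key:
                brute[key] += 1
        assert out == brute
        # permutation invariance under gene relabeling: counts depend only on
        # membership pattern, re-check with shuffled labels
        perm = dict(zip(universe, rng.permutation(universe)))
        relabeled = [{perm[g] for g in s} for s in sets]
        assert venn_partition(*relabeled) == out


class TestBinomialNull:
    def test_single_individual_cannot_share(self):
        assert binomial_sharing_probability(1, 0.05, 2) == 0.0

    @pytest.mark.parametrize(
        "n,expected", [(25, 0.35762), (9, 0.07121), (18, 0.22648)]
    )
    def test_default_group_probabilities(self, n, expected):
        # oracle: direct pmf summation over k..n
        assert brute_force_tail(n, 0.05, 2) == pytest.approx(expected, abs=5e-6)
        assert binomial_sharing_probability(n, 0.05, 2) == pytest.approx(expected, abs=5e-6)

    def test_monotone_in_n_and_p(self):
        for n in range(1, 30):
            assert binomial_sharing_probability(n + 1, 0.05, 2) >= \
                binomial_sharing_probability(n, 0.05, 2)
        for p in np.linspace(0.01, 0.9, 20):
            assert binomial_sharing_probability(25, p + 0.01, 2) >= \
                binomial_sharing_probability(25, p, 2)

    def test_eight_outcome_probabilities_sum_to_one(self):
        for p, k in [(0.05, 2), (0.2, 3), (0.5, 1)]:
            spec = BinomialNullSpec(p=p, k=k)
            assert sum(region_probabilities(spec).values()) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_half_probabilities_give_uniform_conditional(self):
        # q = 0.5 per stage: every region has probability 1/8; conditional 1/7
        spec = BinomialNullSpec(p=0.5, group_sizes=(("diagnosis", 1), ("relapse", 1),
                                                    ("remission", 1)), k=1)
        freqs = expected_region_frequencies(spec, mode="conditional")
        assert all(f == pytest.approx(1 / 7) for f in freqs.values())

    def test_vanishing_p_limit(self):
        spec = BinomialNullSpec(p=1e-9)
        absolute = expected_region_frequencies(spec, mode="absolute")
        assert all(v == pytest.approx(0.0, abs=1e-6) for v in absolute.values())


class TestObservedVsExpected:
    def test_perfect_fit(self):
        stat, df, p = observed_vs_expected_chisq([10] * 7, [10] * 7)
        assert stat == 0 and df == 6 and p == 1

    def test_concentrated_observation(self):
        stat, df, p = observed_vs_expected_chisq(
            [10, 0, 0, 0, 0, 0, 0], [10 / 7] * 7
        )
        assert stat == pytest.approx(60.0)
        assert df == 6

    def test_small_expected_regions_merged(self):
        stat, df, p = observed_vs_expected_chisq([5, 5, 1], [50, 50, 0.5])
        assert df == 1  # third region folded into a neighbour

    def test_all_zero_observed_fatal(self):
        with pytest.raises(ValueError):
            observed_vs_expected_chisq([0] * 7, [1] * 7)

    def test_null_pvalues_uniform(self):
        """On matrices generated under the binomial null the region test's
        p-values are uniform (KS check over 200 seeded replicates)."""
        rng = np.random.default_rng(1)
        spec = BinomialNullSpec(gene_universe=20_000)
        expected = expected_region_frequencies(spec, mode="absolute")
        pvals = []
        for _ in range(200):
            shared = {
                stage: rng.binomial(n, spec.p, spec.gene_universe) >= spec.k
                for stage, n in spec.group_sizes
            }
            observed = {}
            for region in expected:
                mask = np.ones(spec.gene_universe, dtype=bool)
                for stage, _ in spec.group_sizes:
                    mask &= shared[stage] if stage in region else ~shared[stage]
                observed[region] = int(mask.sum())
            pvals.append(observed_vs_expected_chisq(observed, expected)[2])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_sharing_summary_regions_partition_union():
    rng = np.random.default_rng(3)
    from microdna import SampleMeta
    samples, cols = [], []
    for stage, n in (("diagnosis", 6), ("relapse", 4), ("remission", 5)):
        for i in range(n):
            samples.append(SampleMeta(f"{stage}{i}", f"{stage[:3]}{i}", "BM", stage, 10**6))
    det = rng.random((300, len(samples))) < 0.25
    m = PresenceMatrix(genes=[f"g{i}" for i in range(300)], samples=samples, detected=det)
    summary = summarize_sharing(m, tissue="BM", k=2)
    union = set().union(*summary.shared_sets.values())
    assert sum(summary.region_counts.values()) == len(union)
    assert all(v >= 0 for v in summary.region_counts.values())
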