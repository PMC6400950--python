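"""Joint replicate scoring: likelihoods, the log-odds score, decision rule
and post-filters."""

import math

import numpy as np
import pytest
from scipy import stats

from replicall.caller import (
    CallerConfig,
    CallRecord,
    ReplicateEvidence,
    apply_postfilters,
    call_variants,
    mean_adjusted_vaf,
    score_site,
    variant_likelihood,
)
from replicall.error_model import compute_priors
from replicall.pileup_io import (
    PileupSeries,
    ReplicateSet,
    SiteObservation,
    TargetRegion,
)
from replicall.simulator import SimulationConfig, simulate_replicates

from conftest import flat_profile


def obs(b, n=1000, q=30, ref="A", alt="G", pos=100, **kw):
    counts = {alt: b} if b else {}
    quals = {alt: [q] * b} if b else {}
    return SiteObservation("chr1", pos, ref, n, counts, quals, **kw)


def oracle_score(depths, alt_counts, quals_lists, lam, f_v, f_be):
    """Independent single-expression evaluation of the joint log-odds,
    using scipy densities and the documented clamping/floor conventions."""
    floor = math.log(1e-300)
    x_be = []
    for n, b, quals in zip(depths, alt_counts, quals_lists):
        b_be = b - sum(10 ** (-q / 10) for q in quals)
        x_be.append(max(b_be, 0.0) / n)
    mu = min(max(sum(x_be) / len(x_be), 1e-6), 1 - 1e-6)
    log_num = math.log(f_v / (f_v + f_be))
    log_den = math.log(f_be / (f_v + f_be))
    for n, x in zip(depths, x_be):
        sigma = math.sqrt(mu * (1 - mu) / n)
        log_num += max(stats.norm.logpdf(x, mu, sigma), floor)
        den = stats.expon.logpdf(x, scale=1 / lam) if x > 0 else math.log(lam)
        log_den += max(den, floor)
    return log_num - log_den


class TestMeanAdjustedVaf:
    @pytest.mark.parametrize(
        "values,expected", [([0.01, 0.02], 0.015), ([0.01], 0.01), ([0, 0], 0.0)]
    )
    def test_arithmetic_mean(self, values, expected):
        assert mean_adjusted_vaf(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_adjusted_vaf([])


class TestVariantLikelihood:
    def test_density_at_the_mean_is_normal_peak(self):
        sigma = math.sqrt(0.01 * 0.99 / 10_000)
        assert variant_likelihood(0.01, 10_000, 0.01) == pytest.approx(
            1 / (sigma * math.sqrt(2 * math.pi))
        )
        assert variant_likelihood(0.01, 10_000, 0.01) == pytest.approx(400.9, rel=1e-3)

    def test_derived_peak_at_lower_depth(self):
        assert variant_likelihood(0.00999, 1000, 0.00999) == pytest.approx(
            126.85, rel=1e-3
        )

    def test_one_sigma_shape_identity(self):
        mu, n = 0.01, 1000
        sigma = math.sqrt(mu * (1 - mu) / n)
        peak = variant_likelihood(mu, n, mu)
        assert variant_likelihood(mu + sigma, n, mu) == pytest.approx(
            peak * math.exp(-0.5)
        )

    def test_degenerate_mean_rejected(self):
        with pytest.raises(ValueError):
            variant_likelihood(0.01, 1000, 0.0)
        with pytest.raises(ValueError):
            variant_likelihood(0.01, 0, 0.5)


class TestScoreSite:
    def test_concordant_duplicates_called(self, profile700):
        priors = compute_priors(3e-6, 0.01)
        record = score_site([obs(10), obs(10)], "G", profile700, priors)
        assert record.s == pytest.approx(2.458, abs=0.01)
        assert record.s > 0
        assert record.mu_hat == pytest.approx((10 - 0.01) / 1000, rel=1e-6)

    def test_discordant_duplicates_rejected(self, profile700):
        priors = compute_priors(3e-6, 0.01)
        record = score_site([obs(20), obs(0)], "G", profile700, priors)
        assert record.s == pytest.approx(-7.63, abs=0.05)
        assert record.s < 0

    def test_single_replicate_reduces_to_single_sample_ratio(self, profile700):
        priors = compute_priors(3e-6, 0.01)
        record = score_site([obs(10)], "G", profile700, priors)
        x = record.evidence[0].x_be
        sigma = math.sqrt(record.mu_hat * (1 - record.mu_hat) / 1000)
        expected = (
            math.log(priors.phi_v)
            + stats.norm.logpdf(x, record.mu_hat, sigma)
            - math.log(priors.phi_be)
            - stats.expon.logpdf(x, scale=1 / 700.0)
        )
        assert record.s == pytest.approx(expected, rel=1e-9)

    def test_no_background_excess_skipped(self, profile700):
        priors = compute_priors(3e-6, 0.01)
        # one alt read at q=0: expected sequencing errors fully explain it
        site = SiteObservation("chr1", 100, "A", 1000, {"G": 1}, {"G": [0]})
        assert score_site([site, obs(0)], "G", profile700, priors) is None

    def test_zero_coverage_replicate_dropped(self, profile700):
        priors = compute_priors(3e-6, 0.01)
        with_empty = score_site([obs(10), obs(0, n=0)], "G", profile700, priors)
        alone = score_site([obs(10)], "G", profile700, priors)
        assert with_empty.s == pytest.approx(alone.s)
        assert len(with_empty.evidence) == 1

    def test_oracle_equivalence_on_randomized_sites(self, profile700):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            k = int(rng.integers(1, 4))
            depths = [int(rng.integers(100, 10_001)) for _ in range(k)]
            counts = [int(rng.integers(0, max(2, int(0.03 * n)))) for n in depths]
            if not any(counts):
                continue
            quals = [
                [int(q) for q in rng.integers(10, 61, size=b)] for b in counts
            ]
            lam = float(rng.uniform(100, 1000))
            f_v = float(rng.uniform(1e-6, 1e-3))
            f_be = float(rng.uniform(1e-3, 0.5))
            observations = [
                SiteObservation(
                    "chr1", 100, "A", n,
                    {"G": b} if b else {}, {"G": q} if b else {},
                )
                for n, b, q in zip(depths, counts, quals)
            ]
            profile = flat_profile(lam, f_be)
            record = score_site(
                observations, "G", profile, compute_priors(f_v, f_be)
            )
            expected = oracle_score(depths, counts, quals, lam, f_v, f_be)
            assert record.s == pytest.approx(expected, rel=1e-9, abs=1e-9)
            checked += 1

    def test_concordance_maximal_at_equal_split(self, profile700):
        """For fixed total background-error mass over k=2 replicates, the
        score peaks when the adjusted VAFs agree."""
        priors = compute_priors(3e-6, 0.01)
        total = 20
        scores = {}
        for b1 in range(total + 1):
            record = score_site(
                [obs(b1), obs(total - b1)], "G", profile700, priors
            )
            scores[b1] = record.s
        best = max(scores, key=scores.get)
        assert best == total // 2
        for b1 in range(total // 2):
            assert scores[b1] < scores[b1 + 1]  # monotone toward the split
            assert scores[b1] == pytest.approx(scores[total - b1])  # symmetric

    def test_prior_applied_once_regardless_of_k(self, profile700):
        """Adding a third identical replicate adds one likelihood factor
        and no additional prior term."""
        deltas = []
        for f_v, f_be in [(3e-6, 0.01), (1e-3, 0.3)]:
            priors = compute_priors(f_v, f_be)
            s2 = score_site([obs(10)] * 2, "G", profile700, priors).s
            s3 = score_site([obs(10)] * 3, "G", profile700, priors).s
            deltas.append(s3 - s2)
        # the k=2 -> k=3 increment is prior-free, hence prior-invariant
        assert deltas[0] == pytest.approx(deltas[1], rel=1e-12)
        rec = score_site([obs(10)] * 2, "G", profile700, compute_priors(3e-6, 0.01))
        x = rec.evidence[0].x_be
        factor = stats.norm.logpdf(
            x, rec.mu_hat, rec.evidence[0].sigma_hat
        ) - stats.expon.logpdf(x, scale=1 / 700.0)
        assert deltas[0] == pytest.approx(factor, rel=1e-9)


class TestDecisionRule:
    def make_record(self, s, filters=()):
        ev = ReplicateEvidence(1000, 10, 0.01, 0.01, 9.99, 0.00999, 0.003)
        return CallRecord(
            "chr1", 100, "A", "G", "A>G", [ev], 0.00999, 700.0, s,
            list(filters),
        )

    def test_zero_score_not_called(self):
        assert not self.make_record(0.0).called
        assert self.make_record(1e-9).called

    def test_filtered_record_not_called(self):
        assert not self.make_record(5.0, filters=["strand_bias"]).called


def _repset(rep_sites_lists, target=1000, depth=1000):
    series = [
        PileupSeries(
            sites, regions=[TargetRegion("chr1", 0, target)], uniform_depth=depth
        )
        for sites in rep_sites_lists
    ]
    return ReplicateSet(
        replicates=series, regions=[TargetRegion("chr1", 0, target)]
    )


class TestCallVariants:
    def test_all_reference_input_gives_no_records(self, profile700):
        reps = _repset([[], []])
        records = call_variants(reps, profile700, CallerConfig())
        assert records == []

    def test_single_replicate_evidence_scored_not_dropped(self, profile700):
        reps = _repset([[obs(10)], []])
        records = call_variants(reps, profile700, CallerConfig())
        assert len(records) == 1
        assert records[0].s < 0  # discordant: alt reads in one replicate only

    def test_each_alt_allele_scored_independently(self, profile700):
        site = SiteObservation(
            "chr1", 100, "A", 1000, {"G": 10, "T": 8},
            {"G": [30] * 10, "T": [30] * 8},
        )
        site2 = SiteObservation(
            "chr1", 100, "A", 1000, {"G": 9, "T": 9},
            {"G": [30] * 9, "T": [30] * 9},
        )
        records = call_variants(
            _repset([[site], [site2]]), profile700, CallerConfig()
        )
        assert [r.alt for r in records] == ["G", "T"]

    def test_deterministic_ordering(self, profile700):
        reps = _repset([[obs(5, pos=200), obs(5, pos=100)], []])
        records = call_variants(reps, profile700, CallerConfig())
        assert [r.pos for r in records] == [100, 200]


class TestPostfilters:
    def stranded_obs(self, b=15, pos=100):
        n = 1000
        return SiteObservation(
            "chr1", pos, "A", n, {"G": b}, {"G": [30] * b},
            ref_fwd=(n - b) // 2, alt_fwd={"G": b},  # all alt reads forward
        )

    def test_strand_bias_flagged_in_capture_mode(self, profile700):
        reps = _repset([[self.stranded_obs()], [self.stranded_obs()]])
        records = call_variants(reps, profile700, CallerConfig())
        apply_postfilters(records, reps, CallerConfig(mode="capture"))
        assert "strand_bias" in records[0].filters

    def test_strand_bias_skipped_in_amplicon_mode(self, profile700):
        reps = _repset([[self.stranded_obs()], [self.stranded_obs()]])
        records = call_variants(reps, profile700, CallerConfig())
        apply_postfilters(records, reps, CallerConfig(mode="amplicon"))
        assert "strand_bias" not in records[0].filters

    def test_strand_bias_needs_all_replicates_biased(self, profile700):
        balanced = SiteObservation(
            "chr1", 100, "A", 1000, {"G": 14}, {"G": [30] * 14},
            ref_fwd=493, alt_fwd={"G": 7},
        )
        reps = _repset([[self.stranded_obs()], [balanced]])
        records = call_variants(reps, profile700, CallerConfig())
        apply_postfilters(records, reps, CallerConfig(mode="capture"))
        assert "strand_bias" not in records[0].filters

    def test_min_alt_reads_flag(self, profile700):
        reps = _repset([[obs(10)], [obs(1)]])
        records = call_variants(reps, profile700, CallerConfig())
        apply_postfilters(records, reps, CallerConfig(min_alt_reads_per_rep=2))
        assert "min_alt_reads" in records[0].filters

    def test_triallelic_competitor_flagged(self, profile700):
        def tri(pos=100):
            return SiteObservation(
                "chr1", pos, "A", 1000, {"G": 10, "T": 6},
                {"G": [30] * 10, "T": [30] * 6},
            )

        reps = _repset([[tri()], [tri()]])
        records = call_variants(reps, profile700, CallerConfig())
        g_record = next(r for r in records if r.alt == "G")
        apply_postfilters(records, reps, CallerConfig())
        assert "triallelic" in g_record.filters

    def test_blacklist_proximity_flagged(self, profile700):
        reps = _repset([[obs(10)], [obs(10)]])
        records = call_variants(reps, profile700, CallerConfig())
        config = CallerConfig(
            blacklist=[TargetRegion("chr1", 102, 110)], blacklist_pad=5
        )
        apply_postfilters(records, reps, config)
        assert "blacklist" in records[0].filters

    def test_filters_flag_but_never_remove(self, profile700):
        reps = _repset([[obs(1)], [obs(1)]])
        records = call_variants(reps, profile700, CallerConfig())
        n_before = len(records)
        filtered = apply_postfilters(records, reps, CallerConfig())
        assert len(filtered) == n_before


class TestConcordanceSeparation:
    def test_true_sites_more_concordant_than_errors(self):
        """On simulated duplicates the scale-free discordance
        |x1 - x2| / (x1 + x2) of spiked-in variants sits stochastically
        below that of error sites: shared variants show balanced adjusted
        VAFs while independent errors are one-sided."""
        config = SimulationConfig(
            seed=5150,
            target_bp=20_000,
            depth=1000,
            k=2,
            true_vafs=(0.01,),
            n_true_sites=200,
            lambda_by_type={
                t: 700.0 for t in
                ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")
            },
            f_be=0.01,
            with_control=False,
        )
        reps, truth = simulate_replicates(config)
        profile = flat_profile(700.0, 0.01)
        records = call_variants(
            reps, profile,
            CallerConfig(f_v=config.n_true_sites / config.target_bp),
        )
        truth_keys = truth.keys()
        true_diffs, error_diffs = [], []
        for r in records:
            if len(r.evidence) != 2:
                continue
            x1, x2 = r.evidence[0].x_be, r.evidence[1].x_be
            if x1 + x2 <= 0:
                continue
            diff = abs(x1 - x2) / (x1 + x2)
            (true_diffs if r.key in truth_keys else error_diffs).append(diff)
        true_diffs, error_diffs = true_diffs[:200], error_diffs[:200]
        assert len(true_diffs) >= 150 and len(error_diffs) == 200
        result = stats.ks_2samp(true_diffs, error_diffs)
        assert result.pvalue < 0.01
        assert np.median(true_diffs) < np.median(error_diffs)
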