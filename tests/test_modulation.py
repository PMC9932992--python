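"""AR-vs-ΔE_X divergence test, regulatory categories, XCI consensus rules,
and overlap statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from xidosage import modulation as md
from xidosage.modulation import StudyARSummary
from xidosage.types import RunConfig


def mk_dex(genes, values, ses, fdrs):
    return pd.DataFrame(
        {"value": values, "se": ses, "fdr": fdrs}, index=pd.Index(genes)
    )


def mk_gene_ar(genes, means, fdrs):
    return pd.DataFrame(
        {
            "mean_ar": means,
            "fdr": fdrs,
            "xi_expressed": [f < 0.05 for f in fdrs],
        },
        index=pd.Index(genes),
    )


def mk_per_sample(gene, ars):
    return pd.DataFrame({"gene_id": gene, "sample_id": [f"s{i}" for i in range(len(ars))], "ar": ars})


class TestArVsDex:
    def test_ddx3x_like_divergence_detected(self):
        """AR clearly above ΔE_X with a tight ΔE CI is flagged."""
        per_sample = mk_per_sample("g", [0.50, 0.55, 0.60])
        dex = mk_dex(["g"], [0.26], [0.01], [1e-6])
        gene_ar = mk_gene_ar(["g"], [0.55], [1e-4])
        out = md.test_ar_vs_dex(per_sample, dex, gene_ar)
        # oracle: one-sample two-sided t test against mu = 0.26
        p_oracle = scipy.stats.ttest_1samp([0.50, 0.55, 0.60], 0.26).pvalue
        assert out.loc["g", "t_p_value"] == pytest.approx(p_oracle)
        assert bool(out.loc["g", "ar_ne_dex"])

    def test_ar_equal_to_dex_not_flagged(self):
        per_sample = mk_per_sample("g", [0.3, 0.3, 0.3])
        dex = mk_dex(["g"], [0.3], [0.01], [1e-6])
        gene_ar = mk_gene_ar(["g"], [0.3], [1e-4])
        out = md.test_ar_vs_dex(per_sample, dex, gene_ar)
        assert not bool(out.loc["g", "ar_ne_dex"])

    def test_mean_inside_ci_excluded_despite_small_p(self):
        per_sample = mk_per_sample("g", [0.299, 0.300, 0.301])
        dex = mk_dex(["g"], [0.26], [0.05], [1e-6])  # CI halfwidth 0.098
        gene_ar = mk_gene_ar(["g"], [0.30], [1e-4])
        out = md.test_ar_vs_dex(per_sample, dex, gene_ar)
        assert out.loc["g", "fdr"] < 0.1  # the t test alone would flag it
        assert not bool(out.loc["g", "ar_ne_dex"])

    def test_double_nonsignificance_excluded(self):
        per_sample = mk_per_sample("g", [0.058, 0.060, 0.062])
        dex = mk_dex(["g"], [0.0], [0.01], [0.5])  # ΔE_X not significant
        gene_ar = mk_gene_ar(["g"], [0.06], [0.5])  # AR not significant
        out = md.test_ar_vs_dex(per_sample, dex, gene_ar)
        assert not bool(out.loc["g", "ar_ne_dex"])

    def test_missing_se_excluded_with_reason(self):
        per_sample = mk_per_sample("g", [0.1, 0.2, 0.3])
        dex = mk_dex(["g"], [0.2], [np.nan], [0.01])
        gene_ar = mk_gene_ar(["g"], [0.2], [0.01])
        out = md.test_ar_vs_dex(per_sample, dex, gene_ar)
        assert out.loc["g", "excluded_reason"] != ""
        assert not bool(out.loc["g", "ar_ne_dex"])


class TestClassifyModulation:
    def run(self, dex_val, dex_fdr, ar_mean, ar_fdr, prior, ne):
        dex = mk_dex(["g"], [dex_val], [0.02], [dex_fdr])
        gene_ar = mk_gene_ar(["g"], [ar_mean], [ar_fdr])
        prior_s = pd.Series({"g": prior})
        ar_vs = pd.DataFrame({"ar_ne_dex": [ne]}, index=["g"])
        return md.classify_modulation(dex, gene_ar, prior_s, ar_vs).loc["g"]

    def test_mpp1_like_positive_dex_silent_xi(self):
        """ΔE_X = 0.24 significant with AR ≈ 0: Xa is upregulated in trans."""
        row = self.run(0.24, 1e-4, 0.01, 0.8, "Subject", False)
        assert row["category"] == "modulated_no_escape"
        assert bool(row["discordant_with_prior"])
        assert bool(row["modulated"])

    def test_ddx3x_like_escape_and_modulated(self):
        row = self.run(0.26, 1e-4, 0.55, 1e-4, "Escape", True)
        assert row["category"] == "escape_and_modulated"
        assert bool(row["modulated"])

    def test_all_nonsignificant_is_silent_additive(self):
        row = self.run(0.01, 0.6, 0.02, 0.7, "Subject", False)
        assert row["category"] == "silent_additive"
        assert not bool(row["modulated"])

    def test_negative_dex_always_discordant(self):
        row = self.run(-0.2, 1e-4, 0.0, 0.9, "Escape", False)
        assert bool(row["discordant_with_prior"])

    def test_modulated_set_equals_union_oracle(self):
        rng = np.random.default_rng(0)
        n = 60
        genes = [f"g{i}" for i in range(n)]
        dex = mk_dex(
            genes,
            rng.normal(0, 0.3, n),
            np.full(n, 0.02),
            rng.uniform(0, 0.2, n),
        )
        gene_ar = mk_gene_ar(genes, rng.uniform(0, 0.5, n), rng.uniform(0, 0.2, n))
        prior = pd.Series(
            rng.choice(["Subject", "Escape", "NoCall"], n), index=genes
        )
        ne = pd.DataFrame(
            {"ar_ne_dex": rng.random(n) < 0.3}, index=genes
        )
        out = md.classify_modulation(dex, gene_ar, prior, ne)
        # independent union oracle from the two flags
        expected = set(out.index[out["discordant_with_prior"]]) | set(
            ne.index[ne["ar_ne_dex"]]
        )
        assert set(out.index[out["modulated"]]) == expected


def brute_consensus(calls, ars, hybrid):
    """Independent rule-table rendering of the consensus logic."""
    informative = [c for c in calls if c != "NotInformative"]
    if not informative:
        if hybrid is None:
            return "NoCall"
        return "Subject" if hybrid < 0.22 else "Escape"
    n = len(informative)
    ns = informative.count("Subject")
    ne_ = informative.count("Escape")
    known_ars = [a for a in ars if a is not None]
    avg = sum(known_ars) / len(known_ars) if known_ars else None
    if ns == n:
        return "Subject"
    if ns > n / 2 and avg is not None and avg < 0.1:
        return "Subject"
    if ne_ > n / 2:
        return "Escape"
    if 0 < ne_ <= n / 2 and (ne_ > 1 or (avg is not None and avg >= 1)):
        return "Escape"
    return "NoCall"


class TestConsensusXci:
    def s(self, call, ar=None):
        return StudyARSummary("g", "cotton", call, ar=ar)

    def test_all_subject(self):
        calls = [self.s("Subject", 0.0)] * 4
        assert md.consensus_xci(calls) == "Subject"

    def test_majority_escape(self):
        calls = [self.s("Escape", 0.3), self.s("Escape", 0.2), self.s("Subject", 0.0)]
        assert md.consensus_xci(calls) == "Escape"

    def test_half_escape_with_two_escaping_studies(self):
        calls = [
            self.s("Subject", 0.0),
            self.s("Subject", 0.1),
            self.s("Escape", 0.5),
            self.s("Escape", 0.6),
        ]
        assert md.consensus_xci(calls) == "Escape"

    def test_hybrid_fallback(self):
        assert md.consensus_xci([], hybrid_xi_fraction=0.10) == "Subject"
        assert md.consensus_xci([], hybrid_xi_fraction=0.30) == "Escape"
        assert md.consensus_xci([]) == "NoCall"
        not_inf = [self.s("NotInformative")] * 3
        assert md.consensus_xci(not_inf, hybrid_xi_fraction=0.5) == "Escape"

    def test_exhaustive_totality(self):
        """Every pattern of <= 4 study calls x AR bins maps to exactly one
        consensus matching the independent rule table."""
        call_opts = ["Subject", "Escape", "NotInformative"]
        ar_bins = [0.0, 0.05, 0.3, 1.0]
        count = 0
        for n in range(0, 5):
            for calls in itertools.product(call_opts, repeat=n):
                for ar in ar_bins:
                    summaries = [
                        self.s(c, ar if c != "NotInformative" else None)
                        for c in calls
                    ]
                    for hybrid in (None, 0.1, 0.3):
                        import warnings

                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            got = md.consensus_xci(summaries, hybrid)
                        want = brute_consensus(
                            list(calls),
                            [ar] * sum(c != "NotInformative" for c in calls),
                            hybrid,
                        )
                        assert got == want, (calls, ar, hybrid)
                        assert got in ("Subject", "Escape", "NoCall")
                        count += 1
        assert count == (sum(3**n for n in range(5))) * 4 * 3


class TestStudyLevelCall:
    def test_cotton_rules(self):
        low = md.study_level_call("cotton", "g", {"ar": 0.05, "ci_lower": 0.01})
        assert low.call == "Subject"  # AR < 0.1 even though CI excludes 0
        ci0 = md.study_level_call("cotton", "g", {"ar": 0.3, "ci_lower": -0.05})
        assert ci0.call == "Subject"
        esc = md.study_level_call("cotton", "g", {"ar": 0.3, "ci_lower": 0.1})
        assert esc.call == "Escape"

    def test_garieri_conversion_and_rule(self):
        # Xa fraction 0.8 -> AR = 1/0.8 - 1 = 0.25
        out = md.study_level_call(
            "garieri", "g", {"xa_fractions": [0.8, 0.8, 0.8]}
        )
        assert out.ar == pytest.approx(0.25)
        assert out.call == "Escape"
        mono = md.study_level_call("garieri", "g", {"xa_fractions": [1.0, 1.0]})
        assert mono.ar == pytest.approx(0.0)
        assert mono.call == "Subject"

    def test_tukiainen_and_sauteraud(self):
        t = md.study_level_call(
            "tukiainen", "g", {"sig_bulk": False, "sig_single": True}
        )
        assert t.call == "Escape"
        t2 = md.study_level_call(
            "tukiainen", "g", {"sig_bulk": False, "sig_single": False}
        )
        assert t2.call == "Subject"
        s = md.study_level_call("sauteraud", "g", {"padj": 0.005, "ar": 0.2})
        assert s.call == "Escape"
        s2 = md.study_level_call("sauteraud", "g", {"padj": 0.5})
        assert s2.call == "Subject"

    def test_unknown_study_rejected(self):
        with pytest.raises(ValueError, match="unknown study"):
            md.study_level_call("balaton", "g", {})


class TestOverlapEnrichment:
    def test_identical_full_sets(self):
        u = set(range(10))
        overlap, p = md.overlap_enrichment(u, u, u)
        assert overlap == 10
        assert p == pytest.approx(1.0)

    def test_forced_overlap_has_p_one(self):
        # |A| + |B| > |U| forces overlap; minimum possible overlap -> p = 1
        u = set(range(10))
        a, b = set(range(6)), set(range(4, 10))
        overlap, p = md.overlap_enrichment(a, b, u)
        assert overlap == 2
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        u = set(range(100))
        a = set(range(10))
        b = set(range(5, 15))
        overlap, p = md.overlap_enrichment(a, b, u)
        assert overlap == 5
        # brute-force hypergeometric upper tail
        def comb(n, k):
            return math.comb(n, k)
        total = comb(100, 10)
        p_oracle = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(5, 11)
        ) / total
        assert p == pytest.approx(p_oracle, rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            md.overlap_enrichment(set(), set(), set())
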