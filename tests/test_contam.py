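"""Diagnostic positions, read classification and Wilson score bounds."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from palaeomito.contam import (
    DiagnosticPanel,
    DiagnosticSite,
    count_diagnostic_reads,
    estimate_contamination,
    find_diagnostic_positions,
    wilson_interval,
    wilson_upper,
)
from palaeomito.errors import ConfigError, UndefinedEstimateError
from palaeomito.reads import AlignedRead
from palaeomito.reference import GenomeRecord, Variant, apply_variants


class TestWilson:
    def test_reported_contamination_bounds(self):
        """4/1,678 contaminating observations give a 0.6% upper bound and
        0/391 give 1%, at 95% confidence."""
        assert round(wilson_upper(4, 1678) * 100, 1) == 0.6
        assert round(wilson_upper(0, 391) * 100) == 1

    def test_boundary_k_equals_n(self):
        low, high = wilson_interval(10, 10)
        assert high == 1.0
        assert low < 1.0

    def test_zero_n_rejected(self):
        with pytest.raises(UndefinedEstimateError):
            wilson_upper(0, 0)

    @given(n=st.integers(1, 500), k=st.integers(0, 500))
    def test_monotone_in_k(self, n, k):
        if k >= n:
            return
        assert wilson_upper(k + 1, n) >= wilson_upper(k, n)

    @given(n=st.integers(1, 500))
    def test_k0_bound_shrinks_with_n(self, n):
        assert wilson_upper(0, n + 1) <= wilson_upper(0, n)

    @pytest.mark.parametrize("k", [0, 1, 4, 17, 100])
    @pytest.mark.parametrize("n", [30, 391, 1678, 5000])
    def test_agrees_with_score_test_inversion(self, k, n):
        """The closed form must equal the numerical inversion of the score
        test (p where (p_hat - p) = -z * sqrt(p(1-p)/n)) to 1e-9."""
        if k > n:
            return
        z = norm.ppf(0.975)
        p_hat = k / n

        def score(p):
            return (p_hat - p) + z * np.sqrt(p * (1 - p) / n)

        lo = p_hat if p_hat > 0 else 1e-12  # score(lo) > 0, score(1-) < 0
        upper = brentq(score, lo, 1.0 - 1e-15, xtol=1e-14)
        assert wilson_upper(k, n) == pytest.approx(upper, abs=1e-9)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        low, high = proportion_confint(4, 1678, alpha=0.05, method="wilson")
        assert wilson_interval(4, 1678) == (pytest.approx(low), pytest.approx(high))


class TestDiagnosticPositions:
    def test_identical_sample_and_panel_has_no_diagnostics(self):
        g = GenomeRecord("s", "ACGT" * 100)
        panel = [GenomeRecord(f"p{i}", g.sequence) for i in range(20)]
        assert len(find_diagnostic_positions(g, panel)) == 0

    def test_single_engineered_site(self):
        sample = GenomeRecord("s", "ACGT" * 100)
        alt = apply_variants(sample, [Variant(17, sample.base(17), "G")], "p")
        panel = [GenomeRecord(f"p{i}", alt.sequence) for i in range(311)]
        diag = find_diagnostic_positions(sample, panel)
        assert len(diag) == 1
        site = diag.sites[0]
        assert (site.position, site.sample_base, site.contaminant_base) == (17, "A", "G")

    def test_thirty_two_engineered_sites_recovered_through_panel_noise(self, study_fixture):
        """A contaminant differing from the sample at 32 sites is fully
        recovered from a 311-genome panel with 0.5% per-genome N-masking."""
        ref = study_fixture.reference
        sample = GenomeRecord("s", ref.sequence)
        positions = list(range(401, 16001, 500))[:32]
        variants = [
            Variant(p, ref.base(p), "ACGT"[("ACGT".index(ref.base(p)) + 1) % 4])
            for p in positions
        ]
        contaminant = apply_variants(sample, variants, "c")
        rng = np.random.default_rng(99)
        panel = []
        for i in range(311):
            seq = np.frombuffer(contaminant.sequence.encode(), dtype=np.uint8).copy()
            idx = rng.choice(len(seq), size=int(0.005 * len(seq)), replace=False)
            seq[idx] = ord("N")
            panel.append(GenomeRecord(f"p{i}", seq.tobytes().decode()))
        diag = find_diagnostic_positions(sample, panel, threshold=0.99)
        assert [s.position for s in diag.sites] == positions

    def test_sample_n_sites_skipped(self):
        sample = GenomeRecord("s", "NCGT" * 10)
        other = GenomeRecord("p", "ACGT" * 10).sequence
        panel = [GenomeRecord(f"p{i}", other) for i in range(10)]
        diag = find_diagnostic_positions(sample, panel)
        assert all(s.position % 4 != 1 for s in diag.sites)

    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigError):
            find_diagnostic_positions(GenomeRecord("s", "ACGT"), [])


def _panel(*sites):
    return DiagnosticPanel(
        sites=[DiagnosticSite(p, s, c, 1.0) for p, s, c in sites], panel_size=311
    )


class TestCounting:
    L = 100

    def _mol(self, rid, start, bases):
        end = (start - 1 + len(bases) - 1) % self.L + 1
        return AlignedRead(rid, start, end, "+", bases, np.full(len(bases), 30))

    def test_no_coverage_counts_zero(self):
        panel = _panel((50, "A", "G"))
        assert count_diagnostic_reads([self._mol("m", 1, "ACGT")], panel, self.L) == (0, 0, 0)

    def test_reported_tooth_counts(self):
        """1,678 observations with 4 contaminant-matching reads classify as
        (1674, 4, 0)."""
        panel = _panel((10, "A", "G"))
        mols = [self._mol(f"c{i}", 10, "A") for i in range(1674)]
        mols += [self._mol(f"x{i}", 10, "G") for i in range(4)]
        assert count_diagnostic_reads(mols, panel, self.L) == (1674, 4, 0)

    def test_third_base_and_n_count_as_other(self):
        panel = _panel((10, "A", "G"))
        mols = [self._mol("m1", 10, "T"), self._mol("m2", 10, "N")]
        assert count_diagnostic_reads(mols, panel, self.L) == (0, 0, 2)

    def test_molecule_covering_k_sites_contributes_k_observations(self):
        panel = _panel((10, "A", "G"), (12, "C", "T"))
        mol = self._mol("m", 9, "TAGC")  # covers 10 (A: clean) and 12 (C: clean)
        assert count_diagnostic_reads([mol], panel, self.L) == (2, 0, 0)

    def test_classification_is_exhaustive(self):
        rng = np.random.default_rng(3)
        panel = _panel((10, "A", "G"), (40, "C", "T"), (70, "G", "A"))
        mols = []
        total_obs = 0
        for i in range(200):
            start = int(rng.integers(1, self.L + 1))
            m = int(rng.integers(5, 30))
            bases = "".join(rng.choice(list("ACGTN"), m))
            mols.append(self._mol(f"m{i}", start, bases))
            for p in (10, 40, 70):
                if (p - start) % self.L < m:
                    total_obs += 1
        clean, contam, other = count_diagnostic_reads(mols, panel, self.L)
        assert clean + contam + other == total_obs


class TestEstimate:
    def test_tooth_like_counts_reproduce_wilson_bound(self):
        panel = _panel((10, "A", "G"))
        L = 100
        mols = [
            AlignedRead(f"c{i}", 10, 10, "+", "A", np.array([30])) for i in range(1674)
        ] + [AlignedRead(f"x{i}", 10, 10, "+", "G", np.array([30])) for i in range(4)]
        est = estimate_contamination(mols, panel, L)
        assert est.n_informative == 1678
        assert round(est.wilson_high * 100, 1) == 0.6
        assert est.wilson_low <= est.point <= est.wilson_high

    def test_no_observations_raises(self):
        panel = _panel((50, "A", "G"))
        with pytest.raises(UndefinedEstimateError):
            estimate_contamination([], panel, 100)
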