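"""SEC profiles, percentage distributions, peaks and release classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secdeg.design import SAMPLES
from secdeg.errors import SecdegError
from secdeg.profiles import (
    classify_release,
    condition_profile,
    feature_distribution_report,
    peak_fraction,
    percentage_distribution,
    profile_difference,
    protein_fraction_matrix,
    release_calls,
)


def _protein_matrix(values_by_fraction, accession="P1"):
    """values_by_fraction: {fraction: {sample: value}} -> protein QuantMatrix."""
    idx = pd.MultiIndex.from_tuples(
        [(accession, f) for f in values_by_fraction],
        names=("accession", "fraction_id"),
    )
    return pd.DataFrame(
        [
            [vals.get(s, np.nan) for s in SAMPLES]
            for vals in values_by_fraction.values()
        ],
        index=idx, columns=list(SAMPLES),
    )


class TestConditionProfile:
    def test_replicates_averaged(self):
        mat = _protein_matrix({1: {"L_1": 1.0, "L_2": 2.0, "L_3": 3.0}})
        profile = condition_profile(mat, "P1", "L", n_fractions=3)
        assert profile.loc[1] == 2.0

    def test_all_replicates_missing_leaves_fraction_missing(self):
        mat = _protein_matrix({4: {"L+N_1": 1.0}})
        profile = condition_profile(mat, "P1", "L", n_fractions=5)
        assert profile.isna().all()

    def test_single_replicate_passes_through(self):
        mat = _protein_matrix({2: {"L+V_2": 1.25}})
        profile = condition_profile(mat, "P1", "L+V", n_fractions=3)
        assert profile.loc[2] == 1.25

    def test_unknown_feature_raises(self):
        mat = _protein_matrix({1: {"L_1": 1.0}})
        with pytest.raises(KeyError):
            condition_profile(mat, "NOPE", "L")


class TestProfileDifference:
    def test_identical_profiles_give_zero(self):
        p = pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3])
        assert (profile_difference(p, p) == 0).all()

    def test_missing_propagates(self):
        a = pd.Series([1.0, np.nan, 3.0], index=[1, 2, 3])
        b = pd.Series([1.0, 2.0, np.nan], index=[1, 2, 3])
        d = profile_difference(a, b)
        assert np.isnan(d.loc[2]) and np.isnan(d.loc[3]) and d.loc[1] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(SecdegError):
            profile_difference(pd.Series([1.0]), pd.Series([1.0, 2.0]))

    def test_complex_shift_sign_pattern(self, clean_truth, designs21):
        """The condition-shift scenario (treated peak moves to earlier,
        higher-MW fractions) must show positive early differences and
        negative late differences."""
        asc = clean_truth.proteins[0]
        grid = np.arange(1, 22, dtype=float)
        treated = asc.baseline + np.log2(
            np.exp2(6.0 * np.exp(-((grid - asc.primary_mu("L+N")) ** 2) / (2 * 1.5**2)))
        )
        control = asc.baseline + np.log2(
            np.exp2(6.0 * np.exp(-((grid - asc.primary_mu("L")) ** 2) / (2 * 1.5**2)))
        )
        diff = profile_difference(
            pd.Series(treated, index=grid), pd.Series(control, index=grid)
        )
        early = diff.loc[float(round(asc.primary_mu("L+N")))]
        late = diff.loc[float(round(asc.primary_mu("L")))]
        assert early > 0 > late


class TestPercentageDistribution:
    def test_single_nonzero_fraction_gets_100(self):
        rows = pd.DataFrame([[0.0, 5.0, 0.0]], index=["a"], columns=[1, 2, 3])
        pct = percentage_distribution(rows)
        assert pct.loc["a"].tolist() == [0.0, 100.0, 0.0]

    def test_even_split(self):
        rows = pd.DataFrame([[2.0, 2.0]], index=["a"], columns=[1, 2])
        assert percentage_distribution(rows).loc["a"].tolist() == [50.0, 50.0]

    def test_all_zero_row_excluded_with_warning(self):
        rows = pd.DataFrame(
            [[0.0, 0.0], [1.0, 3.0]], index=["z", "a"], columns=[1, 2]
        )
        with pytest.warns(UserWarning, match="all-zero"):
            pct = percentage_distribution(rows)
        assert list(pct.index) == ["a"]

    def test_log2_input_reconstructs_linear(self):
        rows = pd.DataFrame([[1.0, 2.0, np.nan]], index=["a"], columns=[1, 2, 3])
        pct = percentage_distribution(rows, input_scale="log2")
        # 2^1 : 2^2 : 0 -> 33.33 : 66.67 : 0
        assert pct.loc["a", 1] == pytest.approx(100 * 2 / 6)
        assert pct.loc["a", 3] == 0.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
            min_size=2, max_size=21,
        ).filter(lambda v: sum(v) > 0)
    )
    def test_rows_sum_to_100(self, values):
        rows = pd.DataFrame([values], index=["a"],
                            columns=list(range(1, len(values) + 1)))
        assert percentage_distribution(rows).loc["a"].sum() == pytest.approx(
            100.0, abs=1e-9
        )


class TestPeakFraction:
    def test_monotone_profile_peaks_at_last_fraction(self):
        p = pd.Series(np.arange(21.0), index=range(1, 22))
        assert peak_fraction(p) == 21

    def test_tie_resolves_to_lowest_fraction(self):
        p = pd.Series([0.0, 5.0, 5.0, 1.0], index=[7, 8, 9, 10])
        assert peak_fraction(p) == 8

    def test_all_missing_rejected(self):
        with pytest.raises(SecdegError):
            peak_fraction(pd.Series([np.nan, np.nan], index=[1, 2]))

    def test_invariant_under_strictly_monotone_transform(self, rng):
        p = pd.Series(rng.normal(size=21), index=range(1, 22))
        assert peak_fraction(p) == peak_fraction(np.exp2(p))
        assert peak_fraction(p) == peak_fraction(3 * p + 7)


class TestClassifyRelease:
    def _row(self, peak, n=21, width=1.5):
        grid = np.arange(1, n + 1, dtype=float)
        return pd.Series(np.exp(-((grid - peak) ** 2) / (2 * width**2)), index=grid)

    def test_co_eluting_peptide_is_retained(self):
        call = classify_release(self._row(8), self._row(8))
        assert call.call == "retained" and call.shift == 0

    def test_rock1_like_shift_8_to_19_is_released(self):
        call = classify_release(self._row(19), self._row(8))
        assert call.call == "released" and call.shift == 11

    def test_earlier_peak_never_counts_as_release(self):
        call = classify_release(self._row(4), self._row(12))
        assert call.call == "retained"

    def test_sparse_peptide_row_is_ambiguous(self):
        sparse = pd.Series([0.0] * 20 + [1.0], index=range(1, 22))
        call = classify_release(sparse, self._row(8), min_fractions=3)
        assert call.call == "ambiguous"

    def test_missing_protein_row_is_ambiguous(self):
        call = classify_release(self._row(19), None)
        assert call.call == "ambiguous"

    def test_zero_noise_pipeline_recovers_planted_labels(
        self, clean_truth, clean_psms, designs21, clean_config
    ):
        """End-to-end on noise-free synthetic data: every planted
        retained/released label is recovered exactly."""
        from secdeg.quant import (
            aggregate_peptides,
            aggregate_proteins,
            filter_psms,
            normalize_to_reference,
            split_irt,
        )
        from secdeg.terminomics import annotate_peptides

        quant, _ = split_irt(clean_psms)
        kept = filter_psms(quant)
        pep = aggregate_peptides(normalize_to_reference(kept, designs21))
        idx = kept[["peptide", "accession", "start_pos"]].drop_duplicates(
            subset=["peptide", "accession"]
        )
        ann = annotate_peptides(idx, clean_truth.proteome())
        prot = aggregate_proteins(pep, ann)
        calls = release_calls(pep, prot, ann, "L+N")
        truth = {
            (pt.peptide, pt.accession): pt.behavior
            for pt in clean_truth.peptide_catalog()
            if pt.kind != "tryptic"
        }
        evaluable = calls[calls.call != "ambiguous"]
        assert len(evaluable) == len(truth)
        for row in evaluable.itertuples(index=False):
            assert truth[(row.peptide, row.accession)] == row.call


class TestFeatureDistributionReport:
    def _setup(self, clean_truth, clean_psms, designs21):
        from secdeg.quant import (
            aggregate_peptides,
            filter_psms,
            normalize_to_reference,
            split_irt,
        )
        from secdeg.terminomics import annotate_peptides

        quant, _ = split_irt(clean_psms)
        kept = filter_psms(quant)
        pep = aggregate_peptides(normalize_to_reference(kept, designs21))
        idx = kept[["peptide", "accession", "start_pos"]].drop_duplicates(
            subset=["peptide", "accession"]
        )
        ann = annotate_peptides(idx, clean_truth.proteome())
        return pep, ann

    def test_released_peptide_row_peaks_later_than_protein_row(
        self, clean_truth, clean_psms, designs21
    ):
        pep, ann = self._setup(clean_truth, clean_psms, designs21)
        released = next(
            pt for pt in clean_truth.peptide_catalog() if pt.behavior == "released"
        )
        report = feature_distribution_report(released.accession, ann, pep, "L+N")
        prot_peak = peak_fraction(report.loc["tryptic_protein"])
        pep_label = next(
            label for label in report.index if label.startswith(released.peptide)
        )
        assert peak_fraction(report.loc[pep_label]) > prot_peak + 2

    def test_protein_without_semi_peptides_gives_single_row(
        self, clean_truth, clean_psms, designs21
    ):
        pep, ann = self._setup(clean_truth, clean_psms, designs21)
        with_semi = {pt.accession for pt in clean_truth.peptide_catalog()
                     if pt.kind != "tryptic"}
        plain = next(
            p.accession for p in clean_truth.proteins
            if p.accession not in with_semi
        )
        report = feature_distribution_report(plain, ann, pep, "L")
        assert list(report.index) == ["tryptic_protein"]

    def test_unknown_protein_raises(self, clean_truth, clean_psms, designs21):
        pep, ann = self._setup(clean_truth, clean_psms, designs21)
        with pytest.raises(KeyError):
            feature_distribution_report("NOPE", ann, pep, "L")
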