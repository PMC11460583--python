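"""Filtering, reference normalization, aggregation and iRT QC."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secdeg.design import SAMPLES, TMT11_CHANNELS, ChannelRole, PlexDesign
from secdeg.errors import DesignMismatchError, MappingError
from secdeg.quant import (
    aggregate_peptides,
    aggregate_proteins,
    filter_psms,
    normalize_to_reference,
    split_irt,
    validate_channel_assignment,
)


def _design(fraction=1):
    roles = {}
    for i, sample in enumerate(SAMPLES):
        cond, rep = sample.rsplit("_", 1)
        roles[TMT11_CHANNELS[i]] = ChannelRole("sample", cond, int(rep))
    roles[TMT11_CHANNELS[9]] = ChannelRole("reference")
    roles[TMT11_CHANNELS[10]] = ChannelRole("empty")
    return PlexDesign(fraction, roles)


def _psm_frame(intensity_rows, fraction=1, **meta_over):
    design = _design(fraction)
    n = len(intensity_rows)
    meta = {
        "spectrum": [f"s{i}" for i in range(n)],
        "peptide": ["ELVISK"] * n,
        "accession": ["P1"] * n,
        "prev_aa": ["K"] * n,
        "next_aa": ["A"] * n,
        "start_pos": [10] * n,
        "purity": [0.9] * n,
        "is_decoy": [False] * n,
        "is_contaminant": [False] * n,
        "is_irt": [False] * n,
        "has_nterm_label": [True] * n,
        "fraction_id": [fraction] * n,
    }
    meta.update(meta_over)
    frame = pd.DataFrame(meta)
    for j, channel in enumerate(design.channels):
        frame[channel] = [row[j] for row in intensity_rows]
    return frame, design


class TestFilter:
    def test_purity_at_045_removed_and_050_boundary_excluded(self):
        frame, _ = _psm_frame([[100.0] * 11] * 3, purity=[0.45, 0.5, 0.51])
        kept = filter_psms(frame, 0.5)
        assert kept["spectrum"].tolist() == ["s2"]  # strictly > 0.5

    def test_decoys_and_contaminants_removed_despite_high_purity(self):
        frame, _ = _psm_frame(
            [[100.0] * 11] * 3,
            purity=[0.99] * 3,
            is_decoy=[True, False, False],
            is_contaminant=[False, True, False],
        )
        assert filter_psms(frame)["spectrum"].tolist() == ["s2"]

    def test_zero_total_intensity_removed(self):
        frame, _ = _psm_frame([[0.0] * 11, [1.0] * 11])
        assert filter_psms(frame)["spectrum"].tolist() == ["s1"]

    def test_empty_input_gives_empty_output(self):
        frame, _ = _psm_frame([])
        assert filter_psms(frame).empty

    def test_filter_is_idempotent(self, noisy_psms):
        quant, _ = split_irt(noisy_psms)
        once = filter_psms(quant)
        twice = filter_psms(once)
        pd.testing.assert_frame_equal(once, twice)


class TestNormalize:
    def test_intensity_equal_to_reference_gives_zero_everywhere(self):
        frame, design = _psm_frame([[100.0] * 11])
        norm = normalize_to_reference(frame, {1: design})
        assert np.allclose(norm[list(SAMPLES)].to_numpy(), 0.0)

    def test_channel_at_twice_reference_gives_plus_one(self):
        design = _design()
        row = [100.0] * 11
        # double one sample channel
        target_channel = next(iter(design.sample_channels))
        target_sample = design.sample_channels[target_channel]
        row[list(design.channels).index(target_channel)] = 200.0
        frame, _ = _psm_frame([row])
        norm = normalize_to_reference(frame, {1: design})
        assert norm.loc[0, target_sample] == pytest.approx(1.0)

    def test_zero_reference_blanks_the_whole_row(self):
        design = _design()
        row = [100.0] * 11
        row[list(design.channels).index(design.reference_channel)] = 0.0
        frame, _ = _psm_frame([row])
        norm = normalize_to_reference(frame, {1: design})
        assert norm[list(SAMPLES)].isna().all(axis=None)

    def test_zero_sample_cell_is_missing_not_zero(self):
        design = _design()
        row = [100.0] * 11
        target_channel = next(iter(design.sample_channels))
        target_sample = design.sample_channels[target_channel]
        row[list(design.channels).index(target_channel)] = 0.0
        frame, _ = _psm_frame([row])
        norm = normalize_to_reference(frame, {1: design})
        assert np.isnan(norm.loc[0, target_sample])
        others = [s for s in SAMPLES if s != target_sample]
        assert norm.loc[0, others].notna().all()

    def test_fraction_absent_from_design_raises(self):
        frame, design = _psm_frame([[100.0] * 11], fraction=4)
        with pytest.raises(DesignMismatchError):
            normalize_to_reference(frame, {1: _design(1)})

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scaling_all_channels_leaves_ratios_unchanged(self, scale):
        """Normalization is shift-free: per-PSM scaling cancels exactly."""
        design = _design()
        base = np.linspace(50, 150, 11)
        f1, _ = _psm_frame([base.tolist()])
        f2, _ = _psm_frame([(base * scale).tolist()])
        n1 = normalize_to_reference(f1, {1: design})[list(SAMPLES)].to_numpy()
        n2 = normalize_to_reference(f2, {1: design})[list(SAMPLES)].to_numpy()
        assert np.allclose(n1, n2, atol=1e-9)


class TestAggregate:
    def _norm(self, values_by_psm, peptide="ELVISK", accession="P1", fraction=1):
        rows = []
        for i, values in enumerate(values_by_psm):
            row = {
                "spectrum": f"s{i}", "peptide": peptide, "accession": accession,
                "start_pos": 10, "fraction_id": fraction,
            }
            row.update(dict(zip(SAMPLES, values)))
            rows.append(row)
        return pd.DataFrame(rows)

    def test_single_psm_passes_through(self):
        norm = self._norm([[1.5] * 9])
        mat = aggregate_peptides(norm)
        assert mat.loc[("ELVISK", "P1", 1)].tolist() == [1.5] * 9

    def test_median_of_odd_and_even_counts(self):
        norm = self._norm([[0.0] * 9, [2.0] * 9, [10.0] * 9])
        assert (aggregate_peptides(norm).to_numpy() == 2.0).all()
        norm2 = self._norm([[1.0] * 9, [3.0] * 9])
        assert (aggregate_peptides(norm2).to_numpy() == 2.0).all()

    def test_missing_cells_ignored_until_all_missing(self):
        a = [np.nan] + [1.0] * 8
        b = [np.nan] + [3.0] * 8
        mat = aggregate_peptides(self._norm([a, b]))
        row = mat.loc[("ELVISK", "P1", 1)]
        assert np.isnan(row[SAMPLES[0]])
        assert row[SAMPLES[1]] == 2.0

    def test_aggregation_is_permutation_invariant(self):
        v = [[0.5] * 9, [1.5] * 9, [7.0] * 9]
        m1 = aggregate_peptides(self._norm(v))
        m2 = aggregate_peptides(self._norm(v[::-1]))
        pd.testing.assert_frame_equal(m1, m2)

    def _annotations(self, specs):
        idx = pd.MultiIndex.from_tuples(
            [(p, "P1") for p in specs], names=("peptide", "accession")
        )
        return pd.DataFrame({"specificity": list(specs.values())}, index=idx)

    def test_protein_abundance_uses_only_fully_tryptic_peptides(self):
        norm = pd.concat(
            [
                self._norm([[1.0] * 9], peptide="AAAK"),
                self._norm([[2.0] * 9], peptide="CCCK"),
                self._norm([[3.0] * 9], peptide="DDDK"),
                self._norm([[50.0] * 9], peptide="SEMI"),
            ]
        )
        pep = aggregate_peptides(norm)
        ann = self._annotations(
            {"AAAK": "tryptic", "CCCK": "tryptic", "DDDK": "tryptic",
             "SEMI": "semi_N"}
        )
        prot = aggregate_proteins(pep, ann)
        assert (prot.loc[("P1", 1)].to_numpy() == 2.0).all()

    def test_protein_with_only_semi_peptides_absent(self):
        pep = aggregate_peptides(self._norm([[5.0] * 9], peptide="SEMI"))
        prot = aggregate_proteins(pep, self._annotations({"SEMI": "semi_C"}))
        assert prot.empty

    def test_unannotated_peptide_is_an_error(self):
        pep = aggregate_peptides(self._norm([[5.0] * 9], peptide="UNKNOWN"))
        with pytest.raises(MappingError):
            aggregate_proteins(pep, self._annotations({"AAAK": "tryptic"}))


class TestIrtQc:
    def _irt(self, non_empty, empty, fraction=1):
        design = _design(fraction)
        row = []
        for channel in design.channels:
            row.append(empty if channel == design.empty_channel else non_empty)
        frame, _ = _psm_frame([row] * 3, fraction=fraction,
                              accession=["iRT_standard"] * 3,
                              is_irt=[True] * 3)
        return frame, design

    def test_clean_labelling_passes(self):
        frame, design = self._irt(4096.0, 0.5)
        qc = validate_channel_assignment(frame, {1: design})
        assert qc.loc[1, "status"] == "pass"

    def test_hot_empty_channel_fails(self):
        frame, design = self._irt(4096.0, 4096.0)
        qc = validate_channel_assignment(frame, {1: design})
        assert qc.loc[1, "status"] == "fail"

    def test_no_irt_records_not_evaluable(self):
        frame, design = self._irt(4096.0, 0.5)
        qc = validate_channel_assignment(frame.iloc[0:0], {1: design})
        assert qc.loc[1, "status"] == "not_evaluable"
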