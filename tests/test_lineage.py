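"""Lineage records: validation, division classification, tissue summaries."""

import numpy as np
import pytest

from stomapolar import lineage as L, simulator, synth


def _forced_path_record():
    """Founder -> entry ACD -> (meristemoid -> GMC -> 2 guards) + (SLGC -> pavement)."""
    return synth.generate_lineage(synth.SynthLineageParams(
        n_founders=1, p_entry=1.0, p_amp=0.0, p_spacing=0.0, seed=0))


class TestValidateLineage:
    def test_generator_output_is_valid(self):
        record = synth.generate_lineage(synth.SynthLineageParams(
            n_founders=100, p_entry=0.7, p_amp=0.6, p_spacing=0.25, seed=11))
        assert L.validate_lineage(record) == []

    def test_three_daughter_division_flagged(self):
        record = _forced_path_record()
        record.divisions[0].daughter_ids = record.divisions[0].daughter_ids + (999,)
        assert any("daughters" in v for v in L.validate_lineage(record))

    def test_illegal_state_transition_flagged(self):
        record = _forced_path_record()
        # corrupt a meristemoid into a pavement cell mid-timeline
        for cell in record.cells.values():
            tps = [tp for tp in record.timepoints if tp in cell.states]
            if len(tps) >= 2 and cell.states[tps[0]] == L.MERISTEMOID:
                cell.states[tps[1]] = L.PAVEMENT
                break
        issues = L.validate_lineage(record)
        assert any("illegal transition" in v for v in issues)

    def test_lone_guard_cell_flagged(self):
        record = _forced_path_record()
        guard_ids = [c.cell_id for c in record.cells.values()
                     if L.GUARD in c.states.values()]
        cell = record.cells[guard_ids[0]]
        for tp in list(cell.states):
            cell.states[tp] = L.PAVEMENT
        assert L.validate_lineage(record) != []


class TestClassifyDivision:
    @pytest.mark.parametrize("parent,daughters,polarity,expected", [
        (L.MERISTEMOID, (L.MERISTEMOID, L.SLGC), L.POLARIZED, L.AMPLIFYING),
        (L.SLGC, (L.MERISTEMOID, L.SLGC), L.POLARIZED, L.SPACING),
        (L.PROTODERMAL, (L.MERISTEMOID, L.SLGC), L.POLARIZED, L.ENTRY),
        (L.GMC, (L.GUARD, L.GUARD), L.DEPOLARIZED, L.GMC_SCD),
        (L.GMC, (L.GUARD, L.GUARD), L.ABSENT, L.GMC_SCD),
    ])
    def test_rule_table(self, parent, daughters, polarity, expected):
        assert L.classify_division(parent, daughters, polarity).division_type == expected

    def test_conflicting_evidence_unlabeled(self):
        call = L.classify_division(L.GMC, (L.GUARD, L.GUARD), L.POLARIZED)
        assert call.division_type is None and call.reason

    def test_depolarized_acd_unlabeled(self):
        call = L.classify_division(L.MERISTEMOID, (L.MERISTEMOID, L.SLGC), L.DEPOLARIZED)
        assert call.division_type is None

    def test_truth_recovery_on_generated_lineage(self):
        record = synth.generate_lineage(synth.SynthLineageParams(
            n_founders=400, p_entry=0.8, p_amp=0.5, p_spacing=0.3, seed=4))
        calls = L.label_divisions(record)
        assert all(c.division_type == d.division_type
                   for c, d in zip(calls, record.divisions))

    def test_corrupted_polarity_calls_are_flagged_not_mislabeled(self):
        record = synth.generate_lineage(synth.SynthLineageParams(
            n_founders=400, p_entry=0.9, p_amp=0.5, p_spacing=0.2, seed=8))
        rng = np.random.default_rng(0)
        corrupted = set()
        for i, div in enumerate(record.divisions):
            if rng.random() < 0.10:
                parent = record.cells[div.parent_id]
                lt = parent.last_timepoint(record.timepoints)
                flip = {L.POLARIZED: L.DEPOLARIZED, L.DEPOLARIZED: L.POLARIZED}
                parent.polarity[lt] = flip[parent.polarity[lt]]
                corrupted.add(i)
        calls = L.label_divisions(record)
        n_wrong = 0
        for i, (call, div) in enumerate(zip(calls, record.divisions)):
            if i not in corrupted:
                assert call.division_type == div.division_type
            elif call.division_type != div.division_type:
                n_wrong += 1
                assert call.division_type is None, "corruption must flag, not mislabel"
        assert n_wrong == len(corrupted)  # every corrupted call was caught


class TestSummaries:
    def test_forced_path_fractions_and_histogram(self):
        summary = L.summarize_divisions(_forced_path_record())
        assert summary.fractions == {L.ENTRY: 0.5, L.GMC_SCD: 0.5}
        assert summary.meristemoid_histogram == {"0": 1}

    def test_two_forced_amplifying_rounds(self):
        record = synth.generate_lineage(synth.SynthLineageParams(
            n_founders=1, p_entry=1.0, p_amp=1.0, p_spacing=0.0, max_steps=2, seed=0))
        assert L.summarize_divisions(record).meristemoid_histogram == {"2": 1}

    def test_amplifying_fraction_matches_bernoulli_rate(self):
        # meristemoid-line divisions are amplifying vs terminal GMC division;
        # oracle: truncated-geometric expectation E[n] -> fraction E[n]/(E[n]+1)
        p, cap, n = 0.5, 12, 10000
        ks = np.arange(cap)
        e_n = float(np.sum(ks * p ** ks * (1 - p)) + cap * p ** cap)
        expected = e_n / (e_n + 1.0)
        record = synth.generate_lineage(synth.SynthLineageParams(
            n_founders=n, p_entry=1.0, p_amp=p, p_spacing=0.0,
            max_steps=cap, seed=21))
        s = L.summarize_divisions(record)
        n_m = s.counts[L.AMPLIFYING] + s.counts[L.GMC_SCD]
        frac = s.counts[L.AMPLIFYING] / n_m
        se = np.sqrt(expected * (1 - expected) / n_m)
        assert abs(frac - expected) < 3 * se

    def test_unlabeled_divisions_excluded_from_fractions(self):
        record = _forced_path_record()
        record.divisions[0].division_type = None
        parent = record.cells[record.divisions[0].parent_id]
        lt = parent.last_timepoint(record.timepoints)
        parent.polarity[lt] = L.DEPOLARIZED  # entry ACD now contradicts its daughters
        s = L.summarize_divisions(record)
        assert s.n_unlabeled == 1
        assert s.fractions == {L.GMC_SCD: 1.0}


class TestStomatalIndex:
    def test_two_stomata_eight_pavement(self):
        assert L.stomatal_index({L.GUARD: 4, L.PAVEMENT: 8}) == pytest.approx(0.2)

    def test_no_stomata(self):
        assert L.stomatal_index({L.PAVEMENT: 5}) == 0.0

    def test_forced_path_is_half_for_any_founder_count(self):
        for n in (1, 7, 40):
            record = synth.generate_lineage(synth.SynthLineageParams(
                n_founders=n, p_entry=1.0, p_amp=0.0, p_spacing=0.0, seed=1))
            assert L.stomatal_index(record) == pytest.approx(0.5)

    def test_undifferentiated_excluded(self):
        si = L.stomatal_index({L.GUARD: 2, L.PAVEMENT: 3, L.MERISTEMOID: 10, L.GMC: 5})
        assert si == pytest.approx(1 / 4)

    def test_empty_epidermis_errors(self):
        with pytest.raises(ValueError):
            L.stomatal_index({L.MERISTEMOID: 3})

    def test_si_identity_no_spacing(self):
        # SI == N / sum(n_i + 2) exactly when every lineage runs to absorption
        res, record = simulator.simulate(simulator.SimParams(
            n_founders=300, p_entry=1.0, p_amp=0.6, p_spacing=0.0, seed=13))
        n_i = res.amp_rounds_per_founder
        assert L.stomatal_index(record) == pytest.approx(300 / (n_i + 2).sum())


class TestCellCounts:
    def test_single_division_trajectory(self):
        record = _forced_path_record()
        counts = L.cell_count_trajectory(record)
        assert counts[0] == 1 and counts[-1] == 3  # 2 guards + 1 pavement

    def test_no_divisions_constant(self):
        record = synth.generate_lineage(synth.SynthLineageParams(
            n_founders=5, p_entry=0.0, p_amp=0.0, p_spacing=0.0, seed=0))
        counts = L.cell_count_trajectory(record)
        assert all(c == 5 for c in counts)

    def test_conservation_cells_equal_founders_plus_divisions(self):
        record = synth.generate_lineage(synth.SynthLineageParams(
            n_founders=150, p_entry=0.8, p_amp=0.5, p_spacing=0.2, seed=3))
        tp_index = {tp: i for i, tp in enumerate(record.timepoints)}
        n_founders = len(record.founders())
        for tp in record.timepoints:
            done = sum(1 for d in record.divisions
                       if tp_index[d.timepoint] <= tp_index[tp])
            assert len(record.living_at(tp)) == n_founders + done


class TestRoundTrip:
    def test_frame_round_trip_loss_free(self):
        record = synth.generate_lineage(synth.SynthLineageParams(
            n_founders=60, p_entry=0.8, p_amp=0.5, p_spacing=0.25, seed=2))
        rebuilt = L.from_frame(L.to_frame(record))
        assert L.to_frame(rebuilt).equals(L.to_frame(record))
        assert L.validate_lineage(rebuilt) == []
        s1, s2 = L.summarize_divisions(record), L.summarize_divisions(rebuilt)
        assert s1.counts == s2.counts and s1.stomatal_index == s2.stomatal_index
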