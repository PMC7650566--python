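"""NS accounting, percent identity, species assignment, concordance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cantrace as ct
from cantrace.traceability import (
    AMBIGUOUS,
    CONCORDANT,
    FAILED,
    MISIDENTIFIED,
    NSRecord,
    OutcomeRecord,
    PairingError,
    TIE,
)

FRAG_AB = ct.FragmentDef("AB", 1, 236)
FRAG_B = ct.FragmentDef("B", 128, 236)


def make_processed(seq, frag, individual="YFT-IO-1", species="YFT", level="L2"):
    return ct.ProcessedSequence(
        individual=individual, species_truth=species, species_label=species,
        area="IO", level=level, fragment=frag.name, sequence=seq, frag=frag,
    )


def mutate(seq, positions, base_map):
    out = list(seq)
    for pos in positions:
        out[pos - 1] = base_map(seq[pos - 1])
    return "".join(out)


def _other(base):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


class TestCountSubstitutions:
    def test_identical_fragments_count_zero(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=236))
        l1 = make_processed(seq, FRAG_AB, level="L1")
        q = make_processed(seq[127:], FRAG_B, level="L4B")
        assert ct.count_substitutions(q, l1) == (0, frozenset())

    def test_seven_diagnostic_differences_count_seven(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=236))
        cols = {130, 140, 150, 160, 170, 180, 190}
        degraded = mutate(seq, cols, _other)
        l1 = make_processed(seq, FRAG_AB, level="L1")
        q = make_processed(degraded[127:], FRAG_B, level="L4B")
        n, found = ct.count_substitutions(q, l1)
        assert n == 7 and found == frozenset(cols)

    def test_n_column_not_counted(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=236))
        degraded = mutate(seq, {130}, _other)
        degraded = degraded[:139] + "N" + degraded[140:]
        l1 = make_processed(seq, FRAG_AB, level="L1")
        q = make_processed(degraded[127:], FRAG_B, level="L4B")
        n, _ = ct.count_substitutions(q, l1)
        assert n == 1

    def test_individual_mismatch_rejected(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=236))
        l1 = make_processed(seq, FRAG_AB, individual="YFT-IO-1", level="L1")
        q = make_processed(seq[127:], FRAG_B, individual="YFT-IO-2")
        with pytest.raises(PairingError):
            ct.count_substitutions(q, l1)

    def test_uncovered_fragment_rejected(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=236))
        l1_b = make_processed(seq[127:], FRAG_B, level="L1")
        q = make_processed(seq, FRAG_AB)
        with pytest.raises(ct.CoordinateError):
            ct.count_substitutions(q, l1_b)


class TestNSPercent:
    @pytest.mark.parametrize(
        "n,length,expected",
        [
            (7, 109, 6.42),
            (0, 236, 0.00),
            (1, 117, 0.85),
            (1, 109, 0.92),
            (2, 109, 1.83),
            (3, 2400, 0.13),  # exact .125 rounds half away from zero
        ],
    )
    def test_worked_examples(self, n, length, expected):
        assert ct.ns_percent(n, length) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ct.ns_percent(1, 0)
        with pytest.raises(ValueError):
            ct.ns_percent(5, 4)


class TestGroupMeanNS:
    @staticmethod
    def _records(counts, length=109, level="L4B", area="AO", species="YFT"):
        return [
            NSRecord(
                individual=f"{species}-{area}-{i}", species=species, area=area,
                level=level, fragment="B", fragment_length=length, n_ns=c,
                ns_percent=ct.ns_percent(c, length),
            )
            for i, c in enumerate(counts, 1)
        ]

    def test_three_specimens_at_all_seven_diagnostics(self):
        out = ct.group_mean_ns(self._records([7, 7, 7]))
        assert out["mean_ns_percent"].tolist() == [6.42]

    def test_single_substitution_among_three(self):
        out = ct.group_mean_ns(self._records([1, 0, 0]))
        assert out["mean_ns_percent"].tolist() == [0.31]

    def test_single_record_group_passes_through(self):
        out = ct.group_mean_ns(self._records([5]))
        assert out["mean_ns_percent"].tolist() == [ct.ns_percent(5, 109)]

    def test_empty_input_rejected(self):
        with pytest.raises(ct.traceability.GroupingError):
            ct.group_mean_ns([])

    def test_mean_uses_unrounded_percentages(self):
        # counts {1,1,1,1,1,0} on 109 bp: the exact mean 5/6 * 100/109 =
        # 0.7645% displays as 0.76, whereas averaging the already-rounded
        # per-specimen values (0.92 each) would give 0.7667 -> 0.77
        out = ct.group_mean_ns(self._records([1, 1, 1, 1, 1, 0]))
        assert out["mean_ns_percent"].tolist() == [0.76]


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "k,length,expected",
        [(2, 109, 98.17), (4, 109, 96.33), (0, 109, 100.00),
         (3, 236, 98.73), (9, 236, 96.19), (1, 109, 99.08)],
    )
    def test_printed_similarities_from_mismatch_counts(self, k, length, expected, rng):
        a = "".join(rng.choice(list("ACGT"), size=length))
        b = mutate(a, set(range(1, k + 1)), _other)
        assert ct.percent_identity(a, b) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ct.CoordinateError):
            ct.percent_identity("ACGT", "ACG")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=120), st.data())
    def test_complementary_to_p_distance(self, a, data):
        b = "".join(
            data.draw(st.sampled_from("ACGT")) for _ in a
        )
        total = ct.percent_identity(a, b) + 100.0 * ct.p_distance(a, b)
        assert total == pytest.approx(100.0, abs=0.006)


class TestIdentifySpecies:
    def test_self_identification_over_whole_panel(self, default_panel):
        panel, _ = default_panel
        for rec in panel.records:
            q = make_processed(
                rec.sequence, FRAG_AB, individual=f"{rec.species}-IO-1",
                species=rec.species,
            )
            res = ct.identify_species(q, panel)
            assert res.status == "ASSIGNED"
            assert res.best_identity == 100.00
            assert res.species_set == frozenset({rec.species})

    def test_tie_reports_all_species_at_best_identity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=236))
        sp2 = mutate(seq, {10}, _other)
        sp3 = mutate(seq, {200}, _other)
        panel = ct.ReferencePanel(
            records=[
                ct.RefRecord("a", "sp1", seq),
                ct.RefRecord("b", "sp2", sp2),
                ct.RefRecord("c", "sp3", sp3),
            ],
        )
        # query at distance 1 from sp2 and sp3, distance 2 from sp1
        q_seq = mutate(seq, {10, 200}, _other)
        q = make_processed(q_seq, FRAG_AB, species="sp1")
        res = ct.identify_species(q, panel)
        assert res.status == TIE
        assert res.species_set == frozenset({"sp2", "sp3"})

    def test_low_identity_is_ambiguous(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=236))
        panel = ct.ReferencePanel(records=[ct.RefRecord("a", "sp1", seq)])
        q = make_processed(mutate(seq, set(range(1, 11)), _other), FRAG_AB)
        res = ct.identify_species(q, panel)
        assert res.status == AMBIGUOUS
        assert res.best_identity < 98.0

    def test_failed_amplification_is_failed(self, default_panel):
        panel, _ = default_panel
        q = ct.ProcessedSequence(
            individual="YFT-IO-1", species_truth="YFT", species_label="YFT",
            area="IO", level="L4B", fragment="FAIL", sequence="", frag=None,
        )
        assert ct.identify_species(q, panel).status == FAILED


class TestClassifyOutcome:
    def _result(self, status, species, ident=99.0):
        return ct.IdentificationResult("q", ident, frozenset(species), status)

    def test_assigned_wrong_species_is_misidentified(self):
        res = self._result("ASSIGNED", ["K. pelamis"], 100.0)
        assert ct.classify_outcome(res, "T. albacares") == MISIDENTIFIED

    def test_assigned_matching_species_is_concordant(self):
        res = self._result("ASSIGNED", ["YFT"])
        assert ct.classify_outcome(res, "YFT") == CONCORDANT

    def test_tie_without_morphological_species_is_misidentified(self):
        res = self._result(TIE, ["T. thynnus", "T. albacares"], 98.73)
        assert ct.classify_outcome(res, "T. tonggol") == MISIDENTIFIED

    def test_tie_containing_morphological_species_depends_on_mode(self):
        res = self._result(TIE, ["YFT", "BET"])
        assert ct.classify_outcome(res, "YFT") == MISIDENTIFIED
        assert ct.classify_outcome(res, "YFT", lenient_ties=True) == CONCORDANT

    def test_ambiguous_and_failed_pass_through(self):
        assert ct.classify_outcome(self._result(AMBIGUOUS, ["YFT"], 97.2), "YFT") == AMBIGUOUS
        assert ct.classify_outcome(
            ct.IdentificationResult("q", None, frozenset(), FAILED), "YFT"
        ) == FAILED


class TestConcordanceTable:
    def test_counts_sum_to_total(self):
        outcomes = (
            [OutcomeRecord(f"c{i}", "AB", "L2", CONCORDANT) for i in range(5)]
            + [OutcomeRecord("m1", "AB", "L2", MISIDENTIFIED)]
            + [OutcomeRecord("a1", "B", "L4B", AMBIGUOUS)]
        )
        table = ct.concordance_table(outcomes)
        for _, row in table.iterrows():
            assert (
                row.n_concordant + row.n_misidentified + row.n_ambiguous + row.n_failed
                == row.n_total
            )
        ab = table.query("fragment == 'AB' and level == 'ALL'").iloc[0]
        assert ab.n_total == 6 and ab.n_concordant == 5
        assert ab.percent_concordant == 83.33

    def test_empty_input_gives_empty_table(self):
        table = ct.concordance_table([])
        assert len(table) == 0
        assert list(table.columns) == ct.traceability.CONCORDANCE_COLUMNS
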