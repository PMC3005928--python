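"""Probe design: extraction, screening, selection, filtering, accounting."""

import io

import pytest

from homolarray.edit_core import CAP_EXCEEDED, brute_force_infix_distance
from homolarray.probe_design import (
    CandidateProbe,
    DesignConfig,
    RemovedGene,
    cross_species_filter,
    design_array,
    extract_candidates,
    min_cross_distance,
    reverse_complement,
    select_probe_for_gene,
    single_gene_check,
)
from homolarray.sequence_io import ProbeTableRow, TranscriptRecord, write_probe_table

CFG = DesignConfig()


def _tr(gid, seq):
    return TranscriptRecord(gid, "A", seq)


def _mutate(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


class TestExtractCandidates:
    def test_default_scheme_on_160bp(self):
        tr = _tr("g", "ACGT" * 40)
        cands = extract_candidates(tr, CFG)
        assert [c.start for c in cands] == [0, 50, 100]
        assert all(len(c.sequence) == 60 for c in cands)
        assert all(c.sequence == tr.sequence[c.start : c.start + 60] for c in cands)
        assert [c.dist_to_3prime for c in cands] == [100, 50, 0]

    def test_transcript_shorter_than_probe_gives_nothing(self):
        assert extract_candidates(_tr("g", "A" * 59), CFG) == []

    def test_exact_length_transcript_gives_single_flush_candidate(self):
        cands = extract_candidates(_tr("g", "ACGT" * 15), CFG)
        assert len(cands) == 1
        assert cands[0].start == 0
        assert cands[0].dist_to_3prime == 0

    def test_windows_containing_n_are_dropped(self):
        seq = "A" * 55 + "N" + "A" * 104  # N sits in windows at 0 and 50, not 100
        starts = [c.start for c in extract_candidates(_tr("g", seq), CFG)]
        assert starts == [100]


class TestMinCrossDistance:
    def test_identical_window_in_another_gene_scores_zero(self):
        seq = "ACGT" * 30
        cand = CandidateProbe("g1", 0, seq[:60], 60)
        dist, nearest = min_cross_distance(
            cand, [_tr("g1", seq), _tr("g2", "TTT" + seq[:60] + "GGG")], "g1", cap=12
        )
        assert (dist, nearest) == (0, "g2")

    def test_toy_set_matches_bruteforce_oracle(self, random_gene_set):
        base = random_gene_set[0].sequence
        probe = base[100:160]
        near = _tr("near", _mutate(base, range(102, 104)))  # ~2 edits inside window
        far = _tr("far", _mutate(base, range(100, 160, 12)))  # ~5 edits inside window
        others = [_tr("self", base), near, far]
        cand = CandidateProbe("self", 100, probe, len(base) - 160)
        dist, nearest = min_cross_distance(
            cand, others, "self", cap=12, check_reverse_complement=False
        )
        oracle = {
            t.id: brute_force_infix_distance(probe, t.sequence) for t in (near, far)
        }
        assert dist == min(oracle.values())
        assert nearest == min(oracle, key=oracle.get)

    def test_all_far_genes_exceed_cap(self):
        cand = CandidateProbe("g1", 0, "A" * 60, 0)
        dist, nearest = min_cross_distance(cand, [_tr("g2", "C" * 200)], "g1", cap=12)
        assert dist is CAP_EXCEEDED and nearest is None

    def test_empty_set_after_exclusion_is_maximally_specific(self):
        cand = CandidateProbe("g1", 0, "A" * 60, 0)
        assert min_cross_distance(cand, [_tr("g1", "A" * 60)], "g1", cap=12) == (
            CAP_EXCEEDED,
            None,
        )


class TestSelectProbeForGene:
    def _cand(self, start, d3):
        return CandidateProbe("g", start, "ACGT" * 15, d3)

    def test_most_3prime_passing_candidate_wins(self):
        scored = [(self._cand(0, 140), CAP_EXCEEDED, None), (self._cand(50, 90), 15, "x")]
        row = select_probe_for_gene(scored, CFG)
        assert isinstance(row, ProbeTableRow)
        assert row.start == 50 and row.probe_id == "g_50"

    def test_margin_is_strictly_greater_than_20(self):
        rejected = select_probe_for_gene([(self._cand(0, 20), CAP_EXCEEDED, None)], CFG)
        assert isinstance(rejected, RemovedGene)
        assert rejected.reason == "no_specific_candidate"
        accepted = select_probe_for_gene([(self._cand(0, 21), CAP_EXCEEDED, None)], CFG)
        assert isinstance(accepted, ProbeTableRow)

    def test_distance_is_strictly_greater_than_11(self):
        rejected = select_probe_for_gene([(self._cand(0, 100), 11, "x")], CFG)
        assert isinstance(rejected, RemovedGene)
        accepted = select_probe_for_gene([(self._cand(0, 100), 12, "x")], CFG)
        assert isinstance(accepted, ProbeTableRow)
        assert accepted.min_cross_distance == 12

    def test_empty_candidate_list_means_too_short(self):
        removed = select_probe_for_gene([], CFG, gene_id="g")
        assert removed == RemovedGene("g", "too_short")


class TestSingleGeneCheck:
    def test_counts_containing_transcripts(self):
        probe = "ACGT" * 15
        genes = [_tr("a", "TT" + probe), _tr("b", probe + probe), _tr("c", "G" * 80)]
        assert single_gene_check(probe, genes) == 2  # b counts once despite two hits

    def test_reverse_complement_hit_counts(self):
        probe = "AACCGGTTAC" * 6
        genes = [_tr("a", probe), _tr("b", "T" * 5 + reverse_complement(probe))]
        assert single_gene_check(probe, genes) == 2
        assert single_gene_check(probe, genes, check_reverse_complement=False) == 1


class TestCrossSpeciesFilter:
    def _probe(self, seq):
        return ProbeTableRow("g_0", "g", 0, 60, seq, 12, "", 100)

    def test_identical_window_in_other_species_removes_probe(self):
        probe = self._probe("ACGT" * 15)
        kept, removed = cross_species_filter(
            [probe], [TranscriptRecord("sq1", "B", "AA" + "ACGT" * 15 + "CC")], CFG
        )
        assert kept == [] and removed[0].reason == "cross_species_conflict"

    def test_distance_12_probe_survives(self, random_gene_set):
        target = random_gene_set[1].sequence
        probe_seq = _mutate(target[50:110], range(50 - 50, 110 - 50, 5))  # 12 spread edits
        oracle = brute_force_infix_distance(probe_seq, target)
        oracle_rc = brute_force_infix_distance(probe_seq, reverse_complement(target))
        assert min(oracle, oracle_rc) == 12
        kept, removed = cross_species_filter(
            [self._probe(probe_seq)], [TranscriptRecord("sq", "B", target)], CFG
        )
        assert len(kept) == 1 and removed == []

    def test_empty_other_species_keeps_everything(self):
        probes = [self._probe("ACGT" * 15)]
        assert cross_species_filter(probes, [], CFG) == (probes, [])


class TestDesignArray:
    def test_toy_partition_and_accounting(self, toy_sets):
        human, squid = toy_sets
        report_a, report_b = design_array(human, squid, CFG)
        removed = {r.gene_id: r.reason for r in report_a.removed_genes}
        assert removed == {"hsa004": "no_specific_candidate", "hsa005": "too_short"}
        assert sorted(p.gene_id for p in report_a.accepted_probes) == [
            "hsa001",
            "hsa002",
            "hsa003",
        ]
        for rep, n_genes in ((report_a, 5), (report_b, 3)):
            assert len(rep.accepted_probes) + len(rep.removed_genes) == n_genes
            assert len({p.gene_id for p in rep.accepted_probes}) == len(
                rep.accepted_probes
            )

    def test_two_identical_genes_are_both_removed(self):
        seq = "ACGTTGCA" * 20
        genes = [_tr("a", seq), _tr("b", seq)]
        report, _ = design_array(genes, [], CFG)
        assert report.accepted_probes == []
        assert {r.reason for r in report.removed_genes} == {"no_specific_candidate"}

    def test_empty_other_species_makes_cross_filter_a_noop(self, toy_sets):
        human, _ = toy_sets
        report, _ = design_array(human, [], CFG)
        assert "cross_species_conflict" not in {
            r.reason for r in report.removed_genes
        }

    def test_design_is_deterministic_and_byte_identical(self, toy_sets):
        human, squid = toy_sets
        outputs = []
        for _ in range(2):
            report_a, _ = design_array(human, squid, CFG)
            buf = io.StringIO()
            write_probe_table(report_a.accepted_probes, buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_accepted_probes_satisfy_all_rules_posthoc(self, toy_sets):
        """Recompute every screen with the brute-force oracle on the toy design."""
        human, squid = toy_sets
        report_a, _ = design_array(human, squid, CFG)
        by_id = {t.id: t for t in human}
        for probe in report_a.accepted_probes:
            assert len(probe.sequence) == CFG.probe_length
            assert probe.dist_to_3prime > CFG.three_prime_margin
            assert single_gene_check(probe.sequence, human) == 1
            for pool, exclude in ((human, probe.gene_id), (squid, None)):
                dists = [
                    min(
                        brute_force_infix_distance(probe.sequence, t.sequence),
                        brute_force_infix_distance(
                            probe.sequence, reverse_complement(t.sequence)
                        ),
                    )
                    for t in pool
                    if t.id != exclude
                ]
                assert min(dists) > CFG.distance_threshold
            src = by_id[probe.gene_id].sequence
            assert probe.sequence == src[probe.start : probe.start + 60]
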