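"""Cross-species microarray probe design by edit-distance screening.

The design procedure, per species:

1. extract fixed-length candidate windows (default 60 bp) at a fixed step
   (default 50 bp) from every transcript;
2. screen each candidate against every *other* gene of the same species:
   the candidate's specificity score is its minimum infix edit distance to
   any non-target transcript (both strands by default);
3. per gene, keep candidates whose score is strictly greater than the
   distance threshold (default 11) and which end strictly more than the
   3'-margin (default 20 bp) away from the transcript's 3' end, and select
   the 3'-most of them — oligo-dT-primed labeling makes 3'-proximal probes
   the brightest;
4. drop probes whose exact sequence occurs in more than one gene of their
   own species (multi-copy families cannot be probed specifically);
5. drop probes that come within the distance threshold of any transcript of
   the *other* species, so the two probe sets on the shared array cannot
   cross-hybridize.

Genes that lose their probe at any stage are reported with a reason, so the
accounting identity |genes| == |accepted| + |removed| always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .edit_core import (
    CAP_EXCEEDED,
    Distance,
    infix_edit_distance,
    qgram_lower_bound,
)
from .sequence_io import ProbeTableRow, TranscriptRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateProbe",
    "DesignConfig",
    "DesignReport",
    "RemovedGene",
    "extract_candidates",
    "min_cross_distance",
    "select_probe_for_gene",
    "cross_species_filter",
    "single_gene_check",
    "design_array",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CandidateProbe:
    """A fixed-length window of a transcript, 0-based half-open coordinates."""

    gene_id: str
    start: int
    sequence: str
    dist_to_3prime: int


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the design procedure.

    ``distance_threshold`` and ``three_prime_margin`` are strict lower
    bounds ("more than"): a candidate at distance exactly 11 or ending
    exactly 20 bp from the 3' end is rejected.  ``cap`` bounds the distance
    computation and must be at least ``distance_threshold + 1`` so that a
    capped-out distance still certifies threshold passage.
    """

    probe_length: int = 60
    step: int = 50
    distance_threshold: int = 11
    three_prime_margin: int = 20
    cap: Optional[int] = None
    qgram_q: int = 11
    check_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if self.probe_length <= 0 or self.step <= 0:
            raise ValueError("probe_length and step must be positive")
        if self.distance_threshold < 0 or self.three_prime_margin < 0:
            raise ValueError("thresholds must be >= 0")
        if self.cap is None:
            object.__setattr__(self, "cap", self.distance_threshold + 1)
        if self.cap < self.distance_threshold + 1:
            raise ValueError("cap must be >= distance_threshold + 1")
        if not 1 <= self.qgram_q <= self.probe_length:
            raise ValueError("qgram_q must be in [1, probe_length]")


@dataclass(frozen=True)
class RemovedGene:
    gene_id: str
    reason: str  # too_short | no_specific_candidate | multi_copy_exact | cross_species_conflict
    detail: str = ""


@dataclass
class DesignReport:
    """Per-species outcome: accepted probes plus a full removal accounting."""

    species: str
    accepted_probes: list[ProbeTableRow] = field(default_factory=list)
    removed_genes: list[RemovedGene] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)


def extract_candidates(
    transcript: TranscriptRecord, config: DesignConfig
) -> list[CandidateProbe]:
    """Windows of ``probe_length`` at starts 0, step, 2*step, ... in 5'→3' order.

    Windows containing N are discarded (their hybridization distance would
    be undefined).  A transcript shorter than the probe yields no candidates.
    """
    seq = transcript.sequence
    out: list[CandidateProbe] = []
    for start in range(0, len(seq) - config.probe_length + 1, config.step):
        window = seq[start : start + config.probe_length]
        if "N" in window:
            continue
        out.append(
            CandidateProbe(
                gene_id=transcript.id,
                start=start,
                sequence=window,
                dist_to_3prime=len(seq) - (start + config.probe_length),
            )
        )
    return out


def _targets(seq: str, check_rc: bool) -> tuple[str, ...]:
    return (seq, reverse_complement(seq)) if check_rc else (seq,)


def min_cross_distance(
    candidate: CandidateProbe,
    transcripts: Iterable[TranscriptRecord],
    exclude_gene: Optional[str],
    cap: int,
    *,
    qgram_q: Optional[int] = None,
    check_reverse_complement: bool = True,
) -> tuple[Distance, Optional[str]]:
    """Minimum infix edit distance from a candidate to every non-target gene.

    Returns ``(distance, nearest_gene_id)``; the distance is
    :data:`CAP_EXCEEDED` (and the gene id ``None``) when every gene is
    farther than ``cap`` — the maximally specific outcome.  Ties on the
    nearest gene break toward the lexicographically smallest id.  The q-gram
    lower bound is used only to skip genes that provably cannot beat the
    running cap; it never changes a result.
    """
    probe = candidate.sequence
    best: Distance = CAP_EXCEEDED
    best_gene: Optional[str] = None
    running_cap = cap
    for tr in sorted(transcripts, key=lambda t: t.id):
        if tr.id == exclude_gene:
            continue
        for target in _targets(tr.sequence, check_reverse_complement):
            # The q-gram bound cannot exceed ceil(n_grams / q); evaluate it
            # only when it could actually beat the running cap.
            if (
                qgram_q is not None
                and qgram_q <= len(probe)
                and -(-(len(probe) - qgram_q + 1) // qgram_q) > running_cap
                and qgram_lower_bound(probe, target, qgram_q) > running_cap
            ):
                continue
            res = infix_edit_distance(probe, target, running_cap)
            if res.exceeded:
                continue
            if best is CAP_EXCEEDED or res.distance < best:
                best = res.distance
                best_gene = tr.id
                running_cap = res.distance  # only strictly closer genes matter now
        if best == 0:
            break
    return best, best_gene


ScoredCandidate = tuple[CandidateProbe, Distance, Optional[str]]


def select_probe_for_gene(
    candidates_with_distances: Sequence[ScoredCandidate],
    config: DesignConfig,
    gene_id: Optional[str] = None,
) -> Union[ProbeTableRow, RemovedGene]:
    """Apply the specificity and 3'-margin rules, then take the 3'-most keeper.

    A candidate passes when its cross-gene distance is strictly greater than
    ``distance_threshold`` (a capped-out distance passes by construction) and
    its last base lies strictly more than ``three_prime_margin`` bp from the
    transcript's 3' end.  A gene with no passing candidate is removed as
    ``no_specific_candidate`` (duplicated/multi-copy genes end up here); a
    gene with no candidates at all is ``too_short``.
    """
    if not candidates_with_distances:
        return RemovedGene(gene_id or "", "too_short")
    gene_id = candidates_with_distances[0][0].gene_id
    keepers = [
        (cand, dist, nearest)
        for cand, dist, nearest in candidates_with_distances
        if (dist is CAP_EXCEEDED or dist > config.distance_threshold)
        and cand.dist_to_3prime > config.three_prime_margin
    ]
    if not keepers:
        return RemovedGene(gene_id, "no_specific_candidate")
    cand, dist, nearest = max(keepers, key=lambda item: item[0].start)
    stored = config.cap if dist is CAP_EXCEEDED else int(dist)
    return ProbeTableRow(
        probe_id=f"{gene_id}_{cand.start}",
        gene_id=gene_id,
        start=cand.start,
        length=len(cand.sequence),
        sequence=cand.sequence,
        min_cross_distance=stored,
        nearest_nontarget=nearest or "",
        dist_to_3prime=cand.dist_to_3prime,
    )


def single_gene_check(
    probe_sequence: str,
    transcripts: Iterable[TranscriptRecord],
    *,
    check_reverse_complement: bool = True,
) -> int:
    """Number of transcripts containing the probe as an exact substring.

    Both the forward sequence and (by default) its reverse complement are
    searched; a transcript counts once even if it holds several hits.  The
    design pipeline keeps a probe only when this count is exactly 1 within
    its own species.
    """
    queries = _targets(probe_sequence, check_reverse_complement)
    return sum(1 for tr in transcripts if any(q in tr.sequence for q in queries))


def cross_species_filter(
    probes: Sequence[ProbeTableRow],
    other_species: Iterable[TranscriptRecord],
    config: DesignConfig,
) -> tuple[list[ProbeTableRow], list[RemovedGene]]:
    """Drop probes within the distance threshold of any other-species gene.

    A probe survives iff its minimum infix edit distance to every transcript
    of the other species is strictly greater than ``distance_threshold``.
    Removed probes are logged with the nearest conflicting gene.
    """
    others = list(other_species)
    kept: list[ProbeTableRow] = []
    removed: list[RemovedGene] = []
    for probe in probes:
        cand = CandidateProbe(probe.gene_id, probe.start, probe.sequence, probe.dist_to_3prime)
        dist, nearest = min_cross_distance(
            cand,
            others,
            exclude_gene=None,
            cap=config.cap,
            qgram_q=config.qgram_q,
            check_reverse_complement=config.check_reverse_complement,
        )
        if dist is CAP_EXCEEDED or dist > config.distance_threshold:
            kept.append(probe)
        else:
            removed.append(
                RemovedGene(
                    probe.gene_id,
                    "cross_species_conflict",
                    detail=f"distance {dist} to {nearest}",
                )
            )
    return kept, removed


def _design_one_species(
    transcripts: Sequence[TranscriptRecord],
    config: DesignConfig,
    species: str,
) -> DesignReport:
    report = DesignReport(species=species)
    by_id = sorted(transcripts, key=lambda t: t.id)
    report.stage_counts["input_genes"] = len(by_id)
    selected: list[ProbeTableRow] = []
    for tr in by_id:
        candidates = extract_candidates(tr, config)
        scored: list[ScoredCandidate] = []
        for cand in candidates:
            dist, nearest = min_cross_distance(
                cand,
                by_id,
                exclude_gene=tr.id,
                cap=config.cap,
                qgram_q=config.qgram_q,
                check_reverse_complement=config.check_reverse_complement,
            )
            scored.append((cand, dist, nearest))
        outcome = select_probe_for_gene(scored, config, gene_id=tr.id)
        if isinstance(outcome, RemovedGene):
            report.removed_genes.append(outcome)
        else:
            selected.append(outcome)
    report.stage_counts["after_selection"] = len(selected)

    survivors: list[ProbeTableRow] = []
    for probe in selected:
        count = single_gene_check(
            probe.sequence,
            by_id,
            check_reverse_complement=config.check_reverse_complement,
        )
        if count == 1:
            survivors.append(probe)
        else:
            report.removed_genes.append(
                RemovedGene(
                    probe.gene_id,
                    "multi_copy_exact",
                    detail=f"exact match in {count} genes",
                )
            )
    report.stage_counts["after_single_gene_check"] = len(survivors)
    report.accepted_probes = survivors
    return report


def design_array(
    species_a: Sequence[TranscriptRecord],
    species_b: Sequence[TranscriptRecord],
    config: DesignConfig,
) -> tuple[DesignReport, DesignReport]:
    """Run the full design for both species, then cross-filter each against the other.

    Deterministic given inputs and config: genes are processed in id order
    and every tie-break is lexicographic.
    """
    report_a = _design_one_species(species_a, config, species="A")
    report_b = _design_one_species(species_b, config, species="B")
    for report, others in ((report_a, species_b), (report_b, species_a)):
        kept, removed = cross_species_filter(report.accepted_probes, others, config)
        report.accepted_probes = kept
        report.removed_genes.extend(removed)
        report.stage_counts["after_cross_species_filter"] = len(kept)
        report.stage_counts["accepted"] = len(kept)
        report.stage_counts["removed"] = len(report.removed_genes)
        assert report.stage_counts["accepted"] + report.stage_counts["removed"] == (
            report.stage_counts["input_genes"]
        ), "design accounting identity violated"
        logger.info(
            "species %s: %d genes in, %d probes accepted, %d genes removed",
            report.species,
            report.stage_counts["input_genes"],
            len(kept),
            len(report.removed_genes),
        )
    return report_a, report_b
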