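"""Intensity-threshold homolog calling and head/body differential expression.

Given per-probe intensities from the two tissue samples, the analysis:

* flags *detected* probes — intensity above a background-plus-k-SD cutoff
  (a documented stand-in for the scanner vendor's significance call);
* flags *homolog candidates* — probes whose intensity strictly exceeds the
  high-expression cutoff (default 1,000 on the linear scale): cross-hybridizing
  non-targets lose signal so fast with edit distance that intensities this
  high are taken as evidence of a genuine conserved homolog;
* splits candidates into already-known and newly identified homologs against
  a reference pair table;
* reports head-vs-body fold changes (larger/smaller, with a direction flag)
  for probes that are a homolog candidate in at least one sample;
* summarizes three-way overlaps between the two probe sets' calls and a
  precomputed sequence-homology gene list (Venn region counts).

All threshold comparisons are strict ("more than").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .sequence_io import IntensityRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CallConfig",
    "HomologCall",
    "DifferentialResult",
    "detect_expressed",
    "call_homologs",
    "classify_known_new",
    "detection_percentage",
    "differential_expression",
    "venn_summary",
]


@dataclass(frozen=True)
class CallConfig:
    """Analysis thresholds.

    ``homolog_intensity_threshold``: linear-scale cutoff for calling a
    homolog candidate (strict >; default 1,000).
    ``detection_k``: number of background SDs above the background mean for
    the detection call (default 2.6).
    ``fold_change_min``: smallest fold change kept in the differential list
    (default 2).
    ``min_intensity_for_fc``: floor added to both samples before the ratio,
    so near-zero intensities cannot blow the fold change up; defaults to a
    typical background mean.
    """

    homolog_intensity_threshold: float = 1000.0
    detection_k: float = 2.6
    fold_change_min: float = 2.0
    min_intensity_for_fc: float = 50.0

    def __post_init__(self) -> None:
        if self.homolog_intensity_threshold <= 0 or self.detection_k <= 0:
            raise ValueError("thresholds must be > 0")
        if self.fold_change_min < 1 or self.min_intensity_for_fc < 0:
            raise ValueError("fold_change_min >= 1 and floor >= 0 required")


@dataclass(frozen=True)
class HomologCall:
    probe_id: str
    gene_id: str
    sample_id: str
    intensity: float
    is_detected: bool
    is_homolog_candidate: bool
    status: str = "unknown"  # known | new | unknown


@dataclass(frozen=True)
class DifferentialResult:
    probe_id: str
    fold_change: float
    regulation: str  # "up" = higher in head, "down" = higher in body
    annotation: str = ""


def detect_expressed(
    records: Iterable[IntensityRecord],
    background_mean: float,
    background_sd: float,
    config: CallConfig,
) -> list[IntensityRecord]:
    """Set the detection flag: intensity > background_mean + k * background_sd."""
    if background_mean < 0 or background_sd < 0:
        raise ValueError("background parameters must be >= 0")
    cutoff = background_mean + config.detection_k * background_sd
    return [
        IntensityRecord(
            probe_id=r.probe_id,
            sample_id=r.sample_id,
            intensity=r.intensity,
            detected=r.intensity > cutoff,
        )
        for r in records
    ]


def call_homologs(
    records: Iterable[IntensityRecord],
    config: CallConfig,
    gene_of_probe: Optional[Mapping[str, str]] = None,
) -> list[HomologCall]:
    """Flag homolog candidates: intensity strictly above the high-expression cutoff."""
    gene_of_probe = gene_of_probe or {}
    return [
        HomologCall(
            probe_id=r.probe_id,
            gene_id=gene_of_probe.get(r.probe_id, r.probe_id),
            sample_id=r.sample_id,
            intensity=r.intensity,
            is_detected=r.detected,
            is_homolog_candidate=r.intensity > config.homolog_intensity_threshold,
        )
        for r in records
    ]


def classify_known_new(
    candidates: Sequence[str],
    known_table: Iterable[tuple[str, str]],
) -> tuple[int, int, list[str], list[str]]:
    """Partition candidate genes into already-known and newly identified homologs.

    ``known_table`` holds (species-A gene, species-B gene) pairs; a candidate
    is known when it appears on either side of any pair.  Returns
    ``(n_known, n_new, known_list, new_list)`` with
    ``n_known + n_new == len(candidates)``.
    """
    known_ids: set[str] = set()
    for a, b in known_table:
        known_ids.add(a)
        known_ids.add(b)
    known = [g for g in candidates if g in known_ids]
    new = [g for g in candidates if g not in known_ids]
    return len(known), len(new), known, new


def detection_percentage(n_detected: int, n_total: int) -> int:
    """Percentage of probes detected, rounded to the nearest integer."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return round(100 * n_detected / n_total)


def differential_expression(
    head_records: Sequence[IntensityRecord],
    body_records: Sequence[IntensityRecord],
    config: CallConfig,
    annotations: Optional[Mapping[str, str]] = None,
) -> list[DifferentialResult]:
    """Head-vs-body fold changes for probes called homolog in at least one sample.

    Both intensities are floored (``+ min_intensity_for_fc``) before the
    ratio; the fold change is larger/smaller, with regulation "up" when head
    is higher and "down" when body is higher.  Only probes with fold change
    >= ``fold_change_min`` and at least one sample above the homolog cutoff
    are reported, sorted by fold change descending (probe id breaks ties).
    Probes present in only one table are excluded with a warning.
    """
    annotations = annotations or {}
    head = {r.probe_id: r for r in head_records}
    body = {r.probe_id: r for r in body_records}
    for pid in sorted(set(head) ^ set(body)):
        logger.warning("probe %s present in only one sample; excluded", pid)
    results: list[DifferentialResult] = []
    for pid in set(head) & set(body):
        h, b = head[pid].intensity, body[pid].intensity
        if max(h, b) <= config.homolog_intensity_threshold:
            continue
        hf, bf = h + config.min_intensity_for_fc, b + config.min_intensity_for_fc
        fold = max(hf, bf) / min(hf, bf)
        if fold < config.fold_change_min:
            continue
        results.append(
            DifferentialResult(
                probe_id=pid,
                fold_change=fold,
                regulation="up" if hf > bf else "down",
                annotation=annotations.get(pid, ""),
            )
        )
    results.sort(key=lambda r: (-r.fold_change, r.probe_id))
    return results


_VENN_REGIONS = ("A_only", "B_only", "C_only", "AB", "AC", "BC", "ABC")


def venn_summary(
    calls_from_a_probes: Iterable[str],
    calls_from_b_probes: Iterable[str],
    sequence_homology_table: Iterable[tuple[str, str]],
) -> dict[str, int]:
    """Three-set Venn region counts over gene identifiers.

    The three sets are: genes called by species-A probes, genes called by
    species-B probes, and genes on the precomputed sequence-homology pair
    list.  Pairs map species-B identifiers onto their species-A partner so
    all three sets live in one identifier space; the homology set itself is
    the species-A side of the pairs.  Region counts sum to the union size.
    """
    pairs = list(sequence_homology_table)
    b_to_a = {b: a for a, b in pairs}
    set_a = set(calls_from_a_probes)
    set_b = {b_to_a.get(g, g) for g in calls_from_b_probes}
    set_c = {a for a, _ in pairs}
    counts = dict.fromkeys(_VENN_REGIONS, 0)
    for gene in set_a | set_b | set_c:
        key = ("A" if gene in set_a else "") + ("B" if gene in set_b else "") + (
            "C" if gene in set_c else ""
        )
        counts[key if len(key) > 1 else f"{key}_only"] += 1
    return counts
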