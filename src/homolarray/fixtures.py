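"""Deterministic toy dataset for docs, smoke tests and quick starts.

Five "human" genes and three "squid" genes, all generated from a seeded RNG:
three squid genes are moderately diverged orthologs of the first three human
genes (so cross-species structure exists by construction), one human gene is
a near-duplicate of another (a multi-copy family the design must reject),
and one human gene is too short to carry a probe.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .hybridization_sim import EvolutionConfig, evolve_ortholog
from .sequence_io import (
    TranscriptRecord,
    write_annotations,
    write_fasta,
    write_known_homologs,
)

_BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def toy_transcripts(
    seed: int = 0,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Build the 5-gene "human" and 3-gene "squid" toy sets in memory."""
    rng = np.random.default_rng(seed)
    lengths = [400, 350, 300, 320, 45]  # last one shorter than a 60-mer
    human = []
    for i, n in enumerate(lengths, start=1):
        human.append(
            TranscriptRecord(
                id=f"hsa{i:03d}",
                species="human",
                sequence=random_dna(rng, n),
                description=f"toy human gene {i}",
            )
        )
    # hsa004 becomes a near-duplicate of hsa001: same sequence, 2 substitutions
    dup = list(human[0].sequence[:320])
    for pos in (60, 200):
        dup[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[dup[pos]]
    human[3] = TranscriptRecord(
        id="hsa004",
        species="human",
        sequence="".join(dup),
        description="toy near-duplicate of hsa001",
    )
    evo = EvolutionConfig(
        substitution_rate=0.25, insertion_rate=0.03, deletion_rate=0.03, rng_seed=seed
    )
    evo_rng = np.random.default_rng(seed + 1)
    squid = [
        TranscriptRecord(
            id=f"idi{i:03d}",
            species="squid",
            sequence=evolve_ortholog(human[i - 1].sequence, evo, evo_rng),
            description=f"toy squid ortholog of hsa{i:03d}",
        )
        for i in (1, 2, 3)
    ]
    return human, squid


def write_toy_dataset(out_dir: Path, seed: int = 0) -> list[Path]:
    """Write the toy FASTAs plus known-homolog and annotation tables."""
    out_dir.mkdir(parents=True, exist_ok=True)
    human, squid = toy_transcripts(seed)
    paths = []
    for name, records in (("toy_human.fasta", human), ("toy_squid.fasta", squid)):
        path = out_dir / name
        write_fasta(records, path)
        paths.append(path)
    known = out_dir / "toy_known_homologs.tsv"
    write_known_homologs([("hsa001", "idi001"), ("hsa002", "idi002")], known)
    paths.append(known)
    annot = out_dir / "toy_annotations.tsv"
    write_annotations(
        {
            "hsa001": "toy kinase",
            "hsa002": "toy transcription factor",
            "hsa003": "toy ribosomal protein",
            "hsa004": "toy kinase paralog",
            "hsa005": "toy short fragment",
        },
        annot,
    )
    paths.append(annot)
    return paths
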