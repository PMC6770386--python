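"""Synthetic annotated genome sets, taxonomies and submissions.

Everything the curation, simulation and scoring machinery consumes can
be generated here from a seed, so the whole toolkit is exercisable —
and testable — without any download. A :class:`SyntheticWorld` plays
the role of an annotated genome repository: records carry completeness,
host-class and taxonomy annotations at user-requested rates, grouped
into clades of user-requested sizes. Genome sequences are i.i.d.
uniform nucleotides (clade structure in the curation step is
annotation-driven, not sequence-driven, so sequence realism buys
nothing); an optional planted per-clade k-mer is available for tests
that want detectable shared sequence.

Synthetic accessions live in a ``SYN_...`` namespace that cannot be
mistaken for a real repository accession, so nothing here can trigger
an accidental live lookup.

:func:`make_submission` fabricates a participant metrics file with a
*known* sensitivity and false-positive count from a ground-truth
manifest — the oracle input for the scoring module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .refdb import ReferenceRecord
from .score import AccessionResolver, ExpectedVirusPattern, VirusMetricsRow
from .simulate import GroundTruthManifest

__all__ = [
    "SyntheticWorld",
    "TaxonomyEntry",
    "make_world",
    "make_contaminant_pool",
    "make_submission",
    "species_stand_ins",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class TaxonomyEntry(NamedTuple):
    name: str
    species: str
    genus: str
    family: str
    host_class: str


@dataclass(frozen=True)
class SyntheticWorld:
    """A seeded, self-consistent stand-in for an annotated genome set."""

    records: tuple[ReferenceRecord, ...]
    taxonomy: Mapping[str, TaxonomyEntry]
    seed: int

    def sequences(self) -> dict[str, str]:
        return {r.accession: r.sequence for r in self.records}

    def resolver(self) -> AccessionResolver:
        """Offline accession resolver backed by the world's taxonomy."""
        return AccessionResolver(
            {
                acc: (t.name, t.species, t.family)
                for acc, t in self.taxonomy.items()
            }
        )

    def expected_patterns(
        self, accessions: Sequence[str]
    ) -> list[ExpectedVirusPattern]:
        """Expected-positive patterns for the species of given accessions."""
        import re as _re

        out = []
        seen = set()
        for acc in accessions:
            t = self.taxonomy[acc]
            if t.species in seen:
                continue
            seen.add(t.species)
            out.append(
                ExpectedVirusPattern(
                    species_label=t.species,
                    patterns=(_re.escape(t.species),),
                    family=t.family,
                )
            )
        return out

    # --- text-format export (FASTA + TSV tables) ----------------------

    def write_fasta(self, path: str | Path) -> int:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        return SeqIO.write(
            [
                SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
                for r in self.records
            ],
            str(path),
            "fasta",
        )

    def write_annotations(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "accession": r.accession,
                    "is_complete": int(r.is_complete),
                    "host_class": r.host_class,
                    "species": r.species,
                    "genus": r.genus,
                    "family": r.family,
                }
                for r in self.records
            ]
        ).to_csv(path, sep="\t", index=False)

    def write_resolver_table(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "accession": acc,
                    "name": t.name,
                    "species": t.species,
                    "family": t.family,
                }
                for acc, t in self.taxonomy.items()
            ]
        ).to_csv(path, sep="\t", index=False)


def _clade_sizes(
    entries_per_clade, n_clades: int, rng: np.random.Generator
) -> list[int]:
    if isinstance(entries_per_clade, int):
        return [entries_per_clade] * n_clades
    if (
        isinstance(entries_per_clade, tuple)
        and len(entries_per_clade) == 2
        and all(isinstance(x, int) for x in entries_per_clade)
    ):
        lo, hi = entries_per_clade
        if lo > hi or lo < 1:
            raise ValueError(f"invalid clade size range {entries_per_clade}")
        return list(rng.integers(lo, hi + 1, n_clades))
    sizes = list(entries_per_clade)
    if len(sizes) != n_clades:
        raise ValueError(
            f"explicit clade sizes ({len(sizes)}) must match n_clades ({n_clades})"
        )
    return [int(s) for s in sizes]


def make_world(
    n_clades: int = 5,
    entries_per_clade: int | tuple[int, int] | Sequence[int] = 6,
    genome_length: int | tuple[int, int] = (1000, 3000),
    fraction_incomplete: float = 0.0,
    fraction_nonvertebrate: float = 0.0,
    fraction_ambiguous: float = 0.0,
    seed: int = 0,
    plant_kmer_len: int = 0,
) -> SyntheticWorld:
    """Generate a synthetic annotated genome set.

    ``entries_per_clade`` is a fixed count, an inclusive (lo, hi) range
    drawn per clade, or an explicit per-clade size list. Each annotation
    flag is an independent seeded Bernoulli draw at the requested rate:
    incompleteness from stream ``[seed, 2]``, non-vertebrate host from
    ``[seed, 3]`` and ambiguity (one planted N) from ``[seed, 4]``;
    clade sizes use ``[seed, 0]`` and sequences ``[seed, 1]``. The
    per-stream layout is part of the contract, so a test can replay any
    draw independently with ``numpy.random.default_rng([seed, k])``.

    Identical arguments and seed give a byte-identical world.
    """
    for frac_name, frac in (
        ("fraction_incomplete", fraction_incomplete),
        ("fraction_nonvertebrate", fraction_nonvertebrate),
        ("fraction_ambiguous", fraction_ambiguous),
    ):
        if not 0 <= frac <= 1:
            raise ValueError(f"{frac_name} must be in [0, 1], got {frac}")
    if n_clades < 1:
        raise ValueError("n_clades must be >= 1")
    if isinstance(genome_length, int):
        genome_length = (genome_length, genome_length)
    lo, hi = genome_length
    if lo > hi or lo < 1:
        raise ValueError(f"empty genome length range {genome_length}")

    rng_sizes = np.random.default_rng([seed, 0])
    rng_seq = np.random.default_rng([seed, 1])
    sizes = _clade_sizes(entries_per_clade, n_clades, rng_sizes)
    n_records = sum(sizes)

    incomplete = np.random.default_rng([seed, 2]).random(n_records) < fraction_incomplete
    nonvert = np.random.default_rng([seed, 3]).random(n_records) < fraction_nonvertebrate
    ambiguous = np.random.default_rng([seed, 4]).random(n_records) < fraction_ambiguous
    rng_ambig_pos = np.random.default_rng([seed, 5])

    records: list[ReferenceRecord] = []
    taxonomy: dict[str, TaxonomyEntry] = {}
    idx = 0
    for c, size in enumerate(sizes, start=1):
        kmer = None
        if plant_kmer_len > 0:
            kmer = bytes(_BASES[rng_seq.integers(0, 4, plant_kmer_len)]).decode()
        for j in range(1, size + 1):
            idx += 1
            acc = f"SYN_{idx:06d}"
            length = int(rng_seq.integers(lo, hi + 1))
            seq = bytes(_BASES[rng_seq.integers(0, 4, length)]).decode()
            if kmer and length >= len(kmer):
                seq = kmer + seq[len(kmer):]
            if ambiguous[idx - 1]:
                pos = int(rng_ambig_pos.integers(0, length))
                seq = seq[:pos] + "N" + seq[pos + 1:]
            # zero-padded names keep no species a prefix of another, so
            # escaped-name patterns can never match two species
            species = f"Synthetic virus {c:03d}-{j:03d}"
            genus = f"Syngenus {c:03d}"
            family = f"Synviridae {c:03d}"
            host = "other" if nonvert[idx - 1] else "vertebrate"
            name = f"{species} isolate {acc}, complete genome"
            records.append(
                ReferenceRecord(
                    accession=acc,
                    description=name,
                    sequence=seq,
                    is_complete=not incomplete[idx - 1],
                    host_class=host,
                    species=species,
                    genus=genus,
                    family=family,
                )
            )
            taxonomy[acc] = TaxonomyEntry(name, species, genus, family, host)
    return SyntheticWorld(records=tuple(records), taxonomy=taxonomy, seed=seed)


def make_contaminant_pool(
    n_human: int = 3,
    n_other: int = 5,
    genome_length: int | tuple[int, int] = (2000, 5000),
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Synthetic contaminant source pools (human, non-human).

    Returns two accession -> sequence mappings in the ``SYNHUM_`` /
    ``SYNCON_`` namespaces, for use as the contaminant background of
    generated datasets.
    """
    if isinstance(genome_length, int):
        genome_length = (genome_length, genome_length)
    lo, hi = genome_length
    rng = np.random.default_rng([seed, 10])

    def pool(prefix: str, n: int) -> dict[str, str]:
        out = {}
        for i in range(1, n + 1):
            length = int(rng.integers(lo, hi + 1))
            out[f"{prefix}_{i:04d}"] = bytes(_BASES[rng.integers(0, 4, length)]).decode()
        return out

    return pool("SYNHUM", n_human), pool("SYNCON", n_other)


def species_stand_ins(
    species: Sequence[str],
    genome_length: int | tuple[int, int] = (5000, 30000),
    seed: int = 0,
    family: str = "Synviridae",
) -> tuple[dict[str, str], dict[str, str], AccessionResolver]:
    """Synthetic one-strain-per-species genomes for a named species list.

    Returns (species -> accession, accession -> sequence, resolver).
    Used to instantiate the built-in challenge designs when no real
    curated test set is at hand.
    """
    if isinstance(genome_length, int):
        genome_length = (genome_length, genome_length)
    lo, hi = genome_length
    rng = np.random.default_rng([seed, 20])
    spec_to_acc: dict[str, str] = {}
    sequences: dict[str, str] = {}
    table: dict[str, tuple] = {}
    for i, sp in enumerate(species, start=1):
        acc = f"SYNSP_{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        spec_to_acc[sp] = acc
        sequences[acc] = bytes(_BASES[rng.integers(0, 4, length)]).decode()
        table[acc] = (f"{sp} strain {acc}, complete genome", sp, family)
    return spec_to_acc, sequences, AccessionResolver(table)


def make_submission(
    manifest: GroundTruthManifest,
    sensitivity: float,
    n_false_positives: int,
    decoy_pool: Sequence[str],
    seed: int = 0,
    world: SyntheticWorld | None = None,
    read_length: int = 150,
    default_genome_size: int = 30000,
) -> list[VirusMetricsRow]:
    """Fabricate a participant submission with known performance.

    Reports ``round(sensitivity x n_true_viruses)`` of the manifest's
    viral accessions (a seeded uniform choice) with read counts taken
    from the manifest, plus ``n_false_positives`` decoy accessions, all
    with report = 1. Scoring such a submission against the manifest's
    expected species must recover the planted sensitivity and a
    precision of TP/(TP + n_false_positives).
    """
    if not 0 <= sensitivity <= 1:
        raise ValueError("sensitivity must be in [0, 1]")
    if n_false_positives < 0:
        raise ValueError("n_false_positives must be >= 0")
    if len(decoy_pool) < n_false_positives:
        raise ValueError(
            f"decoy pool ({len(decoy_pool)}) smaller than requested "
            f"false positives ({n_false_positives})"
        )
    truth_counts = manifest.viral_read_counts()
    truth = sorted(truth_counts)
    overlap = set(decoy_pool) & set(truth)
    if overlap:
        raise ValueError(f"decoy accessions overlap the truth set: {sorted(overlap)}")
    n_tp = int(math.floor(sensitivity * len(truth) + 0.5))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(truth, size=n_tp, replace=False)) if n_tp else []
    decoys = sorted(rng.choice(sorted(decoy_pool), size=n_false_positives, replace=False))

    sizes = (
        {r.accession: len(r.sequence) for r in world.records} if world is not None else {}
    )
    names = (
        {acc: t.species for acc, t in world.taxonomy.items()} if world is not None else {}
    )

    rows: list[VirusMetricsRow] = []
    for acc in chosen:
        gsize = sizes.get(acc, default_genome_size)
        reads = truth_counts[acc]
        rows.append(
            VirusMetricsRow(
                virus=names.get(acc, acc),
                database_id=acc,
                number_of_reads=reads,
                percent_coverage=min(100.0, 100.0 * reads * read_length / gsize),
                genome_size=gsize,
                report=1,
            )
        )
    for acc in decoys:
        gsize = sizes.get(acc, default_genome_size)
        reads = int(rng.integers(1, 20))
        rows.append(
            VirusMetricsRow(
                virus=names.get(acc, acc),
                database_id=acc,
                number_of_reads=reads,
                percent_coverage=min(100.0, 100.0 * reads * read_length / gsize),
                genome_size=gsize,
                report=1,
            )
        )
    return rows
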