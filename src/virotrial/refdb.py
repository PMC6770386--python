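"""Curation of a common viral reference database for a ring trial.

The curation pipeline turns a raw set of annotated viral genome records
into a clean, clade-balanced database split into a training set (handed
to participants) and a test set (kept back to generate blinded in-silico
challenge datasets). The steps are:

1. :func:`filter_records` — keep only complete genomes from vertebrate
   hosts with no ambiguous nucleotides;
2. :func:`build_clades` — group records one taxonomic rank above their
   most specific known rank (species-level records by genus, genus-level
   records by family);
3. :func:`enforce_clade_sizes` — drop clades with fewer than two entries
   and randomly down-sample clades above the cap (default 20);
4. :func:`split_train_test` — within each clade, send every fifth entry
   (in canonical accession order) to the test set.

:func:`curate` chains the four steps and records provenance counts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceRecord",
    "CladeIndex",
    "CuratedDatabase",
    "filter_records",
    "build_clades",
    "enforce_clade_sizes",
    "split_train_test",
    "curate",
    "export_database",
    "load_records",
]

HOST_CLASSES = ("vertebrate", "other", "unknown")

#: matches any character that is not an unambiguous nucleotide
_AMBIGUOUS = re.compile(r"[^ACGTacgt]")

#: drop-log keys, in the order the criteria are applied; a record is
#: charged to the FIRST criterion it fails
DROP_CRITERIA = ("incomplete", "nonvertebrate_host", "ambiguous_nucleotides")


@dataclass(frozen=True)
class ReferenceRecord:
    """One annotated genome entry — the unit of database curation.

    Completeness and host class come from the annotation table, not from
    parsing the free-text description. Taxonomic ranks may be empty
    strings when the record is not classified at that rank.
    """

    accession: str
    description: str
    sequence: str
    is_complete: bool
    host_class: str
    species: str = ""
    genus: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) == 0:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        if self.host_class not in HOST_CLASSES:
            raise ValueError(
                f"{self.accession}: host_class {self.host_class!r} "
                f"not one of {HOST_CLASSES}"
            )

    @property
    def has_ambiguous(self) -> bool:
        return bool(_AMBIGUOUS.search(self.sequence))


@dataclass(frozen=True)
class CladeIndex:
    """Mapping from clade key to the accessions it contains.

    Clade keys are prefixed with the grouping rank (``genus:`` or
    ``family:``) so that a genus and a family sharing a name can never
    collide. Records with no usable rank live in ``unclassified`` and
    take no further part in curation.
    """

    clades: Mapping[str, tuple[str, ...]]
    unclassified: tuple[str, ...] = ()

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.clades.items()}

    def accessions(self) -> list[str]:
        return [a for v in self.clades.values() for a in v]

    def __len__(self) -> int:
        return len(self.clades)


@dataclass(frozen=True)
class CuratedDatabase:
    """Result of the full curation: disjoint train/test record sets."""

    train: tuple[ReferenceRecord, ...]
    test: tuple[ReferenceRecord, ...]
    clades: CladeIndex
    provenance: dict = field(default_factory=dict)

    @property
    def records(self) -> tuple[ReferenceRecord, ...]:
        return self.train + self.test

    def record_map(self) -> dict[str, ReferenceRecord]:
        return {r.accession: r for r in self.records}


def filter_records(
    records: Sequence[ReferenceRecord],
) -> tuple[list[ReferenceRecord], dict[str, int]]:
    """Apply the three admission criteria, in order.

    A record must (i) be a complete genome, (ii) have a vertebrate host
    and (iii) contain no ambiguous nucleotides (any character outside
    A/C/G/T, case-insensitively). Dropped records are counted against the
    first criterion they fail, so the drop log partitions the dropped set.

    Returns
    -------
    kept, drop_log
        ``kept`` preserves input order; ``drop_log`` has one count per
        criterion in :data:`DROP_CRITERIA`.
    """
    drop_log = dict.fromkeys(DROP_CRITERIA, 0)
    kept: list[ReferenceRecord] = []
    for rec in records:
        if not rec.is_complete:
            drop_log["incomplete"] += 1
        elif rec.host_class != "vertebrate":
            drop_log["nonvertebrate_host"] += 1
        elif rec.has_ambiguous:
            drop_log["ambiguous_nucleotides"] += 1
        else:
            kept.append(rec)
    return kept, drop_log


def build_clades(records: Sequence[ReferenceRecord]) -> CladeIndex:
    """Group records one taxonomic rank above their most specific rank.

    Records known to the species level are grouped by genus; records
    known only to the genus level are grouped by family. A record whose
    grouping rank is itself unannotated (for example, known only to the
    family level, or a species with no genus) cannot be placed and is
    routed to the unclassified bin.
    """
    clades: dict[str, list[str]] = {}
    unclassified: list[str] = []
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
        if rec.species and rec.genus:
            key = f"genus:{rec.genus}"
        elif not rec.species and rec.genus and rec.family:
            key = f"family:{rec.family}"
        else:
            unclassified.append(rec.accession)
            continue
        clades.setdefault(key, []).append(rec.accession)
    return CladeIndex(
        clades={k: tuple(v) for k, v in clades.items()},
        unclassified=tuple(unclassified),
    )


def enforce_clade_sizes(
    clades: CladeIndex,
    min_size: int = 2,
    cap: int = 20,
    seed: int = 0,
) -> tuple[CladeIndex, dict[str, int]]:
    """Drop undersized clades and randomly cap oversized ones.

    Clades with fewer than ``min_size`` entries are removed entirely.
    Clades above ``cap`` are reduced to exactly ``cap`` entries drawn
    uniformly at random without replacement (seeded); the excess is
    discarded. Clades already within bounds pass through unchanged.

    Returns the new index and a log with ``clades_dropped``,
    ``records_dropped`` and ``records_capped_away`` counts.
    """
    if min_size > cap:
        raise ValueError(f"min_size ({min_size}) must not exceed cap ({cap})")
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[str, ...]] = {}
    log = {"clades_dropped": 0, "records_dropped": 0, "records_capped_away": 0}
    for key in sorted(clades.clades):
        members = clades.clades[key]
        if len(members) < min_size:
            log["clades_dropped"] += 1
            log["records_dropped"] += len(members)
            continue
        if len(members) > cap:
            idx = rng.choice(len(members), size=cap, replace=False)
            log["records_capped_away"] += len(members) - cap
            members = tuple(members[i] for i in sorted(idx))
        out[key] = members
    return CladeIndex(clades=out, unclassified=clades.unclassified), log


def split_train_test(
    clades: CladeIndex,
    records: Mapping[str, ReferenceRecord] | Sequence[ReferenceRecord],
    period: int = 5,
) -> CuratedDatabase:
    """Split each clade into train and test by the every-Nth rule.

    Within each clade, entries are put in a canonical order
    (lexicographic by accession) and every ``period``-th entry (the 5th,
    10th, ... in 1-based position) goes to the test set; all others go to
    the training set. Clades are processed in sorted key order. The split
    is applied per clade so that every sufficiently large clade
    contributes test-set material for challenge generation.
    """
    if period < 2:
        raise ValueError("period must be at least 2")
    if not isinstance(records, Mapping):
        records = {r.accession: r for r in records}
    train: list[ReferenceRecord] = []
    test: list[ReferenceRecord] = []
    for key in sorted(clades.clades):
        for pos, acc in enumerate(sorted(clades.clades[key]), start=1):
            (test if pos % period == 0 else train).append(records[acc])
    prov = {
        "period": period,
        "train_size": len(train),
        "test_size": len(test),
    }
    return CuratedDatabase(
        train=tuple(train), test=tuple(test), clades=clades, provenance=prov
    )


def curate(
    records: Sequence[ReferenceRecord],
    min_size: int = 2,
    cap: int = 20,
    period: int = 5,
    seed: int = 0,
) -> CuratedDatabase:
    """Run the full curation pipeline and collect provenance counts."""
    kept, drop_log = filter_records(records)
    clades = build_clades(kept)
    clades, size_log = enforce_clade_sizes(clades, min_size=min_size, cap=cap, seed=seed)
    record_map = {r.accession: r for r in kept}
    db = split_train_test(clades, record_map, period=period)
    prov = {
        "input": len(records),
        "filtered": drop_log,
        "unclassifiable": len(clades.unclassified),
        **size_log,
        **db.provenance,
        "min_size": min_size,
        "cap": cap,
        "seed": seed,
    }
    return CuratedDatabase(
        train=db.train, test=db.test, clades=db.clades, provenance=prov
    )


# --- I/O -----------------------------------------------------------------

DATABASE_VARIANTS = ("viral", "contaminant", "human")


def _to_seqrecord(rec: ReferenceRecord) -> SeqRecord:
    # accession first in the header, description after it
    return SeqRecord(Seq(rec.sequence), id=rec.accession, description=rec.description)


def export_database(
    db: CuratedDatabase,
    variant: str,
    path: str | Path,
    which: str = "train",
    contaminant_records: Sequence[ReferenceRecord] = (),
    human_records: Sequence[ReferenceRecord] = (),
    provenance_path: str | Path | None = None,
) -> int:
    """Write one variant of the curated database as FASTA.

    Variants mirror the three distributed flavours: ``viral`` (reference
    viral sequences only), ``contaminant`` (viral plus non-target
    contaminant sequences) and ``human`` (viral plus human sequences).
    Headers carry the accession first. Returns the number of sequences
    written; optionally writes the provenance counts as JSON.
    """
    if variant not in DATABASE_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {DATABASE_VARIANTS}"
        )
    if which not in ("train", "test", "all"):
        raise ValueError(f"which must be train/test/all, got {which!r}")
    base = db.train if which == "train" else db.test if which == "test" else db.records
    records = list(base)
    if variant == "contaminant":
        records += list(contaminant_records)
    elif variant == "human":
        records += list(human_records)
    n = SeqIO.write([_to_seqrecord(r) for r in records], str(path), "fasta")
    if provenance_path is not None:
        Path(provenance_path).write_text(json.dumps(db.provenance, indent=2))
    return n


def load_records(
    fasta_path: str | Path, annotations_path: str | Path
) -> list[ReferenceRecord]:
    """Read records from a FASTA file plus a tab-separated annotation table.

    The annotation table must have columns ``accession``, ``is_complete``
    (0/1 or true/false), ``host_class``, ``species``, ``genus``,
    ``family``. Every FASTA entry must be annotated.
    """
    import pandas as pd

    ann = pd.read_csv(annotations_path, sep="\t", dtype=str).fillna("")
    ann.columns = [c.strip().lower() for c in ann.columns]
    required = {"accession", "is_complete", "host_class"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    table = ann.set_index("accession")
    records = []
    for seq in SeqIO.parse(str(fasta_path), "fasta"):
        acc = seq.id
        if acc not in table.index:
            raise ValueError(f"no annotation for FASTA entry {acc!r}")
        row = table.loc[acc]
        records.append(
            ReferenceRecord(
                accession=acc,
                description=seq.description.removeprefix(acc).strip(),
                sequence=str(seq.seq),
                is_complete=str(row["is_complete"]).strip().lower()
                in ("1", "true", "yes"),
                host_class=str(row["host_class"]).strip().lower(),
                species=str(row.get("species", "")),
                genus=str(row.get("genus", "")),
                family=str(row.get("family", "")),
            )
        )
    return records
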