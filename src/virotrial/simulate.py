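"""Design and generation of ground-truthed in-silico challenge datasets.

Each artificial dataset mixes reads from a handful of target viruses
(drawn from the held-back test set of the curated database) into a fixed
contaminant background: 54% of reads are of human origin, 45% of
non-human contaminant origin, and 1% of viral origin. Per-virus read
budgets are defined at 150 bp and normalised across sequencing settings
so that the *viral information* — reads of viral origin times read
length — is identical whether a participant asks for 1x100, 2x250 or
anything in between. Serial dilutions divide the viral budgets and are
re-generated from the source sequences, never subsampled from the
undiluted dataset; "high mutation" variants multiply the substitution
rate of the read simulator.

Reads are produced by a built-in Illumina-like simulator: uniform start
positions and strands, i.i.d. per-base substitution errors at a tunable
rate, a linearly decaying quality profile, and (for paired layouts)
proper mate pairs from a truncated normal fragment-length distribution.
FASTQ headers are opaque sequential tokens; the true origin of every
read lives only in the :class:`GroundTruthManifest`, the answer key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._util import derive_seed, round_half_away

__all__ = [
    "ReadSettings",
    "ChallengeDesign",
    "Composition",
    "GroundTruthManifest",
    "SimulatedRead",
    "ReadBatch",
    "STANDARD_SETTINGS",
    "CHALLENGE_II_SPECIES",
    "CHALLENGE_III_SPECIES",
    "compose_counts",
    "generate_reads",
    "generate_dataset",
    "dilution_series",
    "builtin_challenges",
    "write_fastq",
    "design_from_yaml",
    "design_to_yaml",
]

CATEGORIES = ("viral", "human_contaminant", "other_contaminant")

_SETTINGS_TOKEN = re.compile(r"^\s*([12])\s*[x×X]\s*(\d+)\s*$")


@dataclass(frozen=True)
class ReadSettings:
    """One sequencing configuration: single/paired layout and read length."""

    layout: str
    read_length: int

    def __post_init__(self) -> None:
        if self.layout not in ("single", "paired"):
            raise ValueError(f"layout must be 'single' or 'paired', got {self.layout!r}")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")

    @property
    def mates(self) -> int:
        return 2 if self.layout == "paired" else 1

    @property
    def token(self) -> str:
        """Canonical settings token, e.g. ``'2x150'``."""
        return f"{self.mates}x{self.read_length}"

    @classmethod
    def from_token(cls, token: str) -> "ReadSettings":
        """Parse ``'1x100'``, ``'2 × 250'``, ``'2X150'`` and friends."""
        m = _SETTINGS_TOKEN.match(token)
        if not m:
            raise ValueError(f"cannot parse settings token {token!r}")
        return cls(
            layout="paired" if m.group(1) == "2" else "single",
            read_length=int(m.group(2)),
        )


#: the six setting combinations offered to participants
STANDARD_SETTINGS: tuple[ReadSettings, ...] = tuple(
    ReadSettings(layout, length)
    for layout in ("single", "paired")
    for length in (100, 150, 250)
)


@dataclass(frozen=True)
class ChallengeDesign:
    """Recipe for one artificial dataset.

    ``virus_sources`` lists (accession, reads-per-virus) pairs with the
    budget expressed at 150 bp single-end; :func:`compose_counts`
    rescales it to other settings. ``dilution`` is the denominator of
    the dilution ratio (40 for a 1:40 dilution). Composition fractions
    default to the fixed 54% human / 45% other / 1% viral background.
    """

    name: str
    virus_sources: tuple[tuple[str, int], ...]
    dilution: float = 1.0
    mutation_level: str = "normal"
    viral_fraction: float = 0.01
    human_fraction: float = 0.54
    other_fraction: float = 0.45
    settings_list: tuple[ReadSettings, ...] = STANDARD_SETTINGS
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.viral_fraction + self.human_fraction + self.other_fraction
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"composition fractions sum to {total}, expected 1")
        if self.dilution < 1:
            raise ValueError("dilution denominator must be >= 1")
        if self.mutation_level not in ("normal", "high"):
            raise ValueError("mutation_level must be 'normal' or 'high'")
        for acc, budget in self.virus_sources:
            if budget < 0:
                raise ValueError(f"{acc}: reads_per_virus_at_150bp must be >= 0")


@dataclass(frozen=True)
class Composition:
    """Per-source read counts for one (design, settings) combination.

    Counts are stored in *fragments* (a fragment is a read for
    single-end layouts and a proper pair for paired layouts) so that
    paired datasets always contain whole pairs; ``*_reads`` properties
    convert to FASTQ records (mates).
    """

    settings: ReadSettings
    per_virus_fragments: Mapping[str, int]
    human_fragments: int
    other_fragments: int

    @property
    def viral_fragments(self) -> int:
        return sum(self.per_virus_fragments.values())

    @property
    def total_fragments(self) -> int:
        return self.viral_fragments + self.human_fragments + self.other_fragments

    @property
    def per_virus_reads(self) -> dict[str, int]:
        m = self.settings.mates
        return {a: m * f for a, f in self.per_virus_fragments.items()}

    @property
    def viral_reads(self) -> int:
        return self.settings.mates * self.viral_fragments

    @property
    def human_reads(self) -> int:
        return self.settings.mates * self.human_fragments

    @property
    def other_reads(self) -> int:
        return self.settings.mates * self.other_fragments

    @property
    def total_reads(self) -> int:
        return self.settings.mates * self.total_fragments

    def fractions(self) -> dict[str, float]:
        n = self.total_reads
        return {
            "viral": self.viral_reads / n,
            "human_contaminant": self.human_reads / n,
            "other_contaminant": self.other_reads / n,
        }


def compose_counts(design: ChallengeDesign, settings: ReadSettings) -> Composition:
    """Derive per-source read counts for a design at given settings.

    The per-virus budget ``r`` (defined at 150 bp) becomes
    ``round(r * 150 / (mates * L) / dilution)`` fragments at read length
    ``L``, which keeps the viral bases — reads times read length, both
    mates of a pair counting — identical across settings. The total is
    then sized so the viral fraction hits its target: total fragments
    ``N = round(V / viral_fraction)``, human fragments
    ``round(human_fraction * N)``, and the non-human contaminant count
    absorbs the rounding remainder.
    """
    m, L = settings.mates, settings.read_length
    per_virus = {
        acc: round_half_away(budget * 150.0 / (m * L) / design.dilution)
        for acc, budget in design.virus_sources
    }
    v = sum(per_virus.values())
    if v <= 0:
        raise ValueError(f"{design.name}: design yields no viral reads")
    total = round_half_away(v / design.viral_fraction)
    human = round_half_away(design.human_fraction * total)
    other = total - v - human
    if other < 0:
        raise ValueError(f"{design.name}: negative contaminant count ({other})")
    return Composition(
        settings=settings,
        per_virus_fragments=per_virus,
        human_fragments=human,
        other_fragments=other,
    )


# --- read generation -----------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(accession: str, sequence: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError(
            f"{accession}: source sequence contains non-ACGT characters"
        )
    return arr


class SimulatedRead(NamedTuple):
    read_id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class ReadBatch:
    """In-memory FASTQ content: one list per mate file."""

    settings: ReadSettings
    mate1: tuple[SimulatedRead, ...]
    mate2: tuple[SimulatedRead, ...] | None = None

    @property
    def n_records(self) -> int:
        return len(self.mate1) + (len(self.mate2) if self.mate2 else 0)


@dataclass(frozen=True)
class GroundTruthManifest:
    """The hidden answer key: true origin of every emitted read.

    One row per FASTQ record (each mate of a pair counts), with the
    anonymised read id, source accession, category (viral /
    human_contaminant / other_contaminant), 0-based start of the read's
    window on the forward strand of the source, strand and mate number.
    """

    entries: pd.DataFrame

    _COLUMNS = ("read_id", "source_accession", "category", "source_start", "strand", "mate")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        ids = self.entries["read_id"]
        if ids.duplicated().any():
            raise ValueError("manifest read ids are not unique")

    @property
    def n_reads(self) -> int:
        return len(self.entries)

    def category_totals(self) -> dict[str, int]:
        counts = self.entries["category"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in CATEGORIES}

    def viral_read_counts(self) -> dict[str, int]:
        """FASTQ records per viral source accession."""
        viral = self.entries[self.entries["category"] == "viral"]
        return {k: int(v) for k, v in viral["source_accession"].value_counts().items()}

    def viral_accessions(self) -> list[str]:
        return sorted(self.viral_read_counts())

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruthManifest":
        return cls(pd.read_csv(path, sep="\t", dtype={"read_id": str}))

    def summary(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "category_totals": self.category_totals(),
            "viral_read_counts": self.viral_read_counts(),
        }


def _rows_to_reads(ids: list[str], mat: np.ndarray, quality: str) -> list[SimulatedRead]:
    decoded = _DECODE[mat]
    return [
        SimulatedRead(rid, bytes(row).decode("ascii"), quality)
        for rid, row in zip(ids, decoded)
    ]


def generate_reads(
    sources: Mapping[str, str],
    counts: Mapping[str, int] | Composition,
    settings: ReadSettings,
    error_rate: float = 0.002,
    mutation_level: str = "normal",
    seed: int = 0,
    categories: Mapping[str, str] | None = None,
    high_factor: float = 2.0,
    fragment_mean: float = 350.0,
    fragment_sd: float = 35.0,
    shuffle: bool = True,
    id_prefix: str = "R",
) -> tuple[ReadBatch, GroundTruthManifest]:
    """Simulate reads from source sequences and record their true origin.

    Start positions are uniform over valid windows and strands uniform;
    substitution errors are i.i.d. per base at ``error_rate``
    (``high_factor`` times that under the high mutation level); no
    indels are introduced. Paired layouts draw a fragment length from a
    normal distribution truncated to [read length, source length] and
    emit proper innie mate pairs. Read ids are opaque sequential tokens
    assigned after a seeded shuffle of all fragments, so file order
    leaks nothing about origin.

    ``counts`` maps accession to *fragment* count (or is a
    :class:`Composition`, in which case only its per-virus counts are
    used and all sources are treated as viral unless ``categories`` says
    otherwise). Every counted accession must have a source sequence at
    least one read (single) or one fragment (paired) long.
    """
    if isinstance(counts, Composition):
        counts = dict(counts.per_virus_fragments)
    if mutation_level not in ("normal", "high"):
        raise ValueError("mutation_level must be 'normal' or 'high'")
    rate = error_rate * (high_factor if mutation_level == "high" else 1.0)
    if not 0 <= rate < 1:
        raise ValueError(f"effective substitution rate {rate} outside [0, 1)")
    categories = dict(categories or {})
    L = settings.read_length
    paired = settings.layout == "paired"
    rng = np.random.default_rng(seed)

    acc_list: list[str] = []
    m1_parts: list[np.ndarray] = []
    m2_parts: list[np.ndarray] = []
    start1_parts: list[np.ndarray] = []
    start2_parts: list[np.ndarray] = []
    strand1_parts: list[np.ndarray] = []

    offsets = np.arange(L)
    for acc in sorted(counts):
        n = int(counts[acc])
        if n < 0:
            raise ValueError(f"{acc}: negative read count")
        if n == 0:
            continue
        if acc not in sources:
            raise ValueError(f"no source sequence for accession {acc!r}")
        seq = _encode(acc, sources[acc])
        glen = len(seq)
        if glen < L:
            raise ValueError(
                f"source {acc!r} ({glen} bp) is shorter than the read length ({L} bp)"
            )
        if paired:
            flen = np.clip(
                np.rint(rng.normal(fragment_mean, fragment_sd, n)).astype(np.int64),
                L,
                glen,
            )
            starts = np.floor(rng.random(n) * (glen - flen + 1)).astype(np.int64)
            ends = starts + flen
            flip = rng.integers(0, 2, n).astype(bool)  # fragment from minus strand
            fwd = seq[starts[:, None] + offsets]
            rev = 3 - seq[(ends[:, None] - L) + offsets][:, ::-1]
            # innie pair: one mate reads the + strand from the fragment's
            # left end, the other the - strand from its right end; `flip`
            # decides which is mate 1
            m1 = np.where(flip[:, None], rev, fwd)
            m2 = np.where(flip[:, None], fwd, rev)
            start1 = np.where(flip, ends - L, starts)
            start2 = np.where(flip, starts, ends - L)
            m1_parts.append(m1)
            m2_parts.append(m2)
            start1_parts.append(start1)
            start2_parts.append(start2)
            strand1_parts.append(flip)
        else:
            starts = rng.integers(0, glen - L + 1, n)
            strands = rng.integers(0, 2, n).astype(bool)
            windows = seq[starts[:, None] + offsets]
            reads = np.where(strands[:, None], 3 - windows[:, ::-1], windows)
            m1_parts.append(reads)
            start1_parts.append(starts)
            strand1_parts.append(strands)
        acc_list.extend([acc] * n)

    if not acc_list:
        raise ValueError("no reads requested")

    m1 = np.concatenate(m1_parts)
    start1 = np.concatenate(start1_parts)
    strand1 = np.concatenate(strand1_parts)
    accessions = np.asarray(acc_list)
    n_frag = len(accessions)

    if paired:
        m2 = np.concatenate(m2_parts)
        start2 = np.concatenate(start2_parts)

    # planted substitution errors (drawn after all sampling, one stream)
    if rate > 0:
        for mat in (m1, m2) if paired else (m1,):
            mask = rng.random(mat.shape) < rate
            shifts = rng.integers(1, 4, int(mask.sum()), dtype=np.uint8)
            mat[mask] = (mat[mask] + shifts) % 4

    order = rng.permutation(n_frag) if shuffle else np.arange(n_frag)
    width = max(6, len(str(n_frag)))
    ids = [f"{id_prefix}{i + 1:0{width}d}" for i in range(n_frag)]

    quality = "".join(
        chr(33 + q) for q in np.linspace(40, 25, L).round().astype(int)
    )

    cat = np.asarray([categories.get(a, "viral") for a in accessions])
    if paired:
        batch = ReadBatch(
            settings=settings,
            mate1=tuple(_rows_to_reads(ids, m1[order], quality)),
            mate2=tuple(_rows_to_reads(ids, m2[order], quality)),
        )
        frames = []
        for mate, starts_m, strands_m in (
            (1, start1, strand1),
            (2, start2, ~strand1),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": [f"{i}/{mate}" for i in ids],
                        "source_accession": accessions[order],
                        "category": cat[order],
                        "source_start": starts_m[order],
                        "strand": np.where(strands_m[order], "-", "+"),
                        "mate": mate,
                    }
                )
            )
        manifest = GroundTruthManifest(pd.concat(frames, ignore_index=True))
    else:
        batch = ReadBatch(
            settings=settings,
            mate1=tuple(_rows_to_reads(ids, m1[order], quality)),
        )
        manifest = GroundTruthManifest(
            pd.DataFrame(
                {
                    "read_id": ids,
                    "source_accession": accessions[order],
                    "category": cat[order],
                    "source_start": start1[order],
                    "strand": np.where(strand1[order], "-", "+"),
                    "mate": 1,
                }
            )
        )
    return batch, manifest


@dataclass(frozen=True)
class DatasetResult:
    design: ChallengeDesign
    composition: Composition
    batch: ReadBatch
    manifest: GroundTruthManifest


def generate_dataset(
    design: ChallengeDesign,
    settings: ReadSettings,
    viral_sources: Mapping[str, str],
    human_sources: Mapping[str, str],
    other_sources: Mapping[str, str],
    error_rate: float = 0.002,
    seed: int | None = None,
    **kwargs,
) -> DatasetResult:
    """Generate one full challenge dataset: viruses plus contaminants.

    Contaminant fragments are spread over the supplied pools — each
    human fragment picks a human source uniformly at random, likewise
    for non-human contaminants — and every read's true source and
    category are recorded in the manifest.
    """
    if seed is None:
        seed = design.seed
    comp = compose_counts(design, settings)
    counts: dict[str, int] = dict(comp.per_virus_fragments)
    categories = {acc: "viral" for acc in counts}
    alloc = np.random.default_rng(derive_seed(seed, 1))
    for pool, total, category in (
        (human_sources, comp.human_fragments, "human_contaminant"),
        (other_sources, comp.other_fragments, "other_contaminant"),
    ):
        if total == 0:
            continue
        keys = sorted(pool)
        if not keys:
            raise ValueError(f"no {category} sources supplied but {total} reads needed")
        picks = np.bincount(alloc.integers(0, len(keys), total), minlength=len(keys))
        for key, k in zip(keys, picks):
            if k:
                counts[key] = counts.get(key, 0) + int(k)
                categories[key] = category
    sources = {**viral_sources, **human_sources, **other_sources}
    batch, manifest = generate_reads(
        sources,
        counts,
        settings,
        error_rate=error_rate,
        mutation_level=design.mutation_level,
        seed=derive_seed(seed, 0),
        categories=categories,
        **kwargs,
    )
    return DatasetResult(design=design, composition=comp, batch=batch, manifest=manifest)


def dilution_series(
    base: ChallengeDesign,
    factors: Sequence[float],
    high_variants: Sequence[float] = (),
) -> list[ChallengeDesign]:
    """Expand a base design into a serial-dilution family.

    For each factor F a design named ``<base>_1-<F>`` is produced with
    the viral budgets divided by F; factors listed in ``high_variants``
    additionally yield a ``_high`` design with the elevated mutation
    level. Each design gets an independent seed derived from the base
    seed, so dilutions are re-generated from the sources rather than
    subsampled from the undiluted dataset.
    """
    if any(f < 1 for f in factors):
        raise ValueError("dilution factors must be >= 1")
    designs: list[ChallengeDesign] = []
    for f in factors:
        fname = f"{base.name}_1-{f:g}"
        designs.append(
            replace(
                base,
                name=fname,
                dilution=base.dilution * f,
                mutation_level="normal",
                seed=derive_seed(base.seed, len(designs)),
            )
        )
        if f in high_variants:
            designs.append(
                replace(
                    base,
                    name=f"{fname}_high",
                    dilution=base.dilution * f,
                    mutation_level="high",
                    seed=derive_seed(base.seed, len(designs)),
                )
            )
    return designs


#: species targeted by the two built-in challenges; one strain of each is
#: planted per dataset
CHALLENGE_II_SPECIES: tuple[str, ...] = (
    "Human mastadenovirus A",
    "Human coronavirus HKU1",
    "Severe acute respiratory syndrome-related coronavirus",
    "Influenza B virus",
    "Human respirovirus 1",
    "Human rubulavirus 4",
    "Human orthopneumovirus",
    "Human metapneumovirus",
    "Norwalk virus",
    "Rotavirus A",
    "Hepacivirus C",
)

CHALLENGE_III_SPECIES: tuple[str, ...] = (
    "Human betaherpesvirus 5",
    "Human alphaherpesvirus 1",
    "Human betaherpesvirus 6A",
    "Parechovirus A",
    "Human alphaherpesvirus 3",
    "JC virus",
    "BK virus",
)


class ConfigurationError(ValueError):
    """A design cannot be instantiated from the supplied database."""


def builtin_challenges(
    species_to_accession: Mapping[str, str],
    seed: int = 2018,
) -> tuple[ChallengeDesign, ChallengeDesign]:
    """Instantiate the two built-in challenge designs.

    Challenge II plants 11 respiratory/enteric/blood-borne virus species
    at ~2000 reads/virus (150 bp scale); challenge III plants 7
    herpes/polyoma/picornavirus species at ~500 reads/virus.
    ``species_to_accession`` supplies one strain per listed species —
    typically from the curated test set, or synthetic stand-ins.
    """
    missing = [
        s
        for s in CHALLENGE_II_SPECIES + CHALLENGE_III_SPECIES
        if s not in species_to_accession
    ]
    if missing:
        raise ConfigurationError(f"database lacks a strain for: {missing}")
    ii = ChallengeDesign(
        name="II",
        virus_sources=tuple(
            (species_to_accession[s], 2000) for s in CHALLENGE_II_SPECIES
        ),
        seed=derive_seed(seed, 2),
    )
    iii = ChallengeDesign(
        name="III",
        virus_sources=tuple(
            (species_to_accession[s], 500) for s in CHALLENGE_III_SPECIES
        ),
        seed=derive_seed(seed, 3),
    )
    return ii, iii


# --- I/O -----------------------------------------------------------------


def write_fastq(
    batch: ReadBatch, out_dir: str | Path, name: str
) -> list[Path]:
    """Write a read batch as FASTQ (mate files suffixed _1/_2).

    Returns the written paths; the file stem is
    ``<name>_<settings token>``, e.g. ``II_1-40_2x100``.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{name}_{batch.settings.token}"
    paths: list[Path] = []
    mates = [batch.mate1] if batch.mate2 is None else [batch.mate1, batch.mate2]
    for i, reads in enumerate(mates, start=1):
        suffix = f"_{i}" if batch.mate2 is not None else ""
        path = out_dir / f"{stem}{suffix}.fastq"
        records = [
            SeqRecord(
                Seq(r.sequence),
                id=r.read_id,
                description="",
                letter_annotations={
                    "phred_quality": [ord(c) - 33 for c in r.quality]
                },
            )
            for r in reads
        ]
        seqio_write(records, str(path), "fastq")
        paths.append(path)
    return paths


def design_to_yaml(design: ChallengeDesign, path: str | Path) -> None:
    import yaml

    data = {
        "name": design.name,
        "viruses": [
            {"accession": a, "reads_per_virus_at_150bp": b}
            for a, b in design.virus_sources
        ],
        "dilution": design.dilution,
        "mutation_level": design.mutation_level,
        "viral_fraction": design.viral_fraction,
        "human_fraction": design.human_fraction,
        "other_fraction": design.other_fraction,
        "settings": [s.token for s in design.settings_list],
        "seed": design.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def design_from_yaml(path: str | Path) -> ChallengeDesign:
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    return ChallengeDesign(
        name=data["name"],
        virus_sources=tuple(
            (v["accession"], int(v["reads_per_virus_at_150bp"]))
            for v in data["viruses"]
        ),
        dilution=float(data.get("dilution", 1.0)),
        mutation_level=data.get("mutation_level", "normal"),
        viral_fraction=float(data.get("viral_fraction", 0.01)),
        human_fraction=float(data.get("human_fraction", 0.54)),
        other_fraction=float(data.get("other_fraction", 0.45)),
        settings_list=tuple(
            ReadSettings.from_token(t)
            for t in data.get("settings", [s.token for s in STANDARD_SETTINGS])
        ),
        seed=int(data.get("seed", 0)),
    )
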