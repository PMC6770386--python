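"""Scoring of participant submissions against expected positives.

A participant submits, per sample, a "virus metrics" table with one row
per identified virus: name, database accession, number of mapped reads,
percent (breadth of) coverage, genome size, a 0/1 report flag and a free
comment. Scoring is species-level:

* the accession of every *reported* row (report = 1) is resolved to a
  full virus name through an offline accession table;
* the name is matched, case-insensitively, against per-species regular
  expression synonym patterns describing the expected positives;
* true positives / false negatives are counted over expected species
  (several reported strains of one species collapse to a single TP),
  and non-matching reported identities are false positives;
* sensitivity = TP/(TP+FN), precision = TP/(TP+FP), and the F1 score is
  their harmonic mean;
* per-virus depth of coverage is estimated as
  ``reads x average read length / genome size`` and summarised per
  sample by the harmonic mean over the reported viruses.

Precision and F1 are *undefined* — serialised as null, never coerced to
zero — when nothing was reported; F1 is likewise undefined for negative
samples (no expected positives), which are summarised by their false
positive count and family breakdown instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml
from scipy.stats import hmean

__all__ = [
    "VirusMetricsRow",
    "ExpectedVirusPattern",
    "SampleScore",
    "AccessionResolver",
    "MetricsFormatError",
    "AmbiguousPatternError",
    "ParseResult",
    "parse_metrics",
    "resolve_name",
    "match_expected",
    "score_sample",
    "depth_of_coverage",
    "sample_mean_depth",
    "fp_families",
    "load_patterns",
    "save_patterns",
    "builtin_patterns",
]


class MetricsFormatError(ValueError):
    """The metrics file header cannot be mapped to the canonical columns."""


class AmbiguousPatternError(ValueError):
    """One virus name matches the patterns of two different species."""


@dataclass(frozen=True)
class VirusMetricsRow:
    """One row of a participant's per-sample virus metrics table."""

    virus: str
    database_id: str
    number_of_reads: int
    percent_coverage: float
    genome_size: int
    report: int
    comment: str = ""

    def __post_init__(self) -> None:
        if self.number_of_reads < 0:
            raise ValueError("number_of_reads must be >= 0")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be > 0")
        if not 0 <= self.percent_coverage <= 100:
            raise ValueError("percent_coverage must be in [0, 100]")
        if self.report not in (0, 1):
            raise ValueError("report must be 0 or 1")


@dataclass(frozen=True)
class ExpectedVirusPattern:
    """Synonym patterns for one expected species.

    ``patterns`` are regular expressions matched case-insensitively
    (search semantics) against resolved virus names; they enumerate the
    names and subtypes under which laboratories report the species.
    """

    species_label: str
    patterns: tuple[str, ...]
    family: str = ""

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"{self.species_label}: needs at least one pattern")
        for p in self.patterns:
            re.compile(p)  # raises re.error on an invalid pattern

    def compiled(self) -> list[re.Pattern]:
        return [re.compile(p, re.IGNORECASE) for p in self.patterns]


class Resolved(NamedTuple):
    """Outcome of an accession lookup; ``name`` is None when unresolved."""

    accession: str
    name: str | None
    species: str | None = None
    family: str | None = None


class AccessionResolver:
    """Offline accession -> (name, species, family) lookup table.

    Stands in for a live taxonomy/nomenclature query so that scoring is
    fully reproducible without network access. Backed by a plain dict;
    can be loaded from a tab-separated table with columns
    ``accession``, ``name``, ``species``, ``family``.
    """

    def __init__(self, table: Mapping[str, tuple]) -> None:
        self._table: dict[str, Resolved] = {}
        for acc, value in table.items():
            padded = (list(value) + [None, None])[:3]
            self._table[acc] = Resolved(acc, padded[0], padded[1], padded[2])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AccessionResolver":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        df.columns = [c.strip().lower() for c in df.columns]
        if "accession" not in df.columns or "name" not in df.columns:
            raise ValueError("resolver table needs 'accession' and 'name' columns")
        return cls(
            {
                row["accession"]: (
                    row["name"],
                    row.get("species") or None,
                    row.get("family") or None,
                )
                for _, row in df.iterrows()
            }
        )

    def resolve(self, accession: str) -> Resolved:
        return self._table.get(accession, Resolved(accession, None))

    def __contains__(self, accession: str) -> bool:
        return accession in self._table

    def __len__(self) -> int:
        return len(self._table)


def resolve_name(database_id: str, resolver: AccessionResolver) -> Resolved:
    """Resolve an accession to a full virus name.

    Never fatal: an accession absent from the table comes back with
    ``name=None`` and is later counted as a false positive (it cannot be
    matched to any expected species), with a warning on the score.
    """
    return resolver.resolve(database_id)


def match_expected(
    name: str, patterns: Sequence[ExpectedVirusPattern]
) -> str | None:
    """Map a virus name to the expected species it belongs to, if any.

    Returns the species label of the (unique) expected species whose
    patterns match, or None for a candidate false positive. A name
    matching two different species indicates a defective pattern file
    and raises :class:`AmbiguousPatternError`.
    """
    hits = [
        exp.species_label
        for exp in patterns
        if any(rx.search(name) for rx in exp.compiled())
    ]
    unique = sorted(set(hits))
    if len(unique) > 1:
        raise AmbiguousPatternError(
            f"name {name!r} matches patterns of several species: {unique}"
        )
    return unique[0] if unique else None


def depth_of_coverage(
    number_of_reads: int, average_read_length: float, genome_size: int
) -> float:
    """Estimated fold-coverage: reads x average read length / genome size.

    Linear in read count and read length, inverse in genome size; the
    exact quotient is returned, never truncated.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    return number_of_reads * average_read_length / genome_size


def sample_mean_depth(per_virus_depths: Sequence[float]) -> float | None:
    """Harmonic mean depth across the reported viruses of one sample.

    Undefined (None) for an empty list or when any depth is zero — the
    harmonic mean does not exist in either case.
    """
    depths = list(per_virus_depths)
    if not depths or any(d == 0 for d in depths):
        return None
    return float(hmean(depths))


@dataclass(frozen=True)
class SampleScore:
    """Species-level detection performance for one (pipeline, sample) cell."""

    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    precision: float | None
    f1: float | None
    per_virus_depth: Mapping[str, float]
    harmonic_mean_depth: float | None
    fp_families: Mapping[str, int]
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "per_virus_depth": dict(self.per_virus_depth),
            "harmonic_mean_depth": self.harmonic_mean_depth,
            "fp_families": dict(self.fp_families),
            "warnings": list(self.warnings),
        }


def score_sample(
    rows: Sequence[VirusMetricsRow],
    expected: Sequence[ExpectedVirusPattern],
    resolver: AccessionResolver,
    average_read_length: float = 150.0,
) -> SampleScore:
    """Score one submission against the expected positives of one sample.

    Only rows with ``report == 1`` enter the evaluation. TP and FN are
    counted over expected species (TP + FN = number of expected
    species); reported species-level identities matching no expected
    pattern are FP, de-duplicated at the species level where the
    resolver provides one. ``average_read_length`` is the declared read
    length of the sample's sequencing settings, used by the depth
    estimate.
    """
    reported = [r for r in rows if r.report == 1]
    warnings: list[str] = []
    found: set[str] = set()
    fp_identities: dict[str, str] = {}  # identity key -> family (or "unknown")
    depths: dict[str, float] = {}
    for row in reported:
        res = resolve_name(row.database_id, resolver)
        depths[row.database_id] = depth_of_coverage(
            row.number_of_reads, average_read_length, row.genome_size
        )
        if res.name is None:
            warnings.append(
                f"accession {row.database_id!r} could not be resolved; counted as FP"
            )
            fp_identities[f"<unresolved:{row.database_id}>"] = "unknown"
            continue
        label = match_expected(res.name, expected)
        if label is not None:
            found.add(label)
        else:
            identity = res.species or res.name
            fp_identities[identity] = res.family or "unknown"

    tp = len(found)
    fp = len(fp_identities)
    fn = len(expected) - tp
    sensitivity = tp / (tp + fn) if expected else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    if not expected or precision is None:
        f1 = None
    elif sensitivity + precision == 0:
        f1 = 0.0
    else:
        f1 = 2 * sensitivity * precision / (sensitivity + precision)

    families: dict[str, int] = {}
    for fam in fp_identities.values():
        families[fam] = families.get(fam, 0) + 1

    return SampleScore(
        tp=tp,
        fp=fp,
        fn=fn,
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        per_virus_depth=depths,
        harmonic_mean_depth=sample_mean_depth(list(depths.values())),
        fp_families=families,
        warnings=tuple(warnings),
    )


def fp_families(
    fp_rows: Sequence[VirusMetricsRow], resolver: AccessionResolver
) -> dict[str, int]:
    """Group false-positive species by family for cross-pipeline comparison.

    Distinct species of the same family count separately; unresolved
    accessions are grouped under ``"unknown"``. The counts always sum to
    the number of distinct false-positive identities.
    """
    identities: dict[str, str] = {}
    for row in fp_rows:
        res = resolver.resolve(row.database_id)
        if res.name is None:
            identities[f"<unresolved:{row.database_id}>"] = "unknown"
        else:
            identities[res.species or res.name] = res.family or "unknown"
    out: dict[str, int] = {}
    for fam in identities.values():
        out[fam] = out.get(fam, 0) + 1
    return out


# --- metrics-file parsing ------------------------------------------------

#: canonical columns of the virus metrics table
CANONICAL_COLUMNS = (
    "virus",
    "database_id",
    "number_of_reads",
    "percent_coverage",
    "genome_size",
    "report",
    "comment",
)

REQUIRED_COLUMNS = CANONICAL_COLUMNS[:5]

#: header alias table: normalised header (lower-case, alphanumerics only)
#: -> canonical column. Covers the case/spacing/typo variants observed in
#: real submissions.
HEADER_ALIASES: dict[str, str] = {
    "virus": "virus",
    "virusname": "virus",
    "organism": "virus",
    "databaseid": "database_id",
    "database": "database_id",
    "accession": "database_id",
    "accessionnumber": "database_id",
    "ncbiaccession": "database_id",
    "id": "database_id",
    "numberofreads": "number_of_reads",
    "numreads": "number_of_reads",
    "nreads": "number_of_reads",
    "readcount": "number_of_reads",
    "reads": "number_of_reads",
    "numberreads": "number_of_reads",
    "percentcoverage": "percent_coverage",
    "percentcoverag": "percent_coverage",
    "coverage": "percent_coverage",
    "pctcoverage": "percent_coverage",
    "perccoverage": "percent_coverage",
    "breadthofcoverage": "percent_coverage",
    "genomesize": "genome_size",
    "genomelength": "genome_size",
    "genomesizebp": "genome_size",
    "report": "report",
    "reported": "report",
    "comment": "comment",
    "comments": "comment",
    "note": "comment",
}

#: comment phrases that force report = 0 ("considered as not reported")
NOT_REPORTED_KEYWORDS = ("uninterpretable", "cannot be excluded")


class RowError(NamedTuple):
    row_index: int
    message: str


@dataclass(frozen=True)
class ParseResult:
    rows: tuple[VirusMetricsRow, ...]
    errors: tuple[RowError, ...] = ()


def _normalise_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.strip().lower())


def parse_metrics(
    path_or_buffer,
    report_accessions: Iterable[str] | None = None,
    not_reported_keywords: Sequence[str] = NOT_REPORTED_KEYWORDS,
) -> ParseResult:
    """Parse a virus metrics file into canonical rows.

    Header variants (case, spacing, common typos) are normalised through
    :data:`HEADER_ALIASES`. When the file has no ``report`` column — as
    in first-increment submissions — the flag is inferred from
    ``report_accessions``, the accession list extracted from the
    participant's clinical report; rows whose comment contains a
    non-reporting phrase ("uninterpretable", "cannot be excluded") are
    forced to report = 0 either way. Malformed rows are collected in a
    row-level error log, never silently dropped.
    """
    df = pd.read_csv(path_or_buffer, sep=None, engine="python", dtype=str)
    mapping: dict[str, str] = {}
    unmatched: list[str] = []
    for col in df.columns:
        canon = HEADER_ALIASES.get(_normalise_header(col))
        if canon is None:
            unmatched.append(col)
        elif canon not in mapping.values():
            mapping[col] = canon
    df = df.rename(columns=mapping)[list(mapping.values())]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetricsFormatError(
            f"unrecognizable header set: missing {missing}; "
            f"unmatched columns {unmatched}"
        )

    has_report = "report" in df.columns
    if not has_report and report_accessions is None:
        raise MetricsFormatError(
            "no 'report' column and no reported-accession list supplied"
        )
    reported_set = set(report_accessions) if report_accessions is not None else None

    rows: list[VirusMetricsRow] = []
    errors: list[RowError] = []
    for i, rec in df.iterrows():
        try:
            acc = str(rec["database_id"]).strip()
            comment = str(rec.get("comment") or "").strip()
            if comment.lower() == "nan":
                comment = ""
            if has_report:
                raw = str(rec["report"]).strip()
                report = int(float(raw)) if raw not in ("", "nan") else 0
            else:
                report = int(acc in reported_set)
            if comment and any(
                kw.lower() in comment.lower() for kw in not_reported_keywords
            ):
                report = 0
            rows.append(
                VirusMetricsRow(
                    virus=str(rec["virus"]).strip(),
                    database_id=acc,
                    number_of_reads=int(float(rec["number_of_reads"])),
                    percent_coverage=float(rec["percent_coverage"]),
                    genome_size=int(float(rec["genome_size"])),
                    report=report,
                    comment=comment,
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            errors.append(RowError(int(i), str(exc)))
    return ParseResult(rows=tuple(rows), errors=tuple(errors))


def write_metrics_csv(rows: Sequence[VirusMetricsRow], path: str | Path) -> None:
    """Write rows in the canonical virus-metrics CSV dialect."""
    pd.DataFrame(
        [
            {
                "Virus": r.virus,
                "database_ID": r.database_id,
                "Number_of_reads": r.number_of_reads,
                "percent_coverage": r.percent_coverage,
                "genome_size": r.genome_size,
                "Report": r.report,
                "comment": r.comment,
            }
            for r in rows
        ]
    ).to_csv(path, index=False)


# --- pattern files -------------------------------------------------------


def load_patterns(path: str | Path) -> list[ExpectedVirusPattern]:
    """Load expected-positive patterns from a YAML file.

    Format: a list of mappings with keys ``species``, ``family``
    (optional) and ``patterns`` (list of regexes).
    """
    data = yaml.safe_load(Path(path).read_text())
    return [
        ExpectedVirusPattern(
            species_label=entry["species"],
            patterns=tuple(entry["patterns"]),
            family=entry.get("family", ""),
        )
        for entry in data
    ]


def save_patterns(patterns: Sequence[ExpectedVirusPattern], path: str | Path) -> None:
    data = [
        {"species": p.species_label, "family": p.family, "patterns": list(p.patterns)}
        for p in patterns
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


#: synonym patterns for the two built-in in-silico challenges; regexes
#: enumerate the common names, abbreviations and older nomenclature under
#: which each species is reported
_CHALLENGE_PATTERNS: dict[str, list[tuple[str, str, tuple[str, ...]]]] = {
    "II": [
        ("Human mastadenovirus A", "Adenoviridae",
         (r"mastadenovirus A", r"adenovirus (12|18|31)", r"\bHAdV-?A\b")),
        ("Human coronavirus HKU1", "Coronaviridae", (r"HKU1",)),
        ("Severe acute respiratory syndrome-related coronavirus", "Coronaviridae",
         (r"SARS", r"severe acute respiratory syndrome")),
        ("Influenza B virus", "Orthomyxoviridae", (r"influenza ?B",)),
        ("Human respirovirus 1", "Paramyxoviridae",
         (r"respirovirus 1", r"parainfluenza virus 1", r"\bHPIV-?1\b")),
        ("Human rubulavirus 4", "Paramyxoviridae",
         (r"rubulavirus 4", r"parainfluenza virus 4", r"\bHPIV-?4\b")),
        ("Human orthopneumovirus", "Pneumoviridae",
         (r"orthopneumovirus", r"respiratory syncytial virus", r"\bh?RSV\b")),
        ("Human metapneumovirus", "Pneumoviridae",
         (r"metapneumovirus", r"\bh?MPV\b")),
        ("Norwalk virus", "Caliciviridae", (r"Norwalk", r"norovirus")),
        ("Rotavirus A", "Reoviridae", (r"rotavirus A",)),
        ("Hepacivirus C", "Flaviviridae", (r"hepacivirus C", r"hepatitis C", r"\bHCV\b")),
    ],
    "III": [
        ("Human betaherpesvirus 5", "Herpesviridae",
         (r"betaherpesvirus 5", r"\bHHV-?5\b", r"\bCMV\b", r"cytomegalovirus")),
        ("Human alphaherpesvirus 1", "Herpesviridae",
         (r"alphaherpesvirus 1", r"herpes simplex virus (type )?1", r"\bHSV-?1\b")),
        ("Human betaherpesvirus 6A", "Herpesviridae",
         (r"betaherpesvirus 6A", r"\bHHV-?6A\b")),
        ("Parechovirus A", "Picornaviridae", (r"parechovirus A", r"human parechovirus")),
        ("Human alphaherpesvirus 3", "Herpesviridae",
         (r"alphaherpesvirus 3", r"varicella", r"\bVZV\b", r"\bHHV-?3\b")),
        ("JC virus", "Polyomaviridae", (r"\bJC\b", r"JC polyomavirus")),
        ("BK virus", "Polyomaviridae", (r"\bBK\b", r"BK polyomavirus")),
    ],
}


def builtin_patterns(challenge: str) -> list[ExpectedVirusPattern]:
    """Expected-positive pattern sets for the built-in challenges II and III."""
    if challenge not in _CHALLENGE_PATTERNS:
        raise ValueError(f"unknown challenge {challenge!r}; expected 'II' or 'III'")
    return [
        ExpectedVirusPattern(species_label=s, patterns=p, family=f)
        for s, f, p in _CHALLENGE_PATTERNS[challenge]
    ]
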