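# Methods

This note records the models, conventions and numerical choices behind
`virotrial`, in the order a trial runs: database curation, challenge
design, read simulation, scoring, orchestration — and what the
synthetic fixtures do and do not emulate.

## Database curation (`refdb`)

**Admission filters.** A record is admitted if it (i) is annotated as a
complete genome, (ii) has a vertebrate host and (iii) contains no
ambiguous nucleotides. "Ambiguous" is read strictly: any character
outside A/C/G/T, case-insensitively (so IUPAC codes, N and gaps all
disqualify). Completeness and host class are taken from the annotation
table, never inferred from the free-text description — annotation
screening is cheap, reproducible, and matches how such repositories are
actually queried. Dropped records are charged to the *first* criterion
they fail, in the order above, so the drop log partitions the input.

**Clade grouping.** Records are grouped one taxonomic rank above their
most specific known rank: species-level records by genus, genus-only
records by family. The annotation schema carries species/genus/family
only, so a record known only to the family level (or a species with no
genus) has no rank to group by; it goes to an explicit unclassified bin
with a logged count rather than being silently dropped or guessed.

**Size enforcement.** Clades with fewer than 2 entries are removed
(a one-entry clade cannot contribute to both a training and a test
set); clades above 20 entries are reduced to exactly 20 by a seeded
uniform draw without replacement. Both bounds are parameters
(`min_size`, `cap`).

**Train/test split.** Within each clade, entries are ordered
lexicographically by accession and every 5th (1-based positions 5, 10,
15, …) goes to the test set. Two choices here were genuinely open:

* *Ordering.* No canonical entry order exists for "every fifth entry";
  lexicographic accession order inside sorted clade keys makes the
  split a pure function of the record set.
* *Per clade, not global.* Splitting per clade guarantees that every
  clade of ≥ 5 entries contributes held-back test sequences, which the
  challenge generator needs (its viruses must come from sequences the
  participants never received). A global split could leave whole clades
  without test representation.

A clade of 4 or fewer entries contributes no test entries (4/5 of 20 →
16 train/4 test; 4 → 4 train/0 test).

## Challenge design (`simulate`)

**Composition.** Every artificial dataset is 1% viral, 54% human
contaminant and 45% other (bacterial/fungal/phage) contaminant reads.
The viral side is specified first — per-virus budgets — and the total
is sized from it: total fragments `N = round(V / viral_fraction)`,
human fragments `round(0.54 N)`, and the other-contaminant count is the
remainder, absorbing all rounding. This keeps the achieved fractions
within 1/N of their targets.

**Cross-setting normalisation.** Per-virus budgets are declared at
150 bp. At read length L with m mates, the fragment budget is
`round(r × 150 / (m·L) / dilution)`, so viral *bases* (reads × length,
both mates of a pair counting) are invariant across the six offered
settings within ±1 read of per-virus rounding — e.g. a 1×150 dataset
carries 67% of the viral reads of its 1×100 counterpart. Working in
fragments (pairs for paired layouts) ensures paired datasets always
contain whole pairs. Counting both mates' bases for paired data is a
convention of this package; the alternative (counting insert coverage)
would double paired budgets.

**Rounding.** All count derivations round half away from zero, stated
so that diluted budgets are reproducible: a ~2000/virus budget at 1:400
gives round(5.0) = 5 reads/virus, and a 1:40 gives 50.

**Dilution series.** `dilution_series` multiplies the design's dilution
denominator and derives an independent child seed per design (numpy
`SeedSequence` spawning), so each dilution re-draws reads from the
sources. Dilutions are therefore *not* subsamples of the undiluted
dataset — positions, strands and errors are fresh.

**Built-in designs.** Challenge II: 11 species at 2000 reads/virus with
its 1:1 / 1:40 / 1:40-high / 1:400 family. Challenge III: 7 species at
500 reads/virus with 1:1 / 1:10 / 1:10-high / 1:100. Both require a
database supplying one strain per species and fail loudly, listing the
absentees, otherwise.

## Read simulation

The simulator is deliberately minimal — an Illumina-like substitution
model whose one important property is a *tunable* mutation rate:

* start positions uniform over valid windows, strand uniform;
* i.i.d. per-base substitutions at `error_rate` (default 0.002,
  a plausible Illumina-order base-call error rate; every planted error
  is a uniformly random different base);
* `mutation_level="high"` multiplies the rate by `high_factor`
  (default 2) — "elevated mutation" is defined relative to normal, and
  the factor is configurable because no absolute value is canonical;
* paired fragments ~ Normal(mean 350 bp, sd 35 bp), rounded and clipped
  to [read length, source length], innie orientation, mate roles
  swapped with probability ½;
* base quality is a fixed linear decay Q40 → Q25 along the read
  (cosmetic: the model does not couple errors to quality);
* no indels, no GC/coverage bias, no duplicates, no platform profiles.

Read ids are opaque sequential tokens (`R000001`, `/1`–`/2` per mate in
the manifest) assigned after a seeded shuffle of all fragments, so
neither header nor file order leaks read origin. The manifest records,
per FASTQ record, the source accession, category, 0-based window start
on the forward strand, strand and mate — enough to map every zero-error
read back exactly, which is the simulator's self-consistency oracle.

Determinism: a (sources, counts, settings, rate, seed) tuple yields
byte-identical FASTQ and manifest.

## Scoring (`score`)

Scoring is species-level and accession-driven: the reported virus
*name* column is ignored (laboratories often report clinician-friendly,
coarser names), and the accession is resolved to a full name through an
offline table, then matched case-insensitively against per-species
regex synonym patterns. Conventions:

* only rows with report = 1 are evaluated; comments containing
  "uninterpretable" or "cannot be excluded" force report = 0
  (configurable keyword list);
* metrics files without a report column (first-increment style) take
  the flag from a supplied reported-accession list;
* several reported strains matching one expected species are one TP;
  TP + FN always equals the number of expected species;
* a reported identity matching no pattern is an FP, de-duplicated by
  the resolver's species where available; FPs are summarised by family
  (distinct species of one family count separately);
* an accession absent from the resolver is an FP with a warning — it
  cannot be credited to any expected species;
* a name matching patterns of two different species is a pattern-file
  defect and raises, rather than being resolved arbitrarily;
* precision and F1 are undefined (null) when nothing is reported, and
  F1 is undefined for negative samples; when sensitivity and precision
  are both defined but both zero, F1 is 0;
* depth of coverage = reads × average read length / genome size, with
  the average read length taken from the sample's declared settings
  (computing it from FASTQ is possible but couples scoring to data
  files); the per-sample summary is the harmonic mean over reported
  viruses, undefined if any depth is 0 or none are reported.

One source-material ambiguity is worth recording: the trial protocol
this mirrors describes mapping *false negatives* to family level "to
compare the false positives" — self-contradictory on its face. The
family breakdown implemented here is of false positives, which is the
quantity actually compared across pipelines; no FN family mapping is
attempted.

## Orchestration (`trial`)

Blinded labels are a seeded uniform permutation of 1..N per increment
(label spaces are per-increment, so a label may recur across
increments). The participant-facing bundle manifest contains labels and
settings only; the answer key is written to a separate file embedding
the bundle manifest's SHA-256 so key and bundle can be re-associated
unambiguously. Submission file names follow
`<pipeline letter><sample number>[_<mates>x<length>].<ext>`, with the
settings token tolerant of spacing, case, and the typographic ×.
Missing cells in the batch report are flagged and stay null — an absent
submission is not a zero score. The common-vs-in-house database
comparison reports paired per-sample F1 plus a two-sided Mann–Whitney U
test (fully tied vectors short-circuit to U = nm/2, p = 1; fewer than
two comparable samples yield an insufficient-data flag instead of a
p-value).

## Synthetic fixtures: what they do and do not show

`fixtures.make_world` emulates only what curation consumes: records
with annotations (completeness, host class, three-rank taxonomy)
arranged in clades, with each annotation flag an independent seeded
Bernoulli draw at the requested rate. The per-stream seed layout
(`[seed, k]` for k = sizes, sequences, incomplete, host, ambiguity) is
part of the contract so tests can replay any draw. Sequences are i.i.d.
uniform nucleotides — clade grouping is annotation-driven, so sequence
realism buys nothing; an optional planted per-clade k-mer exists for
tests that want detectable shared sequence. Species names are
zero-padded (`Synthetic virus 003-002`) so no name is a prefix of
another and escaped-name patterns can never match two species.
Accessions use `SYN_`/`SYNHUM_`/`SYNCON_`/`SYNSP_` namespaces that
cannot collide with real repository accessions.

Consequently, passing tests demonstrate the *bookkeeping* is exact —
filters, splits, budgets, manifests, metrics — but say nothing about
detection difficulty on real data: no real genome composition,
phylogenetic relatedness, codon structure or database incompleteness is
modelled, and `make_submission` fabricates participant behaviour rather
than running any classification pipeline.

## Problem sizes and tolerances in the test suite

The suite exercises composition at 100,000 reads (the smallest size at
which the 1%/54%/45% split is exact to 1/N and still generates in
seconds), the error model at 10,000 × 100 bp reads against a 3-standard-
error binomial band, and end-to-end parameter recovery on 4-virus
manifests over 20 seeded repetitions × 8 (sensitivity, FP) settings.
Recovery assertions are exact, not approximate: the scorer must return
precisely the planted TP/FP/FN.

## Known limitations

* The read simulator is substitution-only; pipelines sensitive to
  indels or platform-specific error structure see an idealised input.
  An adapter shelling out to an external simulator can replace it where
  realism matters.
* The offline resolver only knows what its table contains; real trials
  need a pre-exported nomenclature dump (a live-lookup backend is a
  deliberate non-feature of the scoring path).
* Wet-lab arms of a trial (sample preparation, qPCR controls) and the
  participants' own pipelines are out of scope; the toolkit begins at
  reference records and FASTQ, and ends at score tables.
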