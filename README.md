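# virotrial

A toolkit for running ring trials (external quality assessments, EQA) in
**clinical viral metagenomics**: laboratories that diagnose viral
infections by shotgun sequencing of patient material need periodic
blinded proficiency tests to show their pipelines detect the right
viruses — and only those. `virotrial` provides the organiser's side of
such a trial:

* **Reference database curation** (`virotrial.refdb`) — from a set of
  annotated viral genome records, keep only complete genomes from
  vertebrate hosts without ambiguous nucleotides, group them into clades
  one taxonomic rank above their most specific known rank (species-level
  records by genus, genus-level by family), drop clades with fewer than
  2 entries, randomly cap clades at 20, and split every fifth entry per
  clade into a held-back test set. The training set becomes the common
  database handed to participants; the test set seeds the blinded
  challenges.
* **Challenge dataset simulation** (`virotrial.simulate`) — generate
  Illumina-like FASTQ datasets with a controlled composition of 54%
  human reads, 45% non-human contaminant reads and 1% viral reads.
  Per-virus budgets are set at 150 bp and normalised across sequencing
  settings (1×100 … 2×250) so the *viral information* — reads × read
  length — is identical in every setting. Serial dilutions and
  elevated-mutation variants are re-generated, never subsampled. The
  true origin of every read is masked in the FASTQ headers and kept in a
  ground-truth manifest.
* **Submission scoring** (`virotrial.score`) — parse participant
  "virus metrics" tables, resolve reported accessions to full virus
  names through an offline table, match names against per-species regex
  synonym patterns, and compute

  - sensitivity = TP / (TP + FN),
  - precision = TP / (TP + FP),
  - F1 = the harmonic mean of the two,
  - per-virus depth of coverage = reads × average read length / genome
    size, summarised per sample by its harmonic mean,

  with species-level resolution (several reported strains of one
  expected species are a single TP) and family-level grouping of false
  positives. Undefined quantities (nothing reported, negative sample)
  stay null — they are never coerced to zero.
* **Trial orchestration** (`virotrial.trial`) — blinded sample
  relabelling with a seeded permutation, answer-key custody separate
  from the participant bundle, file-naming validation
  (`B4_2x100.csv`-style), batch scoring across pipelines × samples ×
  databases, and a common-vs-in-house database comparison with a
  two-sided Mann–Whitney U test.
* **Synthetic fixtures** (`virotrial.fixtures`) — seeded generators for
  annotated genome worlds, contaminant pools, stand-in strains and
  participant submissions of *known* sensitivity/precision, so the whole
  toolkit runs and is tested without any download.

## Worked example

```python
from virotrial import fixtures, refdb, simulate, score

# a synthetic annotated genome set: 8 clades of 6 records each
world = fixtures.make_world(n_clades=8, entries_per_clade=6, seed=42)
db = refdb.curate(list(world.records), seed=42)

# a blinded challenge: 4 test-set viruses at 50 reads each (150 bp scale)
targets = [r.accession for r in db.test][:4]
human, other = fixtures.make_contaminant_pool(seed=42)
design = simulate.ChallengeDesign(
    name="demo", virus_sources=tuple((a, 50) for a in targets), seed=42
)
result = simulate.generate_dataset(
    design, simulate.ReadSettings("single", 150),
    world.sequences(), human, other,
)

# a participant who finds half the viruses and reports two spurious ones
rows = fixtures.make_submission(
    result.manifest, sensitivity=0.5, n_false_positives=2,
    decoy_pool=[r.accession for r in db.train[:6]], seed=42, world=world,
)
s = score.score_sample(rows, world.expected_patterns(targets), world.resolver())
```

This prints, step by step:

```text
curation: 40 train / 8 test records in 8 clades
dataset: 20000 reads, {'viral': 200, 'human_contaminant': 10800, 'other_contaminant': 9000}
score: TP=2 FP=2 FN=2 sensitivity=0.50 precision=0.50 F1=0.50 mean depth=0.68x
```

The 48 input records survive curation intact (all pass the admission
filters), each clade of 6 sends its 5th entry to the test set. The
generated dataset holds exactly 1% viral, 54% human and 45% other reads
(200 / 10 800 / 9 000 of 20 000). The fabricated half-sensitivity
submission scores TP=FP=FN=2, hence sensitivity, precision and F1 all
0.5 — the scorer recovers the planted performance exactly.

The same functionality is available from the shell:

```bash
virotrial curate --records genomes.fasta --annotations annot.tsv --seed 1 --out db/
virotrial make-challenge --design II.yaml --settings 2x150 \
    --viral-fasta db/test_viral.fasta --human-fasta human.fasta \
    --other-fasta contaminants.fasta --out challenge/
virotrial score --metrics A4.csv --expected expected.yaml --resolver resolver.tsv
virotrial trial plan --dataset II_1-1 --dataset III_1-1 --seed 4 --out trial/
```

## Built-in challenges

Two ready-made designs mirror a realistic proficiency test:
challenge **II** plants one strain of each of 11 respiratory / enteric /
blood-borne species (adenovirus A, coronaviruses HKU1 and SARS,
influenza B, parainfluenza 1 and 4, RSV, metapneumovirus, norovirus,
rotavirus A, HCV) at ~2000 reads/virus; challenge **III** plants 7
latent/persistent DNA-virus species (CMV, HSV-1, HHV-6A, parechovirus A,
VZV, JC, BK) at ~500 reads/virus. `simulate.dilution_series` expands
either into its 1:1 / diluted / high-mutation family, and
`score.builtin_patterns` supplies the matching synonym regexes.

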