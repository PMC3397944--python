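# Methods

## Scope and model of the data

`sagetag` treats digital gene expression as exact counting of 26-bp
transcript tags. A tag is the NlaIII-anchored (CATG) 26-mer nearest a
transcript's 3' end; tag abundance is proportional to transcript
abundance, and tag identity is resolved purely by perfect sequence match.
Three consequences shape the whole design:

- counting is a multiset tally, so all stages are order-independent and a
  fixed input yields byte-identical outputs;
- mapping is perfect-match only, on both strands. A 26-mer is long enough
  that random collisions against a ~10^8-bp genome are negligible, and
  excluding 1-mismatch neighbours avoids conflating sequencing error with
  allelic variation (polymorphic tags between X and Y^h alleles are a
  *signal* here, not noise);
- presence/absence of a tag in a sex type, rather than a formal
  differential test, is the unit of inference. No distributional test is
  attached; with two samples per sex type and no biological replication, a
  threshold rule is the honest statement of what the design supports.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `index_length` | 6 bases | exact barcode match, no error tolerance |
| `tag_length` | 26 bases | CATG + 22 variable bases (EcoP15I span) |
| `min_total` | 10 | keep tags with combined count > 10 (strict) |
| `window` | 2000 bp | upstream gene-association window |
| `upstream_allele` | 1000 bp | upstream span used for the X-allele search |
| `min_identity` | 0.80 | allele accepted when identity > 0.80 (strict) |
| `min_aligned` | 100 columns | guards against trivially short high-identity hits |
| `t_present` / `t_absent` | 5 / 0 | pooled per-sex presence thresholds |
| `nonsingleton_min` | 2 | count ≥ 2 makes a tag non-singleton |

Choices made where the procedure was genuinely open:

- **Anchor choice.** When a read contains several CATGs, the tag starts at
  the *first* occurrence at or after the index: the library chemistry
  ligates the adapter flush with the NlaIII site, so the first anchor is
  the ligated one.
- **Colorspace missing calls.** A '.' decodes to N and poisons every
  downstream base, because dibase decoding is a chain; any read containing
  N is discarded before counting, consistent with perfect-match mapping.
  The SOLiD primer base is not emitted in the decoded read.
- **"Upstream" is strand-aware**: tags sit near transcript 3' ends, so the
  gene body lies 5' of the anchor on the tag's matched strand. '-'-strand
  hits use the right flank, reverse-complemented on extraction. An
  unstranded mode (`unstranded_window`) covers both flanks for users who
  prefer the agnostic rule.
- **Gene association** uses any-overlap (≥1 bp) between the gene interval
  and the window; results are ordered by proximity to the anchor.
- **Presence calling** pools both stages of a sex type and compares the
  raw sum against `t_present`/`t_absent`. Raw counts are the default
  because the six library depths are of the same order; a CPM-normalised
  mode (`cpm_mode`) exists for unequal depths and is off by default for
  reproducibility. An ambiguous call in any sex type disqualifies the tag
  from the sex-dependent list (conservative: depth artifacts cannot
  promote a tag).
- **Category precedence.** A tag hitting sex + nuclear + organelle
  partitions simultaneously counts as `sex_plus_nuclear`. Multiple hits
  *within* one sex partition (tandem copies, overlapping BACs) remain
  partition-specific; hit multiplicity is reported, not collapsed.
- **X-activity denominator** is the sample's full extracted-tag total
  (pre-filter), so the ratio is a fraction of all transcription observed
  in that sample.

## Local alignment

The X-allele search uses Smith–Waterman with match +2, mismatch −1, linear
gap −2 (open = extend; affine costs with open ≠ extend are rejected rather
than silently approximated). N never matches. Identity is matches /
aligned columns, gaps counted as columns. Determinism is pinned down
explicitly: among co-optimal traceback predecessors diagonal wins, then
the query-consuming move, then the target-consuming one; among co-optimal
end cells the first in row-major order wins. The inner DP is a numba
kernel, so a 1-kb query against a 50-kb partition takes well under a
second; the scores are verified in the test suite against full
alignment-path enumeration on short pairs and against Biopython's
`PairwiseAligner` on random longer pairs.

## The simulator

`synthetic_data` emulates the study design, not sequencing physics. It
generates uniform-random partition backgrounds (X / Yh / other_nuclear /
organelle), plants unique CATG-anchored 26-mers for every category
(X-specific, Y^h-specific, shared, sex+nuclear, sex+organelle, non-SC),
places positive/negative gene models inside/outside the 2-kb upstream
windows, copies ~1 kb of Y^h upstream sequence into X at configured
per-base substitution rates (defaults 0.05 / 0.10 / 0.30, cycled — two
recoverable alleles and one beyond the 80% rule), and emits one pooled
lane of indexed reads. Counts are Poisson: each planted tag has mean 20
reads in every sample whose sex type its pattern includes, zero otherwise;
~200 background transcriptome tags with Zipf-like means fill each sample
to the configured depth (default 50,000 reads/sample); 5% junk reads cover
all discard reasons (bad index, no anchor, too short, N). A rejection +
verification pass guarantees every planted tag occurs *exactly* at its
recorded positions (both strands checked), so the truth table is exact
rather than probabilistic; generation retries with a derived seed on the
(rare) accidental collision.

Expression patterns follow the genetics of the system: Y^h-linked tags
appear in males and hermaphrodites (both carry a Y variant), never in
females; X-specific tags cycle through all-sex and one/two-sex patterns so
both arms of the sex-dependent selection are exercised.

With mean 20 per present cell and two samples per sex type, the pooled
present-sex expectation (≈40) is far above `t_present`=5 and absent cells
are exactly zero, so pattern recovery on simulated data is deterministic
in practice — the tests assert 100% recovery. What passing these tests
does **not** show: robustness to sequencing error inside tags, index
hopping, non-uniform genomic composition (repeats, GC skew), partial
transcript coverage, or biological replicate variance; real data adds all
of these, and the count filter plus perfect-match rule only partially
absorb them.

## Problem sizes used in tests and acceptance

The simulated study runs at the design scale: 6 samples × 50k reads, 25
planted tag sites, ~100 kb of reference. Oracle-equivalence checks use 100
random references of ~12 kb total with ≥200 planted/perturbed/
reverse-complement queries each; alignment correctness uses exhaustive
path enumeration over all pairs of length ≤ 3 (three-letter alphabet)
plus 300 seeded pairs of length 4–6 cross-checked against Biopython;
colorspace round-trips run on 10,000 random 50-mers; Poisson calibration
draws 1,000 seeded count vectors and checks the mean-20 tag stays within
4√20 of its mean in ≥99.9% of them.

## Known limitations

- Exact-index demultiplexing drops every read with a barcode error; fine
  for analysis fidelity, wasteful of reads.
- Tags falling across reference contig boundaries cannot map.
- The allele search reports the single best local alignment per X sequence
  and strand; tandem duplicated alleles on one sequence yield one hit.
- `nonsingleton_min` defaults to count ≥ 2 (the literal reading of
  "non-singleton"); it is exposed as a parameter because usage in the
  field varies between ≥ 2 and > 2.
- The functional-annotation step (BLASTX against protein databases) is out
  of scope; the pipeline exports the upstream query sequences
  (`upstream_windows.fasta`) for external annotation instead.
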