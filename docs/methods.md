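# Methods

This note documents the models, conventions and design choices behind
trarep: what the pipeline computes, what the simulator emulates, and what
the tests do and do not demonstrate about real data.

## The analysis model

A TCRα clonotype is identified by its TRAV gene, its TRAJ gene and the
deduced amino-acid CDR3, where the CDR3 spans the conserved cysteine at
IMGT position 104 through the conserved phenylalanine at position 118,
inclusive of both anchor residues (this equals the AIRR "junction" and is
labelled `junction`/`junction_aa` in outputs). Copy number is the count of
reads carrying an identical clonotype key in one sample; ranks order
clonotypes by descending copy number; percentage occurrence frequencies
divide copy counts by the productive counted reads.

Interpretations where the original description is silent:

- **Frequency denominator.** Frequencies are computed over productive
  counted reads, not all sequenced reads — only productive reads have a
  deduced CDR3, so the unique-read definition presupposes them.
  Nonproductive and failed reads are tallied separately (`n_failed_reads`)
  and excluded from counting. Frequencies are per-sample; pooling across
  samples is available via `merge_profiles`.
- **The glycine after Phe-118** is verified only when the read covers that
  codon; a read ending exactly at the phenylalanine is not penalized.
- **Clonotype identity is exact string equality** on normalized gene names
  and the amino-acid CDR3. No fuzzy CDR3 clustering or error correction is
  performed; nucleotide-level synonymous variants merge into one clonotype.
- **Gene-level resolution.** Allele suffixes (`*01`) are stripped; one
  sequence represents each gene. Mouse duplicate-locus suffixes (the "D"
  in TRAV8D-1) are opaque name text, except that invariant-receptor
  matching applies an alias table (default TRAV11D → TRAV11).

## Reference model

Each segment carries its anchor as explicit metadata (0-based offset of
the first base of the anchor codon) instead of recomputing IMGT gap
numbering — the anchors are the only numbering facts the pipeline needs.
Validation enforces: V anchor codon encodes C; J anchor codon encodes F
and the next codon encodes G; ACGT-only sequences; unique normalized
names. Coordinates are 0-based half-open throughout.

The mock reference builder generates random but fully valid segment sets
(V: ~150–180 nt before the anchor, 8–12 nt after; J: 8–12 nt before the
anchor, ~35–50 nt after), always including TRAV1, TRAV5-1, TRAV8D-1,
TRAV11, TRAJ18, TRAJ33, TRAJ37 and TRAJ49 when at least five of each
class are requested, so the headline and invariant clonotypes can be
simulated. The 15-nt bounds on segment ends around the anchors guarantee
a 300-nt read anchored at the amplicon 5' end covers the whole junction.
Real-data runs must supply their own reference snapshot (FASTA with
`name|class|anchor` headers, or plain FASTA plus a TSV anchor sidecar)
and should document its release.

## Simulator

The generator emulates merged single-end amplicon reads (paired-end
merging is modeled as already done). One sample is produced as follows:

1. **Abundances.** Clone frequencies follow a geometric law (successive
   clones decay by `abundance_param`) or a symmetric Dirichlet, sorted
   descending. Defaults: 200 clones, ratio 0.9 — the top clone holds ~10%
   of the repertoire and the top ten ~40%, i.e. a few dominant clonotypes
   over a long tail.
2. **Recombination.** Clone sequence = V trimmed at the 3' end (0–6 nt) +
   N-insert (0–9 nt) + J trimmed at the 5' end (0–6 nt). Trims never reach
   the anchors. By default clones are productive: the insert is redrawn
   (bounded retries) until the junction is in frame and stop-free. A
   stated fraction of deliberately out-of-frame clones can be injected
   (`nonproductive_fraction`, default 0). Clonotype keys are deduplicated
   at generation so the truth table is well defined.
3. **Spike-ins.** One MAIT clone (TRAV1–TRAJ33) and one iNKT clone
   (TRAV11–TRAJ18) at fixed frequency mass (default 5% each); the
   invariant V–J pairs are excluded from conventional draws so these
   proportions are exact.
4. **Reads.** Per-clone read counts are multinomial in the true
   frequencies (fixed sequencing yield per sample). Each read is the
   clone sequence truncated at 300 nt with i.i.d. substitutions at
   `error_rate` (default 1%), every mutated offset logged. Quality is a
   constant 'I'; indels, PCR bias, chimeras and UMIs are not modeled.
5. **Two-group design.** `round(shared_fraction × n_clones)` clones
   (default 30%) are planted identically in both samples and occupy the
   top abundance slots, the first two being TRAV8D-1/TRAJ49 and
   TRAV5-1/TRAJ37 — the generator's rendering of the dominant shared
   cross-reactive clonotypes. All other keys are kept distinct across
   samples, so the true intersection is exactly the planted set.

Randomness: one integer seed; per-sample generators are derived from
(seed, CRC32 of the sample name), so samples are independent but the whole
experiment is reproducible byte-for-byte.

What passing tests on these data do **not** show about real repertoires:
no indel or position-dependent error structure, no amplification bias, no
allele-level variation, uniform V/J usage among conventional clones, and
CDR3s capped near 15 residues by the 15-nt anchor-to-end bounds. Results
on simulated data bound algorithmic correctness, not wet-lab effects.

## Alignment and assignment

Local alignment uses Smith–Waterman with affine gaps (Gotoh), compiled
with numba. Scoring defaults: match +2, mismatch −1, gap open −4, gap
extend −1, where a gap of length L costs `open + (L−1)·extend`; `N`
scores as a mismatch against everything. Call acceptance requires score
≥ 40 and identity ≥ 0.85 (identity = matches / alignment columns); the
defaults tolerate ~1% error on ≥60-nt overlaps. Ties are broken by higher
identity, then lexicographically smaller gene name; the traceback starts
at the first maximal cell in row-major order and prefers diagonal steps,
so outputs are deterministic. The chosen V must start upstream of the
chosen J on the read; otherwise the lower-scoring call is dropped.

A 9-mer prefilter skips segments sharing no exact 9-mer with the read.
Whenever no prefiltered candidate passes the thresholds, the read is
re-scored against the full reference, so the filter cannot change a call
that the thresholds would accept. Identical read sequences are memoized.

Anchor mapping is strict: the three anchor-codon bases must map onto the
read inside one gap-free alignment block, otherwise the read fails with
`anchor_missing` — junction-proximal indels make frame inference
unreliable, so no repair is attempted. An anchor residue destroyed by a
sequencing error (first residue ≠ C, last ≠ F, or following residue ≠ G)
is also reported as `anchor_missing`; frame violations give
`out_of_frame`, internal stops `stop_codon`, and absent or sub-threshold
segments `no_v` / `no_j` / `low_score`.

## Numerical choices and degenerate inputs

- Geometric abundance weights are floored at 1e-300 before normalization
  so the frequency vector stays strictly positive when the decay
  underflows at large clone numbers.
- An empty productive set yields an empty profile (total 0), not an
  error; frequency computation on a zero total raises.
- Rank ties are broken by lexicographic clonotype key, making tables
  permutation-invariant.
- Frequencies sum to 100 within 1e-6 by construction; the V×J usage
  matrix sums to 100 over all cells.
- Shared-clonotype reports order entries by descending
  `min(freq_in_a, freq_in_b)`.

## Expected behavior under error

At 1% substitution error, V/J assignment is essentially unaffected
(segments are ~200 nt), but a ~24-nt CDR3 acquires a non-synonymous error
in roughly one read in five. Those reads found low-copy satellite
clonotypes rather than being corrected (exact-identity counting), so
exact clonotype-key recovery sits near 80%, per-clone frequencies are
underestimated by the same factor (within the 3·SE + 1 percentage-point
band at the default skew), and the clonotype-level intersection of two
samples can exceed the planted set through satellites recurring in both
samples. Sharing and table-equality guarantees are therefore stated — and
tested — at zero error.

## Problem sizes used in tests

The acceptance-style checks run the stated study conditions (200 clones ×
20,000 reads for the zero-error and 1%-error recovery checks; 10 clones ×
20,000 reads × 5 seeds for the two-group sharing check). The invariant
spike-in check uses 4,000 reads per run (spike frequency 5% leaves the
detection margin enormous at that depth), and unit/property tests use
smaller sizes; each test states its own configuration.
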