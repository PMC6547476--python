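# Methods

This note documents the models behind `fqarc`, the parameters that matter,
the synthetic data the test suite runs on, and the numerical choices that
make encoder and decoder bit-exact mirrors of each other.

## Stream decoupling

A FASTQ file is parsed as a strict sequence of 4-line records and split
column-wise into four streams: identifiers, sequences, plus lines,
qualities. Each stream is internally homogeneous, so a codec matched to its
statistics compresses it far better than any single model applied to the
interleaved file.

The plus stream is almost always redundant. It is classified once per file:

* `BARE` — every plus line is exactly `+` (the overwhelmingly common case);
  nothing is stored.
* `MIRROR` — every plus line repeats the record's identifier; regenerated
  from the identifier stream.
* `VERBATIM` — anything else; the comments are stored and compressed like
  identifiers. This fallback exists because regeneration is only sound for
  uniform files, and the archiver's contract is byte-exactness on
  *arbitrary* input.

Only strict 4-line FASTQ is accepted, and one newline convention (LF or
CRLF, recorded as an archive flag) must be used throughout; violations are
reported with byte offsets rather than silently "repaired", because any
repair would break the round-trip guarantee. The parser is an incremental
record iterator, so batch-oriented callers can stream files larger than
memory.

## Range coder

Both codecs share one integer-only arithmetic coder: a carry-less
byte-oriented range coder (Subbotin style) run on 64-bit `low`/`range`
registers. Bytes are emitted whenever the interval's top byte is pinned;
the range is forcibly renormalised below 2^48. Since cumulative totals are
kept under 2^40, the per-symbol truncation loss is below 2^-8 bits, and
measured payloads sit within a few bytes of the model entropy (the flush
costs a constant 8 bytes). Python integers are arbitrary precision, so the
wide registers cost nothing and buy a much tighter entropy bound than a
32-bit coder; probabilities are still quantized to 16 bits.

Two interfaces share the coder state: a binary interface (16-bit
probability of a 1 bit) for the quality codec, and a cumulative-frequency
interface for the identifier/sequence codecs. The decoder consumes exactly
the bytes the encoder emitted, so a truncated payload raises an error
instead of decoding to wrong output. No floating point enters the coding
loop anywhere in the package; the handful of logarithm/logistic tables are
built once at import and rounded to integers, so payloads are reproducible
across platforms.

## Sequence codec: competing finite-context models

An order-k finite-context model assigns
P(s | ctx) = (n(ctx,s) + α) / (n(ctx) + α·|A|) over A = {A,C,G,T}.
Defaults: orders (2, 5, 8, 11), α = 1/16, per-context counts halved at
16384 so the model keeps adapting on long inputs. Orders above 8 use
24-bit multiplicative-hashed context keys (collisions are rare,
deterministic, and shared by encoder and decoder); lower orders use exact
keys.

Rather than hard-switching between models, the bank blends them: each model
keeps an exponentially decayed code-length accumulator
L ← 0.95·L − log2 p(symbol) (fixed point, 1/256-bit units), and its weight
is 2^−(L−L_min). Blending avoids coding explicit switch events and is never
much worse than the best single model on stationary stretches; a hard-switch
mode remains available behind a config flag. The α, orders, decay and
hashing threshold all ride in the archive header.

Non-ACGT characters are handled by a per-position binary escape flag
(adaptive probability, shared coder) plus a raw literal side channel. The
4-symbol tables stay small, and the rare-N case costs ~1 bit per position
plus one literal byte. Escaped positions advance the context with a
placeholder so both sides stay synchronized. Per-read lengths are
delta-coded as zig-zag varints and compressed with an order-1 byte model;
the quality decoder reuses these lengths, so they are stored once.

## Identifier codec

Identifiers are tokenized into maximal digit runs (numeric fields, kept as
value + original width so `007` survives) and maximal non-digit runs (text
fields). Records sharing the previous record's template (the tag sequence)
are coded as per-field deltas: zig-zag varint residuals for numerics, a
same/changed flag (plus literal) for text. A template change stores the
record's absolute fields; this also covers the first record, whose
"previous" is defined as all zeros. The serialized stream is compressed
with a single order-2 byte-level finite-context model. On typical
run-accession identifiers the residual stream is almost constant and
compresses below 5% of raw.

## Quality codec: context mixing

Quality scores (printable ASCII 33–126, 94 symbols) carry most of a FASTQ
file's irreducible entropy. Each score correlates strongly with its recent
predecessors, and the correlation decays with distance — exactly the regime
bit-level context mixing handles well.

Each symbol is binarized to 7 bits, MSB first. For every bit, five context
models produce a 12-bit probability from a table indexed by
(context value, binarization-tree node):

| context | size | captures |
|---|---|---|
| q_{t−1} | 95 | first-order score correlation |
| (q_{t−1}, q_{t−2}) | 95² | second-order structure |
| log-quantized position (16 buckets) | 16 | positional degradation |
| (q_{t−1}, max of last 8) | 95² | local plateau level |
| sign of q_{t−1} − q_{t−2} | 3 | trend direction |

(95 = 94 symbols + a "read start" sentinel; contexts reset at read
boundaries unless the carry-across-reads option is set.) Position is
log-bucketed so long variable-length reads do not blow up the table.

Predictions are combined in the logistic domain:
p = squash(Σ w_i · stretch(p_i) + w_bias), with stretch/squash as
quantized 12-bit tables. One weight vector is selected per (bucket of
q_{t−1} × bit position) — 8 × 7 vectors. After coding each bit b, weights
update by w_i += η · (b − p) · stretch(p_i) with η = 1/512 in fixed
point, and each contributing probability state moves toward b. Fresh table
slots adapt with large steps (shift 1) that anneal to the steady-state rate
of 1/32 via a per-slot visit counter — running-mean behaviour early,
smooth tracking later. This matters on short streams: without it the codec
paid ~8% over entropy on a known 2-bit/symbol source, with it ~3%.

All contexts are functions of previously *decoded* symbols and position
only, so the decoder reproduces the encoder's model trajectory exactly.
Every parameter above is recorded in the archive header.

## Archive container

One binary file: fixed header (magic, version, flags, record count, global
checksum, header checksum), per-stream entries (stream id, codec id,
embedded codec-parameter block, raw and payload lengths, two 64-bit
blake2b checksums), then the payloads. Three checksum layers serve three
failure modes: the *payload* checksum detects and attributes corruption to
the owning stream before any decoding starts (necessary because flipping a
trailing coder-flush byte need not change decoded output); the *content*
checksum catches model/parameter mismatches after decode; the *global*
checksum is the final word on the reassembled file. A header checksum
(computed with its own field zeroed) makes corruption of accounting-only
header fields detectable too — in the test suite, every single-byte flip
of an archive raises a diagnosable error. Random access and encryption are
out of scope.

## Synthetic data

The generator emulates the two platform archetypes the tool targets:
Illumina-like (fixed length 100, structured identifiers with incrementing
numeric fields and a pair suffix) and PacBio-like (log-normal lengths,
median ≈ 300 in the test fixtures, floor 50, wider quality span, higher
N rate). Sequences are i.i.d. uniform ACGT plus a fixed 200-base motif
re-inserted with 1% per-read probability — genomes are repetitive, and the
repeats give the high-order models something to exploit, while the i.i.d.
background remains the worst case.

Quality strings are generated as: backbone level that *stays* with
probability s (default 0.9) or redraws uniformly over the configured span
(default 41 Phred values); a deterministic down-drift (2 Phred per 100
bases) emulating positional degradation; and i.i.d. jitter uniform on
±2 added per base. Two properties of this design are deliberate:

* the stay-or-redraw backbone has an s-independent stationary law, so the
  lag-1 autocorrelation of emitted scores is ≈ s — measured 0.50 / 0.69 /
  0.89 / 0.97 for s = 0.5 / 0.7 / 0.9 / 0.99 — i.e. correlation strength
  is a clean monotone dial (a stepping random walk does not have this
  property: its variance grows with the move rate and the correlation
  ordering inverts);
* the jitter floor keeps the conditional entropy near what real
  instruments produce. A noiseless stay/step chain at s = 0.9 has ≈ 1
  bit/symbol, which would let the codec compress ~8:1 — far outside the
  2:1–4:1 band observed for real quality streams. With jitter, the codec
  measures ≈ 3.4 bits/symbol (ratio ≈ 2.4) at s = 0.9, inside the band.

What the generator does **not** model: reference-derived sequence content,
realistic error profiles (no ART/PBSIM-style simulation), mate-pair
reverse complements (pairing is emulated only through identifier
suffixes), per-cycle instrument artefacts, and Illumina quality binning.
Passing tests therefore demonstrate correctness (losslessness, integrity,
model behaviour on controlled statistics) and *qualitative* compression
behaviour; absolute ratios on real instrument files will differ.

## Problem sizes and defaults in the test suite

The fixture matrix uses 150 reads × 100 bp (Illumina-like) and 60
variable-length reads (PacBio-like) per fixture — 16 fixtures covering
both platforms × three plus modes × two N rates plus degenerate cases
(empty file, single record, constant quality, CRLF). The quality-band
measurements use 1,000 reads × 100 bp per seed. These sizes are the point
where every codec path and statistic is exercised and the entire suite
plus the acceptance script completes in a couple of minutes on one core;
all generators scale to arbitrary n via their configs.

## Known limitations

* Throughput is roughly 0.05 MB/s symmetric (pure-Python inner loops);
  the design goal ordering is ratio > correctness-diagnostics > speed.
* Whole streams are buffered in memory during codec runs; parsing is
  streaming, coding is not.
* One archive holds one FASTQ file; no random access into the archive.
* The identifier delta model assumes record-to-record template stability;
  pathological identifier streams fall back to absolute storage and
  compress less (never incorrectly).
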