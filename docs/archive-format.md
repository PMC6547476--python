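# fqarc archive format (version 1)

A single binary file: fixed header, stream entry table, payloads back to
back. All integers are little-endian and fixed width. Suggested file
extension: `.fqa` (a suggestion only; the magic bytes are authoritative).

## Fixed header

| offset | size | field |
|---|---|---|
| 0  | 8 | magic `"FQARCv01"` (ASCII) |
| 8  | 2 | format version, u16 (currently 1) |
| 10 | 1 | flags: bits 0–1 plus mode (0 bare, 1 mirror, 2 verbatim), bit 2 newline style (0 LF, 1 CRLF); other bits must be 0 |
| 11 | 8 | record count, u64 |
| 19 | 8 | global checksum of the original FASTQ bytes |
| 27 | 8 | header checksum (blake2b-64 of bytes 0..header end with this field zeroed) |
| 35 | 1 | number of stream entries, u8 |
| 36 | — | stream entries |

## Stream entry

| size | field |
|---|---|
| 1 | stream id: 1 identifiers, 2 sequences, 3 plus, 4 qualities |
| 1 | codec id: 1 identifier FCM, 2 competing-FCM sequences, 3 context-mixing qualities, 4 raw |
| 2 + n | parameter-block length (u16) followed by a JSON object (sorted keys) holding every codec parameter the decoder needs |
| 8 | uncompressed stream length, u64 (canonical form: elements joined by `\n` with trailing `\n`) |
| 8 | payload length, u64 |
| 8 | content checksum: blake2b-64 of the canonical uncompressed stream bytes |
| 8 | payload checksum: blake2b-64 of the payload bytes |

Payloads follow immediately after the last entry, in entry order; their
offsets are derivable from the header alone, and the file length must equal
header size + sum of payload lengths exactly.

## Integrity semantics on read

1. magic, version, flags, structural lengths (truncation / trailing bytes);
2. header checksum;
3. per-stream payload checksums (corruption attributed to the owning
   stream *before* any decoding);
4. after each stream decodes: content checksum against the decoded stream;
5. after reassembly: global checksum against the produced FASTQ bytes.

A failure at any layer aborts with an error naming the layer (and stream,
where applicable); no partially verified output is ever returned.

The plus stream is present only in verbatim mode. An empty FASTQ file
yields a valid archive with record count 0 and empty-stream payloads.
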