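"""Finite-context-model codecs for the identifier and sequence streams.

Sequences are coded by a bank of *competing* order-k Markov models over
{A,C,G,T}: each model proposes a smoothed conditional distribution for the
next base, the bank blends the proposals with weights driven by each
model's recent code length (exponentially decayed), and the blend feeds the
shared range coder.  Low orders dominate on noisy data, high orders take
over inside repeats — the blend adapts per position without coding any
switch events.  Non-ACGT bases (N and friends) are handled with a
per-position binary escape flag plus a literal side channel, so the 4-symbol
tables stay small.

Identifiers are tokenized into alternating text / numeric fields, numeric
fields are delta-coded against the previous record (zig-zag varints, with
the original zero-padded width preserved), and the resulting byte stream is
compressed with a single order-2 finite-context model over bytes.

All coding-path arithmetic is integer-only.  The few logarithm/power tables
involved are built once at import time and rounded to integers, so payloads
are bit-reproducible across runs and platforms.
"""

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .coder import RangeDecoder, RangeEncoder
from .errors import CodingError, CorruptPayloadError

# --------------------------------------------------------------------------
# quantized log2 / pow2 tables (integers; 1/256-bit resolution)
# --------------------------------------------------------------------------

#: CL12[i] ~ -log2(((i<<4)+8)/65536) in 1/256-bit units, for 16-bit probs >> 4
_CL12 = [round(-math.log2(((i << 4) + 8) / 65536.0) * 256) for i in range(4096)]
#: POW2[d] ~ 65536 * 2**(-d/256), clamped to >= 1
_POW2 = [max(1, round(65536.0 * 2.0 ** (-d / 256.0))) for d in range(4096)]

_HASH_MULT = 2654435761
_HASH_MASK = (1 << 24) - 1


# --------------------------------------------------------------------------
# the FCM unit
# --------------------------------------------------------------------------

class ContextModel:
    """Order-k symbol-count table with additive smoothing.

    P(s | ctx) = (count(ctx, s) + alpha) / (total(ctx) + alpha * |alphabet|),
    with ``alpha = alpha_num / alpha_den`` a positive rational.  Unseen
    contexts behave as all-zero counts (uniform prediction).
    """

    def __init__(self, order, alphabet, alpha=(1, 1)):
        if order < 0:
            raise ValueError("order must be non-negative")
        num, den = alpha
        if num <= 0 or den <= 0:
            raise ValueError("alpha must be a positive rational")
        self.order = order
        self.alphabet = list(alphabet)
        self.index = {s: i for i, s in enumerate(self.alphabet)}
        self.alpha = (num, den)
        self.counts = {}

    def _key(self, context):
        return tuple(context)

    def observe(self, context, symbol):
        if len(context) != self.order:
            raise ValueError(
                f"context length {len(context)} != order {self.order}"
            )
        row = self.counts.setdefault(self._key(context), [0] * len(self.alphabet))
        row[self.index[symbol]] += 1

    def observe_string(self, text):
        """Slide over ``text`` and record every (context, symbol) pair."""
        k = self.order
        for i in range(k, len(text)):
            self.observe(text[i - k:i], text[i])

    def probability(self, context, symbol):
        """Smoothed P(symbol | context); strictly positive, sums to 1."""
        if len(context) != self.order:
            raise ValueError(
                f"context length {len(context)} != order {self.order}"
            )
        if symbol not in self.index:
            raise CodingError(f"symbol {symbol!r} outside alphabet")
        num, den = self.alpha
        row = self.counts.get(self._key(context))
        c = row[self.index[symbol]] if row else 0
        total = sum(row) if row else 0
        return (c * den + num) / (total * den + num * len(self.alphabet))

    def distribution(self, context):
        return [self.probability(context, s) for s in self.alphabet]


# --------------------------------------------------------------------------
# varint / zig-zag helpers (identifier residuals, lengths, framing)
# --------------------------------------------------------------------------

def zigzag(n: int) -> int:
    return (n << 1) ^ (n >> 63) if n >= 0 else ((-n) << 1) - 1


def unzigzag(z: int) -> int:
    return (z >> 1) if (z & 1) == 0 else -((z + 1) >> 1)


def write_varint(buf: bytearray, n: int):
    if n < 0:
        raise ValueError("varint must be non-negative")
    while True:
        b = n & 0x7F
        n >>= 7
        if n:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def read_varint(data, pos):
    shift = 0
    n = 0
    while True:
        if pos >= len(data):
            raise CorruptPayloadError("varint runs past end of payload")
        b = data[pos]
        pos += 1
        n |= (b & 0x7F) << shift
        if not b & 0x80:
            return n, pos
        shift += 7
        if shift > 70:
            raise CorruptPayloadError("varint too long")


# --------------------------------------------------------------------------
# byte-alphabet FCM coder (identifiers, lengths, plus-line comments)
# --------------------------------------------------------------------------

class _ByteFCM:
    """Adaptive order-k model over bytes feeding the range coder."""

    def __init__(self, order, alpha=(1, 16), count_limit=16384):
        self.order = order
        self.num, self.den = alpha
        self.limit = count_limit
        self.counts = {}
        self.ctx = 0
        self.mask = (1 << (8 * order)) - 1 if order else 0

    def _freqs(self):
        row = self.counts.get(self.ctx)
        num, den = self.num, self.den
        if row is None:
            return None, 256 * num
        total = sum(row) * den + 256 * num
        return row, total

    def encode(self, enc, byte):
        row, total = self._freqs()
        num, den = self.num, self.den
        if row is None:
            enc.encode_freq(byte * num, (byte + 1) * num, total)
        else:
            cum = 0
            for i in range(byte):
                cum += row[i]
            cum_lo = cum * den + byte * num
            cum_hi = cum_lo + row[byte] * den + num
            enc.encode_freq(cum_lo, cum_hi, total)
        self._update(byte)

    def decode(self, dec):
        row, total = self._freqs()
        num, den = self.num, self.den
        off = dec.decode_freq(total)
        if row is None:
            byte = off // num
            dec.decode_update(byte * num, (byte + 1) * num, total)
        else:
            cum = 0
            byte = 0
            while True:
                step = row[byte] * den + num
                if cum + step > off:
                    break
                cum += step
                byte += 1
            dec.decode_update(cum, cum + step, total)
        self._update(byte)
        return byte

    def _update(self, byte):
        row = self.counts.get(self.ctx)
        if row is None:
            row = [0] * 256
            self.counts[self.ctx] = row
        row[byte] += 1
        if row[byte] >= self.limit:
            for i in range(256):
                row[i] >>= 1
        if self.order:
            self.ctx = ((self.ctx << 8) | byte) & self.mask


def encode_bytes_fcm(data: bytes, order=2, alpha=(1, 16)) -> bytes:
    """Compress an arbitrary byte string with a single adaptive FCM."""
    model = _ByteFCM(order, alpha)
    enc = RangeEncoder()
    for b in data:
        model.encode(enc, b)
    return enc.finish()


def decode_bytes_fcm(payload: bytes, n_bytes: int, order=2, alpha=(1, 16)) -> bytes:
    model = _ByteFCM(order, alpha)
    dec = RangeDecoder(payload)
    out = bytearray()
    for _ in range(n_bytes):
        out.append(model.decode(dec))
    return bytes(out)


# --------------------------------------------------------------------------
# identifier tokenization + delta encoding
# --------------------------------------------------------------------------

TEXT = 0
NUMERIC = 1


@dataclass
class TokenField:
    kind: int  # TEXT or NUMERIC
    text: str = ""  # TEXT payload
    value: int = 0  # NUMERIC payload
    width: int = 0  # original digit-run length (preserves zero padding)


def tokenize_identifier(identifier: str) -> List[TokenField]:
    """Split into maximal digit runs (NUMERIC) and non-digit runs (TEXT).

    Re-joining the fields reproduces the identifier byte-exactly, including
    leading zeros ("007" -> value 7, width 3).
    """
    fields = []
    i = 0
    n = len(identifier)
    while i < n:
        j = i
        if identifier[i].isdigit() and identifier[i].isascii():
            while j < n and identifier[j].isdigit() and identifier[j].isascii():
                j += 1
            run = identifier[i:j]
            fields.append(TokenField(NUMERIC, value=int(run), width=len(run)))
        else:
            while j < n and not (identifier[j].isdigit() and identifier[j].isascii()):
                j += 1
            fields.append(TokenField(TEXT, text=identifier[i:j]))
        i = j
    return fields


def detokenize_identifier(fields: List[TokenField]) -> str:
    parts = []
    for f in fields:
        if f.kind == TEXT:
            parts.append(f.text)
        else:
            parts.append(str(f.value).zfill(f.width))
    return "".join(parts)


def template_of(fields: List[TokenField]) -> Tuple[int, ...]:
    return tuple(f.kind for f in fields)


def delta_encode_numeric(prev: Optional[List[TokenField]],
                         cur: List[TokenField]):
    """Per-field residuals against the previous record.

    For NUMERIC fields the residual is ``current - previous`` (previous
    defined as all-zeros for the first record).  TEXT fields emit
    ``("same",)`` or ``("changed", text)``.  Rows must share a template;
    the caller flags template mismatches and stores those records whole.
    """
    if prev is not None and template_of(prev) != template_of(cur):
        raise ValueError("rows do not share a template")
    out = []
    for i, f in enumerate(cur):
        if f.kind == NUMERIC:
            base = prev[i].value if prev is not None else 0
            out.append(("delta", f.value - base, f.width))
        else:
            if prev is not None and prev[i].text == f.text:
                out.append(("same",))
            else:
                out.append(("changed", f.text))
    return out


_FLAG_SAME_TEMPLATE = 0
_FLAG_NEW_TEMPLATE = 1


def _serialize_identifiers(identifiers: List[str]) -> bytes:
    """Tokenize + delta-encode into a flat byte stream (pre-FCM)."""
    buf = bytearray()
    prev: Optional[List[TokenField]] = None
    for ident in identifiers:
        fields = tokenize_identifier(ident)
        if prev is not None and template_of(prev) == template_of(fields):
            buf.append(_FLAG_SAME_TEMPLATE)
            for item in delta_encode_numeric(prev, fields):
                if item[0] == "delta":
                    write_varint(buf, zigzag(item[1]))
                    write_varint(buf, item[2])
                elif item[0] == "same":
                    buf.append(0)
                else:
                    buf.append(1)
                    raw = item[1].encode("latin-1")
                    write_varint(buf, len(raw))
                    buf.extend(raw)
        else:
            # first record, or template changed: store absolute values
            buf.append(_FLAG_NEW_TEMPLATE)
            write_varint(buf, len(fields))
            for f in fields:
                buf.append(f.kind)
                if f.kind == NUMERIC:
                    write_varint(buf, f.value)
                    write_varint(buf, f.width)
                else:
                    raw = f.text.encode("latin-1")
                    write_varint(buf, len(raw))
                    buf.extend(raw)
        prev = fields
    return bytes(buf)


def _deserialize_identifiers(data: bytes, n_records: int) -> List[str]:
    out = []
    pos = 0
    prev: Optional[List[TokenField]] = None
    for _ in range(n_records):
        if pos >= len(data):
            raise CorruptPayloadError("identifier stream ended early")
        flag = data[pos]
        pos += 1
        if flag == _FLAG_SAME_TEMPLATE:
            if prev is None:
                raise CorruptPayloadError("delta record with no predecessor")
            fields = []
            for pf in prev:
                if pf.kind == NUMERIC:
                    z, pos = read_varint(data, pos)
                    w, pos = read_varint(data, pos)
                    fields.append(
                        TokenField(NUMERIC, value=pf.value + unzigzag(z), width=w)
                    )
                else:
                    if pos >= len(data):
                        raise CorruptPayloadError("identifier stream ended early")
                    marker = data[pos]
                    pos += 1
                    if marker == 0:
                        fields.append(TokenField(TEXT, text=pf.text))
                    else:
                        ln, pos = read_varint(data, pos)
                        fields.append(
                            TokenField(
                                TEXT,
                                text=data[pos:pos + ln].decode("latin-1"),
                            )
                        )
                        pos += ln
        elif flag == _FLAG_NEW_TEMPLATE:
            nf, pos = read_varint(data, pos)
            fields = []
            for _ in range(nf):
                if pos >= len(data):
                    raise CorruptPayloadError("identifier stream ended early")
                kind = data[pos]
                pos += 1
                if kind == NUMERIC:
                    v, pos = read_varint(data, pos)
                    w, pos = read_varint(data, pos)
                    fields.append(TokenField(NUMERIC, value=v, width=w))
                elif kind == TEXT:
                    ln, pos = read_varint(data, pos)
                    fields.append(
                        TokenField(TEXT, text=data[pos:pos + ln].decode("latin-1"))
                    )
                    pos += ln
                else:
                    raise CorruptPayloadError(f"bad field kind {kind}")
        else:
            raise CorruptPayloadError(f"bad identifier record flag {flag}")
        out.append(detokenize_identifier(fields))
        prev = fields
    return out


def encode_identifiers(identifiers: List[str], order=2) -> bytes:
    """Tokenize -> delta -> order-2 byte FCM + range coder."""
    serialized = _serialize_identifiers(identifiers)
    buf = bytearray()
    write_varint(buf, len(identifiers))
    write_varint(buf, len(serialized))
    buf.extend(encode_bytes_fcm(serialized, order=order))
    return bytes(buf)


def decode_identifiers(payload: bytes, order=2) -> List[str]:
    n, pos = read_varint(payload, 0)
    raw_len, pos = read_varint(payload, pos)
    serialized = decode_bytes_fcm(payload[pos:], raw_len, order=order)
    return _deserialize_identifiers(serialized, n)


# --------------------------------------------------------------------------
# competing-FCM sequence codec
# --------------------------------------------------------------------------

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class SequenceCodecConfig:
    """Parameters of the competing-model bank; recorded in the archive header
    so the decoder always mirrors the encoder."""

    orders: Tuple[int, ...] = (2, 5, 8, 11)
    alpha: Tuple[int, int] = (1, 16)
    decay_num: int = 243  # 0.95 in 1/256 fixed point
    decay_den: int = 256
    hash_order_threshold: int = 8  # orders above this use 24-bit hashed keys
    count_limit: int = 16384
    blend: bool = True  # False = hard switch to the current best model

    def to_dict(self):
        return {
            "orders": list(self.orders),
            "alpha": list(self.alpha),
            "decay_num": self.decay_num,
            "decay_den": self.decay_den,
            "hash_order_threshold": self.hash_order_threshold,
            "count_limit": self.count_limit,
            "blend": self.blend,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            orders=tuple(d["orders"]),
            alpha=tuple(d["alpha"]),
            decay_num=d["decay_num"],
            decay_den=d["decay_den"],
            hash_order_threshold=d["hash_order_threshold"],
            count_limit=d["count_limit"],
            blend=d["blend"],
        )


class _CompetingBank:
    """The blendable bank of order-k models over {A,C,G,T}.

    Weights are 2**(-L/256) where L is each model's exponentially decayed
    code-length accumulator in 1/256-bit units — models that recently coded
    cheaply dominate the mixture.
    """

    def __init__(self, config: SequenceCodecConfig):
        self.cfg = config
        self.orders = config.orders
        self.tables = [{} for _ in self.orders]
        self.masks = [(1 << (2 * k)) - 1 for k in self.orders]
        self.hashed = [k > config.hash_order_threshold for k in self.orders]
        self.perf = [0] * len(self.orders)
        self.hist = 0
        self.num, self.den = config.alpha
        self.limit = config.count_limit
        # bits coded so far under the blend, in 1/256-bit units (entropy
        # accounting used by tests and the bench per-stream mode)
        self.blend_cost = 0

    def _keys(self):
        hist = self.hist
        keys = []
        for i, mask in enumerate(self.masks):
            ctx = hist & mask
            if self.hashed[i]:
                ctx = (ctx * _HASH_MULT) & _HASH_MASK
            keys.append(ctx)
        return keys

    def _proposals(self, keys):
        """Per-model 16-bit probability vectors over ACGT (each >= 1)."""
        num, den = self.num, self.den
        props = []
        for i, key in enumerate(keys):
            row = self.tables[i].get(key)
            if row is None:
                props.append((16384, 16384, 16384, 16384))
            else:
                total = (row[0] + row[1] + row[2] + row[3]) * den + 4 * num
                props.append(
                    (
                        (row[0] * den + num) * 65536 // total + 1,
                        (row[1] * den + num) * 65536 // total + 1,
                        (row[2] * den + num) * 65536 // total + 1,
                        (row[3] * den + num) * 65536 // total + 1,
                    )
                )
        return props

    def _weights(self):
        perf = self.perf
        lmin = min(perf)
        if self.cfg.blend:
            return [
                _POW2[min(p - lmin, 4095)] for p in perf
            ]
        # hard switch: winner takes all
        return [65536 if p == lmin else 0 for p in perf]

    def _blend(self, props, weights):
        b0 = b1 = b2 = b3 = 0
        for w, q in zip(weights, props):
            if w:
                b0 += w * q[0]
                b1 += w * q[1]
                b2 += w * q[2]
                b3 += w * q[3]
        return (b0 + 1, b1 + 1, b2 + 1, b3 + 1)

    def _after_symbol(self, keys, props, blend, total, sym):
        cfg = self.cfg
        # decayed per-model code-length accumulators
        for i, q in enumerate(props):
            cl = _CL12[min(q[sym] >> 4, 4095)]
            self.perf[i] = (self.perf[i] * cfg.decay_num) // cfg.decay_den + cl
        # entropy accounting for the blend itself
        p16 = blend[sym] * 65536 // total
        self.blend_cost += _CL12[min(max(p16, 1) >> 4, 4095)]
        # counts
        for i, key in enumerate(keys):
            table = self.tables[i]
            row = table.get(key)
            if row is None:
                row = [0, 0, 0, 0]
                table[key] = row
            row[sym] += 1
            if row[sym] >= self.limit:
                row[0] >>= 1
                row[1] >>= 1
                row[2] >>= 1
                row[3] >>= 1
        self.hist = ((self.hist << 2) | sym) & 0x3FFFFF

    def encode_symbol(self, enc, sym):
        keys = self._keys()
        props = self._proposals(keys)
        weights = self._weights()
        blend = self._blend(props, weights)
        total = blend[0] + blend[1] + blend[2] + blend[3]
        cum = 0
        for s in range(sym):
            cum += blend[s]
        enc.encode_freq(cum, cum + blend[sym], total)
        self._after_symbol(keys, props, blend, total, sym)

    def decode_symbol(self, dec):
        keys = self._keys()
        props = self._proposals(keys)
        weights = self._weights()
        blend = self._blend(props, weights)
        total = blend[0] + blend[1] + blend[2] + blend[3]
        off = dec.decode_freq(total)
        cum = 0
        sym = 0
        while cum + blend[sym] <= off:
            cum += blend[sym]
            sym += 1
        dec.decode_update(cum, cum + blend[sym], total)
        self._after_symbol(keys, props, blend, total, sym)
        return sym

    def advance_escape(self):
        """Shift the context past a non-ACGT position without counting it."""
        self.hist = (self.hist << 2) & 0x3FFFFF


def _encode_lengths(lengths: List[int]) -> bytes:
    buf = bytearray()
    prev = 0
    for ln in lengths:
        write_varint(buf, zigzag(ln - prev))
        prev = ln
    payload = encode_bytes_fcm(bytes(buf), order=1)
    out = bytearray()
    write_varint(out, len(buf))
    out.extend(payload)
    return bytes(out)


def _decode_lengths(data: bytes, n_reads: int) -> Tuple[List[int], int]:
    raw_len, pos = read_varint(data, 0)
    serialized = decode_bytes_fcm(data[pos:], raw_len, order=1)
    lengths = []
    prev = 0
    p = 0
    for _ in range(n_reads):
        z, p = read_varint(serialized, p)
        prev = prev + unzigzag(z)
        if prev < 0:
            raise CorruptPayloadError("negative read length decoded")
        lengths.append(prev)
    return lengths, pos  # pos is start of FCM payload within data


def encode_sequences(sequences: List[str],
                     config: SequenceCodecConfig = None) -> bytes:
    """Compress the sequence stream.

    Payload layout: varint n_reads | lengths block | coded-bases block |
    raw literal side channel (the non-ACGT characters, one byte per escape,
    in stream order).  Each block is varint-length-prefixed.
    """
    if config is None:
        config = SequenceCodecConfig()
    bank = _CompetingBank(config)
    enc = RangeEncoder()
    literals = bytearray()
    p_escape = 2048  # adaptive 16-bit P(non-ACGT); N is rare in short reads
    base_index = _BASE_INDEX
    for r, seq in enumerate(sequences):
        for ch in seq:
            sym = base_index.get(ch)
            if sym is None:
                o = ord(ch)
                if not 33 <= o <= 126:
                    raise CodingError(
                        f"unprintable sequence byte {o} in read {r}"
                    )
                enc.encode_bit(p_escape, 1)
                p_escape += (65536 - p_escape) >> 5
                if p_escape > 65535:
                    p_escape = 65535
                literals.append(o)
                bank.advance_escape()
            else:
                enc.encode_bit(p_escape, 0)
                p_escape -= p_escape >> 5
                if p_escape < 1:
                    p_escape = 1
                bank.encode_symbol(enc, sym)
    coded = enc.finish()
    out = bytearray()
    write_varint(out, len(sequences))
    lengths_block = _encode_lengths([len(s) for s in sequences])
    write_varint(out, len(lengths_block))
    out.extend(lengths_block)
    write_varint(out, len(coded))
    out.extend(coded)
    write_varint(out, len(literals))
    out.extend(literals)
    return bytes(out)


def decode_sequences(payload: bytes,
                     config: SequenceCodecConfig = None) -> List[str]:
    if config is None:
        config = SequenceCodecConfig()
    n_reads, pos = read_varint(payload, 0)
    ln, pos = read_varint(payload, pos)
    lengths, _ = _decode_lengths(payload[pos:pos + ln], n_reads)
    pos += ln
    ln, pos = read_varint(payload, pos)
    coded = payload[pos:pos + ln]
    if len(coded) != ln:
        raise CorruptPayloadError("sequence payload truncated")
    pos += ln
    ln, pos = read_varint(payload, pos)
    literals = payload[pos:pos + ln]
    if len(literals) != ln:
        raise CorruptPayloadError("sequence literal channel truncated")

    bank = _CompetingBank(config)
    dec = RangeDecoder(coded)
    p_escape = 2048
    lit_pos = 0
    out = []
    for read_len in lengths:
        chars = []
        for _ in range(read_len):
            if dec.decode_bit(p_escape):
                p_escape += (65536 - p_escape) >> 5
                if p_escape > 65535:
                    p_escape = 65535
                if lit_pos >= len(literals):
                    raise CorruptPayloadError("literal channel exhausted")
                chars.append(chr(literals[lit_pos]))
                lit_pos += 1
                bank.advance_escape()
            else:
                p_escape -= p_escape >> 5
                if p_escape < 1:
                    p_escape = 1
                chars.append(_BASES[bank.decode_symbol(dec)])
        out.append("".join(chars))
    return out
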