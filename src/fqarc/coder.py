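"""Adaptive arithmetic (range) coding shared by the sequence and quality codecs.

This is a carry-less byte-oriented range coder in the Subbotin style, run on
64-bit registers: ``low`` and ``range`` are masked to 64 bits, bytes are
emitted from the top whenever the leading byte of the interval is pinned
down, and the range is forcibly renormalised when it drops below 2**48.
Keeping the working range at least 2**48 while cumulative-frequency totals
stay below 2**40 makes the truncation loss per symbol smaller than 2**-8
bits, so coded payloads sit essentially at the model's entropy.

Two interfaces are exposed on the same coder state:

* ``encode_bit`` / ``decode_bit`` — binary coding against a 16-bit
  probability, used by the context-mixing quality codec;
* ``encode_freq`` / ``decode_freq`` + ``decode_update`` — cumulative
  frequency coding over an arbitrary alphabet, used by the finite-context
  sequence and identifier codecs.

The coding loop is integer-only; identical inputs produce identical payload
bytes on every platform.
"""

from .errors import CodingError, CorruptPayloadError

_MASK = (1 << 64) - 1
_TOP = 1 << 56  # emit a byte once the top byte of the interval is fixed
_BOT = 1 << 48  # force renormalisation below this range

#: Probabilities for the binary interface live in [1, PROB_ONE - 1].
PROB_BITS = 16
PROB_ONE = 1 << PROB_BITS

#: Upper bound on cumulative-frequency totals for the symbol interface.
MAX_TOTAL = 1 << 40


class RangeEncoder:
    """Stateful encoder producing one opaque byte payload."""

    def __init__(self):
        self.low = 0
        self.rng = _MASK
        self.out = bytearray()
        self._finished = False

    # -- binary interface ------------------------------------------------

    def encode_bit(self, p_one, bit):
        """Code ``bit`` given ``p_one``, the 16-bit probability of a 1 bit.

        ``p_one`` must be in [1, 65535]; models clamp to this range so no
        symbol ever has probability zero.
        """
        if not 0 < p_one < PROB_ONE:
            raise CodingError(f"bit probability {p_one} outside (0, {PROB_ONE})")
        mid = (self.rng >> PROB_BITS) * p_one
        if bit:
            self.rng = mid
        else:
            self.low = (self.low + mid) & _MASK
            self.rng -= mid
        low = self.low
        rng = self.rng
        out = self.out
        while True:
            if (low ^ (low + rng)) < _TOP:
                pass
            elif rng < _BOT:
                rng = (-low) & (_BOT - 1)
            else:
                break
            out.append(low >> 56)
            low = (low << 8) & _MASK
            rng = (rng << 8) & _MASK
        self.low = low
        self.rng = rng

    # -- cumulative-frequency interface ----------------------------------

    def encode_freq(self, cum_lo, cum_hi, total):
        """Code the symbol occupying ``[cum_lo, cum_hi)`` of ``total``."""
        if not (0 <= cum_lo < cum_hi <= total):
            raise CodingError(
                f"bad cumulative interval [{cum_lo}, {cum_hi}) of {total}"
            )
        if total > MAX_TOTAL:
            raise CodingError(f"frequency total {total} exceeds {MAX_TOTAL}")
        r = self.rng // total
        self.low = (self.low + r * cum_lo) & _MASK
        if cum_hi == total:
            # hand the division remainder to the last symbol
            self.rng -= r * cum_lo
        else:
            self.rng = r * (cum_hi - cum_lo)
        self._normalize()

    def _normalize(self):
        low = self.low
        rng = self.rng
        out = self.out
        while True:
            if (low ^ (low + rng)) < _TOP:
                pass
            elif rng < _BOT:
                rng = (-low) & (_BOT - 1)
            else:
                break
            out.append(low >> 56)
            low = (low << 8) & _MASK
            rng = (rng << 8) & _MASK
        self.low = low
        self.rng = rng

    # -- lifecycle -------------------------------------------------------

    def finish(self):
        """Flush the final interval and return the payload bytes."""
        if self._finished:
            raise CodingError("encoder already finished")
        self._finished = True
        low = self.low
        for _ in range(8):
            self.out.append(low >> 56)
            low = (low << 8) & _MASK
        return bytes(self.out)

    def state(self):
        """(low, range) snapshot, for encoder/decoder symmetry checks."""
        return (self.low, self.rng)


class RangeDecoder:
    """Mirror of :class:`RangeEncoder`; consumes exactly the bytes the
    encoder emitted (renormalisation bytes plus the 8-byte flush), so a
    truncated payload raises :class:`CorruptPayloadError` instead of
    decoding to wrong output."""

    def __init__(self, payload):
        self.data = payload
        self.pos = 0
        self.low = 0
        self.rng = _MASK
        if len(payload) < 8:
            raise CorruptPayloadError(
                f"payload too short for coder state: {len(payload)} < 8 bytes"
            )
        code = 0
        for _ in range(8):
            code = (code << 8) | payload[self.pos]
            self.pos += 1
        self.code = code

    def _next_byte(self):
        if self.pos >= len(self.data):
            raise CorruptPayloadError(
                f"payload exhausted at byte {self.pos}"
            )
        b = self.data[self.pos]
        self.pos += 1
        return b

    # -- binary interface ------------------------------------------------

    def decode_bit(self, p_one):
        if not 0 < p_one < PROB_ONE:
            raise CodingError(f"bit probability {p_one} outside (0, {PROB_ONE})")
        mid = (self.rng >> PROB_BITS) * p_one
        if ((self.code - self.low) & _MASK) < mid:
            bit = 1
            self.rng = mid
        else:
            bit = 0
            self.low = (self.low + mid) & _MASK
            self.rng -= mid
        low = self.low
        rng = self.rng
        code = self.code
        data = self.data
        pos = self.pos
        n = len(data)
        while True:
            if (low ^ (low + rng)) < _TOP:
                pass
            elif rng < _BOT:
                rng = (-low) & (_BOT - 1)
            else:
                break
            if pos >= n:
                raise CorruptPayloadError(f"payload exhausted at byte {pos}")
            code = ((code << 8) | data[pos]) & _MASK
            pos += 1
            low = (low << 8) & _MASK
            rng = (rng << 8) & _MASK
        self.low = low
        self.rng = rng
        self.code = code
        self.pos = pos
        return bit

    # -- cumulative-frequency interface ----------------------------------

    def decode_freq(self, total):
        """Return a frequency offset in ``[0, total)``; the caller locates
        the symbol whose cumulative interval contains it, then calls
        :meth:`decode_update` with that interval."""
        if total > MAX_TOTAL:
            raise CodingError(f"frequency total {total} exceeds {MAX_TOTAL}")
        self._r = self.rng // total
        off = ((self.code - self.low) & _MASK) // self._r
        if off >= total:
            off = total - 1
        return off

    def decode_update(self, cum_lo, cum_hi, total):
        r = self._r
        self.low = (self.low + r * cum_lo) & _MASK
        if cum_hi == total:
            self.rng -= r * cum_lo
        else:
            self.rng = r * (cum_hi - cum_lo)
        low = self.low
        rng = self.rng
        code = self.code
        data = self.data
        pos = self.pos
        n = len(data)
        while True:
            if (low ^ (low + rng)) < _TOP:
                pass
            elif rng < _BOT:
                rng = (-low) & (_BOT - 1)
            else:
                break
            if pos >= n:
                raise CorruptPayloadError(f"payload exhausted at byte {pos}")
            code = ((code << 8) | data[pos]) & _MASK
            pos += 1
            low = (low << 8) & _MASK
            rng = (rng << 8) & _MASK
        self.low = low
        self.rng = rng
        self.code = code
        self.pos = pos

    def state(self):
        return (self.low, self.rng)


def encode_symbols(symbols, cum_table, total):
    """Encode ``symbols`` (iterable of indices) against a *static* cumulative
    table ``cum_table`` of length ``n_symbols + 1`` with ``cum_table[-1] ==
    total``.  Convenience wrapper used in tests and by simple static models.
    """
    enc = RangeEncoder()
    for i, s in enumerate(symbols):
        lo, hi = cum_table[s], cum_table[s + 1]
        if lo == hi:
            raise CodingError(f"zero-probability symbol {s} at position {i}")
        enc.encode_freq(lo, hi, total)
    return enc.finish()


def decode_symbols(payload, cum_table, total, n_symbols):
    """Inverse of :func:`encode_symbols` for the same static table."""
    dec = RangeDecoder(payload)
    out = []
    n_alpha = len(cum_table) - 1
    for _ in range(n_symbols):
        off = dec.decode_freq(total)
        # linear scan; static-table helper is only used on tiny alphabets
        s = 0
        while s < n_alpha - 1 and cum_table[s + 1] <= off:
            s += 1
        dec.decode_update(cum_table[s], cum_table[s + 1], total)
        out.append(s)
    return out
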