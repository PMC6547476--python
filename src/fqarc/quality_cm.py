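"""Context-mixing codec for the quality-score stream.

Quality scores carry most of the residual entropy of a FASTQ file: they use
a wide printable-ASCII alphabet and each score is strongly correlated with
the scores just before it, with the correlation fading over distance.  The
codec exploits exactly that structure, in the PAQ/ZPAQ architectural family:

* each quality symbol (ASCII 33..126, i.e. 94 values) is binarized to 7
  bits, most significant first;
* five context models each hold a 12-bit probability state for the next bit,
  indexed by (context, partial-bit prefix).  The contexts are the previous
  score, the previous two scores, a log-quantized within-read position, the
  previous score paired with the maximum of the last eight, and the sign of
  the last score-to-score change;
* a logistic mixer combines the five predictions: p = squash(sum w_i *
  stretch(p_i)), with weights selected by a bucket of the previous score
  (plus bit position) and trained online by gradient on coding loss;
* the mixed probability drives the shared binary range coder.

Every context is a function of previously *decoded* symbols only, so the
decoder reconstructs the model trajectory exactly.  All arithmetic in the
coding loop is fixed-point integer; the stretch/squash tables are built once
at import and rounded to integers.
"""

import math
from dataclasses import dataclass
from typing import List, Tuple

from .coder import RangeDecoder, RangeEncoder
from .errors import CodingError, CorruptPayloadError

__all__ = [
    "QualityCodecConfig",
    "stretch",
    "squash",
    "encode_qualities",
    "decode_qualities",
]

_NSYM = 94  # printable ASCII 33..126
_QOFF = 33
_SENT = 94  # sentinel "no previous score" state at read starts
_NPREV = 95

# ---------------------------------------------------------------------------
# logistic link tables, 12-bit probabilities, 1/256 logit units
# ---------------------------------------------------------------------------

#: _STRETCH[p] ~ 256 * ln(p/4096 / (1 - p/4096)) clamped to +-2047
_STRETCH = [0] * 4096
for _p in range(1, 4096):
    _v = round(256.0 * math.log(_p / (4096.0 - _p)))
    _STRETCH[_p] = max(-2047, min(2047, _v))
_STRETCH[0] = -2047

#: _SQUASH[x + 2048] ~ 4096 / (1 + e**(-x/256)) clamped to [1, 4095]
_SQUASH = [
    max(1, min(4095, round(4096.0 / (1.0 + math.exp(-_x / 256.0)))))
    for _x in range(-2048, 2048)
]


def stretch(p: float) -> float:
    """ln(p / (1-p)) for p in (0,1); domain error otherwise."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"stretch domain error: p={p}")
    return math.log(p / (1.0 - p))


def squash(x: float) -> float:
    """Inverse of :func:`stretch`: 1 / (1 + e**-x)."""
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class QualityCodecConfig:
    """Context-mixing parameters; stored in the archive header so the
    decoder mirrors the encoder exactly.

    ``predictor_rate_shift`` is the bit-shift form of the per-context
    learning rate (5 -> 1/32); ``mixer_rate_shift`` likewise for the mixer
    (13 corresponds to eta = 1/512 on unit-scaled weights).  ``contexts``
    selects which of the five predictors are active, mostly for ablation
    experiments.
    """

    predictor_rate_shift: int = 5
    mixer_rate_shift: int = 13
    mixer_buckets: int = 8
    position_buckets: int = 16
    contexts: Tuple[str, ...] = ("q1", "q2", "pos", "q1max8", "dsign")
    carry_across_reads: bool = False

    def to_dict(self):
        return {
            "predictor_rate_shift": self.predictor_rate_shift,
            "mixer_rate_shift": self.mixer_rate_shift,
            "mixer_buckets": self.mixer_buckets,
            "position_buckets": self.position_buckets,
            "contexts": list(self.contexts),
            "carry_across_reads": self.carry_across_reads,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            predictor_rate_shift=d["predictor_rate_shift"],
            mixer_rate_shift=d["mixer_rate_shift"],
            mixer_buckets=d["mixer_buckets"],
            position_buckets=d["position_buckets"],
            contexts=tuple(d["contexts"]),
            carry_across_reads=d["carry_across_reads"],
        )


_CTX_SIZES = {
    "q1": _NPREV,
    "q2": _NPREV * _NPREV,
    "pos": None,  # position_buckets
    "q1max8": _NPREV * _NPREV,
    "dsign": 3,
}


class _CMState:
    """Shared encoder/decoder model state (predictor tables + mixer)."""

    def __init__(self, cfg: QualityCodecConfig):
        self.cfg = cfg
        self.names = cfg.contexts
        for name in self.names:
            if name not in _CTX_SIZES:
                raise ValueError(f"unknown quality context {name!r}")
        sizes = [
            cfg.position_buckets if n == "pos" else _CTX_SIZES[n]
            for n in self.names
        ]
        # one 12-bit probability per (context value, 7-bit binarization node),
        # plus a small visit counter per slot: fresh slots adapt with large
        # steps (running-mean style), settling to the configured rate
        self.tables = [[2048] * (s * 128) for s in sizes]
        self.visits = [[0] * (s * 128) for s in sizes]
        self.n_in = len(self.names) + 1  # + constant bias input
        # weights per (q1 bucket, bit position); 16.16 fixed point
        self.weights = [
            [1 << 14] * self.n_in
            for _ in range(cfg.mixer_buckets * 7)
        ]
        self.bucket_div = (_NSYM + cfg.mixer_buckets - 1) // cfg.mixer_buckets
        # entropy accounting in 1/256-bit units (for tests/bench)
        self.cost = 0
        self._cl = [
            round(-math.log2((p + 0.5) / 4096.0) * 256) for p in range(4096)
        ]

    def context_bases(self, prev1, prev2, pos, max8):
        """Table base offsets for the current symbol (node index added later).

        All inputs derive from already-decoded history, so encoder and
        decoder compute identical offsets.
        """
        cfg = self.cfg
        bases = []
        for name in self.names:
            if name == "q1":
                c = prev1
            elif name == "q2":
                c = prev1 * _NPREV + prev2
            elif name == "pos":
                c = min(pos.bit_length(), cfg.position_buckets - 1)
            elif name == "q1max8":
                c = prev1 * _NPREV + max8
            else:  # dsign
                if prev1 == _SENT or prev2 == _SENT:
                    c = 0
                elif prev1 > prev2:
                    c = 1
                elif prev1 < prev2:
                    c = 2
                else:
                    c = 0
            bases.append(c * 128)
        return bases

    def mixer_row(self, prev1, bitpos):
        b = 0 if prev1 == _SENT else min(
            prev1 // self.bucket_div, self.cfg.mixer_buckets - 1
        )
        return self.weights[b * 7 + bitpos]


def _code_stream(qualities: List[str], cfg: QualityCodecConfig,
                 coder, decoding: bool, lengths=None):
    """Single implementation of the per-bit loop; the encoder and decoder
    differ only in where the bit comes from."""
    state = _CMState(cfg)
    tables = state.tables
    visits = state.visits
    # visit-count -> update shift: 1, 2, 2, 3, 3, 3, 3, ... capped at `rate`
    shift_for = [
        min(cfg.predictor_rate_shift, max(1, c.bit_length()))
        for c in range(64)
    ]
    names = state.names
    n_models = len(names)
    rate = cfg.predictor_rate_shift
    mshift = cfg.mixer_rate_shift
    stretch_t = _STRETCH
    squash_t = _SQUASH
    cl = state._cl
    carry = cfg.carry_across_reads

    out: List[str] = [] if decoding else qualities
    n_reads = len(lengths) if decoding else len(qualities)
    prev1 = prev2 = _SENT
    for r in range(n_reads):
        if not carry:
            prev1 = prev2 = _SENT
        window: List[int] = []
        read_len = lengths[r] if decoding else len(qualities[r])
        chars: List[str] = []
        for t in range(read_len):
            max8 = max(window) if window else _SENT
            bases = state.context_bases(prev1, prev2, t, max8)
            if decoding:
                v = 0
            else:
                ch = qualities[r][t]
                v = ord(ch) - _QOFF
                if not 0 <= v < _NSYM:
                    raise CodingError(
                        f"quality byte {ord(ch)} outside 33..126 at "
                        f"record {r} position {t}"
                    )
            node = 1
            for bitpos in range(7):
                w = state.mixer_row(prev1, bitpos)
                dot = w[n_models] * 256  # bias input: constant stretch 1.0
                sts = []
                for i in range(n_models):
                    p12 = tables[i][bases[i] + node]
                    s = stretch_t[p12]
                    sts.append(s)
                    dot += w[i] * s
                x = dot >> 16
                if x > 2047:
                    x = 2047
                elif x < -2048:
                    x = -2048
                pmix = squash_t[x + 2048]
                p16 = pmix << 4
                if decoding:
                    bit = coder.decode_bit(p16)
                else:
                    bit = (v >> (6 - bitpos)) & 1
                    coder.encode_bit(p16, bit)
                state.cost += cl[pmix] if bit else cl[4095 - pmix]
                # mixer update: w_i += (err * stretch(p_i)) >> mshift
                err = (bit << 12) - pmix
                for i in range(n_models):
                    w[i] += (err * sts[i]) >> mshift
                w[n_models] += (err * 256) >> mshift
                # predictor updates
                target = bit << 12
                for i in range(n_models):
                    idx = bases[i] + node
                    vc = visits[i][idx]
                    p12 = tables[i][idx]
                    p12 += (target - p12) >> shift_for[vc]
                    if p12 < 1:
                        p12 = 1
                    elif p12 > 4095:
                        p12 = 4095
                    tables[i][idx] = p12
                    if vc < 63:
                        visits[i][idx] = vc + 1
                node = (node << 1) | bit
                if decoding:
                    v = (v << 1) | bit
            if decoding:
                if v >= _NSYM:
                    raise CorruptPayloadError(
                        f"decoded quality symbol {v} out of range at "
                        f"record {r} position {t}"
                    )
                chars.append(chr(v + _QOFF))
            prev2 = prev1
            prev1 = v
            window.append(v)
            if len(window) > 8:
                window.pop(0)
        if decoding:
            out.append("".join(chars))
    return out, state


def encode_qualities(qualities: List[str],
                     config: QualityCodecConfig = None):
    """Compress the quality stream; returns the opaque payload bytes.

    Read lengths are *not* stored here — they are shared with the sequence
    stream, which already codes them.
    """
    if config is None:
        config = QualityCodecConfig()
    enc = RangeEncoder()
    _, state = _code_stream(qualities, config, enc, decoding=False)
    payload = enc.finish()
    return payload


def encoded_cost_bits(qualities: List[str],
                      config: QualityCodecConfig = None) -> float:
    """Model cost of the stream in bits (entropy accounting, no payload).

    Used for ablation comparisons; matches the payload size to within the
    coder's constant flush overhead.
    """
    if config is None:
        config = QualityCodecConfig()
    enc = RangeEncoder()
    _, state = _code_stream(qualities, config, enc, decoding=False)
    enc.finish()
    return state.cost / 256.0


def decode_qualities(payload: bytes, lengths: List[int],
                     config: QualityCodecConfig = None) -> List[str]:
    """Exact inverse of :func:`encode_qualities` given the per-read lengths."""
    if config is None:
        config = QualityCodecConfig()
    dec = RangeDecoder(payload)
    out, _ = _code_stream(None, config, dec, decoding=True, lengths=lengths)
    return out
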