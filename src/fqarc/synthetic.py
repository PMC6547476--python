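"""Seeded synthetic FASTQ generation.

The generator emulates the two platform archetypes the compressor targets:

* ``illumina``-like data — fixed-length short paired reads, structured
  identifiers with incrementing numeric fields and a ``" <i>/1"`` pair
  suffix, rare N bases;
* ``pacbio``-like data — single variable-length long reads (log-normal
  lengths with a hard floor), wider quality spread and a higher error/N
  rate.

Sequences are i.i.d. uniform over ACGT with an occasional repeated motif
(a fixed 200-base block re-inserted with small per-read probability):
genuine genomes are repetitive, and the repeats give the high-order
sequence models structure to exploit, while the i.i.d. background is kept
as the worst case.

Quality strings follow a first-order Markov backbone with stay-probability
``stay_prob``: the backbone keeps its level with probability ``s`` and
otherwise takes a bounded random step; a deterministic positional
down-drift lowers it along the read; independent per-base jitter is added
on top.  High ``s`` means strong correlation between neighbouring scores —
lag-1 autocorrelation increases with ``s`` — while the jitter keeps
per-base entropy in the range real instruments produce.

Identical config + seed always yields byte-identical output (single PCG64
stream, integer draws only).
"""

import math
from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

from .fastq_streams import NewlineStyle, PlusMode

__all__ = [
    "GeneratorConfig",
    "generate",
    "fixture_matrix",
    "quality_lag1_autocorr",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MOTIF_LEN = 200


@dataclass
class GeneratorConfig:
    platform: str = "illumina"  # "illumina" | "pacbio"
    n_reads: int = 1000
    read_length: int = 100  # fixed length (illumina)
    length_log_mean: float = math.log(300.0)  # pacbio log-normal
    length_log_sigma: float = 0.45
    min_length: int = 50
    n_rate: float = 0.0
    motif_rate: float = 0.01
    # quality model: phred span [q_low, q_high] (offset-33), Markov
    # stay-probability, per-base jitter half-width and deterministic
    # down-drift in phred units per 100 bases
    q_low: int = 0
    q_high: int = 40
    stay_prob: float = 0.9
    jitter: int = 2
    drift_per_100: int = 2
    identifier_template: str = "SIM001.{i} {i}/1"
    start_index: int = 1
    plus_mode: PlusMode = PlusMode.BARE
    newline_style: NewlineStyle = NewlineStyle.LF
    seed: int = 0

    def validate(self):
        problems = []
        if self.platform not in ("illumina", "pacbio"):
            problems.append(f"platform: unknown value {self.platform!r}")
        if self.n_reads < 0:
            problems.append("n_reads: must be non-negative")
        if self.platform == "illumina" and self.read_length < 1:
            problems.append("read_length: must be >= 1")
        if self.min_length < 1:
            problems.append("min_length: must be >= 1")
        if not 0.0 <= self.n_rate < 1.0:
            problems.append("n_rate: must be in [0, 1)")
        if not 0.0 <= self.motif_rate <= 1.0:
            problems.append("motif_rate: must be in [0, 1]")
        if not 0.0 <= self.stay_prob <= 1.0:
            problems.append("stay_prob: must be in [0, 1]")
        if not 0 <= self.q_low <= self.q_high <= 93:
            problems.append("q_low/q_high: need 0 <= low <= high <= 93")
        if self.jitter < 0:
            problems.append("jitter: must be >= 0")
        if "{i}" not in self.identifier_template:
            problems.append("identifier_template: must contain '{i}'")
        if problems:
            raise ValueError(
                "invalid generator config: " + "; ".join(problems)
            )


def _read_lengths(cfg: GeneratorConfig, rng) -> np.ndarray:
    if cfg.platform == "illumina":
        return np.full(cfg.n_reads, cfg.read_length, dtype=np.int64)
    raw = rng.lognormal(cfg.length_log_mean, cfg.length_log_sigma,
                        cfg.n_reads)
    return np.maximum(cfg.min_length, raw.astype(np.int64))


def _quality_read(cfg: GeneratorConfig, rng, length: int) -> str:
    """One read's quality string.

    The backbone level keeps its value with probability ``stay_prob`` and
    otherwise redraws uniformly over the span; because the stationary level
    distribution does not depend on ``stay_prob``, the lag-1 autocorrelation
    of the emitted scores grows monotonically with it while the per-symbol
    entropy shrinks.  A deterministic down-drift and bounded i.i.d. jitter
    are layered on top, everything clamped to ``[q_low, q_high]``.
    """
    lo, hi = cfg.q_low, cfg.q_high
    span = hi - lo + 1
    m = hi - int(rng.integers(0, min(5, span)))
    moves = rng.random(length) >= cfg.stay_prob
    fresh = rng.integers(lo, hi + 1, length)
    jit = (
        rng.integers(-cfg.jitter, cfg.jitter + 1, length)
        if cfg.jitter
        else np.zeros(length, dtype=np.int64)
    )
    drift = cfg.drift_per_100
    chars = bytearray(length)
    for t in range(length):
        if moves[t]:
            m = int(fresh[t])
        md = m - (drift * t) // 100
        if md < lo:
            md = lo
        e = md + int(jit[t])
        if e < lo:
            e = lo
        elif e > hi:
            e = hi
        chars[t] = 33 + e
    return chars.decode("latin-1")


def _sequence_read(cfg: GeneratorConfig, rng, length: int,
                   motif: np.ndarray) -> str:
    arr = _BASES[rng.integers(0, 4, length)]
    if cfg.motif_rate and rng.random() < cfg.motif_rate:
        start = int(rng.integers(0, max(1, length - len(motif) + 1)))
        take = min(len(motif), length - start)
        arr = arr.copy()
        arr[start:start + take] = motif[:take]
    if cfg.n_rate:
        mask = rng.random(length) < cfg.n_rate
        if mask.any():
            arr = arr.copy()
            arr[mask] = ord("N")
    return arr.tobytes().decode("latin-1")


def generate(config: GeneratorConfig) -> bytes:
    """Generate a FASTQ byte stream from ``config`` (deterministic)."""
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed))
    motif = _BASES[rng.integers(0, 4, _MOTIF_LEN)]
    lengths = _read_lengths(config, rng)
    nl = config.newline_style.bytes.decode("latin-1")
    records = []
    for k in range(config.n_reads):
        i = config.start_index + k
        length = int(lengths[k])
        ident = config.identifier_template.format(i=i, length=length)
        seq = _sequence_read(config, rng, length, motif)
        qual = _quality_read(config, rng, length)
        if config.plus_mode is PlusMode.BARE:
            plus = "+"
        elif config.plus_mode is PlusMode.MIRROR:
            plus = "+" + ident
        else:
            plus = "+comment for read {}".format(i) if k % 2 else "+"
        records.append(f"@{ident}{nl}{seq}{nl}{plus}{nl}{qual}{nl}")
    return "".join(records).encode("latin-1")


def fixture_matrix(base_seed: int = 20_000) -> Dict[str, bytes]:
    """The deterministic test-fixture suite: both platforms x all three
    plus-line modes x N-rate {0, 0.01}, plus degenerate edge cases.

    Sized so the whole matrix compresses and round-trips in well under a
    minute while still exercising every codec path.
    """
    fixtures: Dict[str, bytes] = {}
    seed = base_seed
    for platform in ("illumina", "pacbio"):
        for plus_mode in (PlusMode.BARE, PlusMode.MIRROR, PlusMode.VERBATIM):
            for n_rate in (0.0, 0.01):
                name = (
                    f"{platform}_{plus_mode.name.lower()}"
                    f"_n{str(n_rate).replace('.', '')}"
                )
                cfg = GeneratorConfig(
                    platform=platform,
                    n_reads=150 if platform == "illumina" else 60,
                    read_length=100,
                    n_rate=n_rate,
                    plus_mode=plus_mode,
                    seed=seed,
                )
                if platform == "pacbio":
                    cfg = replace(
                        cfg,
                        identifier_template="m000001_042/{i}/0_{length}",
                        q_low=0,
                        q_high=50,
                        stay_prob=0.8,
                    )
                fixtures[name] = generate(cfg)
                seed += 1
    fixtures["empty"] = b""
    fixtures["single_record"] = generate(
        GeneratorConfig(n_reads=1, read_length=60, seed=seed)
    )
    fixtures["constant_quality"] = generate(
        GeneratorConfig(
            n_reads=100,
            read_length=80,
            stay_prob=1.0,
            jitter=0,
            drift_per_100=0,
            q_low=40,
            q_high=40,
            seed=seed + 1,
        )
    )
    fixtures["illumina_crlf"] = generate(
        GeneratorConfig(
            n_reads=80,
            read_length=100,
            newline_style=NewlineStyle.CRLF,
            seed=seed + 2,
        )
    )
    return fixtures


def quality_lag1_autocorr(qualities) -> float:
    """Lag-1 Pearson autocorrelation of quality scores, computed within
    reads (pairs never straddle a read boundary)."""
    xs = []
    ys = []
    for q in qualities:
        vals = [ord(c) for c in q]
        xs.extend(vals[:-1])
        ys.extend(vals[1:])
    if len(xs) < 2:
        return float("nan")
    return float(np.corrcoef(np.asarray(xs, float), np.asarray(ys, float))[0, 1])
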