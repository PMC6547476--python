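"""Evaluation harness: compression ratio, speed, peak memory.

Mirrors the standard compressor-comparison protocol: every tool is run
single-threaded on the same input files, and for each tool x dataset pair a
:class:`BenchRecord` reports original and compressed sizes, the compression
ratio (original / compressed, larger is better), compression and
decompression speed, and whether decompression reproduced the input
byte-for-byte (measured by actual comparison, never assumed).

Speed is reported as *input* megabytes per wall-clock second by default.
The other convention — compressed (output) MB per second — is available via
``speed_basis="output"``; the input-relative reading is the conventional
one, since the literal output-relative figure rewards tools for compressing
*less*.

Baselines are the general-purpose codecs available as standard libraries
(deflate/zlib, bzip2, LZMA); a tool that fails yields an "N/A" row rather
than aborting the report.  Speed and memory numbers are hardware-dependent
and are reported, never asserted.
"""

import bz2
import csv
import io
import lzma
import subprocess
import time
import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional

from . import pipeline

__all__ = [
    "BenchRecord",
    "compression_ratio",
    "run_tool",
    "bench",
    "per_stream_ratios",
    "peak_memory_child",
    "format_report",
    "report_csv",
    "BASELINE_TOOLS",
]

_MB = 1_000_000.0


def compression_ratio(original_bytes: int, compressed_bytes: int) -> float:
    """original / compressed; errors on a zero-byte compressed size."""
    if compressed_bytes <= 0:
        raise ValueError("compressed size must be positive")
    return original_bytes / compressed_bytes


@dataclass
class BenchRecord:
    tool: str
    dataset: str
    input_size: int
    output_size: Optional[int] = None
    ratio: Optional[float] = None
    compress_speed_mb_s: Optional[float] = None
    decompress_speed_mb_s: Optional[float] = None
    peak_memory_mb: Optional[float] = None
    round_trip_exact: Optional[bool] = None
    error: Optional[str] = None

    @property
    def ok(self):
        return self.error is None

    def as_row(self) -> Dict[str, str]:
        def fmt(v, spec="{:.2f}"):
            return "N/A" if v is None else (
                spec.format(v) if isinstance(v, float) else str(v)
            )

        return {
            "tool": self.tool,
            "dataset": self.dataset,
            "input_size": str(self.input_size),
            "output_size": fmt(self.output_size),
            "ratio": fmt(self.ratio),
            "compress_MB_s": fmt(self.compress_speed_mb_s),
            "decompress_MB_s": fmt(self.decompress_speed_mb_s),
            "peak_memory_MB": fmt(self.peak_memory_mb),
            "round_trip": "N/A" if self.round_trip_exact is None
            else ("exact" if self.round_trip_exact else "MISMATCH"),
        }


class _Codec:
    def __init__(self, name, compress, decompress):
        self.name = name
        self.compress = compress
        self.decompress = decompress


BASELINE_TOOLS = {
    "deflate": _Codec("deflate",
                      lambda d: zlib.compress(d, 9), zlib.decompress),
    "bzip2": _Codec("bzip2", lambda d: bz2.compress(d, 9), bz2.decompress),
    "lzma": _Codec("lzma", lzma.compress, lzma.decompress),
}


def _self_codec(config=None):
    return _Codec(
        "self",
        lambda d: pipeline.compress_bytes(d, config),
        pipeline.decompress_bytes,
    )


def run_tool(tool: str, data: bytes, dataset: str = "<memory>",
             config=None, speed_basis: str = "input") -> BenchRecord:
    """Benchmark one tool on one in-memory dataset."""
    rec = BenchRecord(tool=tool, dataset=dataset, input_size=len(data))
    if tool == "self":
        codec = _self_codec(config)
    elif tool in BASELINE_TOOLS:
        codec = BASELINE_TOOLS[tool]
    else:
        rec.error = f"unknown tool {tool!r}"
        return rec
    try:
        t0 = time.perf_counter()
        compressed = codec.compress(data)
        t_c = time.perf_counter() - t0
        t0 = time.perf_counter()
        restored = codec.decompress(compressed)
        t_d = time.perf_counter() - t0
    except Exception as exc:  # a failing tool yields an N/A row
        rec.error = f"{type(exc).__name__}: {exc}"
        return rec
    rec.output_size = len(compressed)
    rec.ratio = compression_ratio(len(data), len(compressed))
    basis = len(data) if speed_basis == "input" else len(compressed)
    rec.compress_speed_mb_s = (basis / _MB / t_c) if t_c > 0 else None
    rec.decompress_speed_mb_s = (basis / _MB / t_d) if t_d > 0 else None
    rec.round_trip_exact = restored == data
    return rec


def bench(datasets: Dict[str, bytes], tools: List[str],
          config=None, speed_basis: str = "input") -> List[BenchRecord]:
    """One BenchRecord per tool x dataset."""
    records = []
    for name, data in datasets.items():
        for tool in tools:
            records.append(
                run_tool(tool, data, dataset=name, config=config,
                         speed_basis=speed_basis)
            )
    return records


def per_stream_ratios(data: bytes, config=None) -> Dict[str, object]:
    """Per-stream breakdown on one FASTQ input.

    Reports the identifier+sequence *collective* ratio and the quality-
    stream ratio (raw stream bytes over coded payload bytes), plus the
    accounting identity inputs: archive size, header overhead and the sum
    of payloads.
    """
    archive = pipeline.compress_bytes(data, config)
    sizes = pipeline.stream_sizes(archive)
    id_raw, id_pay = sizes["identifiers"]
    seq_raw, seq_pay = sizes["sequences"]
    qual_raw, qual_pay = sizes["qualities"]
    payload_total = sum(p for _, p in sizes.values())
    out = {
        "archive_size": len(archive),
        "payload_total": payload_total,
        "header_overhead": len(archive) - payload_total,
        "streams": sizes,
        "idseq_ratio": (id_raw + seq_raw) / (id_pay + seq_pay)
        if id_pay + seq_pay else None,
        "quality_ratio": qual_raw / qual_pay if qual_pay else None,
        "whole_file_ratio": len(data) / len(archive) if archive else None,
    }
    return out


def peak_memory_child(argv: List[str], poll_interval: float = 0.005
                      ) -> Optional[float]:
    """Run ``argv`` as a child process and report its peak RSS in MB.

    Samples ``/proc/<pid>/status`` (VmHWM) while the child runs and takes
    the high-water mark; returns None (reported as N/A) if the process
    cannot be started or sampled.
    """
    try:
        proc = subprocess.Popen(
            argv, stdout=subprocess.DEVNULL, stderr=subprocess.DEVNULL
        )
    except OSError:
        return None
    peak_kb = 0
    status_path = f"/proc/{proc.pid}/status"
    while True:
        try:
            with open(status_path) as fh:
                for line in fh:
                    if line.startswith("VmHWM:"):
                        peak_kb = max(peak_kb, int(line.split()[1]))
                        break
        except OSError:
            pass
        if proc.poll() is not None:
            break
        time.sleep(poll_interval)
    proc.wait()
    if peak_kb == 0:
        # fall back to the accounting the kernel keeps for reaped children
        try:
            import resource

            peak_kb = resource.getrusage(resource.RUSAGE_CHILDREN).ru_maxrss
        except Exception:
            return None
    return peak_kb / 1000.0 if peak_kb else None


_COLUMNS = ["tool", "dataset", "input_size", "output_size", "ratio",
            "compress_MB_s", "decompress_MB_s", "peak_memory_MB",
            "round_trip"]


def format_report(records: List[BenchRecord]) -> str:
    """Human-readable aligned table."""
    rows = [r.as_row() for r in records]
    widths = {c: max(len(c), *(len(row[c]) for row in rows)) if rows
              else len(c) for c in _COLUMNS}
    lines = ["  ".join(c.ljust(widths[c]) for c in _COLUMNS)]
    lines.append("  ".join("-" * widths[c] for c in _COLUMNS))
    for row in rows:
        lines.append("  ".join(row[c].ljust(widths[c]) for c in _COLUMNS))
    return "\n".join(lines)


def report_csv(records: List[BenchRecord]) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_COLUMNS)
    writer.writeheader()
    for r in records:
        writer.writerow(r.as_row())
    return buf.getvalue()
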