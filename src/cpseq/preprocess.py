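"""3'-adapter removal and 20-45 nt length selection."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from cpseq._util import ConfigurationError, hamming
from cpseq.iolib import FastqRead

DEFAULT_MIN_LEN = 20
DEFAULT_MAX_LEN = 45
ADAPTER_MISMATCH_FRACTION = 0.1  # tolerated mismatches per overlap, no indels


@dataclass
class PipelineConfig:
    adapter_seq: str
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    max_mismatch: int = 1
    min_adapter_overlap: int = 5
    keep_untrimmed: bool = False

    def __post_init__(self):
        if not self.adapter_seq:
            raise ConfigurationError("adapter_seq must be non-empty")
        if self.min_len > self.max_len:
            raise ConfigurationError("min_len must be <= max_len")
        if self.max_mismatch < 0:
            raise ConfigurationError("max_mismatch must be >= 0")


def trim_adapter(read: str, adapter: str, min_overlap: int = 5) -> tuple[str, bool]:
    """Remove the leftmost read suffix matching an adapter prefix.

    The suffix must overlap the adapter by at least ``min_overlap`` bases with
    at most 10% mismatches (floor) over the overlap; no indels. Returns the
    trimmed read and whether an adapter was found.
    """
    if not read:
        return "", False
    n = len(read)
    for i in range(n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        if overlap < min_overlap:
            break
        allowed = int(ADAPTER_MISMATCH_FRACTION * overlap)
        if hamming(read[i : i + overlap], adapter[:overlap], cutoff=allowed) <= allowed:
            return read[:i], True
    return read, False


@dataclass
class TrimSummary:
    n_input: int = 0
    n_adapter_found: int = 0
    n_length_selected: int = 0
    length_counts: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "input_reads": self.n_input,
                    "adapter_found": self.n_adapter_found,
                    "length_selected": self.n_length_selected,
                }
            ]
        )


def length_select(
    reads: list[FastqRead], min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN
) -> tuple[list[FastqRead], int]:
    """Keep reads with min_len <= length <= max_len; returns (kept, n_discarded)."""
    kept = [r for r in reads if min_len <= len(r.seq) <= max_len]
    return kept, len(reads) - len(kept)


def preprocess_reads(
    reads: list[FastqRead], cfg: PipelineConfig
) -> tuple[list[FastqRead], TrimSummary]:
    """Trim adapters, drop adapter-less reads (unless kept), length-select."""
    summary = TrimSummary(n_input=len(reads))
    trimmed: list[FastqRead] = []
    for r in reads:
        seq, found = trim_adapter(r.seq, cfg.adapter_seq, cfg.min_adapter_overlap)
        if found:
            summary.n_adapter_found += 1
        elif not cfg.keep_untrimmed:
            continue
        trimmed.append(FastqRead(r.id, seq, r.qual[: len(seq)]))
    selected, _ = length_select(trimmed, cfg.min_len, cfg.max_len)
    summary.n_length_selected = len(selected)
    for r in selected:
        summary.length_counts[len(r.seq)] = summary.length_counts.get(len(r.seq), 0) + 1
    return selected, summary
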