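"""Read-level QC and quantification.

Adapter trimming, the 18-25 nt length window typical of mature miRNAs,
a mean-Phred >= 30 quality rule, and exact-match assignment of kept reads
to a mature-miRNA reference.  Reads matching two or more references
equally well are treated as ambiguous and dropped (counted in the stats).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import pandas as pd

Read = tuple[str, str, list[int]]  # (name, sequence, phred qualities)


@dataclass
class ReadQCStats:
    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_discarded_length: int = 0
    n_discarded_quality: int = 0
    n_kept: int = 0
    n_assigned: int = 0
    n_ambiguous: int = 0
    mean_phred: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def trim_adapter(
    sequence: str,
    qualities: Sequence[int] | None,
    adapter: str,
    min_overlap: int = 5,
) -> tuple[str, list[int] | None, bool]:
    """Truncate at the leftmost occurrence of the adapter prefix.

    A full-length adapter match anywhere, or a prefix of at least
    ``min_overlap`` bases running off the 3' end, triggers truncation;
    qualities are cut in lockstep.  Returns (sequence, qualities, trimmed?).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(sequence)
    for i in range(n):
        overlap = min(len(adapter), n - i)
        if overlap < min_overlap:
            break
        if sequence[i : i + overlap] == adapter[:overlap]:
            quals = list(qualities[:i]) if qualities is not None else None
            return sequence[:i], quals, True
    return sequence, (list(qualities) if qualities is not None else None), False


def filter_reads(
    reads: Sequence[Read],
    min_len: int = 18,
    max_len: int = 25,
    min_mean_phred: float = 30.0,
) -> tuple[list[Read], ReadQCStats]:
    """Keep reads with min_len <= length <= max_len and mean Phred >= cutoff."""
    stats = ReadQCStats(n_input=len(reads))
    kept: list[Read] = []
    phred_sum = 0.0
    phred_n = 0
    for idx, read in enumerate(reads):
        try:
            name, seq, quals = read
            if len(seq) != len(quals):
                raise ValueError("length mismatch")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed read record at index {idx}: {exc}") from exc
        if not (min_len <= len(seq) <= max_len):
            stats.n_discarded_length += 1
            continue
        mean_q = sum(quals) / len(quals)
        if mean_q < min_mean_phred:
            stats.n_discarded_quality += 1
            continue
        kept.append(read)
        phred_sum += mean_q
        phred_n += 1
    stats.n_kept = len(kept)
    stats.mean_phred = phred_sum / phred_n if phred_n else float("nan")
    return kept, stats


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def quantify(
    reads: Sequence[Read],
    reference: Mapping[str, str],
    max_mismatches: int = 0,
    stats: ReadQCStats | None = None,
) -> tuple[pd.Series, ReadQCStats]:
    """Assign reads to mature reference sequences by full-length matching.

    A read is assigned iff its sequence equals a reference sequence with at
    most ``max_mismatches`` substitutions (same length); reads with two or
    more equally good best hits are dropped as ambiguous.  Returns the
    count column (indexed by miRNA id, zero-filled) and updated stats.
    """
    if not reference:
        raise ValueError("empty reference")
    seqs = list(reference.values())
    if len(set(seqs)) != len(seqs):
        raise ValueError("reference sequences are not unique")
    stats = stats or ReadQCStats(n_input=len(reads), n_kept=len(reads))
    exact = {seq: mid for mid, seq in reference.items()}
    by_length: dict[int, list[tuple[str, str]]] = {}
    for mid, seq in reference.items():
        by_length.setdefault(len(seq), []).append((mid, seq))

    counts = {mid: 0 for mid in reference}
    for name, seq, _quals in reads:
        hit = exact.get(seq)
        if hit is None and max_mismatches > 0:
            best, best_d, tied = None, max_mismatches + 1, False
            for mid, ref_seq in by_length.get(len(seq), ()):
                d = _hamming(seq, ref_seq)
                if d < best_d:
                    best, best_d, tied = mid, d, False
                elif d == best_d:
                    tied = True
            if best is not None and not tied:
                hit = best
            elif best is not None and tied:
                stats.n_ambiguous += 1
                continue
        if hit is not None:
            counts[hit] += 1
    column = pd.Series(counts, name="count").sort_index()
    stats.n_assigned = int(column.sum())
    if stats.n_assigned > stats.n_kept:
        raise AssertionError("assigned more reads than kept")
    return column, stats


def process_reads(
    reads: Sequence[Read],
    reference: Mapping[str, str],
    adapter: str,
    min_overlap: int = 5,
    min_len: int = 18,
    max_len: int = 25,
    min_mean_phred: float = 30.0,
    max_mismatches: int = 0,
) -> tuple[pd.Series, ReadQCStats]:
    """Trim -> length/quality filter -> quantify, tallying QC stats."""
    trimmed: list[Read] = []
    n_trimmed = 0
    for name, seq, quals in reads:
        tseq, tquals, did = trim_adapter(seq, quals, adapter, min_overlap)
        n_trimmed += did
        trimmed.append((name, tseq, tquals if tquals is not None else []))
    kept, stats = filter_reads(trimmed, min_len, max_len, min_mean_phred)
    stats.n_adapter_trimmed = n_trimmed
    column, stats = quantify(kept, reference, max_mismatches, stats)
    return column, stats
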