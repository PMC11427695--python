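"""Shared fixtures and the independent brute-force assignment oracle."""

from __future__ import annotations

from itertools import product
from typing import Optional

import pytest

from mgidemux import SampleRecord, SampleSheet


def naive_assign(
    observed: str,
    records,
    m7: int,
    m5: int,
) -> tuple[str, frozenset[str], Optional[int]]:
    """Reference demultiplexer: scan every sample-sheet record, compute the
    per-index hamming distances directly, and apply the best-match/tie
    rules. Returns (verdict, sample_ids at minimal distance, total distance).

    Deliberately independent of the lookup-table implementation.
    """
    best_total = None
    best_samples: set[str] = set()
    for rec in records:
        expected = rec.i7 + (rec.i5 or "")
        assert len(expected) == len(observed)
        d7 = sum(a != b for a, b in zip(observed[: len(rec.i7)], rec.i7))
        d5 = (
            sum(a != b for a, b in zip(observed[len(rec.i7):], rec.i5))
            if rec.i5
            else 0
        )
        if d7 > m7 or d5 > m5:
            continue
        total = d7 + d5
        if best_total is None or total < best_total:
            best_total = total
            best_samples = {rec.sample_id}
        elif total == best_total:
            best_samples.add(rec.sample_id)
    if best_total is None:
        return "undetermined", frozenset(), None
    if len(best_samples) > 1:
        return "ambiguous", frozenset(best_samples), best_total
    return "sample", frozenset(best_samples), best_total


def all_strings(length: int, alphabet: str = "ACGTN"):
    """Every string of the given length over the alphabet."""
    for chars in product(alphabet, repeat=length):
        yield "".join(chars)


@pytest.fixture
def dual_sheet() -> SampleSheet:
    """Four dual-index samples, 4 bp indices, pairwise distance >= 3."""
    return SampleSheet(
        records=(
            SampleRecord("S1", "AAAA", "CCCC"),
            SampleRecord("S2", "TTTT", "GGGG"),
            SampleRecord("S3", "ACGT", "TGCA"),
            SampleRecord("S4", "GTAC", "ATGC"),
        )
    )


@pytest.fixture
def single_sheet() -> SampleSheet:
    """Two single-index samples at pairwise distance 4."""
    return SampleSheet(
        records=(
            SampleRecord("S1", "AAAA"),
            SampleRecord("S2", "TTTT"),
        )
    )
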