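"""Mismatch-expansion lookup table for index matching.

Demultiplexing must tolerate sequencing errors in the index bases. Rather
than comparing each observed index against every sample at run time, the
table pre-computes, for every sample-sheet index, its full hamming ball of
radius *m* — every string reachable by substituting at most *m* positions
with a different character from {A, C, G, T, N} — and maps each variant to
the sample(s) at minimal distance. Assigning a read is then a single
dictionary fetch regardless of *m*.

An ``N`` called by the sequencer counts as one mismatch against any expected
base; expected indices themselves may not contain N. Mismatch budgets are
per index (``m7`` for i7, ``m5`` for i5). When variants of two samples
collide on the same key, only the sample(s) at minimal total distance
d7 + d5 are kept; a tie on the total marks the key ambiguous.

The expansion is exponential in *m* (ball volume sum_{k<=m} C(L,k)*4^k per
index), so keeping *m* at 1, at most 2, is strongly advised; a key-count
guard refuses pathological requests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Optional

from .errors import ValidationError
from .samplesheet import SampleSheet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = "ACGTN"

#: Default cap on total precomputed keys (guards against runaway m).
DEFAULT_MAX_KEYS = 50_000_000


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N self-complements."""
    if set(seq) - set(_ALPHABET):
        raise ValidationError(
            f"cannot reverse-complement {seq!r}: alphabet is {{A,C,G,T,N}}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_distance(a: str, b: str) -> int:
    """Number of differing positions between equal-length strings."""
    if len(a) != len(b):
        raise ValidationError(f"hamming distance undefined for lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def hamming_ball(index: str, m: int) -> dict[str, int]:
    """All strings within hamming distance ``m`` of ``index``, with distances.

    Substituted positions take any character from {A,C,G,T,N} different from
    the original, so the ball holds sum_{k=0..m} C(L,k)*4^k strings; each
    maps to its substitution count.
    """
    if m < 0:
        raise ValidationError(f"mismatch allowance m must be >= 0, got {m}")
    if set(index) - set("ACGT"):
        raise ValidationError(f"expected index {index!r} must be over {{A,C,G,T}}")
    if m > len(index):
        raise ValidationError(f"m={m} exceeds index length {len(index)}")
    ball = {index: 0}
    chars = list(index)
    for k in range(1, m + 1):
        for positions in combinations(range(len(index)), k):
            alternatives = [
                [c for c in _ALPHABET if c != chars[p]] for p in positions
            ]
            for subs in product(*alternatives):
                variant = chars.copy()
                for p, c in zip(positions, subs):
                    variant[p] = c
                ball["".join(variant)] = k
    return ball


def ball_volume(length: int, m: int) -> int:
    """Closed-form ball size: sum_{k=0..m} C(length,k)*4^k."""
    return sum(math.comb(length, k) * 4**k for k in range(m + 1))


@dataclass(frozen=True)
class MatchEntry:
    """Verdict stored for one observed-index key.

    ``sample_indices`` holds sample-sheet record indices at minimal total
    distance — one record per distinct sample id, so with index diversity a
    key equidistant from two index pairs of the *same* sample resolves to
    that sample, not to an ambiguity.
    """

    sample_indices: frozenset[int]
    d7: int
    d5: int = 0

    @property
    def ambiguous(self) -> bool:
        return len(self.sample_indices) > 1

    @property
    def total_distance(self) -> int:
        return self.d7 + self.d5


@dataclass
class IndexLookup:
    """Precomputed map from observed index string to :class:`MatchEntry`."""

    entries: dict[str, MatchEntry]
    m7: int
    m5: int
    i7_len: int
    i5_len: Optional[int]
    record_indices: tuple[int, ...] = field(default=())

    @property
    def key_length(self) -> int:
        return self.i7_len + (self.i5_len or 0)

    @property
    def dual(self) -> bool:
        return self.i5_len is not None

    def lookup(self, observed: str) -> Optional[MatchEntry]:
        """One dictionary fetch; never scans the sample sheet.

        Returns ``None`` for no match within (m7, m5). Raises on length
        mismatch — that signals a template/sample-sheet inconsistency.
        """
        if len(observed) != self.key_length:
            raise ValidationError(
                f"observed index length {len(observed)} != table key length "
                f"{self.key_length} (template and sample sheet disagree?)"
            )
        return self.entries.get(observed)


def build_lookup(
    sheet: SampleSheet,
    group: Optional[list[int]] = None,
    m7: int = 1,
    m5: int = 1,
    max_keys: int = DEFAULT_MAX_KEYS,
) -> IndexLookup:
    """Expand every index of the given template group into its hamming ball
    and assemble the lookup table.

    ``group`` lists sample-sheet record indices (default: all records).
    For dual-index records the keys are concatenations of an i7 variant and
    an i5 variant, so the table resolves both indices in one fetch.
    """
    if group is None:
        group = list(range(len(sheet.records)))
    if not group:
        raise ValidationError("cannot build a lookup table for an empty group")
    if m7 < 0 or m5 < 0:
        raise ValidationError("mismatch allowances must be >= 0")

    recs = [sheet.records[i] for i in group]
    i7_len = len(recs[0].i7)
    dual = recs[0].dual
    i5_len = len(recs[0].i5) if dual else None

    predicted = len(recs) * ball_volume(i7_len, min(m7, i7_len))
    if dual:
        predicted *= ball_volume(i5_len, min(m5, i5_len))
    if predicted > max_keys:
        raise ValidationError(
            f"predicted key count {predicted} exceeds cap {max_keys}; "
            f"reduce the mismatch allowance (m7={m7}, m5={m5})"
        )

    sample_numbers = sheet.sample_numbers()
    # key -> (best_total, {sample_id: (record_idx, d7, d5)})
    best: dict[str, tuple[int, dict[str, tuple[int, int, int]]]] = {}
    for rec_idx, rec in zip(group, recs):
        ball7 = hamming_ball(rec.i7, min(m7, i7_len))
        if dual:
            ball5 = hamming_ball(rec.i5, min(m5, i5_len))
            items = (
                (v7 + v5, d7, d5)
                for v7, d7 in ball7.items()
                for v5, d5 in ball5.items()
            )
        else:
            items = ((v7, d7, 0) for v7, d7 in ball7.items())
        sid = rec.sample_id
        for key, d7, d5 in items:
            total = d7 + d5
            cur = best.get(key)
            if cur is None or total < cur[0]:
                best[key] = (total, {sid: (rec_idx, d7, d5)})
            elif total == cur[0]:
                # tie: keep one record per distinct sample id
                cur[1].setdefault(sid, (rec_idx, d7, d5))

    entries: dict[str, MatchEntry] = {}
    for key, (total, by_sample) in best.items():
        rec_idxs = frozenset(v[0] for v in by_sample.values())
        # d7/d5 decompositions may differ among tied samples; report the
        # lexicographically smallest (d7, d5) at the shared total distance
        d7, d5 = min((v[1], v[2]) for v in by_sample.values())
        entries[key] = MatchEntry(sample_indices=rec_idxs, d7=d7, d5=d5)

    return IndexLookup(
        entries=entries,
        m7=m7,
        m5=m5,
        i7_len=i7_len,
        i5_len=i5_len,
        record_indices=tuple(group),
    )


def lookup(table: IndexLookup, observed: str) -> Optional[MatchEntry]:
    """Functional alias for :meth:`IndexLookup.lookup`."""
    return table.lookup(observed)
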