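"""Barcode template: layout of i7/i5/UMI in the read-barcode tail.

The read barcode — the non-biological tail of R2 (paired-end) or R1
(single-end) — concatenates the sample indices and, for some library preps,
a UMI, in an order and orientation that varies between kits. A
:class:`BarcodeTemplate` declares that layout: an ordered list of segments
(kind, length, and for indices whether the observed sequence must be
reverse-complemented before comparison with the sample sheet).

Template spec strings are colon-separated ``<kind>[rc].<length>`` segments
with kinds ``i7``, ``i5`` and ``um``, e.g. ``"i5rc.8:i7.8:um.8"``.

When the layout is unknown, :func:`detect_template` enumerates every
candidate layout (all index orders, all reverse-complement on/off
combinations, the UMI in any gap) and scores each by the number of sampled
reads whose extracted indices exactly match a sample-sheet record, reporting
candidates ranked by match count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from itertools import permutations, product
from typing import Optional, Sequence

from .errors import FormatError, ValidationError
from .index_match import reverse_complement
from .samplesheet import SampleSheet

VALID_KINDS = ("i7", "i5", "umi")

_SEG_RE = re.compile(r"^(i7|i5|um)(rc)?\.(\d+)$")


@dataclass(frozen=True)
class TemplateSegment:
    """One region of the read barcode: its kind, length in bp, and for
    index segments whether it is stored in reverse-complement orientation."""

    kind: str  # "i7" | "i5" | "umi"
    length: int
    rc: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValidationError(f"unknown segment kind {self.kind!r}")
        if self.length < 1:
            raise ValidationError(f"segment length must be >= 1, got {self.length}")
        if self.kind == "umi" and self.rc:
            raise ValidationError("a UMI segment has no orientation (rc not allowed)")

    def to_spec(self) -> str:
        kind = "um" if self.kind == "umi" else self.kind
        return f"{kind}{'rc' if self.rc else ''}.{self.length}"


@dataclass(frozen=True)
class BarcodeTemplate:
    """Ordered segments, 5'->3' within the barcode region."""

    segments: tuple[TemplateSegment, ...]

    def __post_init__(self) -> None:
        kinds = [s.kind for s in self.segments]
        for k in set(kinds):
            if kinds.count(k) > 1:
                raise ValidationError(f"template has more than one {k} segment")
        if "i7" not in kinds:
            raise ValidationError("template must contain an i7 segment")

    @property
    def barcode_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def dual(self) -> bool:
        return any(s.kind == "i5" for s in self.segments)

    @property
    def has_umi(self) -> bool:
        return any(s.kind == "umi" for s in self.segments)

    def segment(self, kind: str) -> Optional[TemplateSegment]:
        for s in self.segments:
            if s.kind == kind:
                return s
        return None

    def to_spec(self) -> str:
        return ":".join(s.to_spec() for s in self.segments)

    def __str__(self) -> str:
        return self.to_spec()


@dataclass(frozen=True)
class TemplateScore:
    """A candidate template and its exact-match count over the sampled reads."""

    template: BarcodeTemplate
    matches: int


def parse_template(spec: str) -> BarcodeTemplate:
    """Parse a spec string like ``"i5rc.8:i7.8:um.8"``."""
    if not spec or not spec.strip():
        raise FormatError("empty template spec")
    segments = []
    for part in spec.strip().split(":"):
        m = _SEG_RE.match(part.strip())
        if not m:
            raise FormatError(
                f"bad template segment {part!r}; expected <i7|i5|um>[rc].<length>"
            )
        kind, rc, length = m.groups()
        kind = "umi" if kind == "um" else kind
        try:
            segments.append(TemplateSegment(kind=kind, length=int(length), rc=bool(rc)))
        except ValidationError as exc:
            raise FormatError(f"bad template segment {part!r}: {exc}") from exc
    try:
        return BarcodeTemplate(segments=tuple(segments))
    except ValidationError as exc:
        raise FormatError(f"invalid template {spec!r}: {exc}") from exc


def expected_barcode_length(t: BarcodeTemplate) -> int:
    """Total barcode length in bp — e.g. 16 for an 8 bp + 8 bp dual index."""
    return t.barcode_length


def enumerate_candidates(
    i7_len: int, i5_len: Optional[int], barcode_len: int
) -> list[BarcodeTemplate]:
    """All layouts consistent with the index lengths and barcode length.

    Every ordering of the present index segments, every reverse-complement
    on/off combination per index, and — when the barcode is longer than the
    indices — one contiguous UMI filling the whole remainder placed in any
    gap (before, between, after the index segments).
    """
    index_lens = [("i7", i7_len)] + ([("i5", i5_len)] if i5_len else [])
    remainder = barcode_len - sum(l for _, l in index_lens)
    if remainder < 0:
        raise ValidationError(
            f"barcode length {barcode_len} shorter than the combined index "
            f"length {sum(l for _, l in index_lens)}"
        )

    out: list[BarcodeTemplate] = []
    seen: set[tuple] = set()
    for order in permutations(index_lens):
        for rcs in product([False, True], repeat=len(order)):
            index_segs = [
                TemplateSegment(kind=k, length=l, rc=rc)
                for (k, l), rc in zip(order, rcs)
            ]
            if remainder == 0:
                layouts = [index_segs]
            else:
                umi = TemplateSegment(kind="umi", length=remainder)
                layouts = [
                    index_segs[:slot] + [umi] + index_segs[slot:]
                    for slot in range(len(index_segs) + 1)
                ]
            for segs in layouts:
                key = tuple(segs)
                if key not in seen:
                    seen.add(key)
                    out.append(BarcodeTemplate(segments=tuple(segs)))
    return out


def extract_indices(barcode: str, t: BarcodeTemplate) -> tuple[str, Optional[str], Optional[str]]:
    """Slice (i7_obs, i5_obs, umi) out of a barcode string per the template.

    rc-flagged index segments are reverse-complemented so the returned
    observations are directly comparable with sample-sheet indices.
    """
    if len(barcode) != t.barcode_length:
        raise ValidationError(
            f"barcode length {len(barcode)} != template length {t.barcode_length}"
        )
    i7 = i5 = umi = None
    pos = 0
    for seg in t.segments:
        piece = barcode[pos : pos + seg.length]
        pos += seg.length
        if seg.kind == "umi":
            umi = piece
        else:
            obs = reverse_complement(piece) if seg.rc else piece
            if seg.kind == "i7":
                i7 = obs
            else:
                i5 = obs
    return i7, i5, umi


def detect_template(
    barcode_reads: Sequence[str],
    sheet: SampleSheet,
    limit: int = 5000,
) -> list[TemplateScore]:
    """Score every candidate layout against the sample sheet.

    ``barcode_reads`` are barcode-region strings (equal length, taken from
    the tail of the barcode-bearing read). Each candidate is scored by the
    number of the first ``limit`` reads whose extracted indices exactly
    match some sample-sheet record; candidates are returned ranked by
    matches descending, ties broken by the canonical (lexicographic)
    ordering of their spec strings — ties are all reported.

    A warning is issued when even the best candidate matches fewer than half
    the sampled reads, which usually means wrong index lengths, a truncated
    barcode region, or a sheet from a different run.
    """
    if not sheet.records:
        raise ValidationError("empty sample sheet")
    if not barcode_reads:
        raise ValidationError("no barcode reads to score")
    if limit < 1:
        raise ValidationError("limit must be >= 1")
    sample = list(barcode_reads[:limit])
    lengths = {len(b) for b in sample}
    if len(lengths) > 1:
        raise ValidationError(f"barcode reads have unequal lengths {sorted(lengths)}")
    barcode_len = lengths.pop()

    rec0 = sheet.records[0]
    i7_len = len(rec0.i7)
    i5_len = len(rec0.i5) if rec0.dual else None
    pairs = {(r.i7, r.i5) for r in sheet.records}

    scores = []
    for cand in enumerate_candidates(i7_len, i5_len, barcode_len):
        n = 0
        for bc in sample:
            i7, i5, _ = extract_indices(bc, cand)
            if (i7, i5) in pairs:
                n += 1
        scores.append(TemplateScore(template=cand, matches=n))

    scores.sort(key=lambda s: (-s.matches, s.template.to_spec()))
    if scores and scores[0].matches < 0.5 * len(sample):
        warnings.warn(
            f"low-confidence template detection: best candidate "
            f"{scores[0].template} matches only {scores[0].matches}/{len(sample)} "
            f"sampled reads"
        )
    return scores
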