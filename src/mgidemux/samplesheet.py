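"""Sample sheet parsing and validation.

The sample sheet is a UTF-8, tab-delimited file with a header row. Recognized
columns are ``sample_id`` and ``i7`` (mandatory), plus optional ``i5``,
``template`` (a per-sample barcode-template override for mixed libraries) and
``project``. Unknown columns are ignored with a warning.

A sample may appear in several rows under distinct index pairs ("index
diversity"); all its reads are routed to the same output files. Only the full
(i7, i5) pair must be unique within a template group — the same i7 under
different i5 values across samples is legal because the dual index
disambiguates.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import FormatError, ValidationError

_VALID_INDEX_CHARS = frozenset("ACGT")

#: Columns the parser understands, in canonical output order.
KNOWN_COLUMNS = ("sample_id", "i7", "i5", "template", "project")


@dataclass(frozen=True)
class SampleRecord:
    """One sample-sheet row: a sample id and its expected index pair."""

    sample_id: str
    i7: str
    i5: Optional[str] = None
    template_override: Optional[str] = None
    project: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        _check_index(self.i7, "i7", self.sample_id)
        if self.i5 is not None:
            _check_index(self.i5, "i5", self.sample_id)

    @property
    def dual(self) -> bool:
        return self.i5 is not None

    @property
    def index_pair(self) -> tuple[str, Optional[str]]:
        return (self.i7, self.i5)


def _check_index(seq: str, name: str, sample_id: str) -> None:
    if not seq:
        raise ValidationError(f"{name} for sample {sample_id!r} is empty")
    bad = set(seq) - _VALID_INDEX_CHARS
    if bad:
        raise ValidationError(
            f"{name} for sample {sample_id!r} contains non-ACGT "
            f"character(s) {sorted(bad)}: {seq!r}"
        )


@dataclass(frozen=True)
class SampleSheet:
    """An ordered, validated collection of :class:`SampleRecord`.

    Records are grouped by their barcode-template override (``None`` for
    records relying on the run-level template). Within one group all i7
    must share a length and all i5 must share a length, and no two records
    may carry an identical (i7, i5) pair — such samples would be
    inseparable.
    """

    records: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("sample sheet has no records")
        self._validate_groups()

    def _validate_groups(self) -> None:
        for tmpl, idxs in self.template_groups().items():
            label = tmpl if tmpl is not None else "<default>"
            seen: dict[tuple[str, Optional[str]], int] = {}
            i7_lens = set()
            i5_lens = set()
            for i in idxs:
                rec = self.records[i]
                pair = rec.index_pair
                if pair in seen:
                    raise ValidationError(
                        f"duplicate index pair {pair} in template group "
                        f"{label}: rows {seen[pair] + 1} "
                        f"({self.records[seen[pair]].sample_id!r}) and "
                        f"{i + 1} ({rec.sample_id!r})"
                    )
                seen[pair] = i
                i7_lens.add(len(rec.i7))
                if rec.i5 is not None:
                    i5_lens.add(len(rec.i5))
            if len(i7_lens) > 1:
                raise ValidationError(
                    f"unequal i7 lengths {sorted(i7_lens)} in template group {label}"
                )
            if len(i5_lens) > 1:
                raise ValidationError(
                    f"unequal i5 lengths {sorted(i5_lens)} in template group {label}"
                )
            dual = {self.records[i].dual for i in idxs}
            if len(dual) > 1:
                raise ValidationError(
                    f"template group {label} mixes single- and dual-index records"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def template_groups(self) -> dict[Optional[str], list[int]]:
        """Map template-override string (None = run default) to record indices."""
        groups: dict[Optional[str], list[int]] = {}
        for i, rec in enumerate(self.records):
            groups.setdefault(rec.template_override, []).append(i)
        return groups

    def sample_numbers(self) -> dict[str, int]:
        """1-based sample numbers by order of first appearance (for S<N> naming)."""
        numbers: dict[str, int] = {}
        for rec in self.records:
            if rec.sample_id not in numbers:
                numbers[rec.sample_id] = len(numbers) + 1
        return numbers

    def sample_ids(self) -> list[str]:
        """Distinct sample ids in order of first appearance."""
        return list(self.sample_numbers())

    def projects(self) -> dict[str, Optional[str]]:
        """sample_id -> project label (first non-empty wins)."""
        out: dict[str, Optional[str]] = {}
        for rec in self.records:
            if rec.sample_id not in out or out[rec.sample_id] is None:
                out[rec.sample_id] = rec.project
        return out


def parse_sample_sheet(source: Union[str, Path, io.TextIOBase]) -> SampleSheet:
    """Parse a TSV sample sheet.

    ``source`` may be a path, raw TSV text (must contain a newline or tab),
    or an open text handle. Index strings are upper-cased on read; hamming
    comparison downstream is therefore case-insensitive.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        if "\n" not in source and "\t" not in source:
            text = Path(source).read_text()
        else:
            text = source
    else:
        text = source.read()

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("sample sheet is empty")

    header = [h.strip().lower() for h in lines[0].split("\t")]
    unknown = [h for h in header if h not in KNOWN_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown sample sheet column(s): {unknown}")
    for col in ("sample_id", "i7"):
        if col not in header:
            raise FormatError(f"sample sheet header is missing mandatory column {col!r}")
    pos = {name: header.index(name) for name in header if name in KNOWN_COLUMNS}

    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")

        def get(col: str) -> Optional[str]:
            i = pos.get(col)
            if i is None or i >= len(fields):
                return None
            v = fields[i].strip()
            return v or None

        sample_id = get("sample_id")
        i7 = get("i7")
        if sample_id is None or i7 is None:
            raise FormatError(f"line {lineno}: missing sample_id or i7")
        i5 = get("i5")
        try:
            records.append(
                SampleRecord(
                    sample_id=sample_id,
                    i7=i7.upper(),
                    i5=i5.upper() if i5 else None,
                    template_override=get("template"),
                    project=get("project"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from exc

    return SampleSheet(records=tuple(records))


def format_sample_sheet(sheet: SampleSheet) -> str:
    """Serialize back to TSV such that ``parse(format(sheet)) == sheet``."""
    cols = ["sample_id", "i7"]
    if any(r.i5 is not None for r in sheet):
        cols.append("i5")
    if any(r.template_override is not None for r in sheet):
        cols.append("template")
    if any(r.project is not None for r in sheet):
        cols.append("project")
    out = ["\t".join(cols)]
    for r in sheet:
        vals = {
            "sample_id": r.sample_id,
            "i7": r.i7,
            "i5": r.i5 or "",
            "template": r.template_override or "",
            "project": r.project or "",
        }
        out.append("\t".join(vals[c] for c in cols))
    return "\n".join(out) + "\n"
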