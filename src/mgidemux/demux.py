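"""Streaming demultiplexer for MGI FASTQ runs.

Reads are streamed once; for each read the barcode region is sliced off the
tail of the barcode-bearing mate (R2 for paired-end, R1 for single-end),
the observed indices are looked up in the precomputed mismatch table, and
the read pair is written — barcode trimmed, header rewritten in the chosen
dialect, UMI carried into both mates' headers — to the per-sample output
files. Input order is preserved within every output file.

MGI read-header grammar used throughout (parser and simulator share it)::

    @<flowcell>L<lane:1 digit>C<col:3 digits>R<row:3 digits><serial>/<mate>

Illumina-dialect output synthesizes a syntactically standard header from
those coordinates: tile = column*1000 + row, x = serial, y = 1.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from ._fastq import DEFAULT_BUFFER_SIZE, BufferedGzipWriter, read_fastq
from .errors import ConfigError, FormatError, ValidationError
from .index_match import DEFAULT_MAX_KEYS, IndexLookup, build_lookup
from .reports import LaneReport, RunReport, update_stats, write_reports
from .samplesheet import SampleSheet, parse_sample_sheet
from .template import BarcodeTemplate, extract_indices, parse_template

_MGI_ID_RE = re.compile(r"^@(.+)L(\d)C(\d{3})R(\d{3})(\d+)/([12])$")

UNDETERMINED = "Undetermined"
AMBIGUOUS = "Ambiguous"


@dataclass(frozen=True)
class MgiReadId:
    """Parsed MGI read header coordinates."""

    flowcell: str
    lane: int
    column: int
    row: int
    serial: int
    mate: int

    def __post_init__(self) -> None:
        if self.lane < 1:
            raise ValidationError(f"lane must be >= 1, got {self.lane}")
        if self.mate not in (1, 2):
            raise ValidationError(f"mate must be 1 or 2, got {self.mate}")


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ record; ``id`` may be a raw header or a parsed MgiReadId."""

    id: Union[str, MgiReadId]
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValidationError(
                f"sequence/quality length mismatch ({len(self.sequence)} vs "
                f"{len(self.quality)}) for read {self.id}"
            )


@dataclass(frozen=True)
class Assignment:
    """Per-read verdict: the sample it belongs to, or why it does not."""

    verdict: str  # "sample" | "undetermined" | "ambiguous"
    sample_index: Optional[int] = None  # sample-sheet record index
    d7: int = 0
    d5: int = 0
    umi: Optional[str] = None
    observed_barcode: str = ""


def parse_mgi_read_id(header: str) -> MgiReadId:
    """Parse an MGI header like ``@V300014293L2C001R0030000123/1``."""
    m = _MGI_ID_RE.match(header)
    if not m:
        raise FormatError(f"not an MGI read header: {header!r}")
    fc, lane, col, row, serial, mate = m.groups()
    return MgiReadId(
        flowcell=fc,
        lane=int(lane),
        column=int(col),
        row=int(row),
        serial=int(serial),
        mate=int(mate),
    )


def extract_barcode(
    read: ReadRecord, t: BarcodeTemplate
) -> tuple[str, Optional[str], Optional[str], ReadRecord]:
    """Slice the barcode off the read tail and trim it.

    Returns (i7_obs, i5_obs, umi, trimmed): observations for rc-flagged
    segments are reverse-complemented, so they compare directly with the
    sample sheet; ``trimmed`` is the read with the barcode region removed
    from both sequence and quality.
    """
    bl = t.barcode_length
    if len(read.sequence) < bl:
        raise ValidationError(
            f"read {read.id} ({len(read.sequence)} bp) shorter than the "
            f"barcode region ({bl} bp)"
        )
    barcode = read.sequence[-bl:]
    i7, i5, umi = extract_indices(barcode, t)
    trimmed = ReadRecord(
        id=read.id,
        sequence=read.sequence[:-bl],
        quality=read.quality[:-bl],
    )
    return i7, i5, umi, trimmed


def assign_read(
    i7_obs: str, i5_obs: Optional[str], table: IndexLookup
) -> Assignment:
    """One lookup on the concatenated observation; verdict per the tie rules."""
    observed = i7_obs + (i5_obs or "")
    entry = table.lookup(observed)
    if entry is None:
        return Assignment(verdict="undetermined", observed_barcode=observed)
    if entry.ambiguous:
        return Assignment(
            verdict="ambiguous", d7=entry.d7, d5=entry.d5, observed_barcode=observed
        )
    return Assignment(
        verdict="sample",
        sample_index=next(iter(entry.sample_indices)),
        d7=entry.d7,
        d5=entry.d5,
        observed_barcode=observed,
    )


def format_output_id(
    rid: MgiReadId,
    dialect: str,
    umi: Optional[str] = None,
    index_annot: str = "",
    original: Optional[str] = None,
) -> str:
    """Render the output header for one mate.

    MGI dialect keeps the original header (UMI, when present, appended to
    the read id after ``#``). Illumina dialect synthesizes
    ``@<fc>:1:<fc>:<lane>:<tile>:<x>:<y>[:<umi>] <mate>:N:0:<index_annot>``
    with tile = column*1000 + row, x = serial, y = 1.
    """
    if dialect == "mgi":
        base = original if original is not None else (
            f"@{rid.flowcell}L{rid.lane}C{rid.column:03d}R{rid.row:03d}"
            f"{rid.serial:07d}/{rid.mate}"
        )
        if umi:
            stem, _, mate = base.rpartition("/")
            return f"{stem}#{umi}/{mate}"
        return base
    if dialect == "illumina":
        tile = rid.column * 1000 + rid.row
        coord = f"@{rid.flowcell}:1:{rid.flowcell}:{rid.lane}:{tile}:{rid.serial}:1"
        if umi:
            coord += f":{umi}"
        return f"{coord} {rid.mate}:N:0:{index_annot}"
    raise ConfigError(f"unknown dialect {dialect!r}")


def output_path(
    sample_id: str,
    sample_number: int,
    lane: int,
    mate: int,
    dialect: str,
    flowcell: str = "",
) -> str:
    """Per-sample output file name in the chosen dialect."""
    if dialect == "illumina":
        return f"{sample_id}_S{sample_number}_L{lane:03d}_R{mate}_001.fastq.gz"
    if dialect == "mgi":
        return f"{flowcell}_L{lane:02d}_{sample_id}_{mate}.fq.gz"
    raise ConfigError(f"unknown dialect {dialect!r}")


@dataclass
class _Group:
    """One template group: its records, parsed template, and lookup table."""

    template: BarcodeTemplate
    record_indices: list[int]
    table: IndexLookup


def _build_groups(
    sheet: SampleSheet,
    default_template: Optional[BarcodeTemplate],
    m7: int,
    m5: int,
    max_keys: int,
) -> list[_Group]:
    groups = []
    for tmpl_spec, idxs in sheet.template_groups().items():
        if tmpl_spec is not None:
            t = parse_template(tmpl_spec)
        elif default_template is not None:
            t = default_template
        else:
            raise ConfigError(
                "no run-level template given and some sample-sheet records "
                "carry no template override"
            )
        rec = sheet.records[idxs[0]]
        seg7 = t.segment("i7")
        if seg7.length != len(rec.i7):
            raise ConfigError(
                f"template i7 length {seg7.length} != sample-sheet i7 length "
                f"{len(rec.i7)} (template {t})"
            )
        seg5 = t.segment("i5")
        if rec.dual != (seg5 is not None):
            raise ConfigError(
                f"template {t} and sample sheet disagree on dual indexing"
            )
        if seg5 is not None and seg5.length != len(rec.i5):
            raise ConfigError(
                f"template i5 length {seg5.length} != sample-sheet i5 length "
                f"{len(rec.i5)} (template {t})"
            )
        groups.append(
            _Group(
                template=t,
                record_indices=idxs,
                table=build_lookup(sheet, idxs, m7=m7, m5=m5, max_keys=max_keys),
            )
        )
    return groups


class _OutputPool:
    """Lazy per-(lane, sample, mate) buffered gzip writers."""

    def __init__(self, out_dir: Path, dialect: str, sheet: SampleSheet,
                 mates: tuple[int, ...], separate_ambiguous: bool,
                 buffer_size: int):
        self.out_dir = out_dir
        self.dialect = dialect
        self.sheet = sheet
        self.mates = mates
        self.separate_ambiguous = separate_ambiguous
        self.buffer_size = buffer_size
        self.numbers = sheet.sample_numbers()
        self.writers: dict[tuple[int, str, int], BufferedGzipWriter] = {}
        self._lanes_seen: set[int] = set()

    def _open(self, lane: int, sample_id: str, mate: int, flowcell: str) -> None:
        number = self.numbers.get(sample_id, 0)
        name = output_path(sample_id, number, lane, mate, self.dialect, flowcell)
        self.writers[(lane, sample_id, mate)] = BufferedGzipWriter(
            self.out_dir / name, buffer_size=self.buffer_size
        )

    def ensure_lane(self, lane: int, flowcell: str) -> None:
        """Create all output files for a lane on first sight, so every
        sample gets a (possibly empty) file."""
        if lane in self._lanes_seen:
            return
        self._lanes_seen.add(lane)
        targets = list(self.numbers) + [UNDETERMINED]
        if self.separate_ambiguous:
            targets.append(AMBIGUOUS)
        for sid in targets:
            for mate in self.mates:
                self._open(lane, sid, mate, flowcell)

    def get(self, lane: int, sample_id: str, mate: int) -> BufferedGzipWriter:
        return self.writers[(lane, sample_id, mate)]

    def close(self) -> None:
        for w in self.writers.values():
            w.close()


def demultiplex_run(
    r1: Union[str, Path],
    r2: Optional[Union[str, Path]] = None,
    *,
    sheet: Union[SampleSheet, str, Path],
    template: Optional[Union[BarcodeTemplate, str]] = None,
    m7: int = 1,
    m5: int = 1,
    dialect: str = "illumina",
    out_dir: Union[str, Path],
    lane: Optional[int] = None,
    separate_ambiguous: bool = False,
    buffer_size: int = DEFAULT_BUFFER_SIZE,
    report_prefix: Optional[Union[str, Path]] = None,
    max_keys: int = DEFAULT_MAX_KEYS,
) -> RunReport:
    """Demultiplex a run and return the populated :class:`RunReport`.

    Paired-end when ``r2`` is given (barcode on the R2 tail), single-end
    otherwise (barcode on the R1 tail). ``lane`` forces a lane label;
    without it a file mixing lanes is rejected. When ``report_prefix`` is
    set the TSV/JSON reports are written as well.
    """
    if not isinstance(sheet, SampleSheet):
        sheet = parse_sample_sheet(sheet)
    if isinstance(template, str):
        template = parse_template(template)
    if dialect not in ("illumina", "mgi"):
        raise ConfigError(f"unknown dialect {dialect!r}")

    groups = _build_groups(sheet, template, m7, m5, max_keys)
    default_group = groups[0]
    paired = r2 is not None
    mates = (1, 2) if paired else (1,)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool = _OutputPool(out_dir, dialect, sheet, mates, separate_ambiguous,
                       buffer_size)

    lane_reports: dict[int, LaneReport] = {}
    sample_ids = sheet.sample_ids()
    forced_lane = lane

    if paired:
        stream = itertools.zip_longest(read_fastq(r1), read_fastq(r2))
    else:
        stream = ((rec, None) for rec in read_fastq(r1))

    try:
        for ordinal, (rec1, rec2) in enumerate(stream, start=1):
            if rec1 is None or (paired and rec2 is None):
                raise ValidationError(
                    f"paired files desynchronized: one input ended at read "
                    f"{ordinal}"
                )
            h1, s1, q1 = rec1
            if paired:
                h2, s2, q2 = rec2
                if h1.rpartition("/")[0] != h2.rpartition("/")[0]:
                    raise ValidationError(
                        f"paired files desynchronized at read {ordinal}: "
                        f"{h1!r} vs {h2!r}"
                    )
            bc_header, bc_seq, bc_qual = (h2, s2, q2) if paired else (h1, s1, q1)
            rid_bc = parse_mgi_read_id(bc_header)

            read_lane = forced_lane if forced_lane is not None else rid_bc.lane
            if forced_lane is None:
                if lane_reports and read_lane not in lane_reports:
                    raise ValidationError(
                        f"input mixes lanes {sorted(lane_reports)} and "
                        f"{read_lane}; pass an explicit lane label to proceed"
                    )
            pool.ensure_lane(read_lane, rid_bc.flowcell)
            if read_lane not in lane_reports:
                lane_reports[read_lane] = LaneReport.empty(
                    read_lane, sample_ids, mm_max=m7 + m5
                )
            report = lane_reports[read_lane]

            bc_read = ReadRecord(id=bc_header, sequence=bc_seq, quality=bc_qual)

            # evaluate the read against each template group
            sample_hits: list[tuple[_Group, Assignment, Optional[str], ReadRecord]] = []
            any_ambiguous = False
            for g in groups:
                i7o, i5o, umi, trimmed = extract_barcode(bc_read, g.template)
                a = assign_read(i7o, i5o, g.table)
                if a.verdict == "sample":
                    sample_hits.append((g, a, umi, trimmed))
                elif a.verdict == "ambiguous":
                    any_ambiguous = True

            if len(sample_hits) == 1:
                g, assignment, umi, trimmed_bc = sample_hits[0]
            else:
                g = default_group
                raw_bc = bc_seq[-g.template.barcode_length:]
                verdict = (
                    "ambiguous" if (len(sample_hits) > 1 or any_ambiguous)
                    else "undetermined"
                )
                _, _, umi, trimmed_bc = extract_barcode(bc_read, g.template)
                assignment = Assignment(verdict=verdict, umi=umi,
                                        observed_barcode=raw_bc)
            if assignment.umi is None and umi is not None:
                assignment = Assignment(
                    verdict=assignment.verdict,
                    sample_index=assignment.sample_index,
                    d7=assignment.d7,
                    d5=assignment.d5,
                    umi=umi,
                    observed_barcode=assignment.observed_barcode,
                )

            if assignment.verdict == "sample":
                rec = sheet.records[assignment.sample_index]
                sample_key = rec.sample_id
                annot = rec.i7 + (f"+{rec.i5}" if rec.i5 else "")
            elif assignment.verdict == "ambiguous" and separate_ambiguous:
                sample_key, annot = AMBIGUOUS, "undetermined"
            else:
                sample_key, annot = UNDETERMINED, "undetermined"

            if paired:
                out1 = (h1, s1, q1)           # R1 untouched (barcode on R2)
                out2 = (h2, trimmed_bc.sequence, trimmed_bc.quality)
            else:
                out1 = (h1, trimmed_bc.sequence, trimmed_bc.quality)
                out2 = None

            for mate, out in zip(mates, (out1, out2)):
                header, seq, qual = out
                rid = parse_mgi_read_id(header)
                new_header = format_output_id(
                    rid, dialect, umi=umi, index_annot=annot, original=header
                )
                pool.get(read_lane, sample_key, mate).write_record(
                    new_header, seq, qual
                )

            trimmed_records = (
                [(1, s1, q1), (2, trimmed_bc.sequence, trimmed_bc.quality)]
                if paired
                else [(1, trimmed_bc.sequence, trimmed_bc.quality)]
            )
            sid = sheet.records[assignment.sample_index].sample_id \
                if assignment.verdict == "sample" else None
            update_stats(report, assignment, trimmed_records, sample_id=sid)
    finally:
        pool.close()

    run = RunReport(
        lanes=[lane_reports[k] for k in sorted(lane_reports)],
        projects=sheet.projects(),
        params={
            "m7": m7,
            "m5": m5,
            "dialect": dialect,
            "paired": paired,
            "templates": sorted({str(g.template) for g in groups}),
        },
    )
    if report_prefix is not None:
        write_reports(run, report_prefix)
    return run
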