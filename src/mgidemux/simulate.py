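"""Seeded simulator of ground-truthed MGI runs.

Generates sample sheets, MGI-dialect FASTQ (gzip) and a truth table mapping
every read to the sample that emitted it, so demultiplexing accuracy can be
measured exactly. The error model is substitution-only: index matching is
positional (hamming distance), and indels would shift the barcode frame, so
they are out of scope. Per index segment the number of substituted bases is
Binomial(length, substitution_rate), optionally capped at
``max_errors_per_index``; each substituted base is replaced uniformly by one
of the four alternatives from {A,C,G,T,N}. The injected counts (d7, d5) are
recorded in the truth table. UMI bases are drawn uniformly at random, so an
additional substitution there would be distribution-equivalent and is not
modelled.

Biological sequence is uniform random ACGT; base qualities are drawn from a
two-state Q40/Q12 mixture (85% Q40) so Q30 statistics are non-degenerate.
Identical seeds give byte-identical output files (gzip mtime is pinned).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from ._fastq import BufferedGzipWriter
from .errors import ValidationError
from .samplesheet import SampleRecord, SampleSheet, format_sample_sheet
from .template import BarcodeTemplate, TemplateSegment, parse_template

_BASES = np.array(list("ACGT"))
_ALPHABET5 = "ACGTN"

#: Phred+33 characters for the two-state quality mixture.
_Q_HI, _Q_LO = chr(40 + 33), chr(12 + 33)
_Q_HI_PROB = 0.85


@dataclass
class SimConfig:
    """Study conditions for one synthetic run."""

    n_samples: int = 4
    i7_len: int = 8
    i5_len: Optional[int] = 8
    umi_len: Optional[int] = 8
    template: Optional[Union[BarcodeTemplate, str]] = None
    reads_per_sample: int = 1000
    read_len: int = 100
    substitution_rate: float = 0.0
    undetermined_fraction: float = 0.0
    lanes: int = 1
    seed: int = 0
    paired: bool = True
    flowcell: str = "V300000001"
    min_index_distance: int = 3
    max_errors_per_index: Optional[int] = None
    project: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValidationError("substitution_rate must be in [0, 1]")
        if not (0.0 <= self.undetermined_fraction <= 1.0):
            raise ValidationError("undetermined_fraction must be in [0, 1]")
        if self.n_samples < 1 or self.reads_per_sample < 1 or self.lanes < 1:
            raise ValidationError("n_samples, reads_per_sample and lanes must be >= 1")
        if isinstance(self.template, str):
            self.template = parse_template(self.template)
        if self.template is None:
            segs = [TemplateSegment("i7", self.i7_len)]
            if self.i5_len:
                segs.append(TemplateSegment("i5", self.i5_len))
            if self.umi_len:
                segs.append(TemplateSegment("umi", self.umi_len))
            self.template = BarcodeTemplate(segments=tuple(segs))
        self._check_template()

    def _check_template(self) -> None:
        t = self.template
        seg7 = t.segment("i7")
        if seg7.length != self.i7_len:
            raise ValidationError(
                f"template i7 length {seg7.length} != i7_len {self.i7_len}"
            )
        seg5 = t.segment("i5")
        if (seg5 is not None) != bool(self.i5_len):
            raise ValidationError("template and i5_len disagree on dual indexing")
        if seg5 is not None and seg5.length != self.i5_len:
            raise ValidationError(
                f"template i5 length {seg5.length} != i5_len {self.i5_len}"
            )
        segu = t.segment("umi")
        if (segu is not None) != bool(self.umi_len):
            raise ValidationError("template and umi_len disagree on UMI presence")
        if segu is not None and segu.length != self.umi_len:
            raise ValidationError(
                f"template UMI length {segu.length} != umi_len {self.umi_len}"
            )


@dataclass
class SimRun:
    """Paths produced by :func:`simulate_run` plus the in-memory sheet."""

    sample_sheet_path: Path
    truth_path: Path
    fastq: dict[int, dict[int, Path]]  # lane -> mate -> path
    sheet: SampleSheet

    def r1_paths(self) -> list[Path]:
        return [self.fastq[lane][1] for lane in sorted(self.fastq)]

    def r2_paths(self) -> list[Path]:
        return [self.fastq[lane][2] for lane in sorted(self.fastq) if 2 in self.fastq[lane]]


def random_index_set(
    n: int,
    length: int,
    min_pairwise_distance: int = 3,
    seed: Union[int, np.random.Generator] = 0,
    max_tries: int = 10_000,
) -> list[str]:
    """Draw ``n`` distinct indices with every pair at hamming distance >=
    ``min_pairwise_distance``; deterministic given the seed.

    Rejection sampling with a bounded retry budget; clearly infeasible
    requests (more indices than strings of that length exist) fail fast.
    """
    if n < 1 or length < 1:
        raise ValidationError("n and length must be >= 1")
    if n > 4**length:
        raise ValidationError(
            f"cannot draw {n} distinct indices of length {length}: "
            f"only {4 ** length} exist"
        )
    if n > 1 and min_pairwise_distance > length:
        raise ValidationError(
            f"min pairwise distance {min_pairwise_distance} exceeds index "
            f"length {length}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen: list[str] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise ValidationError(
                f"could not place {n} indices of length {length} at pairwise "
                f"distance >= {min_pairwise_distance} within {max_tries} draws"
            )
        cand = "".join(_BASES[rng.integers(0, 4, size=length)])
        ok = all(
            sum(a != b for a, b in zip(cand, prev)) >= min_pairwise_distance
            for prev in chosen
        )
        if ok:
            chosen.append(cand)
    return chosen


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_qual(rng: np.random.Generator, length: int) -> str:
    hi = rng.random(length) < _Q_HI_PROB
    return "".join(_Q_HI if h else _Q_LO for h in hi)


def _mutate_index(
    rng: np.random.Generator, index: str, rate: float, cap: Optional[int]
) -> tuple[str, int]:
    """Substitute a Binomial(len, rate) number of positions (capped); each
    substituted base becomes a different character from {A,C,G,T,N}."""
    if rate <= 0.0:
        return index, 0
    k = int(rng.binomial(len(index), rate))
    if cap is not None:
        k = min(k, cap)
    if k == 0:
        return index, 0
    positions = rng.choice(len(index), size=k, replace=False)
    chars = list(index)
    for p in positions:
        alternatives = [c for c in _ALPHABET5 if c != chars[p]]
        chars[p] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(chars), k


def simulate_run(cfg: SimConfig, out_dir: Union[str, Path]) -> SimRun:
    """Write the sample sheet, per-lane FASTQ files and the truth table.

    Each lane holds ``n_samples * reads_per_sample`` reads in a seeded
    random sample order; serials are strictly increasing within a lane.
    A read becomes a decoy with probability ``undetermined_fraction``: its
    barcode region is replaced by uniform random bases and the truth table
    marks it ``undetermined``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    t: BarcodeTemplate = cfg.template

    # reverse-complement here mirrors the extraction step at demux time
    from .index_match import reverse_complement

    i7s = random_index_set(cfg.n_samples, cfg.i7_len, cfg.min_index_distance, rng)
    i5s = (
        random_index_set(cfg.n_samples, cfg.i5_len, cfg.min_index_distance, rng)
        if cfg.i5_len
        else [None] * cfg.n_samples
    )
    records = tuple(
        SampleRecord(
            sample_id=f"S{i + 1}",
            i7=i7s[i],
            i5=i5s[i],
            project=cfg.project,
        )
        for i in range(cfg.n_samples)
    )
    sheet = SampleSheet(records=records)

    sheet_path = out_dir / "samplesheet.tsv"
    sheet_path.write_text(format_sample_sheet(sheet))

    truth_path = out_dir / "truth.tsv"
    truth_lines = ["lane\tserial\tread_id\ttrue_sample\td7\td5\tumi"]

    fastq: dict[int, dict[int, Path]] = {}
    mates = (1, 2) if cfg.paired else (1,)
    bio_len = cfg.read_len

    for lane in range(1, cfg.lanes + 1):
        paths = {}
        writers = {}
        for mate in mates:
            p = out_dir / f"{cfg.flowcell}_L{lane:02d}_R{mate}.fq.gz"
            paths[mate] = p
            writers[mate] = BufferedGzipWriter(p)
        fastq[lane] = paths

        order = np.repeat(np.arange(cfg.n_samples), cfg.reads_per_sample)
        rng.shuffle(order)
        for serial, sample_idx in enumerate(order, start=1):
            col = int(rng.integers(1, 1000))
            row = int(rng.integers(1, 1000))
            stem = f"@{cfg.flowcell}L{lane}C{col:03d}R{row:03d}{serial:07d}"

            decoy = rng.random() < cfg.undetermined_fraction
            umi = _random_seq(rng, cfg.umi_len) if cfg.umi_len else None
            if decoy:
                barcode = _random_seq(rng, t.barcode_length)
                true_sample, d7, d5 = "undetermined", "", ""
            else:
                rec = records[sample_idx]
                pieces = []
                d7 = d5 = 0
                for seg in t.segments:
                    if seg.kind == "umi":
                        pieces.append(umi)
                        continue
                    true_idx = rec.i7 if seg.kind == "i7" else rec.i5
                    obs, k = _mutate_index(
                        rng, true_idx, cfg.substitution_rate, cfg.max_errors_per_index
                    )
                    if seg.kind == "i7":
                        d7 = k
                    else:
                        d5 = k
                    pieces.append(reverse_complement(obs) if seg.rc else obs)
                barcode = "".join(pieces)
                true_sample = rec.sample_id

            truth_lines.append(
                f"{lane}\t{serial}\t{stem[1:]}\t{true_sample}\t{d7}\t{d5}\t{umi or ''}"
            )

            for mate in mates:
                bio = _random_seq(rng, bio_len)
                if mate == mates[-1]:  # barcode-bearing mate: R2 if PE, R1 if SE
                    seq = bio + barcode
                else:
                    seq = bio
                qual = _random_qual(rng, len(seq))
                writers[mate].write_record(f"{stem}/{mate}", seq, qual)

        for w in writers.values():
            w.close()

    truth_path.write_text("\n".join(truth_lines) + "\n")
    return SimRun(
        sample_sheet_path=sheet_path,
        truth_path=truth_path,
        fastq=fastq,
        sheet=sheet,
    )
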