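"""Per-lane demultiplexing/quality statistics and mergeable reports.

Each lane accumulates, per sample: read count, a histogram of total index
mismatches (0..m7+m5), and Q30/total base counts over the trimmed biological
sequence. The lane additionally tracks undetermined and ambiguous read
counts, a tally of undetermined barcodes, and per-cycle mean Phred quality
per mate.

Reports serialize to two TSVs (sample stats; top undetermined barcodes) and
one JSON file. The JSON carries the full accumulators — including the
complete undetermined tally and per-cycle quality sums/counts — so that
merging reports from files is exact: counts sum as integers and per-cycle
means recombine as base-count-weighted averages. The TSVs are the
human/MultiQC-facing views; percentages there are rounded to two decimals
while full precision is kept internally.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import MergeError, ValidationError

PHRED_OFFSET = 33
Q30 = 30

#: Default number of top undetermined barcodes written to the TSV.
DEFAULT_TOP_K = 50


@dataclass
class SampleStats:
    sample_id: str
    reads: int = 0
    mismatch_hist: dict[int, int] = field(default_factory=dict)
    q30_bases: int = 0
    total_bases: int = 0

    def add(self, other: "SampleStats") -> None:
        self.reads += other.reads
        for k, v in other.mismatch_hist.items():
            self.mismatch_hist[k] = self.mismatch_hist.get(k, 0) + v
        self.q30_bases += other.q30_bases
        self.total_bases += other.total_bases

    @property
    def q30_pct(self) -> float:
        return 100.0 * self.q30_bases / self.total_bases if self.total_bases else 0.0


@dataclass
class LaneReport:
    lane: int
    samples: dict[str, SampleStats]
    undetermined: int = 0
    ambiguous: int = 0
    undetermined_tally: Counter = field(default_factory=Counter)
    mm_max: int = 0
    # per-mate per-cycle Phred sums and base counts
    qual_sums: dict[int, list[int]] = field(default_factory=dict)
    qual_counts: dict[int, list[int]] = field(default_factory=dict)

    @classmethod
    def empty(cls, lane: int, sample_ids: Sequence[str], mm_max: int = 0) -> "LaneReport":
        return cls(
            lane=lane,
            samples={sid: SampleStats(sample_id=sid) for sid in sample_ids},
            mm_max=mm_max,
        )

    @property
    def total_reads(self) -> int:
        return sum(s.reads for s in self.samples.values()) + self.undetermined + self.ambiguous

    def top_undetermined(self, k: int = DEFAULT_TOP_K) -> list[tuple[str, int]]:
        """Most frequent undetermined barcodes; count descending, ties
        ordered lexicographically."""
        return sorted(self.undetermined_tally.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

    def per_position_quality(self) -> dict[int, list[float]]:
        """Mean Phred per cycle per mate over the trimmed biological bases."""
        out = {}
        for mate, sums in self.qual_sums.items():
            counts = self.qual_counts[mate]
            out[mate] = [s / c if c else 0.0 for s, c in zip(sums, counts)]
        return out

    def _accumulate_quality(self, mate: int, qual: str) -> tuple[int, int]:
        sums = self.qual_sums.setdefault(mate, [])
        counts = self.qual_counts.setdefault(mate, [])
        if len(sums) < len(qual):
            pad = len(qual) - len(sums)
            sums.extend([0] * pad)
            counts.extend([0] * pad)
        q30 = 0
        for i, ch in enumerate(qual):
            q = ord(ch) - PHRED_OFFSET
            sums[i] += q
            counts[i] += 1
            if q >= Q30:
                q30 += 1
        return q30, len(qual)

    def add(self, other: "LaneReport") -> None:
        if set(self.samples) != set(other.samples):
            raise MergeError(
                "mismatched sample sets: "
                f"only-left={sorted(set(self.samples) - set(other.samples))}, "
                f"only-right={sorted(set(other.samples) - set(self.samples))}"
            )
        for sid, st in other.samples.items():
            self.samples[sid].add(st)
        self.undetermined += other.undetermined
        self.ambiguous += other.ambiguous
        self.undetermined_tally.update(other.undetermined_tally)
        self.mm_max = max(self.mm_max, other.mm_max)
        for mate, sums in other.qual_sums.items():
            mine = self.qual_sums.setdefault(mate, [])
            mine_c = self.qual_counts.setdefault(mate, [])
            if len(mine) < len(sums):
                pad = len(sums) - len(mine)
                mine.extend([0] * pad)
                mine_c.extend([0] * pad)
            for i, v in enumerate(sums):
                mine[i] += v
            for i, v in enumerate(other.qual_counts[mate]):
                mine_c[i] += v


def update_stats(
    report: LaneReport,
    a,
    trimmed: Sequence[tuple[int, str, str]],
    sample_id: Optional[str] = None,
) -> LaneReport:
    """Fold one assignment into the lane accumulators.

    ``a`` is the demultiplexer's per-read assignment (verdict, d7, d5,
    observed_barcode); ``trimmed`` lists (mate, sequence, quality) for the
    biological portion of each mate — barcode bases are excluded from all
    quality statistics.
    """
    if a.verdict == "sample":
        if sample_id is None:
            raise ValidationError("sample verdict requires a sample_id")
        st = report.samples.setdefault(sample_id, SampleStats(sample_id=sample_id))
        st.reads += 1
        d = a.d7 + a.d5
        st.mismatch_hist[d] = st.mismatch_hist.get(d, 0) + 1
        for mate, _seq, qual in trimmed:
            q30, total = report._accumulate_quality(mate, qual)
            st.q30_bases += q30
            st.total_bases += total
    elif a.verdict == "ambiguous":
        report.ambiguous += 1
        for mate, _seq, qual in trimmed:
            report._accumulate_quality(mate, qual)
    elif a.verdict == "undetermined":
        report.undetermined += 1
        report.undetermined_tally[a.observed_barcode] += 1
        for mate, _seq, qual in trimmed:
            report._accumulate_quality(mate, qual)
    else:
        raise ValidationError(f"unknown verdict {a.verdict!r}")
    return report


@dataclass
class RunReport:
    """Per-lane reports plus run-level aggregates."""

    lanes: list[LaneReport]
    projects: dict[str, Optional[str]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def merged(self) -> LaneReport:
        """Lane-shaped aggregate over all lanes (lane label 0 = 'all')."""
        if not self.lanes:
            return LaneReport.empty(0, [])
        out = LaneReport.empty(0, list(self.lanes[0].samples), mm_max=self.lanes[0].mm_max)
        for lr in self.lanes:
            out.add(lr)
        return out

    @property
    def total_reads(self) -> int:
        return sum(lr.total_reads for lr in self.lanes)

    def project_rollups(self) -> dict[str, dict[str, int]]:
        """Read totals aggregated by the sample sheet's project column."""
        merged = self.merged
        out: dict[str, dict[str, int]] = {}
        for sid, st in merged.samples.items():
            proj = self.projects.get(sid) or "default"
            agg = out.setdefault(proj, {"reads": 0, "samples": 0})
            agg["reads"] += st.reads
            agg["samples"] += 1
        return out


def _lane_to_json(lr: LaneReport) -> dict:
    return {
        "lane": lr.lane,
        "mm_max": lr.mm_max,
        "undetermined": lr.undetermined,
        "ambiguous": lr.ambiguous,
        "samples": [
            {
                "sample_id": st.sample_id,
                "reads": st.reads,
                "mismatch_hist": {str(k): v for k, v in sorted(st.mismatch_hist.items())},
                "q30_bases": st.q30_bases,
                "total_bases": st.total_bases,
            }
            for st in lr.samples.values()
        ],
        "undetermined_tally": dict(sorted(lr.undetermined_tally.items())),
        "qual_sums": {str(m): v for m, v in sorted(lr.qual_sums.items())},
        "qual_counts": {str(m): v for m, v in sorted(lr.qual_counts.items())},
    }


def _lane_from_json(d: dict) -> LaneReport:
    lr = LaneReport.empty(d["lane"], [s["sample_id"] for s in d["samples"]],
                          mm_max=d.get("mm_max", 0))
    lr.undetermined = d["undetermined"]
    lr.ambiguous = d["ambiguous"]
    lr.undetermined_tally = Counter(d["undetermined_tally"])
    for s in d["samples"]:
        st = lr.samples[s["sample_id"]]
        st.reads = s["reads"]
        st.mismatch_hist = {int(k): v for k, v in s["mismatch_hist"].items()}
        st.q30_bases = s["q30_bases"]
        st.total_bases = s["total_bases"]
    lr.qual_sums = {int(m): list(v) for m, v in d["qual_sums"].items()}
    lr.qual_counts = {int(m): list(v) for m, v in d["qual_counts"].items()}
    return lr


def write_reports(
    run: RunReport,
    prefix: Union[str, Path],
    k: int = DEFAULT_TOP_K,
) -> list[Path]:
    """Write ``<prefix>.sample_stats.tsv``, ``<prefix>.undetermined.tsv``
    and ``<prefix>.general.json``; returns the paths written.

    Ordering is deterministic: samples in sample-sheet order, lanes
    ascending.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mm_max = max((lr.mm_max for lr in run.lanes), default=0)

    stats_path = prefix.with_name(prefix.name + ".sample_stats.tsv")
    mm_cols = [f"mm_{i}" for i in range(mm_max + 1)]
    lines = ["\t".join(["sample_id", "lane", "reads", "pct_of_lane"] + mm_cols + ["q30_pct"])]
    for lr in sorted(run.lanes, key=lambda x: x.lane):
        total = lr.total_reads
        for st in lr.samples.values():
            pct = 100.0 * st.reads / total if total else 0.0
            row = [st.sample_id, str(lr.lane), str(st.reads), f"{pct:.2f}"]
            row += [str(st.mismatch_hist.get(i, 0)) for i in range(mm_max + 1)]
            row.append(f"{st.q30_pct:.2f}")
            lines.append("\t".join(row))
    stats_path.write_text("\n".join(lines) + "\n")

    undet_path = prefix.with_name(prefix.name + ".undetermined.tsv")
    merged = run.merged
    lines = ["barcode\tcount"]
    for bc, n in merged.top_undetermined(k):
        lines.append(f"{bc}\t{n}")
    undet_path.write_text("\n".join(lines) + "\n")

    json_path = prefix.with_name(prefix.name + ".general.json")
    payload = {
        "total_reads": run.total_reads,
        "undetermined": merged.undetermined,
        "ambiguous": merged.ambiguous,
        "params": run.params,
        "projects": run.projects,
        "project_rollups": run.project_rollups(),
        "lanes": [_lane_to_json(lr) for lr in sorted(run.lanes, key=lambda x: x.lane)],
    }
    json_path.write_text(json.dumps(payload, indent=1) + "\n")
    return [stats_path, undet_path, json_path]


def read_report(prefix: Union[str, Path]) -> RunReport:
    """Load a serialized report from its ``<prefix>.general.json``."""
    prefix = Path(prefix)
    json_path = prefix.with_name(prefix.name + ".general.json")
    d = json.loads(json_path.read_text())
    return RunReport(
        lanes=[_lane_from_json(x) for x in d["lanes"]],
        projects=d.get("projects", {}),
        params=d.get("params", {}),
    )


def merge_reports(
    reports: Sequence[Union[LaneReport, RunReport, str, Path]],
) -> RunReport:
    """Merge reports across lanes.

    Inputs may be in-memory lane/run reports or prefixes of serialized
    reports. Counts and histograms sum exactly; undetermined tallies are
    recombined before ranking; per-cycle quality recombines as
    base-count-weighted means. Lanes sharing a label are summed.
    """
    if not reports:
        raise MergeError("nothing to merge")
    lanes: dict[int, LaneReport] = {}
    projects: dict[str, Optional[str]] = {}
    params: dict = {}

    def absorb_lane(lr: LaneReport) -> None:
        if lr.lane in lanes:
            lanes[lr.lane].add(lr)
        else:
            fresh = LaneReport.empty(lr.lane, list(lr.samples), mm_max=lr.mm_max)
            fresh.add(lr)
            lanes[lr.lane] = fresh

    for item in reports:
        if isinstance(item, (str, Path)):
            item = read_report(item)
        if isinstance(item, RunReport):
            projects.update(item.projects)
            params = params or dict(item.params)
            for lr in item.lanes:
                absorb_lane(lr)
        elif isinstance(item, LaneReport):
            absorb_lane(lr=item)
        else:
            raise MergeError(f"cannot merge object of type {type(item).__name__}")

    sample_sets = {frozenset(lr.samples) for lr in lanes.values()}
    if len(sample_sets) > 1:
        raise MergeError("lanes disagree on the sample set")
    return RunReport(
        lanes=[lanes[k] for k in sorted(lanes)],
        projects=projects,
        params=params,
    )
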