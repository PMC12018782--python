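"""Read-depth genotyping of a target MITE insertion across accessions.

Each accession's coverage rate value (CV) over the target interval — by
default the breadth of coverage, the fraction of positions with depth >= 1 —
classifies the accession as carrying no copy of the element (negative), a
truncated copy (partial) or a full-length copy (full). Thresholds 0.3 and
0.75 separate the classes; both boundary values fall in the partial class.
"""

from __future__ import annotations

import decimal
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, read_bed, read_depth_table

__all__ = [
    "DepthProfile",
    "CoverageCall",
    "GroupSummary",
    "NEGATIVE_MAX",
    "PARTIAL_MAX",
    "breadth_cv",
    "classify_cv",
    "profile_from_rows",
    "summarize_groups",
    "run_coverage_screen",
]

NEGATIVE_MAX = 0.3   # cv < 0.3            -> negative
PARTIAL_MAX = 0.75   # 0.3 <= cv <= 0.75   -> partial; cv > 0.75 -> full


@dataclass(frozen=True)
class DepthProfile:
    """Per-base depth over a 1-based inclusive target interval."""

    accession_id: str
    interval: GenomicInterval
    depths: np.ndarray  # one non-negative int per interval position

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=np.int64)
        object.__setattr__(self, "depths", depths)
        if depths.size != self.interval.length:
            raise ValueError(
                f"{self.accession_id}: {depths.size} depths for a "
                f"{self.interval.length} bp interval"
            )
        if (depths < 0).any():
            raise ValueError(f"{self.accession_id}: negative depths")


@dataclass(frozen=True)
class CoverageCall:
    accession_id: str
    cv: float
    cls: str  # negative | partial | full


@dataclass(frozen=True)
class GroupSummary:
    group_name: str
    n_total: int
    n_negative: int
    n_partial: int
    n_full: int
    pct_negative: float
    pct_partial: float
    pct_full: float


def profile_from_rows(
    accession_id: str,
    rows: list[tuple[str, int, int]],
    interval: GenomicInterval,
) -> DepthProfile:
    """Densify sparse depth rows over the target interval (absent rows = 0)."""
    depths = np.zeros(interval.length, dtype=np.int64)
    for seq_id, pos, depth in rows:
        if seq_id == interval.seq_id and interval.start <= pos <= interval.end:
            depths[pos - interval.start] = depth
    return DepthProfile(accession_id, interval, depths)


def breadth_cv(profile: DepthProfile, min_depth: int = 1, method: str = "breadth") -> float:
    """Coverage rate value of one accession over the target interval.

    ``breadth`` (default): fraction of positions with depth >= min_depth.
    ``capped_mean``: mean of depths capped at min_depth, divided by
    min_depth — identical to breadth at min_depth=1 but rewarding partial
    stacking at higher thresholds.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if profile.depths.size == 0:
        raise ValueError("empty interval")
    if method == "breadth":
        return float(np.count_nonzero(profile.depths >= min_depth) / profile.depths.size)
    if method == "capped_mean":
        return float(np.minimum(profile.depths, min_depth).mean() / min_depth)
    raise ValueError(f"unknown CV method {method!r}")


def classify_cv(cv: float) -> str:
    """Three-way class of a coverage rate value; boundaries belong to partial."""
    if not 0.0 <= cv <= 1.0:
        raise ValueError(f"cv out of [0, 1]: {cv}")
    if cv < NEGATIVE_MAX:
        return "negative"
    if cv <= PARTIAL_MAX:
        return "partial"
    return "full"


def _round_half_up_1dp(x: float) -> float:
    return float(
        decimal.Decimal(repr(x)).quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP)
    )


def _summary(name: str, classes: list[str]) -> GroupSummary:
    n = len(classes)
    n_neg = classes.count("negative")
    n_par = classes.count("partial")
    n_ful = classes.count("full")
    return GroupSummary(
        group_name=name,
        n_total=n,
        n_negative=n_neg,
        n_partial=n_par,
        n_full=n_ful,
        pct_negative=_round_half_up_1dp(100.0 * n_neg / n),
        pct_partial=_round_half_up_1dp(100.0 * n_par / n),
        pct_full=_round_half_up_1dp(100.0 * n_ful / n),
    )


def summarize_groups(
    calls: list[CoverageCall], group_map: dict[str, str]
) -> list[GroupSummary]:
    """Per-group class counts and percentages (1 decimal, half-up), plus ALL."""
    missing = sorted(c.accession_id for c in calls if c.accession_id not in group_map)
    if missing:
        raise ValueError(f"accessions missing from group map: {missing}")
    by_group: dict[str, list[str]] = {}
    for call in calls:
        by_group.setdefault(group_map[call.accession_id], []).append(call.cls)
    out = [_summary(name, classes) for name, classes in sorted(by_group.items())]
    out.append(_summary("ALL", [c.cls for c in calls]))
    return out


def run_coverage_screen(
    depth_dir: str | os.PathLike,
    target_bed: str | os.PathLike,
    group_tsv: str | os.PathLike | None = None,
    min_depth: int = 1,
    method: str = "breadth",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Screen a directory of per-accession depth tables against a target BED.

    File stems are accession IDs. Returns (calls, summary) DataFrames; the
    summary is None when no group map is given.
    """
    interval = read_bed(target_bed)[0]
    paths = sorted(Path(depth_dir).glob("*.tsv")) + sorted(Path(depth_dir).glob("*.depth"))
    if not paths:
        raise FileNotFoundError(f"no depth tables (*.tsv, *.depth) in {depth_dir}")
    stems = [p.stem for p in paths]
    if len(set(stems)) != len(stems):
        dupes = sorted({s for s in stems if stems.count(s) > 1})
        raise ValueError(f"duplicate accession files: {dupes}")
    calls = []
    for path in sorted(paths, key=lambda p: p.stem):
        profile = profile_from_rows(path.stem, read_depth_table(path), interval)
        cv = breadth_cv(profile, min_depth=min_depth, method=method)
        calls.append(CoverageCall(path.stem, cv, classify_cv(cv)))
    calls_df = pd.DataFrame(
        {
            "accession_id": [c.accession_id for c in calls],
            "cv": [c.cv for c in calls],
            "class": [c.cls for c in calls],
        }
    )
    summary_df = None
    if group_tsv is not None:
        groups = pd.read_csv(group_tsv, sep="\t", header=None, names=["accession_id", "group"])
        group_map = dict(zip(groups.accession_id.astype(str), groups.group.astype(str)))
        summaries = summarize_groups(calls, group_map)
        summary_df = pd.DataFrame([s.__dict__ for s in summaries])
    return calls_df, summary_df
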