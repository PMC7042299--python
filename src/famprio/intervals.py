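"""Interval algebra for constitutional deletions.

Coordinates are stored 1-based and fully inclusive, matching the way
breakpoints are printed in clinical reports (e.g. the chr21 RUNX1 deletion
hotspot in familial platelet disorder).  BED I/O converts to and from the
0-based half-open convention at the file boundary, so printed breakpoints
survive a round trip bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(f"{self.label or self.chrom}: start > end")

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class FeatureModel:
    """Named gene features (promoter, exons, ...) on one chromosome."""

    features: list[tuple[str, GenomicInterval]]

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f[1].chrom, f[1].start))


def intersect_intervals(intervals: list[GenomicInterval]) -> GenomicInterval | None:
    """Maximal interval common to all inputs; None when they do not overlap.

    All intervals must share a chromosome.  With 1-based inclusive
    coordinates the intersection is [max(starts), min(ends)] whenever that
    pair is ordered.
    """
    if not intervals:
        raise ValueError("need at least one interval")
    chroms = {i.chrom for i in intervals}
    if len(chroms) > 1:
        raise ValueError(f"mixed chromosomes: {sorted(chroms)}")
    start = max(i.start for i in intervals)
    end = min(i.end for i in intervals)
    if start > end:
        return None
    return GenomicInterval(chrom=intervals[0].chrom, start=start, end=end,
                           label="intersection")


def interval_length(interval: GenomicInterval, unit: str = "bp") -> int:
    """Length of a 1-based inclusive interval; ``kb`` rounds to the nearest
    integer kilobase as printed in reports."""
    bp = interval.end - interval.start + 1
    if unit == "bp":
        return bp
    if unit == "kb":
        return round(bp / 1000)
    raise ValueError(f"unknown unit {unit!r}")


def annotate_interval_features(
    interval: GenomicInterval, model: FeatureModel
) -> list[str]:
    """Names of model features fully contained in the interval, in genomic
    order."""
    return [name for name, feat in model.features if interval.contains(feat)]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    intervals = []
    for _, row in df.iterrows():
        intervals.append(
            GenomicInterval(
                chrom=str(row["chrom"]),
                start=int(row["start"]) + 1,
                end=int(row["end"]),
                label="" if pd.isna(row["name"]) else str(row["name"]),
            )
        )
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in intervals:
            fh.write(f"{i.chrom}\t{i.start - 1}\t{i.end}\t{i.label}\n")


def read_feature_bed(path: str | Path) -> FeatureModel:
    return FeatureModel(features=[(i.label, i) for i in read_bed(path)])


def load_constitutional_deletions(
    source: str = "table", path: str | Path | None = None
) -> list[GenomicInterval]:
    """Packaged constitutional chr21 deletion intervals.

    ``source`` selects between the tabulated breakpoints (default; one
    interval per family) and the narrative coordinates published for the
    third family.
    """
    if path is None:
        from importlib import resources

        path = Path(str(resources.files("famprio.data") / "runx1_deletions.tsv"))
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df[df["source"] == source]
    return [
        GenomicInterval(
            chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]),
            label=str(r["family"]),
        )
        for _, r in df.iterrows()
    ]
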