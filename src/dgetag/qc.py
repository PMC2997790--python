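"""Raw-tag quality control: from sequenced reads to clean tag counts.

Each raw read carries at most one informative 21-base tag in its first 21
bases (``CATG`` + 17). Three filters turn a pile of raw reads into a clean
tag library: reads with an ``N`` in the tag window are low quality; reads
whose insert does not start with ``CATG`` are adaptor-only ("empty"); and
tags seen exactly once library-wide are discarded as probable sequencing
errors. Each read lands in exactly one category, so the accounting is an
exact partition of the raw reads — the basis for composition summaries.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .index import ANCHOR, TAG_LEN

ADAPTOR1 = "ACACTCTTTCCCTACACGACGCTCTTCCGATC"
ADAPTOR2 = "GATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"

DEFAULT_BIN_EDGES: tuple[float, ...] = (2, 5, 10, 20, 50, 100, float("inf"))


@dataclass
class FilterReport:
    """Partition of a library's raw reads into QC categories."""

    n_raw: int
    n_distinct_raw: int
    n_with_N: int
    n_empty: int
    n_singleton_tags_removed: int
    n_clean: int
    n_distinct_clean: int

    @property
    def clean_fraction(self) -> float:
        return self.n_clean / self.n_raw

    def validate(self) -> None:
        total = self.n_with_N + self.n_empty + self.n_singleton_tags_removed + self.n_clean
        if total != self.n_raw:
            raise AssertionError(
                f"QC partition broken: {self.n_raw} != {total}"
            )


@dataclass
class TagLibrary:
    """Clean distinct tags of one sample, with copy numbers ≥ 2."""

    library_id: str
    counts: dict[str, int]
    report: FilterReport

    @property
    def total_clean(self) -> int:
        return sum(self.counts.values())


def classify_raw_tags(
    records: Sequence[str],
    library_id: str = "lib",
    adaptor1_seq: str = ADAPTOR1,
    adaptor2_seq: str = ADAPTOR2,
) -> TagLibrary:
    """Apply the three QC filters to raw reads and tally clean tags.

    Filter precedence (first matching rule wins): reads shorter than the tag
    length or without ``CATG`` at position 0 — which includes reads beginning
    with adaptor-2 sequence, i.e. no insert — are *empty*, except that an
    ``N`` anywhere in the first 21 bases is checked first and wins; finally,
    tags with library-wide copy number 1 are removed as singletons. Bases
    beyond position 21 (adaptor-2 side) are ignored.
    """
    if not records:
        raise ValueError("empty library")

    n_with_N = 0
    n_empty = 0
    tally: Counter[str] = Counter()
    distinct_raw: set[str] = set()

    for read in records:
        window = read[:TAG_LEN]
        distinct_raw.add(window)
        if "N" in window:
            n_with_N += 1
        elif len(window) < TAG_LEN or not window.startswith(ANCHOR):
            n_empty += 1
        else:
            tally[window] += 1

    counts = {t: c for t, c in tally.items() if c >= 2}
    n_singletons = sum(1 for c in tally.values() if c == 1)
    n_clean = sum(counts.values())

    report = FilterReport(
        n_raw=len(records),
        n_distinct_raw=len(distinct_raw),
        n_with_N=n_with_N,
        n_empty=n_empty,
        n_singleton_tags_removed=n_singletons,
        n_clean=n_clean,
        n_distinct_clean=len(counts),
    )
    report.validate()
    return TagLibrary(library_id=library_id, counts=counts, report=report)


def composition_summary(report: FilterReport) -> pd.Series:
    """Percentage of each QC category among raw reads (sums to 100)."""
    if report.n_raw == 0:
        raise ValueError("n_raw must be positive")
    return pd.Series(
        {
            "with_N": 100.0 * report.n_with_N / report.n_raw,
            "empty": 100.0 * report.n_empty / report.n_raw,
            "singleton": 100.0 * report.n_singleton_tags_removed / report.n_raw,
            "clean": 100.0 * report.n_clean / report.n_raw,
        },
        name="percent_of_raw",
    )


def copy_number_distribution(
    lib: TagLibrary, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Share of total and of distinct clean tags per copy-number bin.

    Bins are half-open ``[lo, hi)`` over the supplied edges, which must cover
    every observed copy number (the default covers ``[2, inf)``). Both share
    columns each sum to 1.
    """
    if not lib.counts:
        raise ValueError("empty library")
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    copies = np.array(list(lib.counts.values()), dtype=float)
    if copies.min() < edges[0] or copies.max() >= edges[-1]:
        raise ValueError("bin_edges do not cover the observed copy numbers")

    which = np.digitize(copies, edges[1:-1], right=False)
    n_bins = len(edges) - 1
    total = np.zeros(n_bins)
    distinct = np.zeros(n_bins)
    for b in range(n_bins):
        sel = which == b
        total[b] = copies[sel].sum()
        distinct[b] = sel.sum()
    labels = [
        f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n_bins)
    ]
    return pd.DataFrame(
        {
            "total_share": total / copies.sum(),
            "distinct_share": distinct / len(copies),
        },
        index=pd.Index(labels, name="copy_number_bin"),
    )


def high_copy_shares(lib: TagLibrary, threshold: int = 100) -> tuple[float, float]:
    """(total-clean share, distinct-clean share) of tags with copies > threshold."""
    copies = np.array(list(lib.counts.values()))
    hi = copies > threshold
    return float(copies[hi].sum() / copies.sum()), float(hi.mean())


# ---------------------------------------------------------------------------
# I/O

def read_raw_reads(path: str | Path) -> list[str]:
    """Read raw tag reads from FASTQ or one-read-per-line text, gzipped or not."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
        fh.seek(0)
        if first.startswith("@"):
            reads = []
            for i, line in enumerate(fh):
                if i % 4 == 1:
                    reads.append(line.strip().upper())
            return reads
        return [line.strip().upper() for line in fh if line.strip()]


def write_tag_library_tsv(lib: TagLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#library_id\t{lib.library_id}\n")
        r = lib.report
        fh.write(
            "#report\t"
            f"n_raw={r.n_raw};n_distinct_raw={r.n_distinct_raw};"
            f"n_with_N={r.n_with_N};n_empty={r.n_empty};"
            f"n_singleton_tags_removed={r.n_singleton_tags_removed};"
            f"n_clean={r.n_clean};n_distinct_clean={r.n_distinct_clean}\n"
        )
        fh.write("tag_seq\tcount\n")
        for tag in sorted(lib.counts):
            fh.write(f"{tag}\t{lib.counts[tag]}\n")


def read_tag_library_tsv(path: str | Path) -> TagLibrary:
    counts: dict[str, int] = {}
    library_id = "lib"
    report_kv: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#library_id"):
                library_id = line.split("\t")[1]
            elif line.startswith("#report"):
                for kv in line.split("\t")[1].split(";"):
                    k, v = kv.split("=")
                    report_kv[k] = int(v)
            elif line and not line.startswith("tag_seq"):
                tag, c = line.split("\t")
                counts[tag] = int(c)
    report = FilterReport(**report_kv)
    return TagLibrary(library_id=library_id, counts=counts, report=report)
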