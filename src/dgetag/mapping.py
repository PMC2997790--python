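"""Tag-to-gene mapping and TPM quantification.

Each distinct clean tag is resolved against the virtual tag index (exact
first, then one mismatch). Tags hitting exactly one gene are *unambiguous*
and carry their full copy number into that gene's count; tags hitting
several genes are counted as mapped but excluded from quantification; tags
hitting nothing are *unknown*. Expression is reported as TPM — tag count
per million clean tags, a library-size normalization only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .index import TagIndex, query_tag
from .qc import FilterReport, TagLibrary


def tpm(count: int, total_clean: int) -> float:
    """Tags per million clean tags: ``count / total_clean × 1e6``."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if not 0 <= count <= total_clean:
        raise ValueError("count must lie in [0, total_clean]")
    return count / total_clean * 1_000_000


@dataclass
class MappingStats:
    """Table-1-style accounting of one library's mapping outcome."""

    library_id: str
    reference_size: int
    clean_tags: int
    clean_copies: int
    all_mapped_tags: int = 0
    all_mapped_copies: int = 0
    unambiguous_tags: int = 0
    unambiguous_copies: int = 0
    unknown_tags: int = 0
    unknown_copies: int = 0
    all_tag_mapped_genes: int = 0
    unambiguous_tag_mapped_genes: int = 0

    def validate(self) -> None:
        if self.all_mapped_tags + self.unknown_tags != self.clean_tags:
            raise AssertionError("distinct-tag conservation broken")
        if self.all_mapped_copies + self.unknown_copies != self.clean_copies:
            raise AssertionError("copy conservation broken")


@dataclass
class GeneExpression:
    gene_id: str
    count: int
    tpm: float


def map_library(
    lib: TagLibrary,
    index: TagIndex,
    max_mismatch: int = 1,
    anchor_strict: bool = True,
) -> tuple[MappingStats, list[GeneExpression]]:
    """Map every distinct clean tag of a library and quantify genes.

    The TPM denominator is the library's total clean tags, not the mapped
    copies, so gene TPMs sum to 1e6 only when every clean tag maps
    unambiguously.
    """
    if not lib.counts:
        raise ValueError("empty library")
    if not index.tags:
        raise ValueError("empty index")

    stats = MappingStats(
        library_id=lib.library_id,
        reference_size=index.reference_size,
        clean_tags=len(lib.counts),
        clean_copies=lib.total_clean,
    )
    gene_counts: dict[str, int] = {}
    all_genes: set[str] = set()
    unamb_genes: set[str] = set()

    for tag_seq, copies in lib.counts.items():
        report = query_tag(index, tag_seq, max_mismatch, anchor_strict)
        if report.match_tier == "none":
            stats.unknown_tags += 1
            stats.unknown_copies += copies
            continue
        stats.all_mapped_tags += 1
        stats.all_mapped_copies += copies
        all_genes.update(report.gene_ids)
        if len(report.gene_ids) == 1:
            (gene,) = report.gene_ids
            stats.unambiguous_tags += 1
            stats.unambiguous_copies += copies
            gene_counts[gene] = gene_counts.get(gene, 0) + copies
            unamb_genes.add(gene)

    stats.all_tag_mapped_genes = len(all_genes)
    stats.unambiguous_tag_mapped_genes = len(unamb_genes)
    stats.validate()

    total = lib.total_clean
    expr = [
        GeneExpression(g, c, tpm(c, total))
        for g, c in sorted(gene_counts.items())
    ]
    return stats, expr


_PCT = lambda a, b: round(100.0 * a / b, 2) if b else float("nan")


def library_summary_table(
    stats: list[MappingStats], reports: list[FilterReport] | None = None
) -> pd.DataFrame:
    """Per-library mapping statistics with an arithmetic-mean column.

    Mirrors the usual tag-library accounting table: raw/clean tag counts,
    mapped and unambiguous tags (distinct and copies, with percent of clean
    tags), mapped gene counts (percent of reference unigenes) and unknown
    tags. Percentages are ratios × 100 rounded to two decimals.
    """
    if not stats:
        raise ValueError("need at least one library")
    if reports is not None and len(reports) != len(stats):
        raise ValueError("reports must align with stats")

    cols = {}
    for i, st in enumerate(stats):
        rows: dict[str, float] = {}
        if reports is not None:
            r = reports[i]
            rows["Raw Data"] = r.n_raw
            rows["Distinct Raw Data"] = r.n_distinct_raw
            rows["Clean Tag"] = r.n_clean
            rows["Distinct Clean Tag"] = r.n_distinct_clean
            rows["Clean Tag/Raw Tag (%)"] = _PCT(r.n_clean, r.n_raw)
        rows["All Tag Mapping to Gene"] = st.all_mapped_copies
        rows["All Tag Mapping to Gene (% of Clean Tag)"] = _PCT(
            st.all_mapped_copies, st.clean_copies
        )
        rows["Distinct All Tag Mapping to Gene"] = st.all_mapped_tags
        rows["Distinct All Tag Mapping to Gene (% of Distinct Clean Tag)"] = _PCT(
            st.all_mapped_tags, st.clean_tags
        )
        rows["Unambiguous Tag Mapping to Gene"] = st.unambiguous_copies
        rows["Unambiguous Tag Mapping to Gene (% of Clean Tag)"] = _PCT(
            st.unambiguous_copies, st.clean_copies
        )
        rows["Distinct Unambiguous Tag Mapping to Gene"] = st.unambiguous_tags
        rows["Distinct Unambiguous Tag Mapping to Gene (% of Distinct Clean Tag)"] = _PCT(
            st.unambiguous_tags, st.clean_tags
        )
        rows["All Tag-mapped Genes"] = st.all_tag_mapped_genes
        rows["All Tag-mapped Genes (% of Ref Unigenes)"] = _PCT(
            st.all_tag_mapped_genes, st.reference_size
        )
        rows["Unambiguous Tag-mapped Genes"] = st.unambiguous_tag_mapped_genes
        rows["Unambiguous Tag-mapped Genes (% of Ref Unigenes)"] = _PCT(
            st.unambiguous_tag_mapped_genes, st.reference_size
        )
        rows["Unknown Tag"] = st.unknown_copies
        rows["Unknown Tag (% of Clean Tag)"] = _PCT(st.unknown_copies, st.clean_copies)
        rows["Distinct Unknown Tag"] = st.unknown_tags
        rows["Distinct Unknown Tag (% of Distinct Clean Tag)"] = _PCT(
            st.unknown_tags, st.clean_tags
        )
        cols[st.library_id] = rows

    table = pd.DataFrame(cols)
    table["Averages"] = table.mean(axis=1).round(2)
    table.index.name = "Summary"
    return table


# ---------------------------------------------------------------------------
# I/O

def write_expression_tsv(
    expr: list[GeneExpression], total_clean: int, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(f"#total_clean\t{total_clean}\n")
        fh.write("gene_id\tcount\ttpm\n")
        for e in expr:
            fh.write(f"{e.gene_id}\t{e.count}\t{e.tpm:.6g}\n")


def read_expression_tsv(path: str | Path) -> tuple[dict[str, int], int]:
    """Return (gene→count, total_clean) from an expression TSV."""
    counts: dict[str, int] = {}
    total_clean = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#total_clean"):
                total_clean = int(line.split("\t")[1])
            elif line and not line.startswith("gene_id"):
                g, c, _ = line.split("\t")
                counts[g] = int(c)
    return counts, total_clean
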