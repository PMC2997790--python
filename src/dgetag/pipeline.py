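"""End-to-end workflow: index → QC → map → differential calls → enrichment.

Mirrors a multi-library tag-sequencing study: every raw library is
filtered to clean tags, mapped against the reference tag index, and
quantified; named pairs of libraries are then compared (up/down counts per
comparison), and, when an annotation is supplied, the DE genes of each
comparison are tested for gene-set enrichment. A machine-readable JSON
summary ties the stages together.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment as enr
from . import index as idx
from . import mapping as mp
from . import qc
from .stats import DGEConfig, call_de, pairs_from_counts

log = logging.getLogger("dgetag")


@dataclass
class RunConfig:
    reference_fasta: str
    libraries: dict[str, str]  # library_id -> reads path (FASTQ/text)
    outdir: str
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    annotation: str | None = None
    both_strands: bool = True
    max_mismatch: int = 1
    anchor_strict: bool = True
    fdr_threshold: float = 0.001
    log2_threshold: float = 1.0
    enrich_mode: str = "bonferroni"
    enrich_alpha: float = 0.05

    def validate(self) -> None:
        if not Path(self.reference_fasta).exists():
            raise FileNotFoundError(self.reference_fasta)
        for lib_id, path in self.libraries.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{lib_id}: {path}")
        for a, b in self.comparisons:
            for name in (a, b):
                if name not in self.libraries:
                    raise ValueError(f"unknown library {name!r} in comparisons")
        if self.annotation is not None and not Path(self.annotation).exists():
            raise FileNotFoundError(self.annotation)
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if self.enrich_mode not in ("bonferroni", "fdr"):
            raise ValueError("enrich_mode must be 'bonferroni' or 'fdr'")


def compare_matrix(
    expressions: dict[str, tuple[dict[str, int], int]],
    comparisons: list[tuple[str, str]],
    cfg: DGEConfig | None = None,
) -> pd.DataFrame:
    """Up/down DE gene counts for every requested ordered library pair.

    ``expressions`` maps library id to ``(gene→count, total_clean)``;
    "up" means higher in the second-named library.
    """
    rows = []
    for a, b in comparisons:
        if a not in expressions or b not in expressions:
            missing = a if a not in expressions else b
            raise ValueError(f"unknown library {missing!r}")
        (ca, na), (cb, nb) = expressions[a], expressions[b]
        _, n_up, n_down = call_de(pairs_from_counts(ca, cb, na, nb), cfg)
        rows.append({"lib1": a, "lib2": b, "n_up": n_up, "n_down": n_down})
    return pd.DataFrame(rows, columns=["lib1", "lib2", "n_up", "n_down"])


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the whole workflow; returns (and writes) the JSON summary."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "MANIFEST"
    manifest.write_text("INCOMPLETE\n")
    t0 = time.time()

    summary: dict = {"stages": {}, "libraries": {}, "comparisons": []}

    log.info("indexing reference %s", cfg.reference_fasta)
    reference = idx.read_reference_fasta(cfg.reference_fasta)
    tag_index = idx.build_tag_index(reference, both_strands=cfg.both_strands)
    idx.write_index_tsv(tag_index, outdir / "index.tsv")
    summary["stages"]["index"] = {
        "n_tags": len(tag_index),
        "reference_size": tag_index.reference_size,
        "n_genes_with_tags": tag_index.n_genes_with_tags,
    }

    expressions: dict[str, tuple[dict[str, int], int]] = {}
    stats_list, report_list = [], []
    for lib_id, path in cfg.libraries.items():
        log.info("filtering library %s", lib_id)
        reads = qc.read_raw_reads(path)
        lib = qc.classify_raw_tags(reads, library_id=lib_id)
        qc.write_tag_library_tsv(lib, outdir / f"{lib_id}.tags.tsv")
        stats, expr = mp.map_library(
            lib, tag_index, cfg.max_mismatch, cfg.anchor_strict
        )
        mp.write_expression_tsv(expr, lib.total_clean, outdir / f"{lib_id}.expr.tsv")
        expressions[lib_id] = ({e.gene_id: e.count for e in expr}, lib.total_clean)
        stats_list.append(stats)
        report_list.append(lib.report)
        r = lib.report
        summary["libraries"][lib_id] = {
            "n_raw": r.n_raw,
            "n_clean": r.n_clean,
            "n_distinct_clean": r.n_distinct_clean,
            "clean_fraction": r.clean_fraction,
            "all_mapped_copies": stats.all_mapped_copies,
            "unambiguous_copies": stats.unambiguous_copies,
            "unknown_copies": stats.unknown_copies,
        }

    table = mp.library_summary_table(stats_list, report_list)
    table.to_csv(outdir / "summary_table.tsv", sep="\t")

    de_cfg = DGEConfig(cfg.fdr_threshold, cfg.log2_threshold)
    ann = enr.read_annotation_tsv(cfg.annotation) if cfg.annotation else None
    for a, b in cfg.comparisons:
        (ca, na), (cb, nb) = expressions[a], expressions[b]
        results, n_up, n_down = call_de(pairs_from_counts(ca, cb, na, nb), de_cfg)
        de_path = outdir / f"{a}_vs_{b}.de.tsv"
        _write_de_tsv(results, de_path)
        comp = {"lib1": a, "lib2": b, "n_up": n_up, "n_down": n_down}
        if ann is not None:
            de_genes = [r.gene_id for r in results if r.significant]
            background = sorted(set(ca) | set(cb))
            if de_genes:
                er = enr.enrich(
                    de_genes, background, ann, cfg.enrich_mode, cfg.enrich_alpha
                )
                enr.write_enrichment_tsv(er, outdir / f"{a}_vs_{b}.enrich.tsv")
                comp["n_enriched_terms"] = sum(r.significant for r in er)
            else:
                comp["n_enriched_terms"] = 0
        summary["comparisons"].append(comp)

    summary["elapsed_sec"] = round(time.time() - t0, 3)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest.write_text("COMPLETE\n")
    return summary


def _write_de_tsv(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tx\ty\ttpm1\ttpm2\tlog2_ratio\tp_value\tfdr\t"
            "direction\tlibrary_specific\n"
        )
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.x}\t{r.y}\t{r.tpm1:.6g}\t{r.tpm2:.6g}\t"
                f"{r.log2_ratio:.6g}\t{r.p_value:.6g}\t{r.fdr:.6g}\t"
                f"{r.direction}\t{r.library_specific}\n"
            )
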