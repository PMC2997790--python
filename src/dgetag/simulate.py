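"""Synthetic references, annotations, and tag libraries with ground truth.

The generator emulates the statistical structure a tag-based expression
study assumes, without any real data: a unigene reference in which every
gene carries one canonical 3′-most CATG tag; heavy-tailed relative
expression (log-normal by default) under which a small minority of
high-copy tags carries most of the sequenced mass; per-base substitution
errors that create near-miss and singleton tags; and contaminating reads
(N-containing, adaptor-only) at configurable rates. Every generating call
takes an explicit seed and is fully deterministic given it.

Two sampling paths are provided. ``simulate_library`` materializes raw
35-base reads for exercising QC and mapping end to end. For differential
expression studies, ``make_paired_experiment`` samples clean per-gene
counts multinomially — the same sampling law the read path induces after
QC, without the cost of materializing reads — and records the ground truth
(true abundances, fold changes, DE flags) needed for recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import Annotation
from .index import ReferenceUnigene, TAG_LEN, ANCHOR
from .qc import ADAPTOR2

READ_LEN = 35
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_FILLER = ADAPTOR2[: READ_LEN - TAG_LEN]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale library over a reference of realistic
    size: 30,000 genes with log-normal gene lengths (median 841 bases) and
    log-normal relative expression (sigma 2.5, calibrated so that at one
    million reads the tags with copy number above 100 carry more than 60%
    of the clean mass but under 4% of the distinct clean tags), 1% per-base
    substitution error, and 3% / 4% N-containing / adaptor-only
    contamination, which together leave a clean fraction in the high 80s%.
    """

    n_genes: int = 30000
    gene_length_median: float = 841.0
    gene_length_sigma: float = 0.45
    min_gene_length: int = 100
    duplicate_tag_fraction: float = 0.0

    expression_law: str = "lognormal"  # or "zipf"
    expression_sigma: float = 2.5
    zipf_exponent: float = 1.1

    depth: int = 1_000_000
    error_rate: float = 0.01
    n_rate: float = 0.03
    empty_rate: float = 0.04

    de_fraction: float = 0.1
    de_fold_change: float = 4.0

    n_terms: int = 50
    term_size_mean: float = 25.0
    term_size_sigma: float = 0.8
    n_enriched_terms: int = 1
    enriched_odds: float = 10.0

    def __post_init__(self) -> None:
        for name in ("error_rate", "n_rate", "empty_rate", "duplicate_tag_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.expression_law not in ("lognormal", "zipf"):
            raise ValueError("expression_law must be 'lognormal' or 'zipf'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticReference:
    unigenes: list[ReferenceUnigene]
    canonical_tags: list[str]  # one per gene, same order

    @property
    def gene_ids(self) -> list[str]:
        return [u.gene_id for u in self.unigenes]


def generate_reference(cfg: SimulationConfig, seed: int) -> SyntheticReference:
    """Random unigene set, each ending in a planted canonical CATG tag.

    The canonical tag occupies the last 21 bases, making it the 3′-most
    site with a full 17-base downstream window — the tag the library
    chemistry would read out. A configurable fraction of genes reuses
    another gene's canonical tag, to exercise ambiguous mapping.
    """
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    mu = math.log(cfg.gene_length_median)
    lengths = np.maximum(
        rng.lognormal(mu, cfg.gene_length_sigma, cfg.n_genes).astype(int),
        max(cfg.min_gene_length, TAG_LEN),
    )
    width = len(str(cfg.n_genes))
    unigenes: list[ReferenceUnigene] = []
    canonical: list[str] = []
    for i, L in enumerate(lengths):
        arr = _BASES[rng.integers(0, 4, L)]
        seq = bytearray(arr.tobytes())
        seq[L - TAG_LEN : L - TAG_LEN + 4] = ANCHOR.encode()
        s = seq.decode()
        unigenes.append(ReferenceUnigene(f"g{i:0{width}d}", s))
        canonical.append(s[-TAG_LEN:])

    if cfg.duplicate_tag_fraction > 0 and cfg.n_genes > 1:
        n_dup = int(round(cfg.duplicate_tag_fraction * cfg.n_genes))
        dup_idx = rng.choice(cfg.n_genes, size=n_dup, replace=False)
        for i in dup_idx:
            donor = int(rng.integers(0, cfg.n_genes))
            if donor == i:
                donor = (donor + 1) % cfg.n_genes
            tag = canonical[donor]
            s = unigenes[i].sequence[:-TAG_LEN] + tag
            unigenes[i] = ReferenceUnigene(unigenes[i].gene_id, s)
            canonical[i] = tag
    return SyntheticReference(unigenes, canonical)


def draw_expression(cfg: SimulationConfig, seed: int) -> np.ndarray:
    """Relative abundances under the configured heavy-tailed law."""
    rng = np.random.default_rng(seed)
    if cfg.expression_law == "lognormal":
        w = rng.lognormal(0.0, cfg.expression_sigma, cfg.n_genes)
    else:
        ranks = rng.permutation(cfg.n_genes) + 1
        w = 1.0 / ranks ** cfg.zipf_exponent
    return w / w.sum()


def _truncated_error_counts(rng, m: int, error_rate: float) -> np.ndarray:
    """Error counts (>=1) per errored read: Binomial(21, e) truncated at 1."""
    from scipy.stats import binom

    ks = np.arange(1, TAG_LEN + 1)
    pmf = binom.pmf(ks, TAG_LEN, error_rate)
    pmf /= pmf.sum()
    return rng.choice(ks, size=m, p=pmf)


def simulate_library(
    reference: SyntheticReference,
    expression: np.ndarray,
    cfg: SimulationConfig,
    library_id: str,
    seed: int,
) -> tuple[list[str], pd.DataFrame]:
    """Draw one raw tag library of ``cfg.depth`` 35-base reads.

    Reads are the gene's canonical tag plus adaptor-2 filler; substitution
    errors hit the 21-base informative window at the per-base rate
    (the filler is never read downstream and is emitted error-free);
    ``n_rate`` reads get an N in the window and ``empty_rate`` reads are
    adaptor-only. Returns the reads and a truth table with each gene's
    true relative abundance and sampled tag count.
    """
    if cfg.depth < 1:
        raise ValueError("depth must be positive")
    if not np.isclose(expression.sum(), 1.0):
        raise ValueError("expression must sum to 1")
    rng = np.random.default_rng(seed)
    n_genes = len(expression)
    tags_u8 = np.frombuffer(
        "".join(reference.canonical_tags).encode(), dtype=np.uint8
    ).reshape(n_genes, TAG_LEN)

    n_N, n_empty, n_tag = rng.multinomial(
        cfg.depth, [cfg.n_rate, cfg.empty_rate, 1.0 - cfg.n_rate - cfg.empty_rate]
    )
    gene_counts = rng.multinomial(n_tag, expression)

    # split each gene's reads into error-free and errored
    p_err = 1.0 - (1.0 - cfg.error_rate) ** TAG_LEN
    n_err = rng.binomial(gene_counts, p_err)
    n_perfect = gene_counts - n_err

    reads: list[str] = []
    for g in range(n_genes):
        if n_perfect[g]:
            reads.extend([reference.canonical_tags[g] + _FILLER] * int(n_perfect[g]))

    m = int(n_err.sum())
    if m:
        idx = np.repeat(np.arange(n_genes), n_err)
        mat = tags_u8[idx].copy()
        ks = _truncated_error_counts(rng, m, cfg.error_rate)
        order = np.argsort(rng.random((m, TAG_LEN)), axis=1)
        rows = np.arange(m)
        lut = np.zeros(256, dtype=np.uint8)  # base byte -> 0..3
        lut[_BASES] = np.arange(4)
        for k in np.unique(ks):
            sel = ks == k
            for j in range(int(k)):
                pos = order[sel, j]
                old = mat[rows[sel], pos]
                shift = rng.integers(1, 4, size=sel.sum())
                mat[rows[sel], pos] = _BASES[(lut[old] + shift) % 4]
        for row in mat:
            reads.append(row.tobytes().decode() + _FILLER)

    if n_N:
        gidx = rng.choice(n_genes, size=n_N, p=expression)
        pos = rng.integers(0, TAG_LEN, size=n_N)
        for g, p in zip(gidx, pos):
            t = reference.canonical_tags[g]
            reads.append(t[:p] + "N" + t[p + 1 :] + _FILLER)

    empty_read = (ADAPTOR2 + ADAPTOR2)[:READ_LEN]
    reads.extend([empty_read] * int(n_empty))

    truth = pd.DataFrame(
        {
            "gene_id": reference.gene_ids,
            "library_id": library_id,
            "true_abundance": expression,
            "true_tag_count": gene_counts,
        }
    )
    return reads, truth


@dataclass
class PairedExperiment:
    """Clean per-gene counts of two libraries plus the planted truth."""

    gene_ids: list[str]
    counts1: np.ndarray
    counts2: np.ndarray
    N1: int
    N2: int
    truth: pd.DataFrame  # gene_id, abundance1, abundance2, fold_change, is_de, direction


def make_paired_experiment(
    cfg: SimulationConfig, seed: int, gene_ids: list[str] | None = None
) -> PairedExperiment:
    """Two multinomially sampled libraries with a planted DE structure.

    Library 2 shares library 1's relative expression except for a
    ``de_fraction`` of genes scaled by ``de_fold_change`` (half up, half
    down), after which abundances are renormalized. The truth table records
    the applied factor (1 for non-DE genes).
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_genes
    if gene_ids is None:
        width = len(str(n))
        gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    expr1 = draw_expression(cfg, int(rng.integers(2**31)))

    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    up_idx = de_idx[: n_de // 2]
    down_idx = de_idx[n_de // 2 :]

    factor = np.ones(n)
    factor[up_idx] = cfg.de_fold_change
    factor[down_idx] = 1.0 / cfg.de_fold_change
    expr2 = expr1 * factor
    expr2 /= expr2.sum()

    counts1 = rng.multinomial(cfg.depth, expr1)
    counts2 = rng.multinomial(cfg.depth, expr2)

    direction = np.full(n, "none", dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "abundance1": expr1,
            "abundance2": expr2,
            "fold_change": factor,
            "is_de": factor != 1.0,
            "direction": direction,
        }
    )
    return PairedExperiment(
        gene_ids=gene_ids,
        counts1=counts1,
        counts2=counts2,
        N1=int(counts1.sum()),
        N2=int(counts2.sum()),
        truth=truth,
    )


def generate_annotation(
    gene_ids: list[str],
    cfg: SimulationConfig,
    seed: int,
    de_genes: set[str] | None = None,
) -> tuple[Annotation, set[str]]:
    """Random gene→term annotation with optionally planted enriched terms.

    Background term sizes follow a log-normal law. The first
    ``n_enriched_terms`` terms are planted: they take the configured mean
    size exactly (a heavy-tailed draw could leave a planted term too small
    to ever reach significance, which would make it useless as a recovery
    benchmark) and sample their members with weight ``enriched_odds`` on
    the designated DE genes; the remaining terms sample uniformly.
    """
    if cfg.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    genes = np.asarray(gene_ids)
    de_mask = (
        np.isin(genes, sorted(de_genes)) if de_genes else np.zeros(len(genes), bool)
    )
    enriched: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for t in range(cfg.n_terms):
        term = f"T{t:04d}"
        plant = t < cfg.n_enriched_terms and de_genes and cfg.enriched_odds != 1.0
        if plant:
            size = int(np.clip(round(cfg.term_size_mean), 2, len(genes)))
        else:
            size = int(
                np.clip(
                    rng.lognormal(math.log(cfg.term_size_mean), cfg.term_size_sigma),
                    2,
                    len(genes),
                )
            )
        if plant:
            w = np.where(de_mask, cfg.enriched_odds, 1.0)
            w = w / w.sum()
            members = rng.choice(genes, size=size, replace=False, p=w)
            enriched.add(term)
        else:
            members = rng.choice(genes, size=size, replace=False)
        pairs.extend((g, term) for g in members)
    ann = Annotation.from_pairs(pairs)
    ann.validate()
    return ann, enriched


# ---------------------------------------------------------------------------
# I/O

def write_fasta(reference: SyntheticReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u in reference.unigenes:
            fh.write(f">{u.gene_id}\n")
            for i in range(0, len(u.sequence), 70):
                fh.write(u.sequence[i : i + 70] + "\n")


def write_fastq(reads: list[str], path: str | Path, library_id: str = "lib") -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{library_id}_{i}\n{r}\n+\n{'I' * len(r)}\n")


def write_annotation_tsv(ann: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.gene2terms):
            for term in sorted(ann.gene2terms[gene]):
                fh.write(f"{gene}\t{term}\n")
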