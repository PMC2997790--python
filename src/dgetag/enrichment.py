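"""Hypergeometric gene-set enrichment of a DE gene list.

With N annotated background genes of which M carry a term, and n annotated
DE genes of which m carry it, the enrichment p-value is the upper tail of
the hypergeometric distribution,

    P = 1 - Σ_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)  =  P(X ≥ m),

i.e. the chance of drawing at least m term members in n draws without
replacement. GO-style runs correct by Bonferroni over the tested terms,
KO-style runs by Benjamini–Hochberg FDR; only annotated genes enter the
background, and only terms present in the background are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from scipy.stats import hypergeom

from .stats import bh_fdr


@dataclass
class Annotation:
    """Bidirectional gene ↔ term maps, kept mutually consistent."""

    gene2terms: dict[str, set[str]]
    term2genes: dict[str, set[str]]

    @classmethod
    def from_pairs(cls, pairs) -> "Annotation":
        g2t: dict[str, set[str]] = {}
        t2g: dict[str, set[str]] = {}
        for gene, term in pairs:
            g2t.setdefault(gene, set()).add(term)
            t2g.setdefault(term, set()).add(gene)
        return cls(g2t, t2g)

    def validate(self) -> None:
        for g, terms in self.gene2terms.items():
            for t in terms:
                if g not in self.term2genes.get(t, set()):
                    raise AssertionError("gene2terms/term2genes out of sync")


@dataclass(frozen=True)
class EnrichmentCount:
    N: int  # annotated background genes
    n: int  # annotated DE genes
    M: int  # background genes carrying the term
    m: int  # DE genes carrying the term

    def __post_init__(self) -> None:
        if self.M > self.N:
            raise ValueError("M > N")
        if self.n > self.N:
            raise ValueError("n > N")
        if self.m > min(self.n, self.M):
            raise ValueError("m > min(n, M)")
        if min(self.N, self.n, self.M, self.m) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EnrichmentResult:
    term_id: str
    counts: EnrichmentCount
    p_raw: float
    p_corrected: float
    significant: bool


def hypergeom_enrich_p(c: EnrichmentCount) -> float:
    """Upper-tail hypergeometric probability P(X ≥ m)."""
    if c.m == 0:
        return 1.0
    return float(hypergeom.sf(c.m - 1, c.N, c.M, c.n))


def enrich(
    de_genes,
    background_genes,
    ann: Annotation,
    mode: str = "bonferroni",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every annotated term for overrepresentation in the DE list.

    Unannotated genes are dropped from both the background (N) and the DE
    list (n). ``mode`` selects the multiplicity correction: ``"bonferroni"``
    (corrected p = p_raw × number of tested terms, capped at 1) or ``"fdr"``
    (Benjamini–Hochberg). A term is significant when its corrected value is
    below ``alpha``.
    """
    if mode not in ("bonferroni", "fdr"):
        raise ValueError(f"unknown mode {mode!r}")
    de_genes = set(de_genes)
    background_genes = set(background_genes)
    if not de_genes:
        raise ValueError("empty DE gene list")
    if not ann.gene2terms:
        raise ValueError("empty annotation")
    if not de_genes <= background_genes:
        raise ValueError("DE genes must be a subset of the background")

    annotated_bg = {g for g in background_genes if ann.gene2terms.get(g)}
    annotated_de = de_genes & annotated_bg
    N, n = len(annotated_bg), len(annotated_de)

    terms = sorted(
        t for t, genes in ann.term2genes.items() if genes & annotated_bg
    )
    counts = []
    p_raws = []
    for t in terms:
        members = ann.term2genes[t] & annotated_bg
        c = EnrichmentCount(N=N, n=n, M=len(members), m=len(members & annotated_de))
        counts.append(c)
        p_raws.append(hypergeom_enrich_p(c))

    k = len(terms)
    if mode == "bonferroni":
        p_corr = [min(1.0, p * k) for p in p_raws]
    else:
        p_corr = list(bh_fdr(p_raws))

    return [
        EnrichmentResult(t, c, p, pc, pc < alpha)
        for t, c, p, pc in zip(terms, counts, p_raws, p_corr)
    ]


# ---------------------------------------------------------------------------
# I/O

def read_annotation_tsv(path: str | Path) -> Annotation:
    """Two-column TSV, one (gene_id, term_id) pair per line."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            pairs.append((gene, term))
    return Annotation.from_pairs(pairs)


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tN\tn\tM\tm\tp_raw\tp_corrected\tsignificant\n")
        for r in sorted(results, key=lambda r: r.p_corrected):
            c = r.counts
            fh.write(
                f"{r.term_id}\t{c.N}\t{c.n}\t{c.M}\t{c.m}\t"
                f"{r.p_raw:.6g}\t{r.p_corrected:.6g}\t{int(r.significant)}\n"
            )
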