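"""Differential expression between two tag libraries.

For a gene observed ``x`` times among ``N1`` clean tags in one library and
``y`` times among ``N2`` in another, the Audic–Claverie model gives the
probability of the second observation conditional on the first, with a flat
prior on the (shared) underlying abundance:

    p(y | x) = (N2/N1)^y · (x+y)! / ( x! · y! · (1 + N2/N1)^(x+y+1) )

Writing r = N2/N1, this is a negative binomial in y with x+1 "successes"
and success probability 1/(1+r), which is how the cumulative tails are
evaluated (regularized incomplete beta). The pmf itself is computed in
log space so that counts up to millions stay finite.

The two-sided p-value doubles the smaller inclusive tail; because the
conditional construction is not literally symmetric in the two libraries
(the two orientations differ by exactly the observed point's mass), the
reported p is the larger of the two orientations — a conservative choice
that makes the test exactly invariant under swapping (x, N1) ↔ (y, N2).

Genes pass at FDR < 0.001 (Benjamini–Hochberg) and |log2 ratio| > 1 by
default; genes seen in only one library are additionally flagged as
library-specific.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, betaincc, gammaln
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PairedCounts:
    """One gene's counts in two libraries of given clean-tag depths."""

    gene_id: str
    x: int
    y: int
    N1: int
    N2: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if self.N1 < 1 or self.N2 < 1:
            raise ValueError("library sizes must be >= 1")
        if self.x > self.N1 or self.y > self.N2:
            raise ValueError("count exceeds library size")


@dataclass
class DGEConfig:
    fdr_threshold: float = 0.001
    log2_threshold: float = 1.0
    pseudocount: int = 1  # applied to zero counts only, for the display ratio

    def __post_init__(self) -> None:
        if self.fdr_threshold <= 0 or self.log2_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class DGEResult:
    gene_id: str
    x: int
    y: int
    tpm1: float
    tpm2: float
    log2_ratio: float
    p_value: float
    fdr: float
    significant: bool
    direction: str  # "up" | "down" | "ns"
    library_specific: str  # "none" | "lib1_only" | "lib2_only"


def ac_pmf(x: int, y_prime: int, N1: int, N2: int) -> float:
    """Audic–Claverie conditional probability p(y′ | x)."""
    if y_prime < 0:
        raise ValueError("y_prime must be non-negative")
    x = np.asarray(x)
    y = np.asarray(y_prime)
    log_r = np.log(N2) - np.log(N1)
    log_p = (
        gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        + y * log_r
        - (x + y + 1) * np.logaddexp(0.0, log_r)
    )
    return float(np.exp(log_p))


def _tails(x, y, N1, N2):
    """Inclusive lower and upper tails of Y | x under the conditional model."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = N1 / (N1 + N2)  # NB success probability
    lower = betainc(x + 1, y + 1, p)
    # P(Y >= y) = 1 - P(Y <= y-1); betaincc gives the complement accurately
    upper = np.where(y > 0, betaincc(x + 1, np.maximum(y, 1), p), 1.0)
    return lower, upper


def ac_test_array(x, y, N1: int, N2: int) -> np.ndarray:
    """Vectorized two-sided Audic–Claverie p-values (swap-symmetric)."""
    lo_f, hi_f = _tails(x, y, N1, N2)
    p_fwd = 2.0 * np.minimum(lo_f, hi_f)
    lo_b, hi_b = _tails(y, x, N2, N1)
    p_bwd = 2.0 * np.minimum(lo_b, hi_b)
    return np.minimum(1.0, np.maximum(p_fwd, p_bwd))


def ac_test(pc: PairedCounts) -> float:
    """Two-sided p-value for one gene's paired counts."""
    return float(ac_test_array(pc.x, pc.y, pc.N1, pc.N2))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(pairs: list[PairedCounts], cfg: DGEConfig | None = None):
    """Test every gene of a two-library comparison and call DE genes.

    Returns ``(results, n_up, n_down)``. "Up" means higher in the second
    library. The fold change shown (and thresholded) is the TPM ratio after
    substituting one pseudo-tag for zero counts only, so genes private to
    one library get a finite ratio; the test itself uses the raw counts.
    """
    if not pairs:
        raise ValueError("empty input")
    cfg = cfg or DGEConfig()
    N1, N2 = pairs[0].N1, pairs[0].N2
    if any(pc.N1 != N1 or pc.N2 != N2 for pc in pairs):
        raise ValueError("all pairs must share N1 and N2")

    x = np.array([pc.x for pc in pairs], dtype=np.int64)
    y = np.array([pc.y for pc in pairs], dtype=np.int64)
    p = ac_test_array(x, y, N1, N2)
    q = bh_fdr(p)

    tpm1 = x / N1 * 1e6
    tpm2 = y / N2 * 1e6
    x_eff = np.maximum(x, cfg.pseudocount)
    y_eff = np.maximum(y, cfg.pseudocount)
    log2_ratio = np.log2((y_eff / N2) / (x_eff / N1))

    significant = (q < cfg.fdr_threshold) & (np.abs(log2_ratio) > cfg.log2_threshold)
    results: list[DGEResult] = []
    n_up = n_down = 0
    for i, pc in enumerate(pairs):
        if significant[i]:
            direction = "up" if log2_ratio[i] > 0 else "down"
            if direction == "up":
                n_up += 1
            else:
                n_down += 1
        else:
            direction = "ns"
        if pc.x == 0 and pc.y > 0:
            specific = "lib2_only"
        elif pc.y == 0 and pc.x > 0:
            specific = "lib1_only"
        else:
            specific = "none"
        results.append(
            DGEResult(
                gene_id=pc.gene_id,
                x=pc.x,
                y=pc.y,
                tpm1=float(tpm1[i]),
                tpm2=float(tpm2[i]),
                log2_ratio=float(log2_ratio[i]),
                p_value=float(p[i]),
                fdr=float(q[i]),
                significant=bool(significant[i]),
                direction=direction,
                library_specific=specific,
            )
        )
    return results, n_up, n_down


def pairs_from_counts(
    counts1: dict[str, int],
    counts2: dict[str, int],
    N1: int,
    N2: int,
) -> list[PairedCounts]:
    """Join two gene→count maps over the union of genes (missing → 0)."""
    genes = sorted(set(counts1) | set(counts2))
    return [
        PairedCounts(g, counts1.get(g, 0), counts2.get(g, 0), N1, N2)
        for g in genes
    ]
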