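"""Master Regulator Analysis: Fisher enrichment of regulons in the signature.

Each TF is scored by the one-sided (enrichment) Fisher exact test on the
2x2 table [in-regulon x in-signature] over a gene universe; the p-value is
the hypergeometric upper tail P(X >= overlap). p-values are corrected
across all tested TFs with the Benjamini-Hochberg step-up, and TFs are
ranked by ascending p (ties: descending overlap, then TF id). The full
regulon enters the test, not only its differentially expressed members.
The default universe is the set of genes that were eligible as network
targets (i.e. the expression matrix genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import Regulon
from .signature import Signature


@dataclass
class MRAResult:
    tf_id: str
    regulon_size: int
    overlap: int
    signature_size: int
    universe_size: int
    fisher_p: float
    odds_ratio: float
    fdr: float
    rank: int


@dataclass
class OverlapReport:
    """Signature-restricted intersection counts among selected regulons."""

    set_sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    triple: dict[tuple[str, str, str], int]


def fisher_enrichment(
    regulon: set[str], signature_genes: set[str], universe: set[str]
) -> tuple[float, float, int]:
    """One-sided Fisher enrichment p, sample odds ratio, and overlap count.

    p = P(X >= overlap) for X hypergeometric with population `universe`,
    `signature_genes` successes, and `regulon`-many draws.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not regulon:
        raise ValueError("empty regulon: enrichment undefined")
    if not signature_genes:
        raise ValueError("empty signature: enrichment undefined")
    if not regulon <= universe:
        raise ValueError("regulon must be a subset of the universe")
    if not signature_genes <= universe:
        raise ValueError("signature genes must be a subset of the universe")
    N = len(universe)
    K = len(signature_genes)
    n = len(regulon)
    a = len(regulon & signature_genes)
    p = float(hypergeom(N, K, n).sf(a - 1))
    b = n - a
    c = K - a
    d = N - K - b
    odds = float(np.inf) if b * c == 0 else (a * d) / (b * c)
    return min(p, 1.0), odds, a


def bh_correct(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def master_regulator_analysis(
    regulons: Iterable[Regulon],
    signature: Signature,
    universe: set[str],
) -> list[MRAResult]:
    """Score every regulon, BH-correct across TFs, and rank.

    Regulon and signature membership are restricted to the universe before
    testing; a signature empty after restriction is an error.
    """
    regulons = list(regulons)
    if not regulons:
        raise ValueError("need at least one regulon")
    sig_genes = set(signature.genes) & universe
    if not sig_genes:
        raise ValueError("signature is empty after intersecting with the universe")

    rows = []
    for reg in regulons:
        targets = reg.targets & universe
        p, odds, overlap = fisher_enrichment(targets, sig_genes, universe)
        rows.append((reg.tf_id, len(targets), overlap, p, odds))

    fdrs = bh_correct([r[3] for r in rows])
    order = sorted(
        range(len(rows)), key=lambda i: (rows[i][3], -rows[i][2], rows[i][0])
    )
    ranks = {i: rank for rank, i in enumerate(order, start=1)}
    results = [
        MRAResult(
            tf_id=tf,
            regulon_size=size,
            overlap=overlap,
            signature_size=len(sig_genes),
            universe_size=len(universe),
            fisher_p=p,
            odds_ratio=odds,
            fdr=fdrs[i],
            rank=ranks[i],
        )
        for i, (tf, size, overlap, p, odds) in enumerate(rows)
    ]
    results.sort(key=lambda r: r.rank)
    return results


def regulon_overlap(
    regulons: Sequence[Regulon], signature: Signature
) -> OverlapReport:
    """Pairwise (and three-way, if three given) signature-restricted overlaps."""
    if len(regulons) < 2:
        raise ValueError("need at least two regulons to report overlaps")
    sig = set(signature.genes)
    restricted = {r.tf_id: r.targets & sig for r in regulons}
    names = [r.tf_id for r in regulons]
    pairwise = {
        (a, b): len(restricted[a] & restricted[b]) for a, b in combinations(names, 2)
    }
    triple = {}
    if len(names) >= 3:
        triple = {
            trio: len(set.intersection(*(restricted[t] for t in trio)))
            for trio in combinations(names, 3)
        }
    return OverlapReport(
        set_sizes={t: len(s) for t, s in restricted.items()},
        pairwise=pairwise,
        triple=triple,
    )
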