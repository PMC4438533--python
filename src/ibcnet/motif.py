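"""PWM promoter scanning and first-occurrence enrichment against a random-PWM null.

A promoter window is a hit when its log-odds score (uniform 0.25
background, probabilities floored at 1e-3 before the log) reaches a
fraction of the maximal achievable score (default 0.8). Both strands are
scanned. Distances are measured from the TSS: position 0 of each promoter
is the TSS-proximal end. A site read on the reverse strand is assigned the
distance of its start along that strand (window - L - start), which makes
the scan exactly strand-symmetric: reverse-complementing every promoter
permutes strands but leaves every first-occurrence distance unchanged.

Enrichment of a motif in a regulon's promoters is judged against the
first occurrences of random PWMs of the same length (flat-Dirichlet
columns): the empirical p-value is the add-one rank of the observed median
distance among the null medians, and a two-sample KS statistic against the
pooled null distances is reported descriptively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import ks_2samp

from .datatypes import AnalysisConfig

PROB_FLOOR = 1e-3
BACKGROUND = 0.25

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class PWM:
    """Position weight matrix: per-position probabilities over A, C, G, T."""

    probabilities: np.ndarray  # shape (4, L), rows in A, C, G, T order

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[0] != 4:
            raise ValueError("PWM must be a 4 x L matrix")
        if np.any(self.probabilities < 0):
            raise ValueError("PWM entries must be >= 0")
        sums = self.probabilities.sum(axis=0)
        if np.any(np.abs(sums - 1) > 1e-9):
            raise ValueError("each PWM column must sum to 1")

    @property
    def length(self) -> int:
        return self.probabilities.shape[1]

    def log_odds(self) -> np.ndarray:
        return np.log(np.maximum(self.probabilities, PROB_FLOOR) / BACKGROUND)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        # rows are A,C,G,T, so complementing is reversing the row order
        return PWM(probabilities=self.probabilities[::-1, ::-1].copy())

    @classmethod
    def from_consensus(cls, consensus: str, p: float = 1.0) -> "PWM":
        """PWM concentrated on a consensus string (probability p per position)."""
        codes = encode_sequence(consensus)
        probs = np.full((4, len(consensus)), (1 - p) / 3)
        probs[codes, np.arange(len(consensus))] = p
        return cls(probabilities=probs)


@dataclass
class FirstOccurrenceDistribution:
    """Per-gene first-occurrence distance from the TSS (None = no hit)."""

    distances: dict[str, int | None]

    @property
    def present(self) -> np.ndarray:
        return np.array(
            sorted(d for d in self.distances.values() if d is not None), dtype=float
        )

    @property
    def hit_fraction(self) -> float:
        if not self.distances:
            return 0.0
        return float(np.mean([d is not None for d in self.distances.values()]))

    def median(self) -> float:
        vals = self.present
        if vals.size == 0:
            raise ValueError("no hits: median undefined")
        return float(np.median(vals))

    def ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        """Support points and ECDF values over genes with a hit."""
        vals = self.present
        if vals.size == 0:
            return np.array([]), np.array([])
        return vals, np.arange(1, vals.size + 1) / vals.size


@dataclass
class MotifEnrichmentResult:
    observed_median: float
    null_medians: list[float]
    empirical_p: float
    ks_statistic: float
    hit_fraction: float


def encode_sequence(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if np.any(codes < 0):
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return codes


def _score_all_windows(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window start for every sequence row."""
    n, window = codes.shape
    L = log_odds.shape[1]
    npos = window - L + 1
    scores = np.zeros((n, npos))
    for j in range(L):
        scores += log_odds[:, j][codes[:, j : j + npos]]
    return scores


def _first_occurrence_batch(
    pwm: PWM, codes: np.ndarray, score_fraction: float
) -> np.ndarray:
    """First-occurrence TSS distance per row; inf where no window is a hit."""
    window = codes.shape[1]
    L = pwm.length
    if L > window:
        raise ValueError("PWM longer than the promoter window")
    threshold = score_fraction * pwm.max_score()
    npos = window - L + 1

    fwd = _score_all_windows(codes, pwm.log_odds()) >= threshold
    rev = _score_all_windows(codes, pwm.reverse_complement().log_odds()) >= threshold

    dist = np.full(codes.shape[0], np.inf)
    any_f = fwd.any(axis=1)
    dist[any_f] = fwd[any_f].argmax(axis=1)
    any_r = rev.any(axis=1)
    # reverse-strand start i lies at distance (npos - 1) - i along that strand
    first_r = (npos - 1) - rev[any_r, ::-1].argmax(axis=1)
    dist[any_r] = np.minimum(dist[any_r], (npos - 1) - first_r)
    return dist


def scan_first_occurrence(
    pwm: PWM, promoter: str, score_fraction: float
) -> int | None:
    """Smallest TSS distance among hit windows on either strand, else None."""
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    codes = encode_sequence(promoter)[None, :]
    d = _first_occurrence_batch(pwm, codes, score_fraction)[0]
    return None if np.isinf(d) else int(d)


def first_occurrence_distribution(
    pwm: PWM, promoters: Mapping[str, str], score_fraction: float
) -> FirstOccurrenceDistribution:
    """First-occurrence distances over a promoter set (uniform length required)."""
    if not promoters:
        raise ValueError("need at least one promoter")
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    genes = list(promoters)
    lengths = {len(promoters[g]) for g in genes}
    if len(lengths) != 1:
        raise ValueError("promoters must have uniform length")
    codes = np.vstack([encode_sequence(promoters[g]) for g in genes])
    dist = _first_occurrence_batch(pwm, codes, score_fraction)
    return FirstOccurrenceDistribution(
        distances={
            g: (None if np.isinf(d) else int(d)) for g, d in zip(genes, dist)
        }
    )


def random_pwm_null(length: int, n_random: int, seed: int) -> list[PWM]:
    """Random PWMs with columns drawn from a flat Dirichlet over the 4 letters."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        PWM(probabilities=rng.dirichlet(np.ones(4), size=length).T)
        for _ in range(n_random)
    ]


def motif_enrichment(
    pwm: PWM, promoters: Mapping[str, str], config: AnalysisConfig
) -> MotifEnrichmentResult:
    """Compare a motif's first-occurrence distances against a random-PWM null.

    empirical p = (1 + #{null PWMs with median <= observed median}) /
    (n_random + 1); null PWMs with no hits anywhere never count as closer.
    """
    observed = first_occurrence_distribution(pwm, promoters, config.score_fraction)
    if observed.present.size == 0:
        raise ValueError("query PWM has no hits: enrichment undefined")
    obs_median = observed.median()

    genes = list(promoters)
    codes = np.vstack([encode_sequence(promoters[g]) for g in genes])
    null_medians: list[float] = []
    pooled: list[np.ndarray] = []
    for rand_pwm in random_pwm_null(pwm.length, config.n_random_pwms, config.seed):
        d = _first_occurrence_batch(rand_pwm, codes, config.score_fraction)
        hits = d[np.isfinite(d)]
        null_medians.append(float(np.median(hits)) if hits.size else float("inf"))
        pooled.append(hits)
    n_closer = sum(m <= obs_median for m in null_medians)
    empirical_p = (1 + n_closer) / (config.n_random_pwms + 1)

    pooled_arr = np.concatenate(pooled) if pooled else np.array([])
    ks = (
        float(ks_2samp(observed.present, pooled_arr).statistic)
        if pooled_arr.size
        else float("nan")
    )
    return MotifEnrichmentResult(
        observed_median=obs_median,
        null_medians=null_medians,
        empirical_p=float(empirical_p),
        ks_statistic=ks,
        hit_fraction=observed.hit_fraction,
    )
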