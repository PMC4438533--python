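"""Synthetic two-phenotype expression cohorts with planted regulatory structure.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of IBC and nIBC samples, a set of transcription factors
each driving a disjoint regulon of correlated targets through a
linear-Gaussian coupling, a subset of "master regulator" TFs whose
phenotype-dependent shift propagates to their targets, and a pool of
unregulated background genes. Promoter sequences with motif sites planted
near the transcription start site provide matching input for the motif
stage.

The linear-Gaussian TF->target model is the simplest model that produces
the mutual-information structure an ARACNe-style inference step assumes,
while keeping closed-form checks available (Gaussian MI is
-0.5*ln(1-rho^2)). Regulons are pairwise disjoint so planted-truth
recovery is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionMatrix, PhenotypeLabels

BASELINE_MEAN = 8.0  # log2-intensity-like scale, cosmetic
BASELINE_SD = 1.0


@dataclass
class GeneratorParams:
    """Cohort and network parameters of the expression simulator.

    Sample-count defaults (63 IBC / 134 nIBC) mirror the learning cohort
    the analysis was designed for; `effect` is the phenotype shift of a
    master-regulator TF in units of the noise scale sigma, and `coupling`
    is the regression weight of a target on its (centred) TF.
    """

    n_ibc: int = 63
    n_nibc: int = 134
    n_tfs: int = 20
    n_mr: int = 3
    regulon_size: int = 30
    n_background: int = 500
    coupling: float = 0.8
    effect: float = 1.5
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ibc", "n_nibc", "n_tfs", "n_mr", "regulon_size", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_mr > self.n_tfs:
            raise ValueError("n_mr cannot exceed n_tfs")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth: regulon membership, edge signs, MR identities."""

    tf_ids: list[str]
    regulons: dict[str, set[str]]
    mr_ids: list[str]
    edge_signs: dict[tuple[str, str], int]
    effect_directions: dict[str, int]

    def __post_init__(self) -> None:
        if not set(self.mr_ids) <= set(self.tf_ids):
            raise ValueError("mr_ids must be a subset of tf_ids")
        all_targets: set[str] = set()
        for tf, targets in self.regulons.items():
            if all_targets & targets:
                raise ValueError("regulons must be pairwise disjoint over targets")
            all_targets |= targets

    @property
    def target_ids(self) -> list[str]:
        out: list[str] = []
        for tf in self.tf_ids:
            out.extend(sorted(self.regulons[tf]))
        return out


@dataclass
class PromoterParams:
    """Parameters of the promoter-sequence generator.

    `window` is the promoter length upstream of the TSS; planted motif
    sites sit at an exponentially distributed distance from the TSS (mean
    `planted_distance_scale`), reproducing the near-TSS concentration seen
    for genuine binding motifs.
    """

    window: int = 2000
    planted_distance_scale: float = 200.0
    background_gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must be in (0, 1)")


def generate_truth(params: GeneratorParams) -> SyntheticTruth:
    """Draw the planted regulatory structure (deterministic for a fixed seed)."""
    rng = np.random.default_rng(params.seed)
    tf_ids = [f"TF{i:03d}" for i in range(1, params.n_tfs + 1)]
    regulons: dict[str, set[str]] = {}
    edge_signs: dict[tuple[str, str], int] = {}
    g = 0
    for tf in tf_ids:
        targets = set()
        for _ in range(params.regulon_size):
            g += 1
            target = f"G{g:05d}"
            targets.add(target)
            edge_signs[(tf, target)] = 1 if rng.random() < 0.5 else -1
        regulons[tf] = targets
    mr_ids = sorted(rng.choice(tf_ids, size=params.n_mr, replace=False).tolist())
    effect_directions = {tf: (1 if rng.random() < 0.5 else -1) for tf in mr_ids}
    return SyntheticTruth(
        tf_ids=tf_ids,
        regulons=regulons,
        mr_ids=mr_ids,
        edge_signs=edge_signs,
        effect_directions=effect_directions,
    )


def simulate_expression(
    truth: SyntheticTruth, params: GeneratorParams
) -> tuple[ExpressionMatrix, PhenotypeLabels]:
    """Simulate a log2 expression cohort from the planted truth.

    Model: TF g has expression mu_g + s_g*Delta*sigma*1[IBC and g is MR]
    + N(0, sigma^2); a target of g is mu_t + sign(g,t)*coupling*(TF_g -
    mu_g) + N(0, sigma^2); background genes are mu + N(0, sigma^2)
    independent of phenotype. Per-gene baselines mu are drawn once from
    N(8, 1).
    """
    rng = np.random.default_rng(params.seed + 1)  # offset: truth vs values
    n = params.n_ibc + params.n_nibc
    sample_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    is_ibc = np.zeros(n, dtype=bool)
    is_ibc[: params.n_ibc] = True
    labels = PhenotypeLabels(
        {s: ("IBC" if flag else "nIBC") for s, flag in zip(sample_ids, is_ibc)}
    )

    target_ids = truth.target_ids
    background_ids = [f"BG{i:05d}" for i in range(1, params.n_background + 1)]
    gene_ids = list(truth.tf_ids) + target_ids + background_ids
    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=len(gene_ids))
    mu = dict(zip(gene_ids, baselines))

    values = np.empty((len(gene_ids), n))
    row = {g: i for i, g in enumerate(gene_ids)}

    for tf in truth.tf_ids:
        shift = np.zeros(n)
        if tf in truth.mr_ids:
            shift[is_ibc] = (
                truth.effect_directions[tf] * params.effect * params.sigma
            )
        values[row[tf]] = mu[tf] + shift + rng.normal(0, params.sigma, size=n)

    for tf in truth.tf_ids:
        centred_tf = values[row[tf]] - mu[tf]
        for target in sorted(truth.regulons[tf]):
            sign = truth.edge_signs[(tf, target)]
            values[row[target]] = (
                mu[target]
                + sign * params.coupling * centred_tf
                + rng.normal(0, params.sigma, size=n)
            )

    for bg in background_ids:
        values[row[bg]] = mu[bg] + rng.normal(0, params.sigma, size=n)

    return ExpressionMatrix(gene_ids, sample_ids, values), labels


def generate_promoters(
    truth: SyntheticTruth,
    pwm,
    params: PromoterParams,
    target_tf: str,
    gene_ids: list[str] | None = None,
) -> dict[str, str]:
    """Generate promoter sequences with motif sites planted in one regulon.

    Promoters of `target_tf`'s regulon genes carry a single site sampled
    from the PWM at an exponential-distributed distance from the TSS
    (position 0 = TSS-proximal end, distance increases upstream);
    promoters of all other genes are background-only. Returns a mapping
    gene id -> sequence of length `window`.
    """
    if target_tf not in truth.tf_ids:
        raise ValueError(f"unknown TF {target_tf!r}")
    length = pwm.length
    if length > params.window:
        raise ValueError("PWM longer than the promoter window")
    if gene_ids is None:
        gene_ids = list(truth.tf_ids) + truth.target_ids
    rng = np.random.default_rng(params.seed)
    gc = params.background_gc
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    regulon = truth.regulons[target_tf]

    out: dict[str, str] = {}
    for gene in gene_ids:
        codes = rng.choice(4, size=params.window, p=base_probs)
        if gene in regulon:
            d = int(rng.exponential(params.planted_distance_scale))
            d = min(d, params.window - length)
            site = np.array(
                [rng.choice(4, p=pwm.probabilities[:, j]) for j in range(length)]
            )
            codes[d : d + length] = site
        out[gene] = "".join(alphabet[codes])
    return out
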