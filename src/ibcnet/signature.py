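"""Differential-expression signature and the centroid "IBC score" classifier.

The signature is the set of genes passing an absolute linear fold-change
filter (on log2 differences, |log2fc| >= log2(fc_threshold)) together with
a two-sided pooled-variance Student t-test at p <= alpha; no multiple-
testing correction is applied inside the filter. The classifier correlates
each sample's signature-gene profile with the centroid (mean log2 profile
of the IBC learning samples); the Pearson r is the IBC score, and a sample
is called IBC-like exactly when r > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import AnalysisConfig, ExpressionMatrix, PhenotypeLabels


@dataclass
class SignatureEntry:
    gene_id: str
    log2fc: float  # IBC mean - nIBC mean, log2 units
    t_stat: float
    p_value: float
    direction: str  # "up" iff log2fc > 0

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass
class Signature:
    entries: list[SignatureEntry]

    @property
    def genes(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    @property
    def up_set(self) -> set[str]:
        return {e.gene_id for e in self.entries if e.direction == "up"}

    @property
    def down_set(self) -> set[str]:
        return {e.gene_id for e in self.entries if e.direction == "down"}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Centroid:
    """Mean log2 expression of signature genes over the IBC learning samples."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids),):
            raise ValueError("centroid values must align with gene_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("centroid contains non-finite values")


@dataclass
class ScoredSample:
    sample_id: str
    r: float  # IBC score, Pearson correlation with the centroid
    call: str  # "IBC-like" iff r > 0


@dataclass
class ValidationResult:
    scores: list[ScoredSample]
    t_stat: float
    p_value: float


def differential_expression(
    X: ExpressionMatrix, labels: PhenotypeLabels, config: AnalysisConfig
) -> Signature:
    """Two-group DE filter: |log2fc| >= log2(fc_threshold) and t-test p <= alpha.

    Entries are ordered by descending |log2fc| (ties broken by gene id).
    The fold-change filter and the t-test are both per-gene, so their
    application order is immaterial.
    """
    labels.validate_against(X)
    labels.require_both_groups()
    ibc = labels.samples_of("IBC")
    nibc = labels.samples_of("nIBC")
    if len(ibc) < 2 or len(nibc) < 2:
        raise ValueError("each phenotype group needs >= 2 samples for the t-test")

    A = X.sample_columns(ibc)  # genes x IBC samples
    B = X.sample_columns(nibc)
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    t_stat, p_value = stats.ttest_ind(A, B, axis=1, equal_var=True)

    fc_cut = np.log2(config.fc_threshold)
    keep = (np.abs(log2fc) >= fc_cut) & (p_value <= config.alpha)
    entries = [
        SignatureEntry(
            gene_id=X.gene_ids[i],
            log2fc=float(log2fc[i]),
            t_stat=float(t_stat[i]),
            p_value=float(p_value[i]),
            direction="up" if log2fc[i] > 0 else "down",
        )
        for i in np.flatnonzero(keep)
    ]
    entries.sort(key=lambda e: (-abs(e.log2fc), e.gene_id))
    return Signature(entries=entries)


def build_centroid(
    X: ExpressionMatrix, labels: PhenotypeLabels, signature: Signature
) -> Centroid:
    """Per-gene arithmetic mean over IBC-labeled samples only."""
    labels.validate_against(X)
    ibc = labels.samples_of("IBC")
    if not ibc:
        raise ValueError("no IBC samples to build the centroid from")
    genes = signature.genes
    known = set(X.gene_ids)
    for g in genes:
        if g not in known:
            raise KeyError(f"signature gene {g!r} missing from the matrix")
    idx = [X.gene_index(g) for g in genes]
    sub = X.sample_columns(ibc)[idx, :]
    return Centroid(gene_ids=genes, values=sub.mean(axis=1))


def ibc_score(
    sample_id: str, sample_profile: np.ndarray, centroid: Centroid
) -> ScoredSample:
    """Pearson correlation of a sample's signature-gene profile with the centroid.

    r > 0 -> IBC-like; r <= 0 (including exactly 0) -> nIBC-like.
    """
    profile = np.asarray(sample_profile, dtype=float)
    if profile.shape != centroid.values.shape:
        raise ValueError("sample profile and centroid must share gene order/length")
    if np.std(profile) == 0 or np.std(centroid.values) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    r = float(np.corrcoef(profile, centroid.values)[0, 1])
    return ScoredSample(sample_id=sample_id, r=r, call="IBC-like" if r > 0 else "nIBC-like")


def score_samples(X: ExpressionMatrix, centroid: Centroid) -> list[ScoredSample]:
    idx = [X.gene_index(g) for g in centroid.gene_ids]
    sub = X.values[idx, :]
    return [
        ibc_score(sample, sub[:, j], centroid)
        for j, sample in enumerate(X.sample_ids)
    ]


def validate_signature(
    X_val: ExpressionMatrix, labels_val: PhenotypeLabels, centroid: Centroid
) -> ValidationResult:
    """Score a validation cohort and t-test the IBC score between true groups."""
    labels_val.validate_against(X_val)
    labels_val.require_both_groups()
    scores = score_samples(X_val, centroid)
    by_sample = {s.sample_id: s.r for s in scores}
    r_ibc = [by_sample[s] for s in labels_val.samples_of("IBC") if s in by_sample]
    r_nibc = [by_sample[s] for s in labels_val.samples_of("nIBC") if s in by_sample]
    t_stat, p_value = stats.ttest_ind(r_ibc, r_nibc, equal_var=True)
    return ValidationResult(scores=scores, t_stat=float(t_stat), p_value=float(p_value))
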