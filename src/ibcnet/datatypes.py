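"""Core containers shared across the pipeline.

Expression values are assumed to be on the log2 scale throughout (the RMA
convention for microarray intensities); the fold-change filter in
:mod:`ibcnet.signature` therefore operates on log2 differences. Gene and
sample identifiers are matched exactly and case-sensitively everywhere to
avoid silent probe/gene aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np
import yaml

PHENOTYPES = ("IBC", "nIBC")


class FormatError(ValueError):
    """Malformed on-disk input (readers reject rather than coerce)."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers, order preserved.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))`` with no
        missing or non-finite entries.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {name} id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def sample_columns(self, sample_ids: Iterable[str]) -> np.ndarray:
        idx = [self._sample_index[s] for s in sample_ids]
        return self.values[:, idx]


@dataclass
class PhenotypeLabels:
    """Mapping sample id -> phenotype (``IBC`` or ``nIBC``)."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = dict(self.labels)
        for sample, phen in self.labels.items():
            if phen not in PHENOTYPES:
                raise FormatError(
                    f"unknown phenotype {phen!r} for sample {sample!r}; "
                    f"expected one of {PHENOTYPES}"
                )

    def samples_of(self, phenotype: str) -> list[str]:
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        return [s for s, p in self.labels.items() if p == phenotype]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check every labeled sample exists in the paired matrix."""
        missing = [s for s in self.labels if s not in set(matrix.sample_ids)]
        if missing:
            raise ValueError(f"labeled samples not in matrix: {missing[:5]}")

    def require_both_groups(self) -> None:
        for phen in PHENOTYPES:
            if not self.samples_of(phen):
                raise ValueError(f"phenotype {phen!r} has no samples")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline.

    Defaults are the analysis' standard operating point: linear fold change
    1.5 and p <= 0.05 for the differential-expression filter, k = 3
    neighbours and 1e-12 jitter for the KSG mutual-information estimator,
    DPI tolerance 0, 100 random PWMs for the motif null, and a strict 5%
    cutoff for IHC marker positivity.
    """

    fc_threshold: float = 1.5
    alpha: float = 0.05
    k: int = 3
    noise_amplitude: float = 1e-12
    dpi_eps: float = 0.0
    n_random_pwms: int = 100
    score_fraction: float = 0.8
    positivity_cutoff_percent: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.dpi_eps < 0:
            raise ValueError("dpi_eps must be >= 0")
        if not 0 < self.score_fraction <= 1:
            raise ValueError("score_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None
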