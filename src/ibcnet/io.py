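"""Readers and writers for the pipeline's on-disk formats.

Formats: expression matrices and phenotype labels as tab-delimited text,
networks as three-column TSV, regulons as GMT (one gene set per line),
promoters as FASTA (via Biopython), PWMs as JASPAR-style 4-row matrices.
Every reader validates and raises :class:`~ibcnet.datatypes.FormatError`
on malformed input instead of silently coercing; every write/read pair
round-trips exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import ExpressionMatrix, FormatError, PhenotypeLabels

NETWORK_HEADER = ("tf", "target", "mi")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV: first row sample ids, first column gene ids."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or len(rows) < 2:
        raise FormatError(f"{path}: expected a header row and at least one gene row")
    sample_ids = rows[0][1:]
    if not sample_ids:
        raise FormatError(f"{path}: no sample columns")
    gene_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(sample_ids)), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}: row {i} has {len(row)} fields, expected {len(sample_ids) + 1}"
            )
        gene_ids.append(row[0])
        for j, cell in enumerate(row[1:]):
            try:
                values[i - 2, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at gene {row[0]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", *matrix.sample_ids])
        for gene, row in zip(matrix.gene_ids, matrix.values):
            w.writerow([gene, *(repr(float(v)) for v in row)])


def read_phenotype_labels(path: str | Path) -> PhenotypeLabels:
    """Read a two-column TSV of (sample_id, phenotype) pairs."""
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if i == 1 and row[0] in ("sample_id", "sample"):
                continue
            if len(row) != 2:
                raise FormatError(f"{path}: line {i} has {len(row)} fields, expected 2")
            sample, phen = row
            if sample in labels:
                raise FormatError(f"{path}: duplicate sample {sample!r}")
            labels[sample] = phen
    if not labels:
        raise FormatError(f"{path}: no phenotype labels found")
    return PhenotypeLabels(labels)


def write_phenotype_labels(labels: PhenotypeLabels, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "phenotype"])
        for sample, phen in labels.labels.items():
            w.writerow([sample, phen])


def write_network_table(network, path: str | Path) -> None:
    """Write TF-target-MI edges sorted by TF, then descending MI, then target.

    The tie-break on target id makes the output deterministic for equal MI.
    """
    edges = sorted(network.edges, key=lambda e: (e[0], -e[2], e[1]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(NETWORK_HEADER)
        for tf, target, mi in edges:
            w.writerow([tf, target, repr(float(mi))])


def read_network_table(path: str | Path):
    from .network import MINetwork

    path = Path(path)
    edges = []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or tuple(rows[0]) != NETWORK_HEADER:
        raise FormatError(f"{path}: expected header {NETWORK_HEADER}")
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != 3:
            raise FormatError(f"{path}: line {i} has {len(row)} fields, expected 3")
        try:
            mi = float(row[2])
        except ValueError:
            raise FormatError(f"{path}: non-numeric MI {row[2]!r} on line {i}") from None
        edges.append((row[0], row[1], mi))
    return MINetwork(edges=set(edges))


def write_gmt(regulons, path: str | Path) -> None:
    """Write regulons in GMT format: name, description, then member genes."""
    with open(path, "w", newline="") as fh:
        for reg in regulons:
            targets = sorted(reg.targets)
            fh.write("\t".join([reg.tf_id, f"regulon of {reg.tf_id}", *targets]) + "\n")


def read_gmt(path: str | Path):
    from .network import Regulon

    path = Path(path)
    regulons = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {i} needs name, description and >= 1 gene"
                )
            name = parts[0]
            if name in seen:
                raise FormatError(f"{path}: duplicate set name {name!r}")
            seen.add(name)
            regulons.append(Regulon(tf_id=name, targets=set(parts[2:])))
    return regulons


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def read_pwm(path: str | Path):
    """Read a JASPAR-style 4-row PWM (counts or probabilities) via Biopython."""
    from .motif import PWM

    path = Path(path)
    with open(path) as fh:
        try:
            motif = motifs.read(fh, "jaspar")
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse JASPAR matrix ({exc})") from exc
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    col_sums = counts.sum(axis=0)
    if np.any(col_sums <= 0):
        raise FormatError(f"{path}: PWM column with non-positive total")
    return PWM(probabilities=counts / col_sums)


def write_pwm(pwm, name: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", pwm.probabilities):
            fh.write(f"{base}  [ " + "  ".join(f"{v:.6f}" for v in row) + " ]\n")
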