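"""TSV readers and writers for the benchmark's file dialects.

One dialect throughout: tab-delimited UTF-8 text with Unix newlines.
Expression matrices have a ``gene_id`` first column and one column per
sample, values written with 6 decimal places. Design tables carry
``sample_id``, ``globin_fraction``, ``tissue``, ``protocol`` and the
optional ``time``/``dose`` columns. Signatures carry ``gene_id``,
``direction`` and optional ``log_ratio``/``p_value``.

Readers validate aggressively and raise :class:`FormatError` naming the
offending line or column rather than silently coercing.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import validate_signature
from .containers import (DesignError, ExpressionMatrix, GroundTruth,
                         SpikeInDesign, TISSUES)

__all__ = [
    "FormatError",
    "read_expression", "write_expression",
    "read_design", "write_design",
    "read_ground_truth", "write_ground_truth",
    "read_signature", "write_signature",
    "write_gene_stats",
    "align_design",
]


class FormatError(ValueError):
    """A file does not conform to the expected TSV dialect."""


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format="%.6f",
                           lineterminator="\n")


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise FormatError(f"{path.name}: empty expression file")
    lines = text.rstrip("\n").split("\n")
    header = lines[0].split("\t")
    if header[0] != "gene_id":
        raise FormatError(f"{path.name}: first column must be 'gene_id', "
                          f"got {header[0]!r}")
    samples = header[1:]
    if not samples:
        raise FormatError(f"{path.name}: no sample columns")
    seen: dict = {}
    for col in samples:
        if col in seen:
            raise FormatError(f"{path.name}: duplicated sample column {col!r}")
        seen[col] = True

    n_cols = len(header)
    gene_ids = []
    rows = np.empty((len(lines) - 1, len(samples)))
    gene_seen: set = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise FormatError(f"{path.name}: line {lineno} has {len(fields)} "
                              f"fields, expected {n_cols}")
        gid = fields[0]
        if gid in gene_seen:
            raise FormatError(f"{path.name}: line {lineno}: duplicate gene id "
                              f"{gid!r}")
        gene_seen.add(gid)
        gene_ids.append(gid)
        try:
            rows[lineno - 2] = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise FormatError(
                f"{path.name}: line {lineno}: non-numeric cell ({exc})") from None
    return ExpressionMatrix(rows, np.asarray(gene_ids, dtype=object),
                            np.asarray(samples, dtype=object))


def write_design(design: SpikeInDesign, path) -> None:
    design.samples.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_design(path) -> SpikeInDesign:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path.name}: empty design file") from None
    required = ["sample_id", "globin_fraction", "tissue", "protocol"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"{path.name}: missing design column(s) {missing}")

    frac = pd.to_numeric(table["globin_fraction"], errors="coerce")
    if frac.isna().any():
        row = int(frac.index[frac.isna()][0]) + 2
        raise FormatError(f"{path.name}: line {row}: non-numeric globin_fraction")
    percentish = frac > 1.0
    if percentish.any():
        warnings.warn(f"{path.name}: globin_fraction values > 1 interpreted "
                      "as percent and divided by 100")
        frac = frac.where(~percentish, frac / 100.0)
    table = table.assign(globin_fraction=frac,
                         tissue=table["tissue"].astype(str).str.lower())
    bad = set(table["tissue"].unique()) - set(TISSUES)
    if bad:
        raise FormatError(f"{path.name}: unknown tissue label(s) {sorted(bad)}; "
                          f"allowed: {list(TISSUES)}")
    return SpikeInDesign(table)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f",
                            lineterminator="\n")


def read_ground_truth(path) -> GroundTruth:
    table = pd.read_csv(path, sep="\t")
    required = ["gene_id", "baseline", "artifact_slope", "de_effect"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"missing ground-truth column(s) {missing}")
    return GroundTruth.from_frame(table)


def write_signature(sig: pd.DataFrame, path) -> None:
    validate_signature(sig).to_csv(path, sep="\t", index=False,
                                   lineterminator="\n")


def read_signature(path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path.name}: empty signature file") from None
    return validate_signature(table)


def write_gene_stats(gene_stats: pd.DataFrame, path) -> None:
    gene_stats.to_csv(path, sep="\t", index=False, float_format="%.6g",
                      lineterminator="\n")


def align_design(expr: ExpressionMatrix, design: SpikeInDesign) -> SpikeInDesign:
    """Design rows matching the matrix samples, in matrix order.

    Missing samples raise a :class:`DesignError` naming them; extra design
    rows are dropped with a warning.
    """
    available = set(design.samples["sample_id"])
    wanted = list(expr.sample_ids)
    missing = [s for s in wanted if s not in available]
    if missing:
        raise DesignError(f"design is missing sample(s): {missing}")
    extra = available - set(wanted)
    if extra:
        warnings.warn(f"ignoring {len(extra)} design row(s) without matrix "
                      f"columns: {sorted(extra)[:5]}")
    return design.subset(wanted)
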