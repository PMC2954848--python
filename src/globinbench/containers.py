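"""Core data containers shared across the benchmark.

The benchmark revolves around three objects: a log2-scale gene-by-sample
expression matrix, the spike-in design annotating each sample (globin mass
fraction, spiked tissue, processing protocol, and optionally time/dose for
ex vivo dosing experiments), and — for simulated data — the planted ground
truth (per-gene baseline, globin-artifact slope, and differential effect).

A :class:`ProtocolProfile` captures how a sample-processing protocol shapes
the data: how strongly the globin artifact comes through
(``artifact_susceptibility``), how noisy the measurements are (``noise_sd``,
log2 units), and what share of genes respond to globin with positive or
negative slopes (the negative minority mimics normalization compensation).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
import pandas as pd

TISSUES = ("brain", "liver")

__all__ = [
    "TISSUES",
    "DesignError",
    "ParameterError",
    "ProtocolProfile",
    "SpikeInDesign",
    "ExpressionMatrix",
    "GroundTruth",
]


class DesignError(ValueError):
    """The experimental design is invalid or inconsistent with the data."""


class ParameterError(ValueError):
    """A numeric parameter is out of range or non-finite."""


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")


@dataclasses.dataclass(frozen=True)
class ProtocolProfile:
    """Statistical fingerprint of one sample-processing protocol.

    Parameters
    ----------
    name
        Protocol label (e.g. ``"no_treatment"``, ``"pna"``, ``"cdna"``).
    artifact_susceptibility
        Multiplier ``alpha`` in [0, 1] applied to every gene's globin slope;
        1 means the full artifact comes through, 0 means complete mitigation.
    noise_sd
        Residual measurement noise standard deviation, log2-intensity units.
    pos_artifact_fraction, neg_artifact_fraction
        Fractions of genes assigned positive / negative globin slopes.
    """

    name: str
    artifact_susceptibility: float
    noise_sd: float
    pos_artifact_fraction: float = 0.35
    neg_artifact_fraction: float = 0.15

    def __post_init__(self) -> None:
        for field in ("artifact_susceptibility", "noise_sd",
                      "pos_artifact_fraction", "neg_artifact_fraction"):
            _check_finite(field, getattr(self, field))
        if not 0.0 <= self.artifact_susceptibility <= 1.0:
            raise ParameterError("artifact_susceptibility must be in [0, 1]")
        if self.noise_sd <= 0.0:
            raise ParameterError("noise_sd must be > 0")
        if self.pos_artifact_fraction < 0 or self.neg_artifact_fraction < 0:
            raise ParameterError("artifact fractions must be non-negative")
        if self.pos_artifact_fraction + self.neg_artifact_fraction > 1.0:
            raise ParameterError(
                "pos_artifact_fraction + neg_artifact_fraction must be <= 1")


@dataclasses.dataclass(frozen=True)
class SpikeInDesign:
    """Per-sample annotation table for a spike-in experiment.

    Wraps a DataFrame with columns ``sample_id``, ``globin_fraction``
    (mass fraction in [0, 1]), ``tissue`` (``brain``/``liver``),
    ``protocol``, and optionally ``time`` (hours) and ``dose``.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "globin_fraction", "tissue", "protocol"}
        missing = required - set(self.samples.columns)
        if missing:
            raise DesignError(f"design is missing columns: {sorted(missing)}")
        if len(self.samples) == 0:
            raise DesignError("design has no samples")
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DesignError(f"duplicate sample_id in design: {dup!r}")
        frac = self.samples["globin_fraction"].to_numpy(dtype=float)
        if not np.all(np.isfinite(frac)):
            raise DesignError("globin_fraction contains non-finite values")
        if np.any(frac < 0) or np.any(frac > 1):
            raise DesignError("globin_fraction must lie in [0, 1]")
        bad = set(self.samples["tissue"].unique()) - set(TISSUES)
        if bad:
            raise DesignError(
                f"unknown tissue label(s) {sorted(bad)}; allowed: {list(TISSUES)}")
        self.samples.reset_index(drop=True, inplace=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy(dtype=object)

    @property
    def globin_fractions(self) -> np.ndarray:
        return self.samples["globin_fraction"].to_numpy(dtype=float)

    @property
    def tissues(self) -> np.ndarray:
        return self.samples["tissue"].to_numpy(dtype=object)

    @property
    def brain_indicator(self) -> np.ndarray:
        """1.0 for brain-spiked samples, 0.0 for liver-spiked."""
        return (self.samples["tissue"] == "brain").to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, sample_ids: Iterable[str]) -> "SpikeInDesign":
        """Rows for ``sample_ids``, in that order; missing ids raise."""
        wanted = list(sample_ids)
        table = self.samples.set_index("sample_id")
        missing = [s for s in wanted if s not in table.index]
        if missing:
            raise DesignError(f"design is missing sample(s): {missing}")
        return SpikeInDesign(table.loc[wanted].reset_index())


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale intensities."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        sample_ids = np.asarray(self.sample_ids, dtype=object)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        if values.ndim != 2:
            raise ParameterError("values must be a 2-D genes x samples array")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ParameterError(
                f"shape {values.shape} inconsistent with {len(gene_ids)} genes"
                f" and {len(sample_ids)} samples")
        if not np.all(np.isfinite(values)):
            raise ParameterError("expression values must all be finite")
        for name, ids in (("gene", gene_ids), ("sample", sample_ids)):
            if len(set(ids)) != len(ids):
                raise ParameterError(f"duplicate {name} ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float),
                   frame.index.to_numpy(dtype=object),
                   np.asarray(frame.columns, dtype=object))

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        wanted = list(gene_ids)
        missing = [g for g in wanted if g not in index]
        if missing:
            raise ParameterError(f"unknown gene id(s): {missing[:5]}")
        rows = [index[g] for g in wanted]
        return ExpressionMatrix(self.values[rows], np.asarray(wanted, dtype=object),
                                self.sample_ids)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Planted generative parameters for a simulated experiment.

    ``artifact_slope`` holds the per-gene slope ``beta`` (log2 units per unit
    globin mass fraction) *before* protocol attenuation; the realized slope in
    the data is ``alpha * beta`` for the profile's susceptibility ``alpha``.
    ``de_effect`` is the planted brain-minus-liver log2 difference.
    """

    gene_ids: np.ndarray
    baseline: np.ndarray
    artifact_slope: np.ndarray
    de_effect: np.ndarray

    def __post_init__(self) -> None:
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        object.__setattr__(self, "gene_ids", gene_ids)
        for field in ("baseline", "artifact_slope", "de_effect"):
            arr = np.asarray(getattr(self, field), dtype=float)
            object.__setattr__(self, field, arr)
            if arr.shape != (len(gene_ids),):
                raise ParameterError(f"{field} length does not match gene_ids")
            if not np.all(np.isfinite(arr)):
                raise ParameterError(f"{field} contains non-finite values")

    @property
    def artifact_genes(self) -> set:
        return set(self.gene_ids[self.artifact_slope != 0.0])

    @property
    def de_genes(self) -> set:
        return set(self.gene_ids[self.de_effect != 0.0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "baseline": self.baseline,
            "artifact_slope": self.artifact_slope,
            "de_effect": self.de_effect,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroundTruth":
        return cls(frame["gene_id"].to_numpy(dtype=object),
                   frame["baseline"].to_numpy(dtype=float),
                   frame["artifact_slope"].to_numpy(dtype=float),
                   frame["de_effect"].to_numpy(dtype=float))
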