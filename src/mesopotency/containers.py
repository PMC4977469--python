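"""Core in-memory containers shared across the pipeline.

The pipeline compares three hESC culture conditions (an ordered
baseline -> mid -> high design in the generic case); every matrix carries a
:class:`DesignTable` mapping sample columns to conditions and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """An on-disk artifact could not be parsed."""


class DesignError(ValueError):
    """Sample/condition bookkeeping is inconsistent."""


class ConfigurationError(ValueError):
    """A parameter or truth configuration is invalid."""


@dataclass
class DesignTable:
    """Sample sheet: one row per array/well with its condition and replicate.

    Parameters
    ----------
    table
        DataFrame with columns ``sample``, ``condition``, ``replicate``.
        Conditions keep their order of first appearance, which encodes the
        baseline -> mid -> high ordering of the culture platforms.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].iloc[0]
            raise DesignError(f"duplicate sample id in design: {dup!r}")
        reps = self.table["replicate"]
        if (reps.astype(int) < 1).any():
            raise DesignError("replicate numbers must be positive integers")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def conditions(self) -> list[str]:
        """Conditions in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.table["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        if condition not in set(self.table["condition"]):
            raise DesignError(f"unknown condition: {condition!r}")
        mask = self.table["condition"] == condition
        return list(self.table.loc[mask, "sample"])


@dataclass
class ExpressionMatrix:
    """Gene/probe x sample matrix of log2 intensities with its design.

    ``stage`` tags whether the values are raw or quantile-normalized; the
    differential machinery accepts either but the pipeline normalizes first.
    """

    values: pd.DataFrame
    design: DesignTable
    stage: str = "raw"

    def __post_init__(self) -> None:
        design_samples = self.design.samples
        matrix_cols = list(self.values.columns)
        if set(design_samples) - set(matrix_cols):
            missing = sorted(set(design_samples) - set(matrix_cols))
            raise DesignError(f"design samples absent from matrix: {missing}")
        # keep only designed samples, in design order
        self.values = self.values[design_samples]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.design.samples_for(condition)]

    def condition_means(self) -> pd.DataFrame:
        """Per-gene mean per condition, columns ordered as the design."""
        out = {c: self.condition_values(c).mean(axis=1) for c in self.design.conditions}
        return pd.DataFrame(out)


@dataclass
class BetaTable:
    """Methylation beta values (probe x sample) with a probe->gene map.

    Beta is the methylated fraction of a CpG probe and must lie in [0, 1].
    """

    betas: pd.DataFrame
    probe_to_gene: pd.Series
    design: DesignTable

    def __post_init__(self) -> None:
        vals = self.betas.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("beta table contains missing values")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("beta values must lie in [0, 1]")
        design_samples = self.design.samples
        if set(design_samples) - set(self.betas.columns):
            missing = sorted(set(design_samples) - set(self.betas.columns))
            raise DesignError(f"design samples absent from beta table: {missing}")
        self.betas = self.betas[design_samples]
        self.probe_to_gene = self.probe_to_gene.reindex(self.betas.index)

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.betas[self.design.samples_for(condition)]


@dataclass
class CtTable:
    """qPCR threshold-cycle table (gene x well) with the reference gene.

    ``design`` groups wells; a group is typically one culture/time point with
    its technical replicates. The reference (housekeeping) gene anchors the
    delta-Ct quantification.
    """

    values: pd.DataFrame
    reference_gene: str
    design: DesignTable

    def __post_init__(self) -> None:
        if self.reference_gene not in self.values.index:
            raise ValueError(f"reference gene {self.reference_gene!r} not in Ct table")
        design_samples = self.design.samples
        if set(design_samples) - set(self.values.columns):
            missing = sorted(set(design_samples) - set(self.values.columns))
            raise DesignError(f"design samples absent from Ct table: {missing}")
        self.values = self.values[design_samples]
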