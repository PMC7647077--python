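"""Core data containers shared across the pipeline stages.

The central object is :class:`ExpressionDataset`, a genes x samples
log-expression matrix annotated with per-gene regulatory roles, a per-sample
scalar modulator (e.g. an EMT score) and optional tissue-of-origin labels.
Stage 1 consumes it to build a :class:`NetworkTensor` — a third-order array of
per-sample regulatory coefficients in which each sample's slice is one
personalized network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

ROLES = ("regulator", "target", "both")


@dataclass
class ExpressionDataset:
    """Expression matrix plus the metadata the pipeline needs.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes x samples matrix of (log-)expression values. The index holds
        gene identifiers, the columns sample identifiers.
    roles : pandas.Series
        Per-gene role, one of ``{"regulator", "target", "both"}``, indexed
        like ``values``.
    modulator : numpy.ndarray
        Length-n vector of the per-sample scalar modulator, aligned with the
        columns of ``values``.
    tissue : pandas.Series, optional
        Per-sample tissue-of-origin label, indexed by sample identifier.
    """

    values: pd.DataFrame
    roles: pd.Series
    modulator: np.ndarray
    tissue: pd.Series | None = None

    def __post_init__(self):
        self.modulator = np.asarray(self.modulator, dtype=float)
        if self.values.isna().any().any():
            na = self.values.isna()
            gene = na.any(axis=1).idxmax()
            sample = na.loc[gene].idxmax()
            raise InvalidArgumentError(
                f"missing value in expression matrix at gene {gene!r}, sample {sample!r}"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InvalidArgumentError(f"duplicate gene identifier {dup!r}")
        if not self.roles.index.equals(self.values.index):
            self.roles = self.roles.reindex(self.values.index)
            if self.roles.isna().any():
                missing = self.roles.index[self.roles.isna()][0]
                raise InvalidArgumentError(f"gene {missing!r} has no role assignment")
        bad = set(self.roles.unique()) - set(ROLES)
        if bad:
            raise InvalidArgumentError(f"unknown gene roles: {sorted(bad)}")
        if self.modulator.shape != (self.values.shape[1],):
            raise InvalidArgumentError(
                f"modulator length {self.modulator.shape} does not match "
                f"sample count {self.values.shape[1]}"
            )
        if len(self.regulator_ids) == 0 or len(self.target_ids) == 0:
            raise InvalidArgumentError("need at least one regulator and one target gene")
        if self.tissue is not None and not self.tissue.index.equals(self.values.columns):
            self.tissue = self.tissue.reindex(self.values.columns)
            if self.tissue.isna().any():
                missing = self.tissue.index[self.tissue.isna()][0]
                raise InvalidArgumentError(f"sample {missing!r} has no tissue label")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def regulator_ids(self) -> list[str]:
        return [g for g in self.values.index if self.roles[g] in ("regulator", "both")]

    @property
    def target_ids(self) -> list[str]:
        return [g for g in self.values.index if self.roles[g] in ("target", "both")]

    def regulator_matrix(self) -> np.ndarray:
        """Samples x regulators expression array."""
        return self.values.loc[self.regulator_ids].to_numpy().T

    def target_matrix(self) -> np.ndarray:
        """Samples x targets expression array."""
        return self.values.loc[self.target_ids].to_numpy().T


@dataclass
class NetworkTensor:
    """Third-order array of fitted regulatory coefficients.

    ``coefficients[l, j, a]`` is the estimated effect of regulator ``j`` on
    target ``l`` in the personalized network of sample ``a``; each sample
    slice ``coefficients[:, :, a]`` is one network, treated downstream as a
    second-order tensor. Self-edges (a gene regressed on itself) are
    structurally zero.
    """

    coefficients: np.ndarray  # targets x regulators x samples
    intercepts: np.ndarray  # targets x samples
    target_ids: list[str]
    regulator_ids: list[str]
    sample_ids: list[str]
    modulator: np.ndarray = field(default=None)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        i1, i2, n = self.coefficients.shape
        if (len(self.target_ids), len(self.regulator_ids), len(self.sample_ids)) != (i1, i2, n):
            raise InvalidArgumentError(
                "coefficient array dimensions do not match identifier lists"
            )
        if self.intercepts.shape != (i1, n):
            raise InvalidArgumentError("intercept array has wrong shape")
        if self.modulator is not None:
            self.modulator = np.asarray(self.modulator, dtype=float)
            if self.modulator.shape != (n,):
                raise InvalidArgumentError("modulator length does not match sample count")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape

    def slices(self) -> np.ndarray:
        """Samples-first view (n, targets, regulators) of the coefficient array."""
        return np.moveaxis(self.coefficients, -1, 0)

    def sample_index(self, sample_ids) -> np.ndarray:
        """Positions of the given sample identifiers, validating membership."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise InvalidArgumentError(f"unknown sample identifier {exc.args[0]!r}") from None
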