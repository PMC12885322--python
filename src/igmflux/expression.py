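"""Relative gene-expression transformations.

Raw expression T (genes x conditions, non-negative, any platform units) is
mapped per gene row into relative expression values in [0, 1] by one of three
reference schemes:

``max_reference``
    divide by the row maximum; the most expressed condition maps to 1.
``minmax``
    min-max scale; row minimum maps to 0, row maximum to 1.
``mean_reference``
    anchor the row mean at 0.5: values above the mean are min-max scaled
    between the mean and the row maximum into (0.5, 1], values below between
    the row minimum and the mean into [0, 0.5).

Rows too flat to scale (guard range <= omega) fall back to a neutral constant
so downstream constraints stay well-posed. The published form of the
below-mean branch is a reflection that maps the row minimum to 0.5 and is
non-monotone; the default here is the monotone variant (row minimum -> 0),
with ``eq18="as-printed"`` available for the literal published formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RelativeExpression",
    "transform_max_reference",
    "transform_minmax",
    "transform_mean_reference",
    "transform",
    "align_to_model",
    "read_expression",
    "DEFAULT_OMEGA",
    "SCHEMES",
]

logger = logging.getLogger(__name__)

DEFAULT_OMEGA = 0.001
SCHEMES = ("max_reference", "minmax", "mean_reference")


@dataclass
class ExpressionMatrix:
    """Raw gene x condition expression table (non-negative values)."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray  # K x D

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        K, D = len(self.gene_ids), len(self.condition_ids)
        if self.values.shape != (K, D):
            raise ValueError(f"values shape {self.values.shape} != ({K}, {D})")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """Rows = genes (index), columns = conditions. Duplicate genes averaged."""
        if frame.index.has_duplicates:
            n_dup = int(frame.index.duplicated().sum())
            logger.warning("expression table: %d duplicated gene rows averaged", n_dup)
            frame = frame.groupby(level=0, sort=False).mean()
        return cls(
            gene_ids=[str(g) for g in frame.index],
            condition_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)

    @property
    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)


@dataclass
class RelativeExpression:
    """Relative expression in [0, 1] plus provenance (scheme, omega, flags)."""

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray  # K x D, in [0, 1]
    scheme: str
    omega: float = DEFAULT_OMEGA
    unmeasured: np.ndarray | None = None  # bool per gene, set by align_to_model

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("relative expression must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)
        if self.unmeasured is None:
            self.unmeasured = np.zeros(len(self.gene_ids), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)

    def column(self, condition_id: str) -> dict[str, float]:
        """g-tilde values of measured genes for one condition, keyed by gene id."""
        d = self.condition_ids.index(condition_id)
        return {
            g: float(self.values[i, d])
            for i, g in enumerate(self.gene_ids)
            if not self.unmeasured[i]
        }


def _check_nonnegative(T: ExpressionMatrix) -> np.ndarray:
    vals = T.values
    if np.any(vals < 0):
        raise ValueError("expression values must be non-negative")
    return vals


def transform_max_reference(T: ExpressionMatrix, omega: float = DEFAULT_OMEGA) -> RelativeExpression:
    """Divide each row by its maximum; all-zero rows fall back to 0.5."""
    vals = _check_nonnegative(T)
    rmax = vals.max(axis=1)
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        if rmax[i] > 0:
            out[i] = vals[i] / rmax[i]
        else:
            out[i] = 0.5
    return RelativeExpression(T.gene_ids, T.condition_ids, out, "max_reference", omega)


def transform_minmax(T: ExpressionMatrix, omega: float = DEFAULT_OMEGA) -> RelativeExpression:
    """Row-wise min-max scaling; rows with range <= omega fall back to 0.5."""
    vals = _check_nonnegative(T)
    rmin = vals.min(axis=1)
    rmax = vals.max(axis=1)
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        rng = rmax[i] - rmin[i]
        if rng > omega:
            out[i] = (vals[i] - rmin[i]) / rng
        else:
            out[i] = 0.5
    return RelativeExpression(T.gene_ids, T.condition_ids, out, "minmax", omega)


def transform_mean_reference(
    T: ExpressionMatrix,
    omega: float = DEFAULT_OMEGA,
    eq18: str = "monotone",
) -> RelativeExpression:
    """Anchor the row mean at 0.5; scale the halves into (0.5, 1] and [0, 0.5).

    Above-mean values: (T - mean) / (2 (max - mean)) + 1/2. Below-mean values,
    monotone default: (T - min) / (2 (mean - min)); ``eq18="as-printed"``
    instead uses the published reflection (mean - T) / (2 (mean - min)).
    Whichever half's guard (range <= omega) fails falls back to 0.5.
    """
    if eq18 not in ("monotone", "as-printed"):
        raise ValueError(f"eq18 must be 'monotone' or 'as-printed', got {eq18!r}")
    vals = _check_nonnegative(T)
    rmin = vals.min(axis=1)
    rmax = vals.max(axis=1)
    rmean = vals.mean(axis=1)
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        hi_rng = rmax[i] - rmean[i]
        lo_rng = rmean[i] - rmin[i]
        for j in range(vals.shape[1]):
            t = vals[i, j]
            if t >= rmean[i]:
                out[i, j] = (t - rmean[i]) / (2 * hi_rng) + 0.5 if hi_rng > omega else 0.5
            elif lo_rng > omega:
                if eq18 == "monotone":
                    out[i, j] = (t - rmin[i]) / (2 * lo_rng)
                else:
                    out[i, j] = (rmean[i] - t) / (2 * lo_rng)
            else:
                out[i, j] = 0.5
    return RelativeExpression(T.gene_ids, T.condition_ids, out, "mean_reference", omega)


def transform(
    T: ExpressionMatrix,
    scheme: str,
    omega: float = DEFAULT_OMEGA,
    eq18: str = "monotone",
) -> RelativeExpression:
    """Dispatch to one of the three transformation schemes by name."""
    if scheme == "max_reference":
        return transform_max_reference(T, omega)
    if scheme == "minmax":
        return transform_minmax(T, omega)
    if scheme == "mean_reference":
        return transform_mean_reference(T, omega, eq18)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def align_to_model(rel: RelativeExpression, net) -> RelativeExpression:
    """Restrict/reorder rows to the model's gene list.

    Model genes absent from the table are kept as rows flagged ``unmeasured``
    (their g variables are later left unconstrained); table genes absent from
    the model are dropped with a logged count.
    """
    model_genes: list[str] = list(net.gene_ids)
    table_index = {g: i for i, g in enumerate(rel.gene_ids)}
    overlap = [g for g in model_genes if g in table_index]
    if model_genes and not overlap:
        raise ValueError("no overlap between expression table genes and model genes")
    dropped = len(rel.gene_ids) - len(overlap)
    if dropped:
        logger.info("expression table: %d genes absent from the model dropped", dropped)
    K, D = len(model_genes), len(rel.condition_ids)
    values = np.full((K, D), 0.5)
    unmeasured = np.ones(K, dtype=bool)
    for i, g in enumerate(model_genes):
        if g in table_index:
            values[i] = rel.values[table_index[g]]
            unmeasured[i] = False
    return RelativeExpression(
        gene_ids=model_genes,
        condition_ids=list(rel.condition_ids),
        values=values,
        scheme=rel.scheme,
        omega=rel.omega,
        unmeasured=unmeasured,
    )


def read_expression(path: str) -> ExpressionMatrix:
    """Read a TSV/CSV table: first column gene ids, header row condition ids."""
    sep = "," if path.lower().endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix.from_frame(frame)
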