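"""Variance partitioning of DMR-constituent CpG methylation.

Splits the multivariate variation of the CpGs inside a called DMR set between
the rearing environment and individual genetic variation (genotype PCoA
axes).  Axis selection for the response follows the broken-stick rule; the
genetic explanatory axes are chosen to reach a cumulative variance fraction
(90% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ordination
from .ordination import VariancePartition

__all__ = [
    "AxisSelection",
    "broken_stick_axes",
    "axes_for_variance_fraction",
    "partition_dmr_variation",
]


@dataclass
class AxisSelection:
    method: str
    n_axes: int
    detail: np.ndarray  # broken-stick expectations or the cumulative curve


def broken_stick_expectations(p: int) -> np.ndarray:
    """Expected ordered proportions b_k = (1/p) * sum_{i=k..p} 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_axes(relative_eigenvalues: np.ndarray) -> AxisSelection:
    """Retain leading axes whose observed proportion exceeds the broken-stick
    expectation; the first failure truncates, and at least one axis is always
    retained so downstream ordinations stay defined."""
    rel = np.asarray(relative_eigenvalues, dtype=float)
    if rel.size == 0:
        raise ValueError("empty eigenvalue list")
    b = broken_stick_expectations(rel.size)
    k = 0
    for lam, exp in zip(rel, b):
        if lam > exp:
            k += 1
        else:
            break
    return AxisSelection(method="broken_stick", n_axes=max(k, 1), detail=b)


def axes_for_variance_fraction(
    relative_eigenvalues: np.ndarray, target: float = 0.90
) -> AxisSelection:
    """Smallest leading-axis count whose cumulative proportion reaches
    ``target``."""
    if target > 1:
        raise ValueError("target fraction cannot exceed 1")
    rel = np.asarray(relative_eigenvalues, dtype=float)
    if rel.size == 0:
        raise ValueError("empty eigenvalue list")
    cum = np.cumsum(rel)
    reach = np.flatnonzero(cum >= target - 1e-12)
    k = int(reach[0]) + 1 if reach.size else rel.size
    return AxisSelection(method="cumulative_fraction", n_axes=k, detail=cum)


def partition_dmr_variation(
    dmr_cpg_matrix: np.ndarray,
    environment_factor: np.ndarray,
    genetic_axes: np.ndarray,
    response_axes: str = "broken_stick",
) -> tuple[VariancePartition, AxisSelection]:
    """Partition DMR-CpG variation between environment and genetic axes.

    The response is the PCoA of the Euclidean distance between samples over
    the DMR CpGs, reduced to broken-stick axes (default) or kept whole
    (``response_axes='all'``, an unreduced, lossless rotation -- appropriate
    when recovering constructed variance fractions, since axis subsetting
    removes residual variance and inflates the explained fractions).
    """
    y = np.asarray(dmr_cpg_matrix, dtype=float)
    n = y.shape[0]
    genetic_axes = np.atleast_2d(np.asarray(genetic_axes, dtype=float))
    if genetic_axes.shape[0] != n:
        genetic_axes = genetic_axes.T
    if genetic_axes.shape[1] >= n - 2:
        raise ValueError("genetic axis count saturates the model (need <= n - 3)")
    d = ordination.euclidean_distance(y)
    pres = ordination.pcoa(d)
    if response_axes == "broken_stick":
        sel = broken_stick_axes(pres.relative_eigenvalues)
        resp = pres.coordinates[:, : sel.n_axes]
    elif response_axes == "all":
        sel = AxisSelection(method="all", n_axes=pres.n_axes, detail=pres.relative_eigenvalues)
        resp = pres.coordinates
    else:
        raise ValueError("response_axes must be 'broken_stick' or 'all'")
    x1 = np.asarray(environment_factor, dtype=float).reshape(n, -1)
    part = ordination.variance_partition(resp, x1, genetic_axes)
    return part, sel
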