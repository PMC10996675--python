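"""Normalization, detection filtering, and genotype-level log2 fold changes.

Fold changes are computed on log2-scale values with no imputation: a
(feature, genotype) cell is the mean over that genotype's observed replicates
minus the mean over the control's observed replicates, and is missing when
either side has fewer than ``min_reps`` observations.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .io import DifferentialMatrix, OmicsMatrix, SampleMetadata, ValidationError

__all__ = ["median_center", "detection_filter", "log2fc_vs_control"]


def median_center(matrix: OmicsMatrix) -> OmicsMatrix:
    """Subtract each sample column's median over its non-missing values."""
    counts = matrix.data.notna().sum(axis=0)
    empty = counts[counts == 0]
    if len(empty):
        raise ValidationError(
            f"sample {empty.index[0]!r} has no observed values; cannot median-center"
        )
    centered = matrix.data - matrix.data.median(axis=0, skipna=True)
    return OmicsMatrix(matrix.layer, centered)


def detection_filter(matrix: OmicsMatrix, min_fraction: float = 0.5) -> OmicsMatrix:
    """Keep features observed in at least ``min_fraction`` of samples."""
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    frac = matrix.data.notna().mean(axis=1)
    kept = matrix.data.index[frac >= min_fraction]
    return OmicsMatrix(matrix.layer, matrix.data.loc[kept].copy())


def log2fc_vs_control(
    matrix: OmicsMatrix,
    meta: SampleMetadata,
    min_reps: int = 2,
) -> DifferentialMatrix:
    """Per-genotype mean log2 fold change versus the control genotype.

    Cells where either the genotype or the control has fewer than ``min_reps``
    non-missing replicate values are reported missing; replicate counts per
    side are recorded. Features with an entirely missing control row come back
    all-missing with a warning rather than an error.
    """
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    ctrl_samples = meta.samples_of(meta.control)
    if not ctrl_samples:
        raise ValidationError("no control samples in metadata")
    missing = [s for s in meta.sample_ids if s not in set(matrix.sample_ids)]
    if missing:
        raise ValidationError(f"metadata sample {missing[0]!r} absent from matrix")

    ctrl = matrix.data[ctrl_samples]
    ctrl_mean = ctrl.mean(axis=1, skipna=True)
    ctrl_n = ctrl.notna().sum(axis=1)
    dead = ctrl_n == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} feature(s) have no control observations; "
            "their fold changes are all-missing",
            stacklevel=2,
        )

    genos = meta.mutant_genotypes
    fc = pd.DataFrame(index=matrix.data.index, columns=genos, dtype=float)
    n_case = pd.DataFrame(0, index=matrix.data.index, columns=genos, dtype=int)
    n_ctrl = pd.DataFrame(0, index=matrix.data.index, columns=genos, dtype=int)
    for g in genos:
        block = matrix.data[meta.samples_of(g)]
        gmean = block.mean(axis=1, skipna=True)
        gn = block.notna().sum(axis=1)
        cell = gmean - ctrl_mean
        ok = (gn >= min_reps) & (ctrl_n >= min_reps)
        fc[g] = cell.where(ok)
        n_case[g] = gn
        n_ctrl[g] = ctrl_n
    return DifferentialMatrix(fc, n_case, n_ctrl, control=meta.control, min_reps=min_reps)
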