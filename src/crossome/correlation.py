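"""Kendall tau-b lipid x protein cross-correlation and connectivity filtering.

The cross-ome matrix correlates every lipid's abundance profile with every
protein's profile across the sample panel using Kendall's tau-b,

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)),

where C and D count concordant and discordant sample pairs, n0 = n(n-1)/2,
and n1, n2 are the tied-pair counts of the two profiles. Missing values are
handled pairwise-complete: a sample contributes to one (lipid, protein) cell
only when both features observe it.

The whole matrix is computed at once through a pair-sign formulation: for a
feature ``f`` with observation mask ``m`` define, over all sample pairs
(i, j), the sign vector ``S_f = sign(v_i - v_j)`` (zero when either sample is
missing or the values tie) and the validity vector ``V_f`` (one when both
samples are observed). Then for any lipid L and protein P

    C - D        = S_L . S_P
    n0 - n1 (L)  = |S_L| . V_P      (pairs usable for both, untied in L)
    n0 - n2 (P)  = V_L . |S_P|

so the full lipid x protein tau-b matrix reduces to three matrix products.
This is exact, including ties and pairwise-complete missingness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import OmicsMatrix, SampleMetadata, ValidationError, _write_float_tsv

__all__ = [
    "CrossomeMatrix",
    "FilterConfig",
    "kendall_tau_b",
    "build_crossome",
    "filter_connected",
]

PROFILE_MODES = ("replicate_level", "genotype_mean")


@dataclass
class FilterConfig:
    """Connectivity-retention filter parameters.

    A feature is kept when it has at least ``min_partners`` cross-ome cells
    with ``|tau|`` strictly above ``tau_threshold``; ``min_overlap`` is the
    minimum pairwise-complete sample count for a tau cell to exist at all.
    """

    tau_threshold: float = 0.4
    min_partners: int = 2
    min_overlap: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.tau_threshold < 1:
            raise ValidationError("tau_threshold must lie in (0, 1)")
        if self.min_partners < 1:
            raise ValidationError("min_partners must be >= 1")
        if self.min_overlap < 2:
            raise ValidationError("min_overlap must be >= 2")


@dataclass
class CrossomeMatrix:
    """Lipid x protein Kendall tau-b matrix with per-cell usable-sample counts."""

    tau: pd.DataFrame      # lipids x proteins, NaN where overlap insufficient
    n_pairs: pd.DataFrame  # usable sample count per cell
    profile_mode: str = "replicate_level"
    min_overlap: int = 12

    def __post_init__(self) -> None:
        if self.profile_mode not in PROFILE_MODES:
            raise ValidationError(f"profile_mode must be one of {PROFILE_MODES}")
        if not (
            self.n_pairs.index.equals(self.tau.index)
            and self.n_pairs.columns.equals(self.tau.columns)
        ):
            raise ValidationError("tau and n_pairs must align")
        vals = self.tau.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise ValidationError("tau values outside [-1, 1]")

    @property
    def lipid_ids(self) -> list[str]:
        return list(self.tau.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.tau.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau.shape

    def restrict(self, lipids: Iterable[str], proteins: Iterable[str]) -> "CrossomeMatrix":
        lip, prot = list(lipids), list(proteins)
        return CrossomeMatrix(
            self.tau.loc[lip, prot].copy(),
            self.n_pairs.loc[lip, prot].copy(),
            self.profile_mode,
            self.min_overlap,
        )

    def to_dense_tsv(self, path: str | Path) -> None:
        _write_float_tsv(self.tau, path)

    def to_long_tsv(self, path: str | Path) -> None:
        long = self.tau.stack(future_stack=True).rename("tau").reset_index()
        long.columns = ["lipid_id", "protein_id", "tau"]
        long["n_pairs"] = self.n_pairs.stack(future_stack=True).to_numpy()
        long = long.dropna(subset=["tau"])
        long.to_csv(path, sep="\t", index=False, float_format="%.10g")


def kendall_tau_b(x, y, *, min_overlap: int = 2) -> tuple[float, int]:
    """Kendall tau-b of two equal-length vectors, pairwise-complete.

    Returns ``(tau, n_used)``; ``tau`` is NaN when fewer than ``min_overlap``
    jointly observed samples remain or either vector is constant on them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("kendall_tau_b requires two equal-length 1-D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < max(2, min_overlap):
        return float("nan"), n
    xs, ys = x[ok], y[ok]
    dx = np.sign(xs[:, None] - xs[None, :])
    dy = np.sign(ys[:, None] - ys[None, :])
    iu = np.triu_indices(n, k=1)
    sx, sy = dx[iu], dy[iu]
    num = float(np.dot(sx, sy))
    den = float(np.dot(np.abs(sx), np.abs(sx)) * np.dot(np.abs(sy), np.abs(sy)))
    if den == 0.0:
        return float("nan"), n
    return num / np.sqrt(den), n


def _pair_signs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature pair-sign (S), pair-validity (V) and sample masks (M).

    ``values`` is features x samples with NaN for missing. Returns arrays of
    shape (features, n_pairs) for S and V and (features, n_samples) for M.
    """
    n_feat, n_samp = values.shape
    i, j = np.triu_indices(n_samp, k=1)
    mask = np.isfinite(values)
    with np.errstate(invalid="ignore"):
        s = np.sign(values[:, i] - values[:, j])
    valid = mask[:, i] & mask[:, j]
    s = np.where(valid, s, 0.0)
    return s, valid.astype(np.float64), mask.astype(np.float64)


def build_crossome(
    protein: OmicsMatrix,
    lipid: OmicsMatrix,
    meta: SampleMetadata | None = None,
    *,
    mode: str = "replicate_level",
    min_overlap: int = 12,
) -> CrossomeMatrix:
    """Kendall tau-b for every (lipid, protein) pair over the sample panel.

    ``mode="genotype_mean"`` first collapses each feature to per-genotype
    means over observed replicates (control included) and correlates those
    profiles; ``"replicate_level"`` correlates across all samples. Cells with
    fewer than ``min_overlap`` jointly observed profiles are missing.
    """
    if mode not in PROFILE_MODES:
        raise ValidationError(f"mode must be one of {PROFILE_MODES}")
    if protein.sample_ids != lipid.sample_ids:
        raise ValidationError("layers must be sample-aligned (run align_layers first)")
    pdata = protein.data
    ldata = lipid.data
    if mode == "genotype_mean":
        if meta is None:
            raise ValidationError("genotype_mean mode requires sample metadata")
        genos = meta.genotypes
        pdata = pd.DataFrame(
            {g: pdata[meta.samples_of(g)].mean(axis=1, skipna=True) for g in genos}
        )
        ldata = pd.DataFrame(
            {g: ldata[meta.samples_of(g)].mean(axis=1, skipna=True) for g in genos}
        )
    if pdata.shape[1] < min_overlap:
        raise ValidationError(
            f"only {pdata.shape[1]} shared profiles; min_overlap={min_overlap}"
        )

    s_l, v_l, m_l = _pair_signs(ldata.to_numpy(dtype=float))
    s_p, v_p, m_p = _pair_signs(pdata.to_numpy(dtype=float))

    num = s_l @ s_p.T                                  # C - D
    untied_l = np.abs(s_l) @ v_p.T                     # (n0 - n1) per cell
    untied_p = v_l @ np.abs(s_p).T                     # (n0 - n2) per cell
    n_used = (m_l @ m_p.T).astype(int)                 # jointly observed samples

    den = untied_l * untied_p
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(den > 0, num / np.sqrt(np.where(den > 0, den, 1.0)), np.nan)
    tau = np.where(n_used >= min_overlap, tau, np.nan)

    tau_df = pd.DataFrame(tau, index=ldata.index, columns=pdata.index)
    n_df = pd.DataFrame(n_used, index=ldata.index, columns=pdata.index)
    tau_df.index.name = n_df.index.name = "lipid_id"
    tau_df.columns.name = n_df.columns.name = "protein_id"
    return CrossomeMatrix(tau_df, n_df, profile_mode=mode, min_overlap=min_overlap)


def filter_connected(cm: CrossomeMatrix, cfg: FilterConfig | None = None) -> CrossomeMatrix:
    """Retain features with enough strong cross-ome partners.

    A lipid (protein) is kept iff it has at least ``cfg.min_partners`` cells
    with ``|tau|`` strictly greater than ``cfg.tau_threshold``, counted in a
    single pass against the full pre-filter matrix (no iterative re-pruning).
    Missing cells never count as partners. The result is the input restricted
    to retained rows and columns; an empty result is valid and warned about.
    """
    cfg = cfg or FilterConfig()
    strong = cm.tau.abs() > cfg.tau_threshold  # NaN -> False
    lip_keep = cm.tau.index[strong.sum(axis=1) >= cfg.min_partners]
    prot_keep = cm.tau.columns[strong.sum(axis=0) >= cfg.min_partners]
    if len(lip_keep) == 0 or len(prot_keep) == 0:
        warnings.warn("connectivity filter retained no features", stacklevel=2)
    return cm.restrict(lip_keep, prot_keep)
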