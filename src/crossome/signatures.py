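"""Genotype signatures, bipartite network extraction, partner frequencies,
and robust outlier detection.

A *signature* aggregates the per-genotype log2 fold changes of a feature set
(a correlation cluster or a curated module) into one value per genotype —
summed for correlation-derived clusters, averaged for curated sets. Networks
are bipartite lipid-protein graphs carved out of the cross-ome matrix around
seed features. Outliers are genotypes whose fold change for a feature sits
far from the panel consensus in robust z units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from typing import Iterable, Mapping

from .correlation import CrossomeMatrix
from .io import AnnotationSets, DifferentialMatrix, ValidationError

__all__ = [
    "SignatureProfile",
    "set_signature",
    "module_signatures",
    "signature_table",
    "extract_network",
    "top_partner_frequency",
    "outlier_analysis",
]

#: consistency factor making the MAD estimate the SD under normality
MAD_SCALE = 1.4826
_EPS = 1e-9


@dataclass
class SignatureProfile:
    """Aggregated log2FC of one feature set across genotypes."""

    set_id: str
    values: pd.Series          # genotype -> aggregated log2fc (NaN if no member)
    n_members_used: pd.Series  # genotype -> members contributing
    mode: str = "sum"

    def __post_init__(self) -> None:
        if self.mode not in ("sum", "mean"):
            raise ValidationError("signature mode must be 'sum' or 'mean'")
        if not self.values.index.equals(self.n_members_used.index):
            raise ValidationError("values and n_members_used must align")
        bad = self.values.isna() & (self.n_members_used > 0)
        if bad.any():
            raise ValidationError("missing signature with contributing members")

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": self.set_id,
                "genotype": self.values.index,
                "value": self.values.to_numpy(),
                "n_used": self.n_members_used.to_numpy(),
                "mode": self.mode,
            }
        )


def set_signature(
    diff: DifferentialMatrix,
    members: Iterable[str],
    mode: str = "sum",
    set_id: str = "set",
) -> SignatureProfile:
    """Sum or mean of member log2 fold changes, per genotype."""
    member_ids = [m for m in members]
    if not member_ids:
        raise ValidationError("empty member set")
    block = diff.log2fc.reindex(member_ids)
    n_used = block.notna().sum(axis=0)
    if mode == "sum":
        vals = block.sum(axis=0, skipna=True).where(n_used > 0)
    elif mode == "mean":
        vals = block.mean(axis=0, skipna=True)
    else:
        raise ValidationError("signature mode must be 'sum' or 'mean'")
    return SignatureProfile(set_id, vals, n_used, mode)


def module_signatures(
    diff: DifferentialMatrix,
    curated: AnnotationSets,
    mode: str = "mean",
) -> dict[str, SignatureProfile]:
    """One :class:`SignatureProfile` per curated annotation set."""
    return {
        term: set_signature(diff, curated.members[term], mode=mode, set_id=term)
        for term in curated.term_ids
    }


def signature_table(profiles: Mapping[str, SignatureProfile]) -> pd.DataFrame:
    """Genotypes x sets matrix of signature values (input to genotype grouping)."""
    return pd.DataFrame({sid: p.values for sid, p in profiles.items()})


def extract_network(
    cm: CrossomeMatrix,
    seed_features: Iterable[str],
    tau_threshold: float = 0.4,
    *,
    node_attributes: Mapping[str, Mapping[str, object]] | None = None,
) -> nx.Graph:
    """Bipartite lipid-protein network around seed features.

    Edges are all (lipid, protein) cells touching a seed on either layer with
    ``|tau|`` strictly above ``tau_threshold``; nodes appear only when they
    carry at least one edge. Node attributes (cluster ids, annotation flags)
    may be supplied as ``{feature_id: {attr: value}}``.
    """
    seeds = set(seed_features)
    known = set(cm.lipid_ids) | set(cm.protein_ids)
    unknown = seeds - known
    if unknown:
        raise ValidationError(f"seed feature {sorted(unknown)[0]!r} not in matrix")
    g = nx.Graph()
    tau = cm.tau
    seed_lipids = [f for f in cm.lipid_ids if f in seeds]
    seed_prots = [f for f in cm.protein_ids if f in seeds]
    edges: dict[tuple[str, str], float] = {}
    for lip in seed_lipids:
        row = tau.loc[lip]
        hits = row[row.abs() > tau_threshold]
        for prot, t in hits.items():
            edges[(lip, prot)] = float(t)
    for prot in seed_prots:
        col = tau[prot]
        hits = col[col.abs() > tau_threshold]
        for lip, t in hits.items():
            edges[(lip, prot)] = float(t)
    for (lip, prot), t in sorted(edges.items()):
        g.add_node(lip, layer="lipid")
        g.add_node(prot, layer="protein")
        g.add_edge(lip, prot, tau=t)
    if node_attributes:
        for node, attrs in node_attributes.items():
            if node in g:
                g.nodes[node].update(attrs)
    return g


def top_partner_frequency(
    cm: CrossomeMatrix,
    lipid_subset: Iterable[str],
    n_top: int = 10,
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """How often each protein appears among the top-N partners of the lipids.

    For each lipid in the subset the ``n_top`` proteins with highest tau are
    taken (ties broken by descending tau then lexicographic protein id);
    appearance counts are aggregated across lipids and optionally labelled
    with a caller-supplied category map. Lipids with fewer than ``n_top``
    non-missing partners contribute all they have, with a warning.
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    lipids = list(lipid_subset)
    missing = [l for l in lipids if l not in set(cm.lipid_ids)]
    if missing:
        raise ValidationError(f"lipid {missing[0]!r} not in matrix")
    counts: dict[str, int] = {}
    short = 0
    for lip in lipids:
        row = cm.tau.loc[lip].dropna()
        if len(row) < n_top:
            short += 1
        order = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
        for prot, _ in order[:n_top]:
            counts[prot] = counts.get(prot, 0) + 1
    if short:
        warnings.warn(
            f"{short} lipid(s) had fewer than {n_top} non-missing partners",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {"protein_id": list(counts), "frequency": list(counts.values())}
    ).sort_values(["frequency", "protein_id"], ascending=[False, True], ignore_index=True)
    if categories is not None:
        table["category"] = [categories.get(p, "other") for p in table["protein_id"]]
    return table


def outlier_analysis(
    diff: DifferentialMatrix,
    feature_ids: Iterable[str] | None = None,
    *,
    z_cutoff: float = 2.5,
    min_genotypes: int = 10,
) -> pd.DataFrame:
    """Robust per-genotype outlier calls over a set of features.

    For each feature, genotypes are scored with a robust z across the panel:
    ``z = (log2fc - median) / (1.4826 * MAD + eps)``, falling back to the
    sample SD when the MAD is zero; ``|z| >= z_cutoff`` flags the genotype.
    Features with fewer than ``min_genotypes`` non-missing fold changes are
    skipped with a warning. For every flagged genotype the other genotypes
    are ranked by Pearson similarity of their log2FC vectors over the tested
    feature set.

    Returns a tidy frame (feature_id, genotype, robust_z, flagged,
    most_similar, similarity) containing one row per tested cell.
    """
    ids = list(feature_ids) if feature_ids is not None else diff.feature_ids
    unknown = set(ids) - set(diff.feature_ids)
    if unknown:
        raise ValidationError(f"feature {sorted(unknown)[0]!r} not in differential matrix")
    if min_genotypes < 2:
        raise ValidationError("min_genotypes must be >= 2")
    fc = diff.log2fc.loc[ids]

    # genotype similarity over the tested feature block (pairwise-complete)
    sim = fc.corr(method="pearson", min_periods=3)

    rows = []
    skipped = 0
    for fid in ids:
        vals = fc.loc[fid].dropna()
        if len(vals) < min_genotypes:
            skipped += 1
            continue
        med = float(vals.median())
        mad = float((vals - med).abs().median())
        scale = MAD_SCALE * mad
        if scale == 0.0:
            scale = float(vals.std(ddof=1))
        z = (vals - med) / (scale + _EPS) if scale > 0 else vals * 0.0
        for geno, zval in z.items():
            flagged = bool(abs(zval) >= z_cutoff)
            most_similar, similarity = "", float("nan")
            if flagged and geno in sim.columns:
                others = sim[geno].drop(index=geno, errors="ignore").dropna()
                if len(others):
                    best = others.sort_values(ascending=False).index[0]
                    most_similar, similarity = str(best), float(others[best])
            rows.append(
                {
                    "feature_id": fid,
                    "genotype": geno,
                    "robust_z": float(zval),
                    "flagged": flagged,
                    "most_similar": most_similar,
                    "similarity": similarity,
                }
            )
    if skipped:
        warnings.warn(
            f"{skipped} feature(s) skipped: fewer than {min_genotypes} genotypes observed",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "genotype", "robust_z", "flagged", "most_similar", "similarity"],
    )
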