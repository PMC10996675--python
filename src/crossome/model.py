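"""Model/Results interface over the cross-ome fingerprinting pipeline.

:class:`CrossOmeModel` is built from a matched protein/lipid abundance panel
plus sample metadata; :meth:`CrossOmeModel.fit` runs the estimation chain —
normalisation, detection filtering, Kendall tau-b cross-correlation,
connectivity filtering, dual clustering, enrichment, and per-genotype fold
changes — and returns a :class:`CrossOmeResults` carrying every artefact,
with downstream queries (signatures, networks, partner frequencies, outlier
calls) as methods.

Example
-------
>>> from crossome import CrossOmeModel, simulate_panel
>>> panel = simulate_panel()
>>> model = CrossOmeModel(panel.protein, panel.lipid, panel.metadata,
...                       k_protein=5, k_lipid=5)
>>> res = model.fit(seed=0)
>>> print(res.summary())              # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from . import preprocess
from .cluster import ClusterModel, cluster_axis, genotype_groups
from .correlation import CrossomeMatrix, FilterConfig, build_crossome, filter_connected
from .enrichment import fisher_enrich
from .io import (
    AnnotationSets,
    DifferentialMatrix,
    OmicsMatrix,
    SampleMetadata,
    align_layers,
)
from .lipids import lipid_class_sets
from .signatures import (
    SignatureProfile,
    extract_network,
    module_signatures,
    outlier_analysis,
    set_signature,
    signature_table,
    top_partner_frequency,
)

__all__ = ["CrossOmeModel", "CrossOmeResults"]


class CrossOmeModel:
    """Lipid-protein cross-correlation fingerprinting model for one panel.

    Parameters
    ----------
    protein, lipid : OmicsMatrix
        The two omic layers, log2 scale; samples are aligned on construction.
    metadata : SampleMetadata
        Sample -> genotype/replicate map with a designated control.
    protein_annotations : AnnotationSets, optional
        Terms for protein-cluster enrichment (e.g. GO Cellular Component).
    lipid_annotations : AnnotationSets, optional
        Terms for lipid-cluster enrichment; derived from lipid-name classes
        when omitted.
    k_protein, k_lipid : int
        Cluster counts per axis. The defaults (18 protein, 13 lipid) suit a
        landscape-scale knockout panel; a 14-cluster lipid cut is a common
        alternative and is one argument away.
    filter_config : FilterConfig
        Connectivity retention filter (default: >=2 partners at |tau| > 0.4).
    profile_mode : {"replicate_level", "genotype_mean"}
        Correlate across all samples (default) or per-genotype means.
    median_center, detection_min_fraction, min_reps
        Preprocessing switches; see the corresponding functions.
    """

    def __init__(
        self,
        protein: OmicsMatrix,
        lipid: OmicsMatrix,
        metadata: SampleMetadata,
        *,
        protein_annotations: AnnotationSets | None = None,
        lipid_annotations: AnnotationSets | None = None,
        k_protein: int = 18,
        k_lipid: int = 13,
        filter_config: FilterConfig | None = None,
        profile_mode: str = "replicate_level",
        median_center: bool = False,
        detection_min_fraction: float = 0.5,
        min_reps: int = 2,
    ) -> None:
        bundle = align_layers(protein, lipid, metadata)
        self.protein = bundle.protein
        self.lipid = bundle.lipid
        self.metadata = bundle.metadata
        self.dropped_samples = bundle.dropped_samples
        self.protein_annotations = protein_annotations
        self.lipid_annotations = lipid_annotations
        self.k_protein = k_protein
        self.k_lipid = k_lipid
        self.filter_config = filter_config or FilterConfig()
        self.profile_mode = profile_mode
        self.median_center = median_center
        self.detection_min_fraction = detection_min_fraction
        self.min_reps = min_reps

    @classmethod
    def from_files(
        cls,
        protein_path,
        lipid_path,
        metadata_path,
        *,
        control: str = "Control",
        protein_annotations_path=None,
        lipid_annotations_path=None,
        **kwargs,
    ) -> "CrossOmeModel":
        """Build a model straight from TSV/GMT files."""
        from .io import read_annotations, read_matrix, read_metadata

        prot = read_matrix(protein_path, "protein")
        lip = read_matrix(lipid_path, "lipid")
        meta = read_metadata(metadata_path, control=control)
        pann = (
            read_annotations(protein_annotations_path, "protein")
            if protein_annotations_path
            else None
        )
        lann = (
            read_annotations(lipid_annotations_path, "lipid")
            if lipid_annotations_path
            else None
        )
        return cls(
            prot, lip, meta,
            protein_annotations=pann, lipid_annotations=lann, **kwargs,
        )

    def fit(self, seed: int = 0, *, restarts: int = 50) -> "CrossOmeResults":
        """Run the full estimation chain and return a results object."""
        prot, lip = self.protein, self.lipid
        if self.median_center:
            prot = preprocess.median_center(prot)
            lip = preprocess.median_center(lip)
        prot = preprocess.detection_filter(prot, self.detection_min_fraction)
        lip = preprocess.detection_filter(lip, self.detection_min_fraction)

        crossome = build_crossome(
            prot, lip, self.metadata,
            mode=self.profile_mode,
            min_overlap=self.filter_config.min_overlap,
        )
        filtered = filter_connected(crossome, self.filter_config)

        protein_clusters = lipid_clusters = None
        if filtered.shape[1] >= self.k_protein and filtered.shape[0] >= 1:
            protein_clusters = cluster_axis(
                filtered, "protein", self.k_protein, seed=seed, restarts=restarts
            )
        if filtered.shape[0] >= self.k_lipid and filtered.shape[1] >= 1:
            lipid_clusters = cluster_axis(
                filtered, "lipid", self.k_lipid, seed=seed + 1, restarts=restarts
            )

        log2fc_prot = preprocess.log2fc_vs_control(prot, self.metadata, self.min_reps)
        log2fc_lip = preprocess.log2fc_vs_control(lip, self.metadata, self.min_reps)

        lipid_ann = self.lipid_annotations
        if lipid_ann is None:
            lipid_ann = lipid_class_sets(filtered.lipid_ids or crossome.lipid_ids)

        enr_prot = enr_lip = None
        if protein_clusters is not None and self.protein_annotations is not None:
            enr_prot = fisher_enrich(
                protein_clusters, self.protein_annotations, filtered.protein_ids
            )
        if lipid_clusters is not None and lipid_ann is not None and len(lipid_ann):
            enr_lip = fisher_enrich(lipid_clusters, lipid_ann, filtered.lipid_ids)

        return CrossOmeResults(
            model=self,
            seed=seed,
            crossome=crossome,
            filtered=filtered,
            protein_clusters=protein_clusters,
            lipid_clusters=lipid_clusters,
            log2fc_protein=log2fc_prot,
            log2fc_lipid=log2fc_lip,
            enrichment_protein=enr_prot,
            enrichment_lipid=enr_lip,
        )


@dataclass
class CrossOmeResults:
    """Everything the fitted cross-ome model estimated."""

    model: CrossOmeModel
    seed: int
    crossome: CrossomeMatrix
    filtered: CrossomeMatrix
    protein_clusters: ClusterModel | None
    lipid_clusters: ClusterModel | None
    log2fc_protein: DifferentialMatrix
    log2fc_lipid: DifferentialMatrix
    enrichment_protein: pd.DataFrame | None = None
    enrichment_lipid: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    # -- derived queries ----------------------------------------------------

    def _diff(self, layer: str) -> DifferentialMatrix:
        return self.log2fc_protein if layer == "protein" else self.log2fc_lipid

    def _clusters(self, layer: str) -> ClusterModel:
        cm = self.protein_clusters if layer == "protein" else self.lipid_clusters
        if cm is None:
            raise ValueError(f"no {layer} clustering available on this fit")
        return cm

    def cluster_signature(
        self, cluster_id: int, layer: str = "protein", mode: str = "sum"
    ) -> SignatureProfile:
        """Aggregated log2FC of one correlation cluster across genotypes."""
        members = self._clusters(layer).members(cluster_id)
        return set_signature(
            self._diff(layer), members, mode=mode,
            set_id=f"{layer}_cluster_{cluster_id}",
        )

    def module_signatures(
        self, curated: AnnotationSets, mode: str = "mean"
    ) -> dict[str, SignatureProfile]:
        """Signatures for curated sets (organelle lists, complex modules)."""
        return module_signatures(self._diff(curated.layer), curated, mode=mode)

    def genotype_groups(
        self, curated: AnnotationSets, k: int, *, mode: str = "mean", seed: int = 0
    ) -> ClusterModel:
        """k-means grouping of genotypes by curated-set signature profiles."""
        table = signature_table(self.module_signatures(curated, mode=mode))
        return genotype_groups(table, k, seed=seed)

    def extract_network(
        self,
        seed_features: Iterable[str],
        tau_threshold: float | None = None,
        node_attributes: Mapping[str, Mapping[str, object]] | None = None,
    ):
        """Bipartite lipid-protein network around seed features."""
        thr = (
            tau_threshold
            if tau_threshold is not None
            else self.model.filter_config.tau_threshold
        )
        return extract_network(
            self.filtered, seed_features, thr, node_attributes=node_attributes
        )

    def top_partner_frequency(
        self,
        lipid_subset: Iterable[str] | None = None,
        n_top: int = 10,
        categories: Mapping[str, str] | None = None,
    ) -> pd.DataFrame:
        """Top-N protein partner frequencies over a lipid subset."""
        subset = list(lipid_subset) if lipid_subset is not None else self.filtered.lipid_ids
        return top_partner_frequency(self.filtered, subset, n_top, categories)

    def outliers(
        self,
        layer: str = "protein",
        feature_ids: Iterable[str] | None = None,
        *,
        z_cutoff: float = 2.5,
        min_genotypes: int = 10,
    ) -> pd.DataFrame:
        """Robust z outlier calls per (feature, genotype)."""
        return outlier_analysis(
            self._diff(layer), feature_ids,
            z_cutoff=z_cutoff, min_genotypes=min_genotypes,
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable account of the fit."""
        m = self.model
        lines = [
            "Cross-ome correlation fingerprinting",
            "=" * 52,
            f"samples:              {m.metadata.table.shape[0]}"
            f" ({len(m.metadata.mutant_genotypes)} mutants + control)",
            f"profile mode:         {m.profile_mode}",
            f"lipids correlated:    {self.crossome.shape[0]}",
            f"proteins correlated:  {self.crossome.shape[1]}",
            f"filter:               >= {m.filter_config.min_partners} partners at "
            f"|tau| > {m.filter_config.tau_threshold}",
            f"lipids retained:      {self.filtered.shape[0]}",
            f"proteins retained:    {self.filtered.shape[1]}",
        ]
        if self.protein_clusters is not None:
            lines.append(
                f"protein clusters:     k={self.protein_clusters.k}, "
                f"inertia={self.protein_clusters.inertia:.3f}"
            )
        if self.lipid_clusters is not None:
            lines.append(
                f"lipid clusters:       k={self.lipid_clusters.k}, "
                f"inertia={self.lipid_clusters.inertia:.3f}"
            )
        for layer, enr in (
            ("protein", self.enrichment_protein),
            ("lipid", self.enrichment_lipid),
        ):
            if enr is not None and len(enr):
                sig = enr[enr["q_value"] < 0.05]
                lines.append(
                    f"{layer} enrichments:  {len(sig)} (cluster, term) pairs at q < 0.05"
                )
                top = sig.sort_values("q_value").head(3)
                for _, row in top.iterrows():
                    lines.append(
                        f"  cluster {row['cluster']:>2} ~ {row['term_id']}"
                        f"  (a={row['a']}, q={row['q_value']:.2e})"
                    )
        return "\n".join(lines)
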