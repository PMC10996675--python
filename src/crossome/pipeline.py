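"""File-level pipeline orchestration with provenance.

:func:`run_pipeline` reads the input files named in a :class:`RunConfig`,
fits a :class:`~crossome.model.CrossOmeModel`, and writes every stage
artefact as TSV plus a ``provenance.json`` echoing all parameters. Reruns
with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


import pandas as pd
import yaml

from .correlation import FilterConfig
from .io import ValidationError
from .model import CrossOmeModel

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("crossome")


@dataclass
class RunConfig:
    """All inputs and stage parameters for one pipeline run."""

    protein_path: str
    lipid_path: str
    metadata_path: str
    output_dir: str
    protein_annotations_path: str | None = None
    lipid_annotations_path: str | None = None
    control: str = "Control"
    # stage parameters
    tau_threshold: float = 0.4
    min_partners: int = 2
    min_overlap: int = 12
    # 18/13 per-axis defaults suit a landscape-scale panel; a 14-cluster
    # lipid cut is the common alternative, one flag away
    k_protein: int = 18
    k_lipid: int = 13
    profile_mode: str = "replicate_level"
    median_center: bool = False
    detection_min_fraction: float = 0.5
    min_reps: int = 2
    restarts: int = 50
    seed: int = 0
    # optional downstream stages
    outlier_z_cutoff: float = 2.5
    outlier_min_genotypes: int = 10
    top_n_partners: int = 10
    run_outliers: bool = True
    run_top_partners: bool = True

    def validate(self) -> None:
        for name in ("protein_path", "lipid_path", "metadata_path"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise ValidationError(f"{name}: no such file: {p}")
        for name in ("protein_annotations_path", "lipid_annotations_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise ValidationError(f"{name}: no such file: {p}")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        FilterConfig(self.tau_threshold, self.min_partners, self.min_overlap)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML key/value config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    missing = {"protein_path", "lipid_path", "metadata_path", "output_dir"} - set(raw)
    if missing:
        raise ValidationError(f"config missing required key(s): {sorted(missing)}")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write artefacts under ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "read"
    try:
        model = CrossOmeModel.from_files(
            config.protein_path,
            config.lipid_path,
            config.metadata_path,
            control=config.control,
            protein_annotations_path=config.protein_annotations_path,
            lipid_annotations_path=config.lipid_annotations_path,
            k_protein=config.k_protein,
            k_lipid=config.k_lipid,
            filter_config=FilterConfig(
                config.tau_threshold, config.min_partners, config.min_overlap
            ),
            profile_mode=config.profile_mode,
            median_center=config.median_center,
            detection_min_fraction=config.detection_min_fraction,
            min_reps=config.min_reps,
        )

        stage = "fit"
        log.info("fitting cross-ome model (seed=%d)", config.seed)
        res = model.fit(seed=config.seed, restarts=config.restarts)

        stage = "write"
        res.crossome.to_long_tsv(out / "crossome_long.tsv")
        res.filtered.to_dense_tsv(out / "crossome_filtered.tsv")
        res.log2fc_protein.to_tsv(out / "log2fc_protein.tsv")
        res.log2fc_lipid.to_tsv(out / "log2fc_lipid.tsv")

        frames = []
        for layer, clu in (("protein", res.protein_clusters), ("lipid", res.lipid_clusters)):
            if clu is not None:
                frames.append(clu.to_frame())
                pd.Series(
                    clu.dendrogram_order, name="feature_id"
                ).to_csv(out / f"dendrogram_order_{layer}.tsv", sep="\t", index=False)
        if frames:
            pd.concat(frames).to_csv(out / "cluster_assignments.tsv", sep="\t")

        for layer, enr in (
            ("protein", res.enrichment_protein),
            ("lipid", res.enrichment_lipid),
        ):
            if enr is not None:
                enr.to_csv(
                    out / f"enrichment_{layer}.tsv",
                    sep="\t", index=False, float_format="%.10g",
                )

        stage = "signatures"
        sig_frames = []
        for layer, clu in (("protein", res.protein_clusters), ("lipid", res.lipid_clusters)):
            if clu is None:
                continue
            for cid in range(1, clu.k + 1):
                sig_frames.append(res.cluster_signature(cid, layer, mode="sum").to_frame())
        if sig_frames:
            pd.concat(sig_frames, ignore_index=True).to_csv(
                out / "cluster_signatures.tsv", sep="\t", index=False,
                float_format="%.10g",
            )

        if config.run_top_partners and res.filtered.shape[0]:
            stage = "top_partners"
            res.top_partner_frequency(n_top=config.top_n_partners).to_csv(
                out / "top_partner_frequency.tsv", sep="\t", index=False
            )

        if config.run_outliers:
            stage = "outliers"
            rep = res.outliers(
                "protein",
                z_cutoff=config.outlier_z_cutoff,
                min_genotypes=config.outlier_min_genotypes,
            )
            rep.to_csv(
                out / "outliers_protein.tsv", sep="\t", index=False,
                float_format="%.10g",
            )

        stage = "provenance"
        prov = {"config": config.to_dict(), "dropped_samples": list(model.dropped_samples)}
        for layer, clu in (("protein", res.protein_clusters), ("lipid", res.lipid_clusters)):
            if clu is not None:
                prov[f"{layer}_clustering"] = {
                    "k": clu.k, "seed": clu.seed, "inertia": clu.inertia, **clu.params,
                }
        (out / "provenance.json").write_text(
            json.dumps(prov, indent=1, sort_keys=True), encoding="utf-8"
        )
        (out / "summary.txt").write_text(res.summary() + "\n", encoding="utf-8")
    except Exception as exc:
        failed_marker.write_text(f"stage {stage!r} failed: {exc}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
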