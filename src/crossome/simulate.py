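"""Synthetic matched protein/lipid genotype panels with planted cross-ome
modules, replicate noise, and missingness.

The generator emulates a knockout screen profiled in quadruplicate: a control
genotype plus ``n_genotypes`` mutants, each feature drawn from a log2-scale
baseline, with disjoint protein and lipid modules co-perturbed (a shared log2
shift) in a module-specific subset of mutants. Cross-ome correlation between
a module's proteins and lipids then arises purely from the shared
affected-genotype pattern, which is exactly the mechanism the analysis is
meant to detect. Dropout combines a uniform random component with an
intensity-dependent (MNAR) component confined to the low-abundance tail.

Ground truth (module memberships, affected genotypes, dropout masks) is
returned alongside the matrices so recovery can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import ClusterModel
from .correlation import CrossomeMatrix
from .io import AnnotationSets, OmicsMatrix, SampleMetadata, ValidationError

__all__ = ["SimConfig", "GroundTruth", "SimulatedPanel", "simulate_panel", "evaluate_recovery"]

#: lipid classes cycled through when naming synthetic lipid features
_LIPID_CLASSES = ("PC", "LPC", "CE", "DG", "TG", "SM", "PE", "PI")


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic panel."""

    n_genotypes: int = 12          # mutants; a control is always added
    n_replicates: int = 4
    n_proteins: int = 600
    n_lipids: int = 300
    n_modules: int = 5
    proteins_per_module: int = 30
    lipids_per_module: int = 15
    effect_size: float = 1.5       # log2 shift in affected genotypes
    affected_genotypes: int = 3    # per module, drawn without replacement
    noise_sd: float = 0.4          # replicate-level Gaussian sd (log2)
    baseline_mean: float = 20.0    # per-feature log2 abundance
    baseline_sd: float = 3.0
    missing_random: float = 0.05
    mnar_strength: float = 1.0     # logistic slope below the 10th percentile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.proteins_per_module > self.n_proteins:
            raise ValidationError("protein modules exceed the protein layer size")
        if self.n_modules * self.lipids_per_module > self.n_lipids:
            raise ValidationError("lipid modules exceed the lipid layer size")
        if self.affected_genotypes > self.n_genotypes:
            raise ValidationError("affected_genotypes exceeds the mutant count")
        if math.comb(self.n_genotypes, self.affected_genotypes) < self.n_modules:
            raise ValidationError(
                "not enough distinct affected-genotype patterns for the modules"
            )
        for rate in (self.missing_random,):
            if not 0 <= rate <= 1:
                raise ValidationError("missing rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of one simulated panel."""

    modules: dict[str, dict] = field(default_factory=dict)
    protein_dropout: pd.DataFrame | None = None
    lipid_dropout: pd.DataFrame | None = None

    def module_labels(self, layer: str) -> pd.Series:
        """Planted module label per module member feature of one layer."""
        key = "protein_members" if layer == "protein" else "lipid_members"
        labels = {}
        for mid, mod in self.modules.items():
            for f in mod[key]:
                labels[f] = mid
        return pd.Series(labels, name="module")

    def to_json(self, path: str | Path) -> None:
        payload = {
            mid: {
                "protein_members": list(m["protein_members"]),
                "lipid_members": list(m["lipid_members"]),
                "affected_genotypes": list(m["affected_genotypes"]),
                "effect_size": m["effect_size"],
            }
            for mid, m in self.modules.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(modules={mid: dict(m) for mid, m in payload.items()})


class SimulatedPanel(NamedTuple):
    protein: OmicsMatrix
    lipid: OmicsMatrix
    metadata: SampleMetadata
    annotations: dict[str, AnnotationSets]  # keyed by layer
    truth: GroundTruth


def _lipid_names(n: int) -> list[str]:
    """Unique, parseable shorthand names for n synthetic lipids."""
    names = []
    i = 0
    while len(names) < n:
        cls = _LIPID_CLASSES[i % len(_LIPID_CLASSES)]
        carbons = 14 + (i // len(_LIPID_CLASSES)) % 30
        dbs = (i // (len(_LIPID_CLASSES) * 30)) % 7
        name = f"{cls} {carbons}:{dbs}"
        if name not in names:
            names.append(name)
        i += 1
    return names


def simulate_panel(cfg: SimConfig | None = None) -> SimulatedPanel:
    """Generate one matched protein/lipid panel from a :class:`SimConfig`.

    value(f, s) = baseline(f) + effect * [f in module m and genotype(s)
    affected by m] + N(0, noise_sd^2), followed by random and MNAR dropout.
    Fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    genotypes = [f"KO{i + 1:02d}" for i in range(cfg.n_genotypes)]
    control = "Control"
    sample_rows = []
    for g in [control] + genotypes:
        for r in range(1, cfg.n_replicates + 1):
            sample_rows.append({"sample_id": f"{g}_r{r}", "genotype": g, "replicate": r})
    meta = SampleMetadata(
        pd.DataFrame(sample_rows).set_index("sample_id"), control=control
    )
    samples = meta.canonical_order()
    meta = meta.subset(samples)

    prot_ids = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    lip_ids = _lipid_names(cfg.n_lipids)

    # disjoint planted modules per layer, affected mutants drawn per module
    prot_pool = list(rng.permutation(prot_ids))
    lip_pool = list(rng.permutation(lip_ids))
    modules: dict[str, dict] = {}
    used_patterns: set[tuple[str, ...]] = set()
    for m in range(cfg.n_modules):
        pm = prot_pool[m * cfg.proteins_per_module : (m + 1) * cfg.proteins_per_module]
        lm = lip_pool[m * cfg.lipids_per_module : (m + 1) * cfg.lipids_per_module]
        # modules must be identifiable: two modules with the same affected
        # genotypes would be one indistinguishable perturbation pattern
        while True:
            affected = tuple(
                sorted(str(g) for g in rng.choice(genotypes, size=cfg.affected_genotypes, replace=False))
            )
            if affected not in used_patterns:
                used_patterns.add(affected)
                break
        modules[f"module{m + 1}"] = {
            "protein_members": tuple(pm),
            "lipid_members": tuple(lm),
            "affected_genotypes": tuple(affected),
            "effect_size": cfg.effect_size,
        }

    def _layer(feature_ids: list[str], member_key: str) -> pd.DataFrame:
        n_feat = len(feature_ids)
        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_feat)
        values = np.tile(baseline[:, None], (1, len(samples)))
        geno_of = meta.table["genotype"]
        feat_index = {f: i for i, f in enumerate(feature_ids)}
        for mod in modules.values():
            rows = [feat_index[f] for f in mod[member_key]]
            cols = [
                j
                for j, s in enumerate(samples)
                if geno_of[s] in set(mod["affected_genotypes"])
            ]
            if rows and cols:
                values[np.ix_(rows, cols)] += mod["effect_size"]
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
        return pd.DataFrame(values, index=feature_ids, columns=samples)

    prot_df = _layer(prot_ids, "protein_members")
    lip_df = _layer(lip_ids, "lipid_members")

    def _dropout(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        vals = df.to_numpy()
        rand_mask = rng.random(vals.shape) < cfg.missing_random
        q10 = np.quantile(vals, 0.10)
        # continuous, monotone-in-abundance extra dropout in the low tail
        p_mnar = np.clip(
            2.0 / (1.0 + np.exp(cfg.mnar_strength * (vals - q10))) - 1.0, 0.0, 1.0
        )
        mnar_mask = rng.random(vals.shape) < p_mnar
        mask = rand_mask | mnar_mask
        out = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
        return out, pd.DataFrame(mask, index=df.index, columns=df.columns)

    prot_obs, prot_mask = _dropout(prot_df)
    lip_obs, lip_mask = _dropout(lip_df)

    # annotation sets: one term per planted module plus size-matched decoys
    def _annotations(layer: str, member_key: str, pool: list[str], size: int) -> AnnotationSets:
        sets: dict[str, tuple[str, ...]] = {}
        desc: dict[str, str] = {}
        planted_members: set[str] = set()
        for mid, mod in modules.items():
            sets[f"{mid}_{layer}"] = tuple(mod[member_key])
            desc[f"{mid}_{layer}"] = f"planted {layer} module {mid}"
            planted_members |= set(mod[member_key])
        spare = [f for f in pool if f not in planted_members]
        for m in range(cfg.n_modules):
            decoy = sorted(rng.choice(spare, size=min(size, len(spare)), replace=False))
            sets[f"decoy{m + 1}_{layer}"] = tuple(decoy)
            desc[f"decoy{m + 1}_{layer}"] = f"size-matched decoy set {m + 1}"
        return AnnotationSets(layer, desc, sets)

    annotations = {
        "protein": _annotations("protein", "protein_members", prot_ids, cfg.proteins_per_module),
        "lipid": _annotations("lipid", "lipid_members", lip_ids, cfg.lipids_per_module),
    }
    truth = GroundTruth(modules=modules, protein_dropout=prot_mask, lipid_dropout=lip_mask)
    return SimulatedPanel(
        OmicsMatrix("protein", prot_obs),
        OmicsMatrix("lipid", lip_obs),
        meta,
        annotations,
        truth,
    )


def evaluate_recovery(
    truth: GroundTruth,
    protein_clusters: ClusterModel | None,
    lipid_clusters: ClusterModel | None,
    enrichment: pd.DataFrame | None,
    cm: CrossomeMatrix | None,
    *,
    q_threshold: float = 0.05,
) -> dict[str, float]:
    """Score pipeline outputs against the planted structure.

    Returns adjusted Rand index per axis (k-means assignments restricted to
    planted features), the fraction of within-module lipid-protein tau values
    that are positive, and the fraction of planted annotation terms reaching
    BH q below ``q_threshold`` in their best-matching cluster. Metrics whose
    inputs have no overlap with the truth come back NaN.
    """
    metrics: dict[str, float] = {}

    for layer, model in (("protein", protein_clusters), ("lipid", lipid_clusters)):
        key = f"ari_{layer}"
        if model is None:
            metrics[key] = float("nan")
            continue
        labels = truth.module_labels(layer)
        common = [f for f in model.feature_ids if f in labels.index]
        if not common:
            metrics[key] = float("nan")
            continue
        metrics[key] = float(
            adjusted_rand_score(
                labels.loc[common].to_numpy(), model.assignments.loc[common].to_numpy()
            )
        )

    if cm is not None:
        taus = []
        lip_set, prot_set = set(cm.lipid_ids), set(cm.protein_ids)
        for mod in truth.modules.values():
            lips = [l for l in mod["lipid_members"] if l in lip_set]
            prots = [p for p in mod["protein_members"] if p in prot_set]
            if lips and prots:
                block = cm.tau.loc[lips, prots].to_numpy().ravel()
                taus.append(block[np.isfinite(block)])
        if taus:
            allt = np.concatenate(taus)
            metrics["tau_sign_accuracy"] = (
                float((allt > 0).mean()) if allt.size else float("nan")
            )
        else:
            metrics["tau_sign_accuracy"] = float("nan")
    else:
        metrics["tau_sign_accuracy"] = float("nan")

    if enrichment is not None and len(enrichment):
        planted = [t for t in enrichment["term_id"].unique() if not t.startswith("decoy")]
        planted = [t for t in planted if t.split("_")[0] in truth.modules]
        hits = 0
        for term in planted:
            sub = enrichment[enrichment["term_id"] == term]
            best = sub.sort_values(["a", "q_value"], ascending=[False, True]).iloc[0]
            if best["q_value"] < q_threshold:
                hits += 1
        metrics["annotation_recovery"] = hits / len(planted) if planted else float("nan")
    else:
        metrics["annotation_recovery"] = float("nan")
    return metrics
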