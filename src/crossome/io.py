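"""Core data model and readers/writers for abundance matrices and annotations.

The containers here are thin, validated wrappers around pandas objects:

* :class:`OmicsMatrix` — one omic layer (protein or lipid), features x samples,
  log2-scale abundances with NaN marking missing values.
* :class:`SampleMetadata` — sample -> genotype / replicate / batch map with a
  designated control genotype.
* :class:`AnnotationSets` — term -> member feature sets (GMT dialect on disk).
* :class:`DifferentialMatrix` — per-genotype mean log2 fold changes vs control.

All on-disk formats are plain UTF-8 TSV (matrices, metadata, differential
tables) or GMT (annotation sets). Missing values are empty cells or ``NA`` on
read and empty cells on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "OmicsMatrix",
    "SampleMetadata",
    "AnnotationSets",
    "DifferentialMatrix",
    "StudyBundle",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
    "align_layers",
]

LAYERS = ("protein", "lipid")

#: accepted missing-value sentinels on read; writes always emit empty cells
NA_SENTINELS = ("", "NA")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(ValueError):
    """A container invariant was violated."""


def _check_layer(layer: str) -> str:
    if layer not in LAYERS:
        raise ValidationError(f"layer must be one of {LAYERS}, got {layer!r}")
    return layer


@dataclass
class OmicsMatrix:
    """Features x samples abundance matrix for one omic layer, log2 scale.

    Parameters
    ----------
    layer : {"protein", "lipid"}
        Which omic layer the matrix holds.
    data : pandas.DataFrame
        Rows are features, columns are samples, float values; NaN is missing.
    """

    layer: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_layer(self.layer)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r} in {self.layer} matrix")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in {self.layer} matrix")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise ValidationError(f"non-finite value in {self.layer} matrix")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "feature_id"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.data.loc[:, list(sample_ids)].copy())

    def select_features(self, feature_ids: Iterable[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.data.loc[list(feature_ids)].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OmicsMatrix):
            return NotImplemented
        return self.layer == other.layer and self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Sample -> (genotype, replicate, batch) map with one control genotype."""

    table: pd.DataFrame
    control: str = "Control"

    def __post_init__(self) -> None:
        required = {"genotype", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in metadata")
        self.table.index = self.table.index.astype(str)
        self.table.index.name = "sample_id"
        self.table["genotype"] = self.table["genotype"].astype(str)
        self.table["replicate"] = self.table["replicate"].astype(int)
        if (self.table["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be positive")
        if self.control not in set(self.table["genotype"]):
            raise ValidationError(
                f"control genotype {self.control!r} has no samples in metadata"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def genotypes(self) -> list[str]:
        """All genotype labels, control first, mutants in sorted order."""
        muts = sorted(set(self.table["genotype"]) - {self.control})
        return [self.control] + muts

    @property
    def mutant_genotypes(self) -> list[str]:
        return [g for g in self.genotypes if g != self.control]

    def samples_of(self, genotype: str) -> list[str]:
        return list(self.table.index[self.table["genotype"] == genotype])

    def canonical_order(self) -> list[str]:
        """Sample ids sorted by (genotype, replicate) for reproducible runs."""
        order = self.table.sort_values(["genotype", "replicate"]).index
        return list(order)

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy(), self.control)


@dataclass
class AnnotationSets:
    """Named feature sets (GO CC terms, lipid classes, curated modules)."""

    layer: str
    descriptions: dict[str, str] = field(default_factory=dict)
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_layer(self.layer)
        for term, mem in self.members.items():
            if len(mem) == 0:
                raise ValidationError(f"annotation term {term!r} has zero members")
            if len(set(mem)) != len(mem):
                raise ValidationError(f"duplicate member within term {term!r}")

    @property
    def term_ids(self) -> list[str]:
        return list(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, term: str) -> bool:
        return term in self.members

    def member_set(self, term: str) -> frozenset[str]:
        return frozenset(self.members[term])

    def restricted_to(self, background: Iterable[str]) -> "AnnotationSets":
        """Drop members outside *background*; terms emptied thereby are dropped."""
        bg = set(background)
        desc, mem = {}, {}
        for term, m in self.members.items():
            kept = tuple(x for x in m if x in bg)
            if kept:
                mem[term] = kept
                desc[term] = self.descriptions.get(term, "")
        return AnnotationSets(self.layer, desc, mem)

    @classmethod
    def from_dict(
        cls,
        layer: str,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> "AnnotationSets":
        mem = {}
        for term, m in sets.items():
            seen: dict[str, None] = dict.fromkeys(str(x) for x in m)
            mem[term] = tuple(seen)
        desc = {t: (descriptions or {}).get(t, "") for t in mem}
        return cls(layer, desc, mem)


@dataclass
class DifferentialMatrix:
    """Mean log2 fold change of each feature in each mutant genotype vs control.

    ``log2fc`` is features x genotypes (control excluded); ``n_case`` and
    ``n_control`` record how many non-missing replicate values entered each
    side of every cell. ``n_used`` is their elementwise minimum.
    """

    log2fc: pd.DataFrame
    n_case: pd.DataFrame
    n_control: pd.DataFrame
    control: str = "Control"
    min_reps: int = 2

    def __post_init__(self) -> None:
        if self.control in self.log2fc.columns:
            raise ValidationError("control genotype must not appear as a column")
        for other in (self.n_case, self.n_control):
            if not (
                other.index.equals(self.log2fc.index)
                and other.columns.equals(self.log2fc.columns)
            ):
                raise ValidationError("count tables must align with log2fc")
        ok = self.log2fc.isna() | (
            (self.n_case >= self.min_reps) & (self.n_control >= self.min_reps)
        )
        if not ok.all().all():
            raise ValidationError(
                f"non-missing log2fc cell with fewer than min_reps={self.min_reps} replicates"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def genotypes(self) -> list[str]:
        return list(self.log2fc.columns)

    @property
    def n_used(self) -> pd.DataFrame:
        return np.minimum(self.n_case, self.n_control)

    def to_tsv(self, path: str | Path) -> None:
        _write_float_tsv(self.log2fc, path)

    def select_features(self, feature_ids: Iterable[str]) -> "DifferentialMatrix":
        idx = list(feature_ids)
        return DifferentialMatrix(
            self.log2fc.loc[idx].copy(),
            self.n_case.loc[idx].copy(),
            self.n_control.loc[idx].copy(),
            self.control,
            self.min_reps,
        )


@dataclass
class StudyBundle:
    """Sample-aligned protein + lipid layers with their metadata."""

    protein: OmicsMatrix
    lipid: OmicsMatrix
    metadata: SampleMetadata
    dropped_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.protein.sample_ids != self.lipid.sample_ids:
            raise ValidationError("protein and lipid layers have different sample sets")
        if self.protein.sample_ids != self.metadata.sample_ids:
            raise ValidationError("layer samples do not match metadata samples")


# ---------------------------------------------------------------------------
# readers / writers


def _write_float_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", na_rep="")


def read_matrix(
    path: str | Path,
    layer: str,
    *,
    apply_log2: bool = False,
) -> OmicsMatrix:
    """Read a feature x sample TSV into an :class:`OmicsMatrix`.

    The first column holds feature ids; the header row holds sample ids.
    Empty cells and ``NA`` are missing. With ``apply_log2=True`` raw positive
    intensities are log2-transformed and non-positive values become missing.
    """
    _check_layer(layer)
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dups = {s for s in samples if samples.count(s) > 1}
    if dups:
        raise ParseError(f"{path}: duplicate sample id {sorted(dups)[0]!r} in header")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=list(NA_SENTINELS),
            keep_default_na=False,
            dtype=str,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot read table: {exc}") from exc
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r} in header")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate feature id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = df.index[rows[0]], df.columns[cols[0]]
        raise ParseError(f"{path}: non-numeric value {df.loc[r, c]!r} at ({r!r}, {c!r})")
    if apply_log2:
        arr = numeric.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            arr = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
        numeric = pd.DataFrame(arr, index=numeric.index, columns=numeric.columns)
    return OmicsMatrix(layer, numeric)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write an :class:`OmicsMatrix` as TSV; missing values become empty cells."""
    _write_float_tsv(matrix.data, path)


def read_metadata(path: str | Path, control: str = "Control") -> SampleMetadata:
    """Read sample metadata TSV (columns sample_id, genotype, replicate[, batch])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: metadata requires a 'sample_id' column")
    df = df.set_index("sample_id")
    try:
        return SampleMetadata(df, control=control)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t")


def read_annotations(path: str | Path, layer: str = "protein") -> AnnotationSets:
    """Read a GMT file: term_id <TAB> description <TAB> member [<TAB> member ...]."""
    path = Path(path)
    desc: dict[str, str] = {}
    members: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            term, description, *mem = fields
            mem = [m for m in mem if m]
            if term in members:
                raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
            deduped = tuple(dict.fromkeys(mem))
            if not deduped:
                raise ParseError(f"{path}:{lineno}: term {term!r} has no members")
            members[term] = deduped
            desc[term] = description
    return AnnotationSets(layer, desc, members)


def write_annotations(sets: AnnotationSets, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sets.term_ids:
            fields = [term, sets.descriptions.get(term, "")] + list(sets.members[term])
            fh.write("\t".join(fields) + "\n")


def align_layers(
    protein: OmicsMatrix,
    lipid: OmicsMatrix,
    meta: SampleMetadata,
) -> StudyBundle:
    """Restrict both layers to the samples shared with the metadata.

    Samples are put into the canonical (genotype, replicate) order; dropped
    sample ids are reported on the returned bundle. Idempotent.
    """
    common = set(protein.sample_ids) & set(lipid.sample_ids) & set(meta.sample_ids)
    if not common:
        raise ValidationError("no samples shared between layers and metadata")
    all_ids = set(protein.sample_ids) | set(lipid.sample_ids) | set(meta.sample_ids)
    dropped = tuple(sorted(all_ids - common))
    sub_meta = meta.subset([s for s in meta.sample_ids if s in common])
    order = sub_meta.canonical_order()
    return StudyBundle(
        protein.select_samples(order),
        lipid.select_samples(order),
        sub_meta.subset(order),
        dropped,
    )
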