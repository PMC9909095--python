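"""Domain types and readers/writers for the tabular and tree formats the pipeline uses.

Every downstream module consumes the types defined here (count tables,
abundance tables, sample metadata, taxonomy maps, phylogenies, distance
matrices) rather than reading files itself.  All tabular formats are plain
TSV; trees are Newick; run manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger("microbiogeo")

#: The six depth layers of the sampling design, shallow to deep.
DEPTH_LAYERS: tuple[str, ...] = ("5m", "75m", "DCM", "200m", "500m", "3000m")

#: Environmental columns required in sample metadata.
ENV_COLUMNS: tuple[str, ...] = (
    "temperature",
    "salinity",
    "dissolved_oxygen",
    "chlorophyll_a",
    "tin",
    "dip",
    "silicate",
)

METADATA_COLUMNS: tuple[str, ...] = (
    "station",
    "depth_layer",
    "latitude",
    "longitude",
) + ENV_COLUMNS


class FormatError(ValueError):
    """Raised when an input file violates its declared format or invariants."""


class ParameterError(ValueError):
    """Raised when an operation receives an out-of-range parameter."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountTable:
    """Integer abundance matrix, taxa (rows) x samples (columns).

    Invariants: unique taxon and sample identifiers, all counts >= 0,
    every sample has at least one nonzero count.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise FormatError("duplicate taxon identifiers in count table")
        if df.columns.duplicated().any():
            raise FormatError("duplicate sample identifiers in count table")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise FormatError("count table cells must be integers")
        if (values < 0).any():
            raise FormatError("negative counts in count table")
        if df.shape[1] and (values.sum(axis=0) == 0).any():
            empty = [s for s, t in zip(df.columns, values.sum(axis=0)) if t == 0]
            raise FormatError(f"samples with all-zero counts: {empty}")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, samples: Iterable[str]) -> "CountTable":
        return CountTable(self.data.loc[:, list(samples)])


@dataclass(frozen=True)
class AbundanceTable:
    """Real-valued abundance matrix on the same axes as :class:`CountTable`.

    ``kind`` records the normalisation: ``"relative"`` columns sum to 1,
    ``"hellinger"`` columns have unit sum of squares, ``"raw"`` is unchecked.
    """

    data: pd.DataFrame
    kind: str = "raw"

    _TOL = 1e-9

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise FormatError("duplicate identifiers in abundance table")
        values = df.to_numpy(dtype=float)
        if (values < 0).any():
            raise FormatError("negative abundances")
        if self.kind == "relative":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=self._TOL):
                raise FormatError("relative-abundance columns must sum to 1")
        elif self.kind == "hellinger":
            sums = (values**2).sum(axis=0)
            if not np.allclose(sums, 1.0, atol=self._TOL):
                raise FormatError("Hellinger columns must have unit sum of squares")
        elif self.kind != "raw":
            raise ParameterError(f"unknown abundance kind {self.kind!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class SampleFrame:
    """Per-sample metadata: station, depth layer, coordinates and environment."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing mandatory columns: {missing}")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample identifiers in metadata")
        bad_layers = set(df["depth_layer"]) - set(DEPTH_LAYERS)
        if bad_layers:
            raise FormatError(f"unknown depth layers: {sorted(bad_layers)}")
        lat = df["latitude"].astype(float)
        lon = df["longitude"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise FormatError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise FormatError("longitude outside [-180, 180]")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def environment(self, columns: Iterable[str] = ENV_COLUMNS) -> pd.DataFrame:
        return self.data.loc[:, list(columns)].astype(float)

    def coordinates(self) -> pd.DataFrame:
        return self.data.loc[:, ["latitude", "longitude"]].astype(float)


@dataclass(frozen=True)
class TaxonomyMap:
    """Total mapping taxon id -> (phylum, class, order)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ("phylum", "class", "order") if c not in df.columns]
        if missing:
            raise FormatError(f"taxonomy missing columns: {missing}")
        if df.index.duplicated().any():
            raise FormatError("duplicate taxon identifiers in taxonomy")
        if (df["order"].astype(str).str.len() == 0).any() or df["order"].isna().any():
            raise FormatError("empty order labels in taxonomy")

    def order_of(self) -> pd.Series:
        return self.data["order"]

    def covers(self, taxa: Iterable[str]) -> list[str]:
        """Return the taxa *not* covered by the map (empty list = total)."""
        return [t for t in taxa if t not in self.data.index]


@dataclass
class RunConfig:
    """Reproducibility knobs shared across the pipeline.

    Defaults follow the study design: 999 null randomizations, the
    |rho| > 0.4 & p < 0.05 network gate, and a rarefaction depth of
    16,704 reads per sample.
    """

    seed: int = 0
    n_null: int = 999
    rho_threshold: float = 0.4
    alpha: float = 0.05
    rarefaction_depth: int = 16704
    n_pcnm: int = 5
    n_permutations: int = 999
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ParameterError("n_null must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if not 0 < self.rho_threshold < 1:
            raise ParameterError("rho_threshold must be in (0, 1)")
        if self.rarefaction_depth < 1:
            raise ParameterError("rarefaction_depth must be >= 1")


#: Fixed stage identifiers used to derive per-stage seeds from the master seed.
_STAGE_IDS: dict[str, int] = {
    "simulate": 1,
    "tree": 2,
    "traits": 3,
    "environment": 4,
    "assembly_sim": 5,
    "rarefy": 6,
    "bnti": 7,
    "rc_bray": 8,
    "mantel": 9,
    "permanova": 10,
    "distance_decay": 11,
    "network": 12,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed from the master seed.

    The rule is fixed: the pair ``(master_seed, stage_id)`` keys a
    ``numpy.random.SeedSequence`` whose first 32-bit word is returned, so a
    full pipeline run is reproducible bit-for-bit from the master seed alone.
    """
    if stage not in _STAGE_IDS:
        raise ParameterError(f"unknown pipeline stage {stage!r}")
    ss = np.random.SeedSequence((int(master_seed), _STAGE_IDS[stage]))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.isna().any().any():
        raise FormatError(f"blank cells in {path}")
    df.index = df.index.astype(str)
    return df


def read_count_table(path: str | Path) -> CountTable:
    """Read a QIIME-style feature table: taxa rows, sample columns, integer cells."""
    header = Path(path).open().readline().rstrip("\n").split("\t")
    sample_ids = header[1:]  # first header cell (taxon-column label) ignored
    if len(sample_ids) != len(set(sample_ids)):
        raise FormatError(f"duplicate sample identifiers in {path}")
    df = _read_tsv(path)
    df.index.name = None
    df.columns.name = None
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"non-numeric cells in count table {path}")
    if not np.allclose(values, np.round(values)):
        raise FormatError(f"non-integer counts in {path}")
    return CountTable(df.round().astype(np.int64))


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon")


def read_newick(path_or_str: str | Path) -> TreeNode:
    """Read a single rooted Newick tree with branch lengths.

    Accepts a file path or a raw Newick string.
    """
    text = str(path_or_str)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"invalid Newick: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError("tree has edges without branch lengths")
        if node.length < 0:
            raise FormatError("negative branch length in tree")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_sample_frame(path: str | Path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.isna().any().any():
        raise FormatError(f"blank cells in metadata {path}")
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path: str | Path) -> None:
    frame.data.to_csv(path, sep="\t", index_label="sample")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyMap(df)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    taxonomy.data.to_csv(path, sep="\t", index_label="taxon")


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = _read_tsv(path).astype(float)
    return DistanceMatrix(df.to_numpy(), ids=list(df.columns))


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
    warnings: list[str] | None = None,
) -> dict:
    """Write result tables as TSV plus a JSON run manifest.

    Returns the manifest dictionary (config echo, seed, file listing,
    accumulated warnings).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t")
        files[name] = path.name
    manifest = {
        "config": dataclasses.asdict(config) if config is not None else None,
        "outputs": files,
        "warnings": warnings or [],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def read_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())


def config_from_manifest(manifest: dict) -> RunConfig:
    cfg = dict(manifest["config"])
    return RunConfig(**cfg)


# ---------------------------------------------------------------------------
# Small shared numerics
# ---------------------------------------------------------------------------


def cophenetic_matrix(tree: TreeNode, taxa: list[str] | None = None) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix, optionally restricted/ordered by ``taxa``."""
    dm = tree.tip_tip_distances()
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    if taxa is not None:
        missing = [t for t in taxa if t not in df.index]
        if missing:
            raise FormatError(f"taxa absent from the phylogeny: {missing[:10]}")
        df = df.loc[taxa, taxa]
    return df


def require_tip_coverage(tree: TreeNode, taxa: Iterable[str]) -> None:
    """Fail loudly if any analysed taxon is not a tip of the tree.

    Total tip coverage is required for all phylogenetic statistics; the
    discrepancy is reported rather than silently pruned.
    """
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise FormatError(
            f"{len(missing)} taxa missing from the phylogeny "
            f"(first few: {missing[:5]}); phylogenetic analyses require total tip coverage"
        )
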