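"""Cohort input/output: node table, connectivity matrices, and manifests.

The node table defines the a-priori community partition used by the
participation coefficient: 400 cortical parcels assigned to 7 intrinsic
connectivity networks plus 12 subcortical regions treated as an 8th network
(412 nodes total by default).  Connectivity matrices are plain delimited
text, one square symmetric matrix per file, with node order defined solely
by the node table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("netcontrast")

#: maximum tolerated |W - W.T| before a file is rejected as corrupt
SYMMETRY_TOL = 1e-6

HEMISPHERES = ("left", "right")

#: per-hemisphere parcel counts of the 400-parcel / 7-network cortical atlas
CORTICAL_NETWORK_COUNTS = {
    "left": {
        "Visual": 31,
        "Somatomotor": 37,
        "DorsalAttention": 23,
        "VentralAttention": 22,
        "Limbic": 13,
        "Control": 30,
        "Default": 44,
    },
    "right": {
        "Visual": 30,
        "Somatomotor": 40,
        "DorsalAttention": 23,
        "VentralAttention": 25,
        "Limbic": 13,
        "Control": 28,
        "Default": 41,
    },
}

#: short parcel-name prefixes per network, mirroring common atlas labels
_NETWORK_PREFIX = {
    "Visual": "Vis",
    "Somatomotor": "SomMot",
    "DorsalAttention": "DorsAttn",
    "VentralAttention": "SalVentAttn",
    "Limbic": "Limbic",
    "Control": "Cont",
    "Default": "Default",
}

#: conventional six subcortical structures per hemisphere
DEFAULT_SUBCORTICAL = (
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
)

SUBCORTICAL_NETWORK = "Subcortical"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class DimensionError(ValidationError):
    """Matrix shape does not match the node table."""


class IntegrityError(ValidationError):
    """Matrix content violates symmetry or numeric requirements."""


class ManifestError(ValidationError):
    """Cohort manifest is malformed or incomplete."""


# ---------------------------------------------------------------------------
# Node table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeTable:
    """Labeled node set defining node order and the community partition.

    ``table`` has columns ``node_id`` (contiguous 0..N-1), ``hemisphere``,
    ``network`` and ``parcel_name``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"node_id", "hemisphere", "network", "parcel_name"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"node table missing columns: {sorted(missing)}")
        ids = self.table["node_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValidationError("node_ids must be unique and contiguous from 0")
        dup = self.table.duplicated(subset=["hemisphere", "parcel_name"])
        if dup.any():
            bad = self.table.loc[dup, ["hemisphere", "parcel_name"]].iloc[0]
            raise ValidationError(
                f"duplicate (hemisphere, parcel_name): {tuple(bad)}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        """Network labels in first-appearance order."""
        return list(dict.fromkeys(self.table["network"]))

    @property
    def community_labels(self) -> np.ndarray:
        """Integer community id per node, by network first-appearance order."""
        order = {net: i for i, net in enumerate(self.networks)}
        return self.table["network"].map(order).to_numpy(dtype=np.int64)

    def nodes_in_network(self, network: str) -> np.ndarray:
        """Node ids belonging to ``network``."""
        if network not in set(self.table["network"]):
            raise ValidationError(f"unknown network: {network!r}")
        return self.table.loc[self.table["network"] == network, "node_id"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NodeTable":
        return cls(pd.read_csv(path))


def build_node_table(
    cortical_spec: Sequence[tuple[str, str, str]],
    subcortical_spec: Sequence[tuple[str, str]] = (),
) -> NodeTable:
    """Assemble a node table from explicit parcel listings.

    Parameters
    ----------
    cortical_spec
        Rows of ``(hemisphere, network, parcel_name)``.
    subcortical_spec
        Rows of ``(hemisphere, structure_name)``; all are assigned to one
        extra network distinct from the cortical ones.
    """
    if not cortical_spec:
        raise ValidationError("cortical_spec must not be empty")
    rows = []
    for hemi, network, parcel in cortical_spec:
        if network == SUBCORTICAL_NETWORK:
            raise ValidationError(
                f"cortical network label clashes with {SUBCORTICAL_NETWORK!r}"
            )
        rows.append((hemi, network, parcel))
    for hemi, structure in subcortical_spec:
        rows.append((hemi, SUBCORTICAL_NETWORK, structure))
    df = pd.DataFrame(rows, columns=["hemisphere", "network", "parcel_name"])
    df.insert(0, "node_id", np.arange(len(df)))
    return NodeTable(df)


def default_cortical_spec() -> list[tuple[str, str, str]]:
    """The 400-parcel, 7-network cortical listing (left then right)."""
    spec = []
    for hemi in HEMISPHERES:
        for network, count in CORTICAL_NETWORK_COUNTS[hemi].items():
            prefix = _NETWORK_PREFIX[network]
            for k in range(1, count + 1):
                spec.append((hemi, network, f"{prefix}_{k}"))
    return spec


def default_subcortical_spec() -> list[tuple[str, str]]:
    """Six subcortical structures per hemisphere (12 regions)."""
    return [(h, s) for h in HEMISPHERES for s in DEFAULT_SUBCORTICAL]


def default_node_table() -> NodeTable:
    """412-node table: 400 cortical parcels in 7 networks + 12 subcortical."""
    return build_node_table(default_cortical_spec(), default_subcortical_spec())


# ---------------------------------------------------------------------------
# Connectivity records
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityRecord:
    """One participant x condition weighted connectivity matrix."""

    participant_id: str
    dataset_id: str
    condition: str
    age: float
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DimensionError(f"matrix must be square, got shape {m.shape}")
        asym = np.abs(m - m.T).max() if m.size else 0.0
        if asym > SYMMETRY_TOL:
            raise IntegrityError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}"
            )
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") >= first.count("\t") and "," in first else "\t"


def read_connectivity(
    path: str | Path,
    node_table: NodeTable,
    *,
    participant_id: str,
    dataset_id: str,
    condition: str,
    age: float,
) -> ConnectivityRecord:
    """Read one delimited square matrix and attach cohort metadata.

    The file carries no labels; node order is defined by ``node_table``.
    Mild asymmetry (below :data:`SYMMETRY_TOL`) is symmetrized as
    ``(W + W.T)/2``; anything larger is an integrity error.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    try:
        matrix = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise IntegrityError(f"non-numeric content in {path}: {exc}") from exc
    if matrix.shape != (node_table.n_nodes, node_table.n_nodes):
        raise DimensionError(
            f"{path}: matrix shape {matrix.shape} does not match "
            f"{node_table.n_nodes}-node table"
        )
    return ConnectivityRecord(
        participant_id=participant_id,
        dataset_id=dataset_id,
        condition=condition,
        age=float(age),
        matrix=matrix,
    )


def write_connectivity(record: ConnectivityRecord, path: str | Path) -> None:
    """Write the matrix as tab-delimited text at full float precision."""
    np.savetxt(path, record.matrix, delimiter="\t", fmt="%.17g")


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["participant_id", "dataset_id", "age", "path_fear", "path_neutral"]

CONDITIONS = ("fear", "neutral")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str, "dataset_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ManifestError(f"participant {dup!r} appears more than once")
    for col in ("path_fear", "path_neutral"):
        if df[col].isna().any():
            who = df.loc[df[col].isna(), "participant_id"].iloc[0]
            raise ManifestError(f"participant {who!r} lacks {col}")
    return df


def load_cohort(
    manifest_path: str | Path, node_table: NodeTable
) -> list[ConnectivityRecord]:
    """Load every participant's fear and neutral matrix.

    Returns exactly two records per manifest row.  Paths in the manifest
    are resolved relative to the manifest's own directory.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    if manifest.empty:
        warnings.warn("empty cohort manifest", stacklevel=2)
        return []
    base = manifest_path.parent
    records: list[ConnectivityRecord] = []
    for row in manifest.itertuples(index=False):
        for condition in CONDITIONS:
            rel = getattr(row, f"path_{condition}")
            p = Path(rel)
            if not p.is_absolute():
                p = base / p
            try:
                records.append(
                    read_connectivity(
                        p,
                        node_table,
                        participant_id=row.participant_id,
                        dataset_id=row.dataset_id,
                        condition=condition,
                        age=row.age,
                    )
                )
            except ValidationError as exc:
                raise type(exc)(
                    f"participant {row.participant_id!r}, condition {condition}: {exc}"
                ) from exc
    return records


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
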