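"""Shared domain types and tabular/network I/O.

The pipeline's central container is :class:`MetabolomeMatrix`: a samples ×
metabolites grid of non-negative intensities (arbitrary units, as delivered
by an LC–MS quantification pipeline) together with sample metadata (variety,
hours after imbibition, replicate) and metabolite annotations (compound
class, optional metabolic-module tag).  Intensities are stored as given —
no log transform happens at I/O time; any transform is an explicit option
of the downstream operation that needs it.

Missing values are allowed on read (empty cells become NaN); every
statistical operation documents its own missing policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "DegenerateDataError",
    "SAMPLE_COLUMNS",
    "COMPOUND_CLASSES",
    "MODULE_TAGS",
    "MetabolomeMatrix",
    "read_metabolome",
    "write_metabolome",
    "read_phenotype",
    "write_phenotype",
    "validate_phenotype",
    "read_annotations",
    "write_network",
    "read_network",
]

#: metadata columns identifying a sample, in canonical order
SAMPLE_COLUMNS = ["sample_id", "variety", "timepoint_hai", "replicate"]

#: open vocabulary of compound classes used throughout (extra labels are accepted)
COMPOUND_CLASSES = (
    "lipids",
    "flavonoids",
    "amino acids and derivatives",
    "polyamines",
    "organic acids",
    "terpenes",
    "nucleotides and derivatives",
    "phytohormones",
    "sugars",
    "vitamins and derivatives",
    "others",
)

MODULE_TAGS = ("ornithine-asparagine-polyamine", "shikimate-aromatic-flavonoid", "none")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class DegenerateDataError(ValueError):
    """Data that makes a requested statistic undefined (e.g. constant series)."""


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass
class MetabolomeMatrix:
    """Samples × metabolites intensity matrix with metadata.

    Attributes
    ----------
    samples : pandas.DataFrame
        Indexed by ``sample_id``; columns ``variety``, ``timepoint_hai``
        (int hours ≥ 0), ``replicate`` (int ≥ 1).
    metabolites : pandas.DataFrame
        Indexed by ``metabolite_id``; columns ``name``, ``compound_class``,
        ``module_tag``.
    values : pandas.DataFrame
        Indexed by ``sample_id``, one column per ``metabolite_id``.  NaN
        marks a missing measurement; present values are ≥ 0.
    """

    samples: pd.DataFrame
    metabolites: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if list(self.values.index) != list(self.samples.index):
            raise InputError("values rows do not match sample metadata")
        if list(self.values.columns) != list(self.metabolites.index):
            raise InputError("values columns do not match metabolite metadata")
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise InputError(f"duplicate sample_id {dup!r}")
        if self.metabolites.index.has_duplicates:
            dup = self.metabolites.index[self.metabolites.index.duplicated()][0]
            raise InputError(f"duplicate metabolite_id {dup!r}")
        triples = self.samples[["variety", "timepoint_hai", "replicate"]]
        if triples.duplicated().any():
            bad = triples[triples.duplicated()].iloc[0]
            raise InputError(
                "duplicate sample triple "
                f"(variety={bad['variety']!r}, timepoint_hai={bad['timepoint_hai']}, "
                f"replicate={bad['replicate']})"
            )
        if (self.samples["timepoint_hai"] < 0).any():
            raise InputError("timepoint_hai must be ≥ 0")
        arr = self.values.to_numpy(dtype=float)
        neg = np.argwhere(np.nan_to_num(arr, nan=0.0) < 0)
        if neg.size:
            i, j = neg[0]
            raise InputError(
                f"negative intensity {arr[i, j]} at sample "
                f"{self.values.index[i]!r}, metabolite {self.values.columns[j]!r}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def varieties(self) -> list:
        return sorted(self.samples["variety"].unique().tolist())

    @property
    def timepoints(self) -> list:
        return sorted(self.samples["timepoint_hai"].unique().tolist())

    def subset_samples(self, sample_ids: Sequence[str]) -> "MetabolomeMatrix":
        ids = list(sample_ids)
        return MetabolomeMatrix(
            samples=self.samples.loc[ids].copy(),
            metabolites=self.metabolites.copy(),
            values=self.values.loc[ids].copy(),
        )

    def replicate_groups(self):
        """Yield ((variety, timepoint_hai), list-of-sample_ids)."""
        for key, grp in self.samples.groupby(["variety", "timepoint_hai"], sort=True):
            yield key, grp.index.tolist()

    def timepoint_means(self, variety) -> pd.DataFrame:
        """Replicate-mean intensity per time point (missing-aware).

        Returns a DataFrame indexed by ``timepoint_hai``, one column per
        metabolite.  NaN cells propagate only when every replicate is
        missing.
        """
        mask = self.samples["variety"] == variety
        if not mask.any():
            raise InputError(f"variety {variety!r} not present")
        sub = self.values.loc[mask.index[mask]]
        tp = self.samples.loc[mask, "timepoint_hai"]
        return sub.groupby(tp.values).mean()

    def copy(self) -> "MetabolomeMatrix":
        return MetabolomeMatrix(
            self.samples.copy(), self.metabolites.copy(), self.values.copy()
        )

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, MetabolomeMatrix):
            return NotImplemented
        return (
            self.samples.equals(other.samples)
            and self.metabolites.equals(other.metabolites)
            and self.values.equals(other.values)
        )


# ---------------------------------------------------------------------------
# metabolome readers/writers
# ---------------------------------------------------------------------------


def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def _default_annotations(metabolite_ids: Iterable[str]) -> pd.DataFrame:
    ids = list(metabolite_ids)
    return pd.DataFrame(
        {"name": ids, "compound_class": "others", "module_tag": "none"},
        index=pd.Index(ids, name="metabolite_id"),
    )


def read_annotations(path, sep: str | None = None) -> pd.DataFrame:
    """Read a metabolite annotation table (metabolite_id, name, compound_class[, module_tag])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path, sep), float_precision="round_trip")
    if "metabolite_id" not in df.columns:
        raise InputError(f"{path}: annotation table needs a metabolite_id column")
    if df["metabolite_id"].duplicated().any():
        dup = df.loc[df["metabolite_id"].duplicated(), "metabolite_id"].iloc[0]
        raise InputError(f"{path}: duplicate metabolite_id {dup!r}")
    df = df.set_index("metabolite_id")
    if "name" not in df.columns:
        df["name"] = df.index
    if "compound_class" not in df.columns:
        df["compound_class"] = "others"
    if "module_tag" not in df.columns:
        df["module_tag"] = "none"
    return df[["name", "compound_class", "module_tag"]]


def read_metabolome(
    path,
    layout: str = "wide",
    sep: str | None = None,
    annotations: pd.DataFrame | None = None,
) -> MetabolomeMatrix:
    """Read an intensity table into a validated :class:`MetabolomeMatrix`.

    Parameters
    ----------
    layout : ``"wide"`` or ``"long"``
        Wide: one row per sample, columns ``sample_id, variety,
        timepoint_hai, replicate`` followed by one column per metabolite.
        Long: columns ``sample_id, variety, timepoint_hai, replicate,
        metabolite_id, intensity``.
    sep : delimiter override; default auto-detects comma vs tab.
    annotations : optional annotation table from :func:`read_annotations`.

    Empty cells become missing values.  Negative intensities, duplicate
    sample triples and duplicate (sample, metabolite) cells are errors that
    name the offending row/column.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    sep = _detect_sep(path, sep)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InputError(f"{path}: malformed header, missing columns {missing_cols}")

    if layout == "wide":
        met_cols = [c for c in df.columns if c not in SAMPLE_COLUMNS]
        if not met_cols:
            raise InputError(f"{path}: no metabolite columns found")
        samples = df[SAMPLE_COLUMNS].copy()
        values = df[met_cols].astype(float)
        values.index = samples["sample_id"]
        values.columns.name = "metabolite_id"
    elif layout == "long":
        for col in ("metabolite_id", "intensity"):
            if col not in df.columns:
                raise InputError(f"{path}: long layout needs a {col!r} column")
        dup = df.duplicated(subset=["sample_id", "metabolite_id"])
        if dup.any():
            bad = df.loc[dup, ["sample_id", "metabolite_id"]].iloc[0]
            raise InputError(
                f"{path}: duplicate cell (sample {bad['sample_id']!r}, "
                f"metabolite {bad['metabolite_id']!r})"
            )
        samples = (
            df[SAMPLE_COLUMNS].drop_duplicates(subset="sample_id").reset_index(drop=True)
        )
        wide = df.pivot(index="sample_id", columns="metabolite_id", values="intensity")
        values = wide.reindex(samples["sample_id"])
    else:
        raise InputError(f"unknown layout {layout!r} (expected 'wide' or 'long')")

    samples = samples.copy()
    samples["timepoint_hai"] = samples["timepoint_hai"].astype(int)
    samples["replicate"] = samples["replicate"].astype(int)
    samples = samples.set_index("sample_id")

    if annotations is not None:
        unknown = [m for m in values.columns if m not in annotations.index]
        if unknown:
            ann = pd.concat([annotations, _default_annotations(unknown)])
        else:
            ann = annotations
        metabolites = ann.loc[values.columns].copy()
    else:
        metabolites = _default_annotations(values.columns)
    metabolites.index.name = "metabolite_id"
    values.columns = metabolites.index
    return MetabolomeMatrix(samples=samples, metabolites=metabolites, values=values)


def write_metabolome(matrix: MetabolomeMatrix, path, layout: str = "wide", sep: str = ",") -> Path:
    """Write a matrix back to CSV/TSV in the requested layout (round-trip safe)."""
    path = Path(path)
    samples = matrix.samples.reset_index()
    if layout == "wide":
        out = pd.concat(
            [samples, matrix.values.reset_index(drop=True)], axis=1
        )
        out.to_csv(path, sep=sep, index=False)
    elif layout == "long":
        long = matrix.values.stack(future_stack=True).rename("intensity").reset_index()
        long = long.dropna(subset=["intensity"])
        out = long.merge(samples, on="sample_id")[
            SAMPLE_COLUMNS + ["metabolite_id", "intensity"]
        ]
        out.to_csv(path, sep=sep, index=False)
    else:
        raise InputError(f"unknown layout {layout!r}")
    return path


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = [
    "variety",
    "timepoint_hai",
    "replicate",
    "germination_fraction",
    "fresh_weight",
    "dry_weight",
    "treatment",
]


def validate_phenotype(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a germination-phenotype table.

    Required: ``variety``, ``timepoint_hai``, ``germination_fraction``.
    Optional: ``replicate``, ``fresh_weight`` (W_a), ``dry_weight`` (W_b),
    ``treatment``.  Germination fractions live in [0, 1]; a fraction that
    decreases over time within a variety × treatment series, or a fresh
    weight below the dry weight, draws a warning (input data may carry
    measurement noise) rather than an error.
    """
    for col in ("variety", "timepoint_hai", "germination_fraction"):
        if col not in df.columns:
            raise InputError(f"phenotype table needs a {col!r} column")
    df = df.copy()
    df["timepoint_hai"] = df["timepoint_hai"].astype(int)
    frac = df["germination_fraction"].dropna()
    if ((frac < 0) | (frac > 1)).any():
        bad = frac[(frac < 0) | (frac > 1)].iloc[0]
        raise InputError(f"germination_fraction {bad} outside [0, 1]")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if "treatment" not in df.columns:
        df["treatment"] = "CK"
    df["treatment"] = df["treatment"].fillna("CK")
    group_cols = ["variety", "treatment"]
    for key, grp in df.groupby(group_cols, sort=False):
        series = grp.groupby("timepoint_hai")["germination_fraction"].mean().sort_index()
        if (series.diff().dropna() < -1e-12).any():
            warnings.warn(
                f"germination fraction decreases over time for {key}", stacklevel=2
            )
    if {"fresh_weight", "dry_weight"} <= set(df.columns):
        both = df.dropna(subset=["fresh_weight", "dry_weight"])
        if (both["dry_weight"] <= 0).any():
            raise InputError("dry_weight must be > 0")
        if (both["fresh_weight"] < both["dry_weight"]).any():
            warnings.warn("fresh_weight < dry_weight for some rows", stacklevel=2)
    return df


def read_phenotype(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    return validate_phenotype(
        pd.read_csv(path, sep=_detect_sep(path, sep), float_precision="round_trip")
    )


def write_phenotype(df: pd.DataFrame, path, sep: str = ",") -> Path:
    path = Path(path)
    cols = [c for c in PHENOTYPE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# correlation-network export
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["source", "target", "variety", "weight", "sign", "p"]


def _trait_node(variety) -> str:
    return f"germination_rate[{variety}]"


def write_network(
    edges: pd.DataFrame,
    node_annotations: pd.DataFrame | None,
    out_prefix,
    formats: Sequence[str] = ("csv", "graphml", "sif"),
) -> dict:
    """Export a metabolite–trait correlation network.

    ``edges`` carries one row per metabolite–trait association with columns
    ``metabolite_id``, ``variety``, ``r`` and optionally ``p``.  Each
    variety contributes one trait node (``germination_rate[variety]``); the
    edge weight is the Pearson r and the sign column is ``pos``/``neg``.
    The CSV edge/node tables round-trip losslessly through
    :func:`read_network`; GraphML and SIF mirrors are written for generic
    graph tools (Cytoscape-compatible).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    edges = edges.copy()
    required = {"metabolite_id", "variety", "r"}
    if not required <= set(edges.columns):
        if len(edges) == 0:
            edges = pd.DataFrame(columns=["metabolite_id", "variety", "r", "p"])
        else:
            raise InputError(f"edge table needs columns {sorted(required)}")
    table = pd.DataFrame(
        {
            "source": edges["metabolite_id"].astype(str) if len(edges) else [],
            "target": [_trait_node(v) for v in edges["variety"]] if len(edges) else [],
            "variety": edges["variety"] if len(edges) else [],
            "weight": edges["r"].astype(float) if len(edges) else [],
            "sign": np.where(edges["r"] >= 0, "pos", "neg") if len(edges) else [],
            "p": edges["p"].astype(float) if "p" in edges.columns and len(edges) else np.nan,
        }
    )
    written = {}
    if "csv" in formats:
        edge_path = out_prefix.with_suffix(".edges.csv")
        table.to_csv(edge_path, index=False)
        written["edges_csv"] = edge_path
        nodes = pd.DataFrame(
            {"node_id": pd.unique(pd.concat([table["source"], table["target"]]))}
            if len(table)
            else {"node_id": []}
        )
        nodes["node_type"] = [
            "trait" if str(n).startswith("germination_rate[") else "metabolite"
            for n in nodes["node_id"]
        ]
        if node_annotations is not None and len(nodes):
            ann = node_annotations["compound_class"]
            nodes["compound_class"] = [
                ann.get(n, "") if not str(n).startswith("germination_rate[") else ""
                for n in nodes["node_id"]
            ]
        else:
            nodes["compound_class"] = ""
        node_path = out_prefix.with_suffix(".nodes.csv")
        nodes.to_csv(node_path, index=False)
        written["nodes_csv"] = node_path
    if "graphml" in formats:
        g = nx.Graph()
        for _, row in table.iterrows():
            g.add_edge(
                row["source"],
                row["target"],
                weight=float(row["weight"]),
                sign=row["sign"],
            )
        gml_path = out_prefix.with_suffix(".graphml")
        nx.write_graphml(g, gml_path)
        written["graphml"] = gml_path
    if "sif" in formats:
        sif_path = out_prefix.with_suffix(".sif")
        with open(sif_path, "w", encoding="utf-8") as fh:
            for _, row in table.iterrows():
                fh.write(f"{row['source']}\t{row['sign']}\t{row['target']}\n")
        written["sif"] = sif_path
    return written


def read_network(out_prefix) -> pd.DataFrame:
    """Read back the CSV edge table written by :func:`write_network`."""
    edge_path = Path(out_prefix).with_suffix(".edges.csv")
    if not edge_path.exists():
        raise InputError(f"no such file: {edge_path}")
    df = pd.read_csv(edge_path)
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            raise InputError(f"{edge_path}: missing column {col!r}")
    return df
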