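"""Readers and writers for the tabular/sparse formats the tool touches.

Expression comes in either as a dense TSV (spots as rows, genes as columns,
header row + index column) or as a MatrixMarket triplet directory
(``matrix.mtx`` in genes × spots orientation, 10x style, with
``barcodes.tsv`` and ``features.tsv`` sidecars).  Coordinates and region
labels are TSVs keyed by spot id; gene sets use the GMT format.  All writers
round-trip bit-exactly with their readers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data import GeneSet, SpatialDataset
from .errors import InvalidConfigError

__all__ = [
    "read_expression",
    "write_expression",
    "read_coordinates",
    "write_coordinates",
    "read_regions",
    "write_regions",
    "read_size_factors",
    "write_size_factors",
    "read_gene_sets",
    "write_gene_sets",
    "load_dataset",
    "save_dataset",
    "write_results",
    "write_run_metadata",
]


def read_expression(path, fmt: str = "dense_tsv"):
    """Read an expression matrix.

    ``dense_tsv``: one TSV file.  ``mtx_triplet``: a directory holding
    ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``.  Returns
    ``(values (n_spots, n_genes), spot_ids, gene_ids)``.
    """
    path = Path(path)
    if fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        values = df.to_numpy(dtype=float)
        return values, df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object)
    if fmt == "mtx_triplet":
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        for f in (mtx, barcodes, features):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar file: {f}")
        M = spio.mmread(mtx)
        M = sparse.coo_matrix(M).toarray().astype(float)
        spot_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].to_numpy(dtype=object)
        gene_ids = pd.read_csv(features, sep="\t", header=None)[0].to_numpy(dtype=object)
        if M.shape != (gene_ids.size, spot_ids.size):
            raise InvalidConfigError(
                f"matrix shape {M.shape} inconsistent with "
                f"{gene_ids.size} features x {spot_ids.size} barcodes"
            )
        return M.T, spot_ids, gene_ids
    raise InvalidConfigError(f"unknown expression format {fmt!r}")


def write_expression(path, values, spot_ids, gene_ids, fmt: str = "dense_tsv") -> None:
    path = Path(path)
    values = np.asarray(values)
    if fmt == "dense_tsv":
        df = pd.DataFrame(values, index=spot_ids, columns=gene_ids)
        df.to_csv(path, sep="\t", float_format="%.17g")  # exact float round trip
        return
    if fmt == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(values.T))
        pd.Series(spot_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
        pd.Series(gene_ids).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
        return
    raise InvalidConfigError(f"unknown expression format {fmt!r}")


def read_coordinates(path):
    """TSV with columns ``spot_id``, ``x``, ``y`` (native slide units)."""
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str})
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise InvalidConfigError(f"coordinates file lacks column {col!r}")
    return df


def write_coordinates(path, spot_ids, coordinates) -> None:
    C = np.asarray(coordinates, dtype=float)
    pd.DataFrame({"spot_id": spot_ids, "x": C[:, 0], "y": C[:, 1]}).to_csv(
        path, sep="\t", index=False
    )


def read_regions(path):
    """TSV with columns ``spot_id``, ``region``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("spot_id", "region"):
        if col not in df.columns:
            raise InvalidConfigError(f"regions file lacks column {col!r}")
    return df


def write_regions(path, spot_ids, region_labels) -> None:
    pd.DataFrame({"spot_id": spot_ids, "region": region_labels}).to_csv(
        path, sep="\t", index=False
    )


def read_size_factors(path):
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str})
    for col in ("spot_id", "size_factor"):
        if col not in df.columns:
            raise InvalidConfigError(f"size-factor file lacks column {col!r}")
    return df


def write_size_factors(path, spot_ids, size_factors) -> None:
    pd.DataFrame({"spot_id": spot_ids, "size_factor": size_factors}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Member order is preserved; duplicate members are dropped with a warning.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidConfigError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields; >=3 required"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: gene set {name!r} contains duplicate "
                    "members; deduplicated"
                )
            sets.append(GeneSet(name, deduped))
    return sets


def write_gene_sets(path, genesets: list[GeneSet], description: str = "-") -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")


def load_dataset(
    expression_path,
    coordinates_path=None,
    regions_path=None,
    size_factors_path=None,
    fmt: str = "dense_tsv",
) -> SpatialDataset:
    """Assemble a :class:`SpatialDataset` from its on-disk pieces, aligning
    the coordinate/region/size tables to the expression spot order."""
    values, spot_ids, gene_ids = read_expression(expression_path, fmt)
    coords = None
    if coordinates_path is not None:
        cdf = read_coordinates(coordinates_path).set_index("spot_id")
        cdf = cdf.reindex(spot_ids.astype(str))
        if cdf[["x", "y"]].isna().any().any():
            missing = cdf.index[cdf["x"].isna()].tolist()[:5]
            raise InvalidConfigError(f"coordinates missing for spots {missing}")
        coords = cdf[["x", "y"]].to_numpy(dtype=float)
    if regions_path is not None:
        rdf = read_regions(regions_path).set_index("spot_id")
        rdf = rdf.reindex(spot_ids.astype(str))
        if rdf["region"].isna().any():
            missing = rdf.index[rdf["region"].isna()].tolist()[:5]
            raise InvalidConfigError(f"region labels missing for spots {missing}")
        labels = rdf["region"].to_numpy(dtype=object)
    else:
        labels = np.array(["all"] * len(spot_ids), dtype=object)
    sizes = None
    if size_factors_path is not None:
        sdf = read_size_factors(size_factors_path).set_index("spot_id")
        sizes = sdf.reindex(spot_ids.astype(str))["size_factor"].to_numpy(dtype=float)
    return SpatialDataset(
        expression=values,
        coordinates=coords,
        region_labels=labels,
        spot_ids=spot_ids,
        gene_ids=gene_ids,
        size_factors=sizes,
    )


def save_dataset(out_dir, dataset: SpatialDataset, fmt: str = "mtx_triplet") -> None:
    """Write a dataset as expression + coordinate/region/size sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx_triplet":
        write_expression(out, dataset.expression, dataset.spot_ids, dataset.gene_ids, fmt)
    else:
        write_expression(
            out / "expression.tsv", dataset.expression, dataset.spot_ids, dataset.gene_ids, fmt
        )
    if dataset.coordinates is not None:
        write_coordinates(out / "coordinates.tsv", dataset.spot_ids, dataset.coordinates)
    write_regions(out / "regions.tsv", dataset.spot_ids, dataset.region_labels)
    if dataset.size_factors is not None:
        write_size_factors(out / "size_factors.tsv", dataset.spot_ids, dataset.size_factors)


def write_results(path, table: pd.DataFrame) -> None:
    """Results TSV with p/q values formatted to 6 significant digits (the
    SMC resolution is bounded by 1/g, so more digits would be noise)."""
    out = table.copy()
    for col in ("p_value", "q_value", "statistic"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def write_run_metadata(path, **fields) -> None:
    """JSON metadata recording the exact configuration of a run (including
    defaulted values) so it is reproducible from the metadata alone."""
    import spotcorr

    payload = {"spotcorr_version": spotcorr.__version__}
    payload.update(fields)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
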