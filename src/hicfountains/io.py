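"""Readers and writers: dense TSV matrices, single-resolution .cool, BED.

The TSV contact-matrix dialect is a tab-separated square table whose header
row and first column both carry the bin start coordinates (bp).  The .cool
support is a minimal h5py implementation of the single-resolution cooler HDF5
schema (groups ``chroms``, ``bins``, ``pixels``), sufficient to exchange cis
maps with standard Hi-C tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .contact_data import ContactMap

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# -- dense TSV dialect -------------------------------------------------------

def write_tsv_matrix(path, matrix: np.ndarray, resolution: int) -> None:
    starts = np.arange(matrix.shape[0]) * resolution
    df = pd.DataFrame(matrix, index=starts, columns=starts)
    df.to_csv(path, sep="\t", index_label="start", float_format="%.8g")


def read_tsv_matrix(path) -> tuple[np.ndarray, int]:
    """Return (matrix, resolution) from the dense TSV dialect."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    starts = df.index.to_numpy(dtype=int)
    if len(starts) > 1:
        resolution = int(starts[1] - starts[0])
    else:
        resolution = int(starts[0]) if starts[0] > 0 else 1
    return df.to_numpy(dtype=float), resolution


def write_map_tsv(cmap: ContactMap, directory) -> None:
    """One ``<chrom>.tsv`` per chromosome plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for chrom in cmap.chromosomes:
        write_tsv_matrix(
            directory / f"{chrom}.tsv", cmap.counts[chrom], cmap.resolution
        )
    meta = {"resolution": cmap.resolution, "chromsizes": dict(cmap.chromsizes)}
    (directory / "map.json").write_text(json.dumps(meta, indent=1))


def read_map_tsv(directory) -> ContactMap:
    directory = Path(directory)
    meta = json.loads((directory / "map.json").read_text())
    counts = {}
    for chrom in meta["chromsizes"]:
        counts[chrom], _ = read_tsv_matrix(directory / f"{chrom}.tsv")
    return ContactMap(
        resolution=int(meta["resolution"]),
        chromsizes={c: int(v) for c, v in meta["chromsizes"].items()},
        counts=counts,
    )


# -- minimal single-resolution .cool -----------------------------------------

def read_cool(path) -> ContactMap:
    """Load the cis part of a single-resolution cooler file."""
    with h5py.File(path, "r") as h5:
        grp = h5["/"]
        if "bins" not in grp and "resolutions" in grp:
            raise ValueError(
                "multi-resolution (.mcool) files are not supported; "
                "pass a single-resolution .cool"
            )
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in grp["chroms/name"][:]
        ]
        lengths = grp["chroms/length"][:].astype(int)
        resolution = int(grp.attrs.get("bin-size", 0))
        bin_chrom = grp["bins/chrom"][:].astype(int)
        bin_start = grp["bins/start"][:].astype(int)
        if resolution == 0 and len(bin_start) > 1:
            resolution = int(np.diff(bin_start[bin_chrom == bin_chrom[0]]).max())
        weights = None
        if "weight" in grp["bins"]:
            weights_flat = grp["bins/weight"][:].astype(float)
            weights = {}
        bin1 = grp["pixels/bin1_id"][:].astype(np.int64)
        bin2 = grp["pixels/bin2_id"][:].astype(np.int64)
        count = grp["pixels/count"][:].astype(float)

    chromsizes = dict(zip(names, (int(x) for x in lengths)))
    offsets = {}
    off = 0
    counts = {}
    for name, length in chromsizes.items():
        n = -(-length // resolution)
        offsets[name] = (off, off + n)
        counts[name] = np.zeros((n, n))
        if weights is not None:
            weights[name] = weights_flat[off : off + n]
        off += n
    for name, (lo, hi) in offsets.items():
        sel = (bin1 >= lo) & (bin1 < hi) & (bin2 >= lo) & (bin2 < hi)
        i = bin1[sel] - lo
        j = bin2[sel] - lo
        mat = counts[name]
        mat[i, j] = count[sel]
        mat[j, i] = count[sel]
    return ContactMap(
        resolution=resolution,
        chromsizes=chromsizes,
        counts=counts,
        weights=weights,
    )


def write_cool(cmap: ContactMap, path) -> None:
    """Write upper-triangular cis pixels in the cooler single-resolution schema."""
    names = cmap.chromosomes
    lengths = [cmap.chromsizes[c] for c in names]
    bin_chrom, bin_start, bin_end, bin_weight = [], [], [], []
    for ci, chrom in enumerate(names):
        n = cmap.n_bins(chrom)
        starts = np.arange(n) * cmap.resolution
        bin_chrom.append(np.full(n, ci))
        bin_start.append(starts)
        bin_end.append(np.minimum(starts + cmap.resolution, lengths[ci]))
        if cmap.weights is not None:
            bin_weight.append(cmap.weights[chrom])
    b1, b2, cnt = [], [], []
    off = 0
    for chrom in names:
        mat = cmap.counts[chrom]
        iu, ju = np.nonzero(np.triu(mat))
        b1.append(iu + off)
        b2.append(ju + off)
        cnt.append(mat[iu, ju])
        off += cmap.n_bins(chrom)
    b1 = np.concatenate(b1) if b1 else np.array([], dtype=np.int64)
    b2 = np.concatenate(b2) if b2 else np.array([], dtype=np.int64)
    cnt = np.concatenate(cnt) if cnt else np.array([])
    order = np.lexsort((b2, b1))
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "HDF5::Cooler"
        h5.attrs["format-version"] = 3
        h5.attrs["bin-size"] = cmap.resolution
        h5.attrs["nbins"] = off
        h5.attrs["nchroms"] = len(names)
        h5.attrs["nnz"] = len(b1)
        h5.create_dataset(
            "chroms/name", data=np.array(names, dtype=h5py.string_dtype())
        )
        h5.create_dataset("chroms/length", data=np.array(lengths, dtype=np.int64))
        h5.create_dataset("bins/chrom", data=np.concatenate(bin_chrom))
        h5.create_dataset("bins/start", data=np.concatenate(bin_start))
        h5.create_dataset("bins/end", data=np.concatenate(bin_end))
        if bin_weight:
            h5.create_dataset("bins/weight", data=np.concatenate(bin_weight))
        h5.create_dataset("pixels/bin1_id", data=b1[order])
        h5.create_dataset("pixels/bin2_id", data=b2[order])
        h5.create_dataset("pixels/count", data=cnt[order])


def read_map(path) -> ContactMap:
    """Dispatch on extension: .cool file or TSV map directory."""
    path = Path(path)
    if path.is_dir():
        return read_map_tsv(path)
    return read_cool(path)


# -- BED ---------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column tab-separated BED file into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("BED requires at least 3 columns")
    df.columns = BED_COLUMNS[: df.shape[1]] + [
        f"col{i}" for i in range(6, df.shape[1])
    ]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any() or (df["start"] < 0).any():
        raise ValueError("BED intervals must satisfy 0 <= start < end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# -- pileup TSV + sidecar ----------------------------------------------------

def write_pileup(path, values: np.ndarray, meta: dict) -> None:
    np.savetxt(path, values, delimiter="\t", fmt="%.8g")
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_pileup(path) -> tuple[np.ndarray, dict]:
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return values, meta
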