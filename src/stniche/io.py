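"""Read spot-level data (spaceranger-style exports, GMT gene sets) and
normalize counts into the pipeline's data model."""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialDataset",
    "GeneSetCollection",
    "load_tenx",
    "log_normalize",
    "load_gmt",
]


@dataclass
class SpatialDataset:
    """Sparse gene x spot counts plus spot coordinates (micrometers).

    ``lognorm`` is filled by :func:`log_normalize`; ``zero_library`` flags
    spots whose total count is zero (their normalized row is all-zero).
    """

    counts: sparse.csr_matrix  # genes x spots, nonnegative integers
    coords: pd.DataFrame  # index = spot_id; columns x_um, y_um (+ array_row/col)
    spot_ids: list[str]
    gene_ids: list[str]
    lognorm: sparse.csr_matrix | None = None
    zero_library: np.ndarray | None = None
    norm_method: str | None = None
    _gene_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        if len(self.coords) != len(self.spot_ids):
            raise ValueError("coords length does not match number of spots")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    @property
    def xy(self) -> np.ndarray:
        """Spot centers as an (n_spots, 2) array of (x_um, y_um)."""
        return self.coords[["x_um", "y_um"]].to_numpy(float)

    def gene_row(self, gene: str, normalized: bool = False) -> np.ndarray:
        """Expression of one gene across spots (dense 1-D)."""
        try:
            i = self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in dataset") from None
        mat = self.lognorm if normalized else self.counts
        if mat is None:
            raise ValueError("dataset is not normalized; run log_normalize first")
        return np.asarray(mat[i].todense()).ravel()

    def genes_present(self, genes) -> list[str]:
        return [g for g in genes if g in self._gene_index]

    def gene_indices(self, genes) -> np.ndarray:
        return np.array([self._gene_index[g] for g in genes], dtype=int)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways or cell-type marker lists)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate gene ids")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(sorted(self.sets))

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_lines_maybe_gz(dirpath: Path, stem: str) -> list[str]:
    for name, opener in ((f"{stem}.tsv.gz", gzip.open), (f"{stem}.tsv", open)):
        p = dirpath / name
        if p.exists():
            with opener(p, "rt") as fh:
                return [ln.rstrip("\n") for ln in fh if ln.strip()]
    raise FileNotFoundError(f"missing {stem}.tsv[.gz] in {dirpath}")


def load_tenx(dirpath: str | Path) -> SpatialDataset:
    """Load a spaceranger-style export: ``matrix.mtx[.gz]``, barcode and
    feature lists, and a tissue-positions CSV with columns
    ``barcode,in_tissue,array_row,array_col,y_um,x_um``.

    Spots are restricted to ``in_tissue == 1`` and the count columns are
    reordered to match the positions file.
    """
    dirpath = Path(dirpath)
    mtx_path = next(
        (dirpath / n for n in ("matrix.mtx", "matrix.mtx.gz") if (dirpath / n).exists()),
        None,
    )
    if mtx_path is None:
        raise FileNotFoundError(f"no matrix.mtx[.gz] in {dirpath}")
    counts = sparse.csr_matrix(spio.mmread(mtx_path))

    barcodes = _read_lines_maybe_gz(dirpath, "barcodes")
    features = [ln.split("\t")[0] for ln in _read_lines_maybe_gz(dirpath, "features")]
    if counts.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix is {counts.shape} but feature/barcode lists give "
            f"{len(features)} x {len(barcodes)}"
        )
    if len(set(barcodes)) != len(barcodes):
        dup = pd.Series(barcodes).value_counts()
        raise ValueError(f"duplicate barcodes: {list(dup[dup > 1].index[:5])}")

    pos_path = next(
        (
            dirpath / n
            for n in ("tissue_positions.csv", "tissue_positions_list.csv")
            if (dirpath / n).exists()
        ),
        None,
    )
    if pos_path is None:
        raise FileNotFoundError(f"no tissue positions CSV in {dirpath}")
    pos = pd.read_csv(pos_path, comment="#")
    pos.columns = ["barcode", "in_tissue", "array_row", "array_col", "y_um", "x_um"]

    missing = set(barcodes) - set(pos["barcode"])
    if missing:
        raise ValueError(
            f"positions file is missing barcodes present in the matrix: "
            f"{sorted(missing)[:5]}"
        )

    pos = pos[pos["in_tissue"] == 1].reset_index(drop=True)
    col_of = {b: i for i, b in enumerate(barcodes)}
    order = [col_of[b] for b in pos["barcode"] if b in col_of]
    pos = pos[pos["barcode"].isin(col_of)].reset_index(drop=True)
    counts = sparse.csr_matrix(counts[:, order])

    coords = pos.set_index("barcode")[["x_um", "y_um", "array_row", "array_col"]]
    return SpatialDataset(
        counts=counts,
        coords=coords,
        spot_ids=list(pos["barcode"]),
        gene_ids=features,
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def log_normalize(dataset: SpatialDataset, scale: str = "median_total") -> SpatialDataset:
    """Per-spot library-size normalization followed by ``log(1 + x)``.

    ``scale`` is ``"median_total"`` (target = median library size over spots
    with nonzero totals, the common ST convention) or ``"fixed:C"`` for an
    explicit target ``C``. Spots with zero total count stay all-zero and are
    flagged in ``zero_library``. Fills ``dataset.lognorm`` in place and
    returns the dataset.
    """
    totals = np.asarray(dataset.counts.sum(axis=0)).ravel().astype(float)
    nonzero = totals > 0
    if not nonzero.any():
        raise ValueError("no spot has a positive total count")

    if scale == "median_total":
        target = float(np.median(totals[nonzero]))
    elif scale.startswith("fixed:"):
        target = float(scale.split(":", 1)[1])
        if target <= 0:
            raise ValueError("fixed scale target must be positive")
    else:
        raise ValueError(f"unknown scale {scale!r}")

    factors = np.zeros_like(totals)
    factors[nonzero] = target / totals[nonzero]
    norm = sparse.csr_matrix(dataset.counts, dtype=float)
    norm = norm @ sparse.diags(factors)
    norm.data = np.log1p(norm.data)
    dataset.lognorm = sparse.csr_matrix(norm)
    dataset.zero_library = ~nonzero
    dataset.norm_method = scale
    return dataset


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name <tab> description <tab> gene1 <tab> gene2...``

    Duplicate genes within a line are dropped with a warning; a line with
    fewer than three fields raises with its line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description, and at least one gene"
                )
            name = fields[0]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    warnings.warn(
                        f"{path}: line {lineno} ({name}): duplicate gene {g!r} "
                        "dropped"
                    )
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def save_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            genes = "\t".join(collection[name])
            fh.write(f"{name}\t{collection.source or 'stniche'}\t{genes}\n")
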