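"""Synthetic Visium-like tissue generator with known ground truth.

Emulates a 6.5 x 6.5 mm capture area of 5000 spots (55 um diameter, 100 um
center-to-center) whose counts mix cell-type expression profiles, with
optional planted gene-set hotspots, distance-decay gradient genes, and
Bernoulli dropout. Every planted feature is serialized alongside the counts
so downstream statistics can be scored against truth.

Counts for spot ``s``, gene ``g`` are Poisson with mean::

    mu[s, g] = (sum_t prop[s, t] * gene_means[t, g])
               * hotspot_multiplier   (if g in a planted set and s in its region)
               * exp(-decay * d(s))   (if g is a gradient gene; d = mean
                                       distance of s to the reference niche)

then thinned entrywise by an independent Bernoulli dropout.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.spatial.distance import cdist

__all__ = [
    "ArraySpec",
    "CellTypeProfile",
    "GroundTruth",
    "HotspotRegion",
    "GradientGene",
    "make_array",
    "simulate_tissue",
    "export_tenx",
    "load_ground_truth",
    "demo_profiles",
    "banded_proportions",
    "disc_region",
]

#: Permitted overhang of the lattice beyond the nominal frame, in row pitches.
#: The printed array figures (5000 spots, exact 100 um spacing, 6.5 mm frame)
#: are jointly infeasible by the hexagonal packing bound; the spot count and
#: the exact spacing take precedence and boundary rows may overhang the frame
#: by at most this many pitches before the request is rejected.
_FRAME_TOLERANCE_PITCHES = 1.0


@dataclass(frozen=True)
class ArraySpec:
    """Geometry of the capture array, all lengths in micrometers."""

    width_um: float = 6500.0
    height_um: float = 6500.0
    spot_diameter_um: float = 55.0
    center_spacing_um: float = 100.0
    n_spots: int = 5000

    def validate(self) -> None:
        if self.n_spots <= 0:
            raise ValueError("n_spots must be positive")
        if not (self.center_spacing_um > self.spot_diameter_um > 0):
            raise ValueError(
                "require center_spacing_um > spot_diameter_um > 0, got "
                f"{self.center_spacing_um} and {self.spot_diameter_um}"
            )
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("capture area dimensions must be positive")


@dataclass(frozen=True)
class CellTypeProfile:
    """Expected counts per gene for one cell type."""

    cell_type: str
    gene_means: np.ndarray  # nonnegative, one entry per gene

    def validate(self, n_genes: int | None = None) -> None:
        means = np.asarray(self.gene_means, dtype=float)
        if means.ndim != 1 or (n_genes is not None and means.size != n_genes):
            raise ValueError(f"profile {self.cell_type}: bad gene_means shape")
        if np.any(means < 0) or not np.any(means > 0):
            raise ValueError(
                f"profile {self.cell_type}: means must be nonnegative with at "
                "least one positive entry"
            )


@dataclass(frozen=True)
class HotspotRegion:
    gene_set: str
    genes: tuple[str, ...]
    spots: tuple[int, ...]  # positional spot indices
    multiplier: float

    def validate(self) -> None:
        if self.multiplier <= 1:
            raise ValueError(
                f"hotspot {self.gene_set}: effect multiplier must be > 1"
            )


@dataclass(frozen=True)
class GradientGene:
    gene: str
    reference_niche: str
    decay_per_um: float  # expression mean decays as exp(-decay * distance)
    baseline: float  # expected count at distance 0

    def validate(self) -> None:
        if not math.isfinite(self.decay_per_um):
            raise ValueError(f"gradient gene {self.gene}: decay must be finite")
        if self.baseline < 0:
            raise ValueError(f"gradient gene {self.gene}: negative baseline")


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring downstream statistics.

    ``niche_spots`` maps a niche label (e.g. "stroma") to the positional spot
    indices that constitute it; gradient genes reference these labels.
    """

    spot_cell_proportions: np.ndarray  # spots x cell types, rows sum to 1
    cell_types: tuple[str, ...] = ()
    hotspot_regions: list[HotspotRegion] = field(default_factory=list)
    gradient_genes: list[GradientGene] = field(default_factory=list)
    niche_spots: dict[str, np.ndarray] = field(default_factory=dict)
    dropout_rate: float = 0.0

    def validate(self) -> None:
        props = np.asarray(self.spot_cell_proportions, dtype=float)
        if props.ndim != 2:
            raise ValueError("spot_cell_proportions must be 2-D")
        if np.any(props < 0) or np.any(np.abs(props.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("proportion rows must be nonnegative and sum to 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate {self.dropout_rate} outside [0, 1]")
        for h in self.hotspot_regions:
            h.validate()
        for g in self.gradient_genes:
            g.validate()
        for label, idx in self.niche_spots.items():
            if np.asarray(idx).size == 0:
                raise ValueError(f"niche {label!r} has no spots")

    @property
    def dominant_type(self) -> np.ndarray:
        """Per-spot index of the most abundant planted cell type."""
        return np.asarray(self.spot_cell_proportions).argmax(axis=1)


# ---------------------------------------------------------------------------
# Array geometry
# ---------------------------------------------------------------------------


def _layout_pitch(spacing: float, layout: str) -> tuple[float, float]:
    if layout == "hex":
        return spacing, spacing * math.sqrt(3.0) / 2.0
    if layout == "square":
        return spacing, spacing
    raise ValueError(f"unknown layout {layout!r}; choose 'hex' or 'square'")


def _row_capacity(n_cols: int, row: int, spec: ArraySpec, layout: str) -> int:
    # Offset (odd) hex rows are shifted by half a spacing; drop the last spot
    # if the shifted row would overhang the frame more than allowed.
    if layout == "hex" and row % 2 == 1:
        span = (n_cols - 1) * spec.center_spacing_um + spec.center_spacing_um / 2
        if span > spec.width_um + 1e-9:
            return n_cols - 1
    return n_cols


def make_array(
    spec: ArraySpec = ArraySpec(),
    layout: Literal["hex", "square"] = "hex",
) -> pd.DataFrame:
    """Place ``spec.n_spots`` spot centers on a regular lattice.

    Builds the smallest centered block of a ``layout`` lattice at exactly
    ``center_spacing_um`` pitch that holds the requested count, then trims
    surplus positions farthest from the block center (deterministically), so
    interior nearest-neighbor distances equal the pitch exactly.

    Returns a DataFrame with columns ``spot_id, array_row, array_col, x_um,
    y_um`` (micrometers, origin at the top-left, y increasing downward).
    """
    spec.validate()
    s = spec.center_spacing_um
    dx, dy = _layout_pitch(s, layout)

    if spec.n_spots == 1:
        return pd.DataFrame(
            {
                "spot_id": ["S00000"],
                "array_row": [0],
                "array_col": [0],
                "x_um": [spec.width_um / 2.0],
                "y_um": [spec.height_um / 2.0],
            }
        )

    max_cols = int(math.floor(spec.width_um / dx + 1e-9)) + 1
    max_rows = int(
        math.floor((spec.height_um + _FRAME_TOLERANCE_PITCHES * dy) / dy + 1e-9)
    ) + 1

    def capacity(n_rows: int, n_cols: int) -> int:
        return sum(
            _row_capacity(n_cols, r, spec, layout) for r in range(n_rows)
        )

    max_feasible = capacity(max_rows, max_cols)
    if spec.n_spots > max_feasible:
        raise ValueError(
            f"cannot place {spec.n_spots} spots at {s} um spacing inside "
            f"{spec.width_um} x {spec.height_um} um; maximum feasible count "
            f"is {max_feasible}"
        )

    # Aim for a block whose aspect matches the lattice pitch ratio.
    n_cols = min(max_cols, max(1, math.ceil(math.sqrt(spec.n_spots * dy / dx))))
    n_rows = 1
    while capacity(n_rows, n_cols) < spec.n_spots:
        n_rows += 1
        if n_rows > max_rows and n_cols < max_cols:
            n_cols = max_cols
            n_rows = 1

    rows_list: list[int] = []
    cols_list: list[int] = []
    for r in range(n_rows):
        for c in range(_row_capacity(n_cols, r, spec, layout)):
            rows_list.append(r)
            cols_list.append(c)
    rows = np.array(rows_list)
    cols = np.array(cols_list)

    x = cols * dx + np.where(
        (layout == "hex") & (rows % 2 == 1), dx / 2.0, 0.0
    )
    y = rows * dy

    # Trim surplus positions farthest from the block centroid; deterministic
    # tie-break on (row, col).
    surplus = len(rows) - spec.n_spots
    if surplus > 0:
        cx, cy = x.mean(), y.mean()
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        order = np.lexsort((cols, rows, -d2))  # farthest first
        keep = np.ones(len(rows), dtype=bool)
        keep[order[:surplus]] = False
        rows, cols, x, y = rows[keep], cols[keep], x[keep], y[keep]

    # Center the block in the frame, clamping to nonnegative coordinates.
    x = x + max(0.0, (spec.width_um - x.max()) / 2.0)
    y = y + max(0.0, (spec.height_um - y.max()) / 2.0)

    array_col = 2 * cols + rows % 2 if layout == "hex" else cols
    return pd.DataFrame(
        {
            "spot_id": [f"S{i:05d}" for i in range(len(rows))],
            "array_row": rows.astype(int),
            "array_col": array_col.astype(int),
            "x_um": x,
            "y_um": y,
        }
    )


# ---------------------------------------------------------------------------
# Tissue simulation
# ---------------------------------------------------------------------------


def _gene_index(gene_ids: Sequence[str]) -> dict[str, int]:
    return {g: i for i, g in enumerate(gene_ids)}


def expected_means(
    coords: pd.DataFrame,
    truth: GroundTruth,
    profiles: Sequence[CellTypeProfile],
    gene_ids: Sequence[str],
) -> np.ndarray:
    """The planted Poisson mean matrix (spots x genes), before dropout."""
    props = np.asarray(truth.spot_cell_proportions, dtype=float)
    means_by_type = np.stack([np.asarray(p.gene_means, float) for p in profiles])
    mu = props @ means_by_type  # spots x genes
    gidx = _gene_index(gene_ids)

    for region in truth.hotspot_regions:
        spot_idx = np.asarray(region.spots, dtype=int)
        gene_idx = [gidx[g] for g in region.genes if g in gidx]
        mu[np.ix_(spot_idx, gene_idx)] *= region.multiplier

    xy = coords[["x_um", "y_um"]].to_numpy(float)
    for gg in truth.gradient_genes:
        if gg.gene not in gidx:
            continue
        ref = np.asarray(truth.niche_spots[gg.reference_niche], dtype=int)
        d = cdist(xy, xy[ref]).mean(axis=1)
        mu[:, gidx[gg.gene]] *= np.exp(-gg.decay_per_um * d)
    return mu


def simulate_tissue(
    coords: pd.DataFrame,
    truth: GroundTruth,
    profiles: Sequence[CellTypeProfile],
    gene_ids: Sequence[str],
    seed: int,
):
    """Draw a count matrix from the planted model. Same seed, same dataset.

    Gradient genes have their profile means overridden with the planted
    baseline, so their expected count is ``baseline * exp(-decay * d)``.

    Returns ``(dataset, truth)`` where dataset is an :class:`~stniche.io.SpatialDataset`.
    """
    from .io import SpatialDataset  # local import to avoid a cycle

    if len(profiles) == 0:
        raise ValueError("at least one cell-type profile is required")
    n_genes = len(gene_ids)
    for p in profiles:
        p.validate(n_genes)
    seen: set[bytes] = set()
    for p in profiles:
        key = np.asarray(p.gene_means, float).tobytes()
        if key in seen:
            raise ValueError("profiles for distinct cell types are identical")
        seen.add(key)
    truth.validate()
    n_spots = len(coords)
    props = np.asarray(truth.spot_cell_proportions, dtype=float)
    if props.shape != (n_spots, len(profiles)):
        raise ValueError(
            f"proportions shape {props.shape} does not match "
            f"{n_spots} spots x {len(profiles)} profiles"
        )
    for region in truth.hotspot_regions:
        if np.any(np.asarray(region.spots) >= n_spots):
            raise ValueError(f"hotspot {region.gene_set}: spot index out of range")

    gidx = _gene_index(gene_ids)
    profiles = [
        CellTypeProfile(p.cell_type, np.asarray(p.gene_means, float).copy())
        for p in profiles
    ]
    for gg in truth.gradient_genes:
        if gg.gene in gidx:
            for p in profiles:
                p.gene_means[gidx[gg.gene]] = gg.baseline

    mu = expected_means(coords, truth, profiles, gene_ids)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu)
    if truth.dropout_rate > 0:
        keep = rng.random(counts.shape) >= truth.dropout_rate
        counts = counts * keep

    keep_cols = [
        c for c in ("x_um", "y_um", "array_row", "array_col") if c in coords
    ]
    dataset = SpatialDataset(
        counts=sparse.csr_matrix(counts.T),  # genes x spots
        coords=coords.set_index("spot_id")[keep_cols].copy(),
        spot_ids=list(coords["spot_id"]),
        gene_ids=list(gene_ids),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# 10x-style export
# ---------------------------------------------------------------------------

_POSITIONS_HEADER = (
    "# coordinates in micrometers, origin at array top-left, y increasing "
    "downward (image convention)\n"
)


def _write_gz_lines(path: Path, lines: Sequence[str]) -> None:
    # mtime=0 keeps gzip output byte-identical across runs
    with gzip.GzipFile(path, "wb", mtime=0) as fh:
        fh.write("".join(lines).encode())


def export_tenx(dataset, truth: GroundTruth | None, outdir: str | Path) -> Path:
    """Write spaceranger-style files: ``matrix.mtx`` + gzipped barcode and
    feature lists + ``tissue_positions.csv`` (+ ``ground_truth.json``)."""
    if dataset.n_spots == 0 or dataset.n_genes == 0:
        raise ValueError("refusing to export an empty dataset")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spio.mmwrite(
        outdir / "matrix.mtx",
        sparse.coo_matrix(dataset.counts).astype(int),
        field="integer",
    )
    _write_gz_lines(outdir / "barcodes.tsv.gz", [f"{b}\n" for b in dataset.spot_ids])
    _write_gz_lines(
        outdir / "features.tsv.gz",
        [f"{g}\t{g}\tGene Expression\n" for g in dataset.gene_ids],
    )
    co = dataset.coords
    ar = co["array_row"] if "array_row" in co else pd.Series(0, index=co.index)
    ac = co["array_col"] if "array_col" in co else pd.Series(0, index=co.index)
    with open(outdir / "tissue_positions.csv", "w") as fh:
        fh.write(_POSITIONS_HEADER)
        fh.write("barcode,in_tissue,array_row,array_col,y_um,x_um\n")
        for b in dataset.spot_ids:
            # repr gives the shortest digit string that round-trips the float
            fh.write(
                f"{b},1,{int(ar[b])},{int(ac[b])},"
                f"{float(co.at[b, 'y_um'])!r},{float(co.at[b, 'x_um'])!r}\n"
            )
    if truth is not None:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(_truth_to_json(truth), fh, indent=1)
    return outdir


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "spot_cell_proportions": np.asarray(
            truth.spot_cell_proportions
        ).tolist(),
        "cell_types": list(truth.cell_types),
        "hotspot_regions": [
            {
                "gene_set": h.gene_set,
                "genes": list(h.genes),
                "spots": [int(i) for i in h.spots],
                "multiplier": h.multiplier,
            }
            for h in truth.hotspot_regions
        ],
        "gradient_genes": [
            {
                "gene": g.gene,
                "reference_niche": g.reference_niche,
                "decay_per_um": g.decay_per_um,
                "baseline": g.baseline,
            }
            for g in truth.gradient_genes
        ],
        "niche_spots": {
            k: [int(i) for i in v] for k, v in truth.niche_spots.items()
        },
        "dropout_rate": truth.dropout_rate,
    }


def load_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        obj = json.load(fh)
    return GroundTruth(
        spot_cell_proportions=np.asarray(obj["spot_cell_proportions"], float),
        cell_types=tuple(obj["cell_types"]),
        hotspot_regions=[
            HotspotRegion(
                h["gene_set"], tuple(h["genes"]), tuple(h["spots"]), h["multiplier"]
            )
            for h in obj["hotspot_regions"]
        ],
        gradient_genes=[
            GradientGene(
                g["gene"], g["reference_niche"], g["decay_per_um"], g["baseline"]
            )
            for g in obj["gradient_genes"]
        ],
        niche_spots={k: np.asarray(v, int) for k, v in obj["niche_spots"].items()},
        dropout_rate=obj["dropout_rate"],
    )


# ---------------------------------------------------------------------------
# Study-condition builders
# ---------------------------------------------------------------------------


def demo_profiles(
    n_genes: int = 90,
    cell_types: Sequence[str] = ("melanoma", "fibroblast", "B cell"),
    n_markers: int = 12,
    base_mean: float = 1.0,
    marker_fold: float = 8.0,
    seed: int = 0,
) -> tuple[list[CellTypeProfile], list[str], dict[str, list[str]]]:
    """Well-separated cell-type profiles: each type elevates its own block of
    ``n_markers`` marker genes ``marker_fold``-fold over the shared baseline.

    Returns ``(profiles, gene_ids, marker_sets)`` where marker_sets maps each
    cell type to its marker gene ids (usable as a GMT bundle).
    """
    if n_genes < n_markers * len(cell_types):
        raise ValueError("not enough genes for the requested marker blocks")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    profiles = []
    marker_sets: dict[str, list[str]] = {}
    for t, ct in enumerate(cell_types):
        means = base_mean * rng.uniform(0.5, 1.5, size=n_genes)
        block = slice(t * n_markers, (t + 1) * n_markers)
        means[block] *= marker_fold
        profiles.append(CellTypeProfile(ct, means))
        marker_sets[ct] = gene_ids[block]
    return profiles, gene_ids, marker_sets


def banded_proportions(
    coords: pd.DataFrame,
    n_types: int,
    purity: float = 0.9,
    axis: str = "x_um",
) -> tuple[np.ndarray, np.ndarray]:
    """Split the tissue into ``n_types`` vertical (or horizontal) bands; spots
    in band ``t`` get proportion ``purity`` of type ``t`` and share the rest.

    Returns ``(proportions, band_of_spot)``.
    """
    if not 1.0 / n_types <= purity <= 1.0:
        raise ValueError("purity must dominate the uniform share")
    v = coords[axis].to_numpy(float)
    edges = np.quantile(v, np.linspace(0, 1, n_types + 1))
    band = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_types - 1)
    props = np.full((len(v), n_types), (1.0 - purity) / max(n_types - 1, 1))
    props[np.arange(len(v)), band] = purity if n_types > 1 else 1.0
    return props, band


def constant_proportions(n_spots: int, weights: Sequence[float]) -> np.ndarray:
    """Spatially constant mixture: every spot shares the same proportions."""
    w = np.asarray(weights, float)
    return np.tile(w / w.sum(), (n_spots, 1))


def demo_tissue(seed: int = 0, spec: ArraySpec | None = None, dropout_rate: float = 0.1):
    """A small, fully-planted demonstration tissue.

    Three banded cell types (melanoma | fibroblast | B cell) at 0.9 purity,
    one planted 25-spot hotspot (multiplier 5) inside the stroma band, and
    three distance-decay genes referenced to the stroma band.

    Returns ``(dataset, truth, markers, pathways)`` where markers is the
    cell-type marker GeneSetCollection and pathways the gene sets for
    hotspot testing (the planted set plus two unplanted ones).
    """
    from .io import GeneSetCollection

    if spec is None:
        spec = ArraySpec(width_um=2200.0, height_um=2200.0, n_spots=450)
    coords = make_array(spec, layout="hex")
    cell_types = ("melanoma", "fibroblast", "B cell")
    profiles, gene_ids, marker_sets = demo_profiles(
        n_genes=80, cell_types=cell_types, n_markers=12, seed=seed
    )
    props, band = banded_proportions(coords, len(cell_types), purity=0.9)
    niche_spots = {
        "tumor": np.flatnonzero(band == 0),
        "stroma": np.flatnonzero(band == 1),
        "immune": np.flatnonzero(band == 2),
    }
    stroma_xy = coords.loc[niche_spots["stroma"], ["x_um", "y_um"]].mean()
    hotspot = HotspotRegion(
        gene_set="planted_hotspot",
        genes=tuple(gene_ids[40:60]),
        spots=tuple(
            int(i)
            for i in disc_region(coords, (stroma_xy["x_um"], stroma_xy["y_um"]), 25)
        ),
        multiplier=5.0,
    )
    gradients = [
        GradientGene(g, "stroma", 1e-3, 5.0) for g in gene_ids[60:63]
    ]
    truth = GroundTruth(
        spot_cell_proportions=props,
        cell_types=cell_types,
        hotspot_regions=[hotspot],
        gradient_genes=gradients,
        niche_spots=niche_spots,
        dropout_rate=dropout_rate,
    )
    dataset, truth = simulate_tissue(coords, truth, profiles, gene_ids, seed=seed)
    markers = GeneSetCollection(dict(marker_sets), source="demo markers")
    # fibroblast_markers is a deliberate true positive: banded cell types
    # are spatially contiguous, so their marker sets aggregate; the null
    # sets draw only from unstructured background genes
    pathways = GeneSetCollection(
        {
            "planted_hotspot": list(hotspot.genes),
            "fibroblast_markers": list(marker_sets["fibroblast"]),
            "null_set_A": gene_ids[63:73],
            "null_set_B": gene_ids[36:40] + gene_ids[73:79],
        },
        source="demo pathways",
    )
    return dataset, truth, markers, pathways


def disc_region(
    coords: pd.DataFrame, center_xy: tuple[float, float], n_spots: int
) -> np.ndarray:
    """Positional indices of the ``n_spots`` spots nearest to ``center_xy``."""
    xy = coords[["x_um", "y_um"]].to_numpy(float)
    d = np.hypot(xy[:, 0] - center_xy[0], xy[:, 1] - center_xy[1])
    return np.argsort(d, kind="stable")[:n_spots]
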