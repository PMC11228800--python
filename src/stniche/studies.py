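"""Desk-scale benchmark studies on synthetic tissues with known truth.

Each function generates its own data, runs one pipeline stage, and scores
the result against the planted ground truth. The conditions (tissue sizes,
panel sizes, effect sizes, noise) are fixed study designs, documented in
docs/methods.md; the seed is the only free input.

Why these shapes:

* Hotspot power is evaluated on the full 5000-spot array with a planted
  20-spot disc at multiplier 5 — a 0.4% lesion. The mean + 1 sd high-spot
  rule only isolates such a small lesion when the per-spot set score is
  tight, so the planted set is KEGG-sized (100 genes) over a well-expressed
  2500-gene panel.
* Null calibration uses a 1000-spot tissue with 200 disjoint 10-gene sets
  and heavy dropout: p-value uniformity under the null does not depend on
  expression level, so the cheaper tissue buys 200 independent tests.
* Gradient recovery plants the weakest decay the pipeline is expected to
  flag (5e-4 per um) among 200 genes on an 800-spot tissue.
* Topic recovery uses a 450-spot, 80-gene, 3-type banded tissue and a
  K = 2..7 grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from . import deconvolve, niches, stenrich, stgradient, synth
from .io import GeneSetCollection, log_normalize
from .niches import NicheLabels

__all__ = [
    "array_fidelity",
    "exhaustive_oracle_gap",
    "stenrich_calibration",
    "stenrich_power",
    "gradient_recovery",
    "noise_free_gradient_rho",
    "k_selection_study",
]


def _child_seeds(seed: int, n: int, tag: str) -> list[int]:
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(tag.encode())])
    return [int(s % (2**31)) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Array
# ---------------------------------------------------------------------------


def array_fidelity() -> dict:
    """Spot count, nearest-neighbor spacing, and diameter of the default
    array, measured from the generated coordinates."""
    spec = synth.ArraySpec()
    coords = synth.make_array(spec, layout="hex")
    xy = coords[["x_um", "y_um"]].to_numpy()
    from scipy.spatial import cKDTree

    d, _ = cKDTree(xy).query(xy, k=2)
    nn = d[:, 1]
    return {
        "n_spots": len(coords),
        "nn_spacing_um": float(np.median(nn)),
        "nn_spacing_max_abs_dev_um": float(np.abs(nn - spec.center_spacing_um).max()),
        "spot_diameter_um": spec.spot_diameter_um,
    }


# ---------------------------------------------------------------------------
# STenrich
# ---------------------------------------------------------------------------


def _truth_labels(spot_ids, labels) -> NicheLabels:
    table = pd.DataFrame(
        {
            "spot_id": list(spot_ids),
            "label": list(labels),
            "dominant_type": "truth",
            "dominant_prop": 1.0,
            "rule": "ground truth",
        }
    ).set_index("spot_id")
    return NicheLabels(table)


def exhaustive_oracle_gap(seed: int = 0, n_spots: int = 12) -> float:
    """Max |exhaustive permutation p - combinatorial tail| on a small
    random tissue (the tail is re-enumerated here, independently)."""
    rng = np.random.default_rng(seed)
    coords = synth.make_array(
        synth.ArraySpec(width_um=400, height_um=400, n_spots=n_spots)
    )
    gene_ids = ["s0"]
    profile = synth.CellTypeProfile("t", np.array([3.0]))
    high_idx = rng.choice(n_spots, size=3, replace=False)
    counts = np.ones((1, n_spots), dtype=int)
    counts[0, high_idx] = 60

    from .io import SpatialDataset
    from scipy import sparse

    ds = SpatialDataset(
        counts=sparse.csr_matrix(counts),
        coords=coords.set_index("spot_id")[["x_um", "y_um"]],
        spot_ids=list(coords["spot_id"]),
        gene_ids=gene_ids,
    )
    ds.lognorm = sparse.csr_matrix(np.log1p(counts.astype(float)))

    res = stenrich.hotspot_test(ds, gene_ids, min_high_spots=3, exhaustive=True)
    xy = ds.xy
    sums = np.array(
        [pdist(xy[list(idx)]).sum() for idx in combinations(range(n_spots), 3)]
    )
    tail = float((sums <= res.observed_sum).mean())
    return abs(res.p_value - tail)


def _flat_panel(n_genes: int, mean: float, rng: np.random.Generator):
    means = rng.gamma(shape=4.0, scale=mean / 4.0, size=n_genes)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    return synth.CellTypeProfile("tissue", means), gene_ids


def stenrich_calibration(
    seed: int,
    n_sets: int = 200,
    genes_per_set: int = 10,
    n_spots: int = 1000,
    n_perm: int = 999,
    dropout_rate: float = 0.2,
) -> dict:
    """Fraction of null gene sets at p < 0.05 on a tissue with no spatial
    structure, with the binomial 99% band the fraction should fall in."""
    rng = np.random.default_rng(seed)
    coords = synth.make_array(
        synth.ArraySpec(width_um=3200, height_um=3200, n_spots=n_spots)
    )
    profile, gene_ids = _flat_panel(n_sets * genes_per_set, 5.0, rng)
    truth = synth.GroundTruth(
        synth.constant_proportions(n_spots, [1.0]),
        ("tissue",),
        dropout_rate=dropout_rate,
    )
    ds, _ = synth.simulate_tissue(coords, truth, [profile], gene_ids, seed=seed)
    log_normalize(ds)
    coll = GeneSetCollection(
        {
            f"NULL{j:03d}": gene_ids[j * genes_per_set : (j + 1) * genes_per_set]
            for j in range(n_sets)
        }
    )
    tab = stenrich.run_gene_sets(ds, coll, n_perm=n_perm, seed=seed)
    tested = tab[tab["status"] == "tested"]
    frac = float((tested["p"] < 0.05).mean())
    half_width = 2.576 * np.sqrt(0.05 * 0.95 / len(tested))
    return {
        "fraction_p_lt_05": frac,
        "n_sets_tested": int(len(tested)),
        "binomial_99_low": 0.05 - half_width,
        "binomial_99_high": 0.05 + half_width,
    }


def stenrich_power(
    seed: int,
    n_seeds: int = 20,
    hotspot_spots: int = 20,
    multiplier: float = 5.0,
    set_size: int = 100,
    panel_size: int = 2500,
    n_perm: int = 1000,
) -> dict:
    """Detection rate (p < 0.05) for a planted disc hotspot on the default
    5000-spot array, across independent simulation seeds."""
    coords = synth.make_array()
    rng = np.random.default_rng(seed)
    profile, gene_ids = _flat_panel(panel_size, 8.0, rng)
    set_genes = tuple(gene_ids[:set_size])
    region = tuple(
        int(i) for i in synth.disc_region(coords, (2000.0, 4500.0), hotspot_spots)
    )
    props = synth.constant_proportions(len(coords), [1.0])
    detected = 0
    for child in _child_seeds(seed, n_seeds, "stenrich_power"):
        truth = synth.GroundTruth(
            props,
            ("tissue",),
            hotspot_regions=[
                synth.HotspotRegion("planted", set_genes, region, multiplier)
            ],
        )
        ds, _ = synth.simulate_tissue(coords, truth, [profile], gene_ids, seed=child)
        log_normalize(ds)
        res = stenrich.hotspot_test(
            ds, list(set_genes), n_perm=n_perm, seed=child, set_name="planted"
        )
        detected += int(res.tested and res.p_value < 0.05)
    return {"detection_rate": detected / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# STgradient
# ---------------------------------------------------------------------------


def _gradient_tissue(seed: int, decay: float, n_spots: int = 800, n_genes: int = 200):
    rng = np.random.default_rng(seed)
    coords = synth.make_array(
        synth.ArraySpec(width_um=2800, height_um=2800, n_spots=n_spots)
    )
    profile, gene_ids = _flat_panel(n_genes, 5.0, rng)
    xs = coords["x_um"].to_numpy()
    stroma_idx = np.flatnonzero(xs <= np.quantile(xs, 0.3))
    planted = [synth.GradientGene(g, "stroma", decay, 5.0) for g in gene_ids[:5]]
    truth = synth.GroundTruth(
        synth.constant_proportions(n_spots, [1.0]),
        ("tissue",),
        gradient_genes=planted,
        niche_spots={"stroma": stroma_idx},
        dropout_rate=0.1,
    )
    labels = _truth_labels(
        coords["spot_id"],
        np.where(np.isin(np.arange(n_spots), stroma_idx), "stroma", "tumor"),
    )
    return coords, truth, profile, gene_ids, labels, planted


def gradient_recovery(
    seed: int, n_seeds: int = 10, decay: float = 5e-4
) -> dict:
    """Fraction of seeds where every planted decay gene is negative and in
    the top decile by |rho|."""
    coords, truth, profile, gene_ids, labels, planted = _gradient_tissue(seed, decay)
    top_n = len(gene_ids) // 10
    hits = 0
    for child in _child_seeds(seed, n_seeds, "gradient_recovery"):
        ds, _ = synth.simulate_tissue(coords, truth, [profile], gene_ids, seed=child)
        log_normalize(ds)
        tab = stgradient.gradient_test(ds, labels, "stroma")
        tab["abs_rho"] = tab["rho"].abs()
        top = set(tab.nlargest(top_n, "abs_rho")["gene"])
        pl = tab[tab["gene"].isin([g.gene for g in planted])]
        hits += int(set(pl["gene"]) <= top and (pl["rho"] < 0).all())
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds}


def noise_free_gradient_rho() -> float:
    """Spearman rho for a deterministic monotone decay: must be exactly -1.

    Spots are in generic position (continuous random coordinates): a
    symmetric lattice produces floating-point near-ties in the mean
    distances that the exponential collapses into exact expression ties,
    breaking the rank bijection for reasons that have nothing to do with
    the statistic.
    """
    from scipy import sparse

    from .io import SpatialDataset

    n = 40
    rng = np.random.default_rng(12345)
    coords = pd.DataFrame(
        {
            "spot_id": [f"S{i:05d}" for i in range(n)],
            "x_um": rng.uniform(0, 900, n),
            "y_um": rng.uniform(0, 900, n),
        }
    )
    labels = _truth_labels(
        coords["spot_id"], ["stroma"] * 5 + ["tumor"] * (n - 5)
    )
    ds = SpatialDataset(
        counts=sparse.csr_matrix(np.ones((1, n), dtype=int)),
        coords=coords.set_index("spot_id")[["x_um", "y_um"]],
        spot_ids=list(coords["spot_id"]),
        gene_ids=["decay_gene"],
    )
    d = niches.niche_distance(ds.coords, labels, "stroma")
    expr = np.ones(n)
    order = {s: i for i, s in enumerate(ds.spot_ids)}
    for s, dist in d.items():
        expr[order[s]] = np.exp(-0.001 * dist)
    ds.lognorm = sparse.csr_matrix(expr[None, :])
    tab = stgradient.gradient_test(ds, labels, "stroma", min_spots=5)
    return float(tab.loc[0, "rho"])


# ---------------------------------------------------------------------------
# Deconvolution + niches
# ---------------------------------------------------------------------------


@dataclass
class KSelectionResult:
    k3_selection_rate: float
    pure_spot_niche_accuracy: float
    n_seeds: int


def k_selection_study(
    seed: int,
    n_seeds: int = 10,
    n_spots: int = 450,
    n_genes: int = 80,
    purity: float = 0.9,
    k_grid=range(2, 8),
) -> KSelectionResult:
    """Three banded cell types: how often the lexicographic rule picks
    K = 3, and whether niche labels on the selection seed's fit match the
    planted compartments for every spot with true dominant share >= 0.9."""
    coords = synth.make_array(
        synth.ArraySpec(width_um=2200, height_um=2200, n_spots=n_spots)
    )
    cell_types = ("melanoma", "fibroblast", "B cell")
    profiles, gene_ids, marker_sets = synth.demo_profiles(
        n_genes=n_genes, cell_types=cell_types, n_markers=12, seed=seed
    )
    props, band = synth.banded_proportions(coords, 3, purity=purity)
    truth = synth.GroundTruth(props, cell_types, dropout_rate=0.1)
    markers = GeneSetCollection(dict(marker_sets))
    # planted compartments: melanoma band -> tumor, fibroblast -> stroma,
    # B cell -> immune
    truth_niche = np.array(["tumor", "stroma", "immune"], dtype=object)[band]

    chosen, acc = [], []
    for child in _child_seeds(seed, n_seeds, "k_selection"):
        ds, _ = synth.simulate_tissue(coords, truth, profiles, gene_ids, seed=child)
        log_normalize(ds)
        fits = [
            deconvolve.fit_topics(ds, K, seed=child, max_iter=20) for K in k_grid
        ]
        k, _report = deconvolve.select_K(fits)
        chosen.append(k)
        # niches come from the selected model, as in the pipeline; topics
        # sharing an annotation label are pooled by assign_niches
        fit = next(f for f in fits if f.K == k)
        ann = deconvolve.annotate_topics(fit, markers)
        labels = niches.assign_niches(fit, ann, ds.spot_ids)
        pure = props.max(axis=1) >= 0.9
        agree = labels.labels.to_numpy()[pure] == truth_niche[pure]
        acc.append(float(agree.mean()))
    return KSelectionResult(
        k3_selection_rate=float(np.mean([k == 3 for k in chosen])),
        pure_spot_niche_accuracy=float(np.mean(acc)),
        n_seeds=n_seeds,
    )
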