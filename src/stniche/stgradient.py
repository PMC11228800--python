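"""Expression gradients versus distance to a reference tissue niche.

For every spot outside the reference niche, its mean Euclidean distance to
the reference spots is computed; a gene shows a gradient when its
log-normalized expression correlates (Spearman) with that distance.
A binned variant compares expression in half-open 2000-um distance
intervals (proximal bin versus each farther bin, rank-sum test), the
procedure used to localize interface-restricted genes such as SERPINA3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SpatialDataset
from .niches import NicheLabels, niche_distance

__all__ = [
    "gradient_test",
    "binned_comparison",
    "nonzero_prevalence",
    "BinnedComparison",
]

DEFAULT_MIN_SPOTS = 10
DEFAULT_BIN_WIDTH_UM = 2000.0


def _usable_spots(
    dataset: SpatialDataset,
    labels: NicheLabels,
    reference: str,
    restrict_to: str | None,
) -> tuple[pd.Index, pd.Series]:
    dist = niche_distance(dataset.coords, labels, reference)
    ids = dist.index
    if restrict_to is not None:
        keep = labels.table.loc[ids, "label"] == restrict_to
        ids = ids[keep.to_numpy()]
        dist = dist.loc[ids]
    return ids, dist


def gradient_test(
    dataset: SpatialDataset,
    labels: NicheLabels,
    reference: str,
    genes: list[str] | None = None,
    restrict_to: str | None = None,
    min_spots: int = DEFAULT_MIN_SPOTS,
    alpha: float = 0.05,
    method: str = "asymptotic",
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of log-normalized expression with mean distance
    to the reference niche, over the non-reference spots.

    ``restrict_to`` keeps only spots of one niche among the non-reference
    spots (e.g. tumor spots versus the stroma reference). Ties are handled
    by midranks; p-values come from the t approximation, or from the exact
    permutation distribution with ``method="exact"`` (small n only).
    Constant genes get an undefined rho (NaN), p = 1 and direction "none".
    Benjamini-Hochberg across the reported genes; ``direction`` is the sign
    of rho where adjusted p < ``alpha``.
    """
    if dataset.lognorm is None:
        raise ValueError("dataset is not normalized; run log_normalize first")
    ids, dist = _usable_spots(dataset, labels, reference, restrict_to)
    if len(ids) < min_spots:
        raise ValueError(
            f"only {len(ids)} usable spots (< min_spots={min_spots}) outside "
            f"the {reference!r} niche"
        )
    if genes is None:
        genes = list(dataset.gene_ids)

    pos = {s: i for i, s in enumerate(dataset.spot_ids)}
    cols = np.array([pos[s] for s in ids])
    expr = np.asarray(dataset.lognorm[:, cols].todense())
    d = dist.to_numpy(float)

    rows = []
    for g in genes:
        x = expr[dataset.gene_indices([g])[0]]
        if np.all(x == x[0]) or np.all(d == d[0]):
            rows.append({"gene": g, "rho": np.nan, "p": 1.0, "n": len(ids)})
            continue
        if method == "exact":
            res = stats.permutation_test(
                (d, x),
                lambda a, b: stats.spearmanr(a, b).statistic,
                permutation_type="pairings",
                n_resamples=np.inf,
                alternative="two-sided",
            )
            rho, p = stats.spearmanr(d, x).statistic, res.pvalue
        else:
            rho, p = stats.spearmanr(d, x)
        rows.append({"gene": g, "rho": float(rho), "p": float(p), "n": len(ids)})

    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["p"], method="fdr_bh")[1]
    out["n_spots_used"] = out.pop("n")
    out["reference_niche"] = reference
    signif = out["adjusted_p"] < alpha
    out["direction"] = np.where(
        signif & (out["rho"] < 0),
        "decreasing_with_distance",
        np.where(signif & (out["rho"] > 0), "increasing_with_distance", "none"),
    )
    return out


@dataclass
class BinnedComparison:
    gene: str
    bin_edges: np.ndarray  # len = n_bins + 1, half-open [e_i, e_{i+1})
    bin_medians: np.ndarray
    bin_counts: np.ndarray
    comparisons: pd.DataFrame  # proximal bin vs each farther bin


def distance_bins(distances: np.ndarray, bin_width_um: float) -> np.ndarray:
    """Half-open bins [0, w), [w, 2w), ... covering the observed distances."""
    n_bins = int(np.floor(distances.max() / bin_width_um)) + 1
    return np.arange(n_bins + 1, dtype=float) * bin_width_um


def binned_comparison(
    dataset: SpatialDataset,
    labels: NicheLabels,
    reference: str,
    gene: str,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    restrict_to: str | None = None,
) -> BinnedComparison:
    """Median expression per distance interval, with a rank-sum test of the
    proximal interval against each farther one (BH-adjusted)."""
    if dataset.lognorm is None:
        raise ValueError("dataset is not normalized; run log_normalize first")
    ids, dist = _usable_spots(dataset, labels, reference, restrict_to)
    d = dist.to_numpy(float)
    edges = distance_bins(d, bin_width_um)
    which = np.minimum(
        np.floor(d / bin_width_um).astype(int), len(edges) - 2
    )

    pos = {s: i for i, s in enumerate(dataset.spot_ids)}
    cols = np.array([pos[s] for s in ids])
    x = dataset.gene_row(gene, normalized=True)[cols]

    groups = [x[which == b] for b in range(len(edges) - 1)]
    nonempty = [b for b, grp in enumerate(groups) if len(grp)]
    if len(nonempty) < 2:
        raise ValueError(
            "all spots fall in a single distance bin; use a smaller bin width"
        )

    medians = np.array(
        [np.median(grp) if len(grp) else np.nan for grp in groups]
    )
    counts = np.array([len(grp) for grp in groups])

    proximal = nonempty[0]
    rows = []
    for b in nonempty[1:]:
        a, c = groups[proximal], groups[b]
        if np.all(np.concatenate([a, c]) == a[0]):
            p = 1.0  # identical constant samples: no evidence either way
        else:
            # the exact U distribution for small groups (auto falls back to
            # the normal approximation whenever ties are present)
            how = "exact" if min(len(a), len(c)) <= 25 else "asymptotic"
            p = float(
                stats.mannwhitneyu(a, c, alternative="two-sided", method=how).pvalue
            )
        rows.append({"proximal_bin": proximal, "far_bin": b, "p": p})
    comp = pd.DataFrame(rows)
    comp["adjusted_p"] = multipletests(comp["p"], method="fdr_bh")[1]
    return BinnedComparison(
        gene=gene,
        bin_edges=edges,
        bin_medians=medians,
        bin_counts=counts,
        comparisons=comp,
    )


def nonzero_prevalence(dataset: SpatialDataset, gene: str) -> float:
    """Fraction of spots with a nonzero raw count for ``gene``."""
    x = dataset.gene_row(gene, normalized=False)
    return float((x > 0).sum() / dataset.n_spots)
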