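"""Permutation test for spatial aggregation ("hotspots") of gene-set
expression.

For a gene set, each spot is scored by its mean log-normalized expression
over the set's genes. Spots scoring above the tissue mean plus one standard
deviation are "high" spots. The observed statistic is the sum of pairwise
Euclidean distances among the high spots; the null re-draws the same number
of spots uniformly without replacement from the whole tissue. Aggregated
high spots sit closer together than random draws, so small distance sums
are evidence of a hotspot and the p-value is the lower tail of the null.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, SpatialDataset

__all__ = ["HotspotResult", "high_spots", "hotspot_test", "run_gene_sets"]

DEFAULT_N_PERM = 1000
DEFAULT_MIN_HIGH_SPOTS = 5

#: Largest C(n_spots, n_high) for which exhaustive enumeration is attempted.
EXHAUSTIVE_CAP = 2_000_000


@dataclass
class HotspotResult:
    set_name: str
    n_high_spots: int
    observed_sum: float | None
    null_sums: np.ndarray | None
    p_value: float | None
    adjusted_p: float | None = None
    status: str = "tested"  # tested | skipped_too_few_high_spots | skipped_no_genes
    n_perm: int | None = None

    @property
    def tested(self) -> bool:
        return self.status == "tested"


def set_scores(dataset: SpatialDataset, genes) -> tuple[np.ndarray, list[str]]:
    """Per-spot mean log-normalized expression over the set genes present in
    the dataset. Absent genes are dropped with a warning."""
    if dataset.lognorm is None:
        raise ValueError("dataset is not normalized; run log_normalize first")
    present = dataset.genes_present(genes)
    absent = [g for g in genes if g not in set(present)]
    if absent:
        warnings.warn(
            f"{len(absent)} of {len(genes)} set genes absent from the dataset"
        )
    if not present:
        raise KeyError("no set genes present in the dataset")
    rows = dataset.gene_indices(present)
    sub = dataset.lognorm[rows]
    return np.asarray(sub.mean(axis=0)).ravel(), present


def high_spots(dataset: SpatialDataset, genes) -> np.ndarray:
    """Positional indices of spots whose set score exceeds the tissue mean
    plus one (population) standard deviation."""
    scores, _ = set_scores(dataset, genes)
    threshold = scores.mean() + scores.std()  # ddof=0: population sd
    return np.flatnonzero(scores > threshold)


def _pair_distance_sum(xy: np.ndarray) -> float:
    if len(xy) < 2:
        return 0.0
    return float(pdist(xy).sum())


def hotspot_test(
    dataset: SpatialDataset,
    genes,
    n_perm: int = DEFAULT_N_PERM,
    min_high_spots: int = DEFAULT_MIN_HIGH_SPOTS,
    seed: int = 0,
    set_name: str = "",
    exhaustive: bool = False,
) -> HotspotResult:
    """Hotspot permutation test for one gene set.

    ``p = (1 + #{null <= observed}) / (1 + n_perm)`` (add-one estimator,
    lower tail: small p means the high spots are aggregated). With
    ``exhaustive=True`` the null enumerates every spot subset of the same
    size and ``p`` is the exact combinatorial tail
    ``#{null <= observed} / C(n, k)`` (the observed subset is one of them).
    """
    if dataset.n_spots < min_high_spots:
        raise ValueError(
            f"dataset has {dataset.n_spots} spots, fewer than "
            f"min_high_spots={min_high_spots}"
        )
    try:
        high = high_spots(dataset, genes)
    except KeyError:
        return HotspotResult(set_name, 0, None, None, None, status="skipped_no_genes")

    k = len(high)
    if k < min_high_spots:
        return HotspotResult(
            set_name, k, None, None, None, status="skipped_too_few_high_spots"
        )

    xy = dataset.xy
    observed = _pair_distance_sum(xy[high])

    if exhaustive:
        n_total = comb(dataset.n_spots, k)
        if n_total > EXHAUSTIVE_CAP:
            raise ValueError(
                f"C({dataset.n_spots}, {k}) = {n_total} subsets is too many "
                "to enumerate; use sampled permutations"
            )
        null = np.fromiter(
            (
                _pair_distance_sum(xy[list(idx)])
                for idx in combinations(range(dataset.n_spots), k)
            ),
            dtype=float,
            count=n_total,
        )
        p = float((null <= observed).sum() / n_total)
        n_perm_used = n_total
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            # sorted gather keeps the sum bit-identical for identical subsets
            idx = np.sort(rng.choice(dataset.n_spots, size=k, replace=False))
            null[i] = _pair_distance_sum(xy[idx])
        p = float((1 + (null <= observed).sum()) / (1 + n_perm))
        n_perm_used = n_perm

    return HotspotResult(
        set_name=set_name,
        n_high_spots=k,
        observed_sum=observed,
        null_sums=null,
        p_value=p,
        status="tested",
        n_perm=n_perm_used,
    )


def run_gene_sets(
    dataset: SpatialDataset,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    min_high_spots: int = DEFAULT_MIN_HIGH_SPOTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Hotspot test for every set in the collection, Benjamini-Hochberg
    adjusted over the tested sets only. One row per set, ordered by name.

    Each set gets an independent child seed, so results for one set do not
    depend on which other sets are in the collection.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    names = sorted(collection)
    results = [
        hotspot_test(
            dataset,
            collection[name],
            n_perm=n_perm,
            min_high_spots=min_high_spots,
            # name-keyed child seed: a set's null does not depend on which
            # other sets are in the collection
            seed=int(
                np.random.SeedSequence(
                    [seed, zlib.crc32(name.encode())]
                ).generate_state(1)[0]
                % (2**31)
            ),
            set_name=name,
        )
        for name in names
    ]

    tested = [r for r in results if r.tested]
    if tested:
        adj = multipletests([r.p_value for r in tested], method="fdr_bh")[1]
        for r, a in zip(tested, adj):
            r.adjusted_p = float(a)

    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "n_high": [r.n_high_spots for r in results],
            "observed_sum": [r.observed_sum for r in results],
            "p": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "status": [r.status for r in results],
        }
    )
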