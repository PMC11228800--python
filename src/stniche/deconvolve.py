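"""Spot deconvolution by latent-topic modeling.

Visium spots are multicellular, so the count vector of a spot is a mixture
of cell-type transcriptional profiles. Latent Dirichlet Allocation treats
spots as documents and genes as words: each topic is a distribution over
genes (a candidate cell-type profile) and each spot a distribution over
topics (its cell-type proportions).

Model order is chosen over a grid of K by a lexicographic rule: fewest
low-abundance topics first (a topic whose mean proportion across spots is
negligible indicates an overspecified model), then lowest perplexity.
Topics are given biological identities by over-representation of their
high log-fold genes in user-supplied marker sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.decomposition import LatentDirichletAllocation

from .io import GeneSetCollection, SpatialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TopicModelFit",
    "TopicAnnotation",
    "fit_topics",
    "fit_topic_grid",
    "select_K",
    "annotate_topics",
]

#: A topic is "low-abundance" when its mean proportion over spots falls
#: below this share.
DEFAULT_LOW_ABUNDANCE = 0.05

#: K grid used by the pipeline when none is given.
DEFAULT_K_GRID = range(3, 16)


@dataclass
class TopicModelFit:
    K: int
    topic_gene: np.ndarray  # K x genes, rows sum to 1
    spot_topic: np.ndarray  # spots x K, rows sum to 1
    perplexity: float
    n_low_abundance_topics: int
    low_abundance_threshold: float
    seed: int
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, mat in (("topic_gene", self.topic_gene), ("spot_topic", self.spot_topic)):
            if np.any(np.abs(np.asarray(mat).sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        if not 0 <= self.n_low_abundance_topics <= self.K:
            raise ValueError("n_low_abundance_topics out of range")

    @property
    def mean_topic_proportion(self) -> np.ndarray:
        return self.spot_topic.mean(axis=0)


def fit_topics(
    dataset: SpatialDataset,
    K: int,
    seed: int,
    low_abundance_threshold: float = DEFAULT_LOW_ABUNDANCE,
    max_iter: int = 30,
    doc_topic_prior: float | None = None,
) -> TopicModelFit:
    """Fit a K-topic LDA to the raw counts (spots as documents).

    Perplexity is evaluated on the training data. Deterministic per seed.
    ``doc_topic_prior`` is the Dirichlet concentration over per-spot topic
    proportions (default 1/K); values well below 1 push each spot toward
    few topics, which lets surplus topics starve and be flagged as
    low-abundance instead of splitting a cell type symmetrically.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if K >= dataset.n_spots or K >= dataset.n_genes:
        raise ValueError(
            f"K={K} must be smaller than both the number of spots "
            f"({dataset.n_spots}) and genes ({dataset.n_genes})"
        )
    X = dataset.counts.T.tocsr()  # spots x genes
    lda = LatentDirichletAllocation(
        n_components=K,
        random_state=seed,
        max_iter=max_iter,
        learning_method="batch",
        doc_topic_prior=doc_topic_prior,
    )
    spot_topic = lda.fit_transform(X)
    spot_topic = spot_topic / spot_topic.sum(axis=1, keepdims=True)
    topic_gene = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    perplexity = float(lda.perplexity(X))
    n_low = int((spot_topic.mean(axis=0) < low_abundance_threshold).sum())
    return TopicModelFit(
        K=K,
        topic_gene=topic_gene,
        spot_topic=spot_topic,
        perplexity=perplexity,
        n_low_abundance_topics=n_low,
        low_abundance_threshold=low_abundance_threshold,
        seed=seed,
        gene_ids=list(dataset.gene_ids),
    )


def fit_topic_grid(
    dataset: SpatialDataset,
    k_grid=DEFAULT_K_GRID,
    seed: int = 0,
    **kwargs,
) -> list[TopicModelFit]:
    return [fit_topics(dataset, K, seed=seed, **kwargs) for K in k_grid]


def select_K(fits: list[TopicModelFit]) -> tuple[int, pd.DataFrame]:
    """Choose K lexicographically: fewest low-abundance topics, then lowest
    perplexity. Returns ``(chosen K, report)`` with both criteria per K."""
    if not fits:
        raise ValueError("select_K needs at least one fitted model")
    if len(fits) == 1:
        warnings.warn("single candidate model; returning its K without selection")
    report = pd.DataFrame(
        {
            "K": [f.K for f in fits],
            "n_low_abundance_topics": [f.n_low_abundance_topics for f in fits],
            "perplexity": [f.perplexity for f in fits],
        }
    ).sort_values("K", ignore_index=True)
    best = min(fits, key=lambda f: (f.n_low_abundance_topics, f.perplexity, f.K))
    report["selected"] = report["K"] == best.K
    return best.K, report


# ---------------------------------------------------------------------------
# Topic annotation
# ---------------------------------------------------------------------------


@dataclass
class TopicAnnotation:
    labels: dict[int, str]  # topic -> cell-type label ("unassigned" allowed)
    marker_table: pd.DataFrame  # topic, gene, log2_fold
    top_bottom_report: pd.DataFrame  # topic, rank_kind, gene, log2_fold
    enrichment: pd.DataFrame  # topic, candidate label, p, overlap
    manually_overridden: dict[int, bool] = field(default_factory=dict)

    def override(self, topic: int, label: str) -> None:
        """Manual-curation hook: replace a topic's label and flag it."""
        if topic not in self.labels:
            raise KeyError(f"no topic {topic}")
        self.labels[topic] = label
        self.manually_overridden[topic] = True

    def label_of(self, topic: int) -> str:
        return self.labels[topic]


def topic_log_folds(topic_gene: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """log2 of each gene's weight in a topic over its mean weight across the
    other topics; identical topics give exactly zero."""
    tg = np.asarray(topic_gene, float)
    K = tg.shape[0]
    if K < 2:
        raise ValueError("log-folds need at least two topics")
    total = tg.sum(axis=0, keepdims=True)
    other_mean = (total - tg) / (K - 1)
    return np.log2((tg + eps) / (other_mean + eps))


def annotate_topics(
    fit: TopicModelFit,
    markers: GeneSetCollection,
    log_fold_cutoff: float = 1.0,
    n_report: int = 15,
) -> TopicAnnotation:
    """Assign a cell-type label to every topic.

    Genes with log2 fold > ``log_fold_cutoff`` versus the mean of the other
    topics are a topic's candidate markers. Each marker set is scored by the
    one-sided hypergeometric over-representation of candidate markers among
    its members over the shared gene universe; the smallest p wins, ties
    broken by larger overlap. Topics with no candidate markers, or no set
    overlapping the universe, are "unassigned". The top/bottom ``n_report``
    log-fold genes per topic are reported for manual curation.
    """
    universe = list(fit.gene_ids)
    uni = set(universe)
    sets_in_universe = {
        name: [g for g in markers[name] if g in uni] for name in markers
    }
    if all(len(v) == 0 for v in sets_in_universe.values()):
        raise ValueError("no marker set overlaps the dataset's gene universe")

    lf = topic_log_folds(fit.topic_gene)
    M = len(universe)

    labels: dict[int, str] = {}
    marker_rows, report_rows, enrich_rows = [], [], []
    for k in range(fit.K):
        folds = pd.Series(lf[k], index=universe)
        candidates = folds[folds > log_fold_cutoff]
        for g, v in candidates.items():
            marker_rows.append({"topic": k, "gene": g, "log2_fold": v})

        order = folds.sort_values(ascending=False, kind="stable")
        for kind, block in (("top", order.head(n_report)), ("bottom", order.tail(n_report))):
            for g, v in block.items():
                report_rows.append(
                    {"topic": k, "rank_kind": kind, "gene": g, "log2_fold": v}
                )

        cand = set(candidates.index)
        best_label, best_key = "unassigned", None
        for name, set_genes in sets_in_universe.items():
            if not set_genes:
                continue
            overlap = len(cand & set(set_genes))
            # P(X >= overlap), X ~ Hypergeom(M, |set|, |candidates|)
            p = float(hypergeom.sf(overlap - 1, M, len(set_genes), len(cand)))
            enrich_rows.append(
                {"topic": k, "label": name, "p": p, "overlap": overlap}
            )
            if len(cand) == 0 or overlap == 0:
                continue
            key = (p, -overlap, name)
            if best_key is None or key < best_key:
                best_key, best_label = key, name
        labels[k] = best_label

    return TopicAnnotation(
        labels=labels,
        marker_table=pd.DataFrame(
            marker_rows, columns=["topic", "gene", "log2_fold"]
        ),
        top_bottom_report=pd.DataFrame(
            report_rows, columns=["topic", "rank_kind", "gene", "log2_fold"]
        ),
        enrichment=pd.DataFrame(
            enrich_rows, columns=["topic", "label", "p", "overlap"]
        ),
        manually_overridden={k: False for k in labels},
    )
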