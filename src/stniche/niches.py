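"""Collapse per-spot cell-type proportions into tumor / immune / stroma
compartments, and distances from spots to a reference compartment.

Rules, applied to the dominant (most abundant) annotated cell type of each
spot, with topics sharing a label pooled first:

  (a) tumor  — dominant label is a tumor class and its proportion reaches
      the dominance threshold (default 0.5);
  (b) immune — dominant label is an immune class (B cell / stroma-immune
      signatures) at the threshold;
  (c) stroma — everything else, including spots with no majority class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .deconvolve import TopicAnnotation, TopicModelFit

__all__ = ["NicheLabels", "NicheClassMap", "assign_niches", "niche_distance"]

NICHES = ("tumor", "immune", "stroma")


@dataclass(frozen=True)
class NicheClassMap:
    """Which annotation labels count as tumor-class and immune-class.

    The defaults mirror a melanoma cohort; other tissues remap here.
    """

    tumor: frozenset[str] = frozenset({"melanoma"})
    immune: frozenset[str] = frozenset({"B cell", "stroma immune"})


@dataclass
class NicheLabels:
    table: pd.DataFrame  # index spot_id; label, dominant_type, dominant_prop, rule

    def __post_init__(self) -> None:
        bad = set(self.table["label"]) - set(NICHES)
        if bad:
            raise ValueError(f"unknown niche labels {bad}")

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def spots_in(self, niche: str) -> pd.Index:
        if niche not in NICHES:
            raise ValueError(f"unknown niche {niche!r}")
        return self.table.index[self.table["label"] == niche]

    def counts(self) -> dict[str, int]:
        return {n: int((self.table["label"] == n).sum()) for n in NICHES}


def assign_niches(
    fit: TopicModelFit,
    annotation: TopicAnnotation,
    spot_ids: list[str],
    dominance_threshold: float = 0.5,
    class_map: NicheClassMap = NicheClassMap(),
) -> NicheLabels:
    """Label every spot tumor / immune / stroma from its deconvolved
    cell-type proportions; a rule trace records why."""
    missing = [k for k in range(fit.K) if k not in annotation.labels]
    if missing:
        raise ValueError(f"annotation does not cover topics {missing}")
    if len(spot_ids) != fit.spot_topic.shape[0]:
        raise ValueError("spot_ids length does not match the fit")

    # Pool topics sharing a cell-type label.
    topic_labels = [annotation.labels[k] for k in range(fit.K)]
    uniq = sorted(set(topic_labels))
    pool = np.zeros((fit.K, len(uniq)))
    for k, lab in enumerate(topic_labels):
        pool[k, uniq.index(lab)] = 1.0
    type_prop = fit.spot_topic @ pool  # spots x unique labels

    dom_idx = type_prop.argmax(axis=1)
    dom_prop = type_prop[np.arange(len(dom_idx)), dom_idx]
    dom_label = np.array(uniq, dtype=object)[dom_idx]

    rows = []
    for sid, lab, prop in zip(spot_ids, dom_label, dom_prop):
        if lab in class_map.tumor and prop >= dominance_threshold:
            niche, rule = "tumor", f"(a) dominant tumor-class {lab!r} at {prop:.3f}"
        elif lab in class_map.immune and prop >= dominance_threshold:
            niche, rule = "immune", f"(b) dominant immune-class {lab!r} at {prop:.3f}"
        elif prop < dominance_threshold:
            niche, rule = "stroma", f"(c) no class reaches {dominance_threshold}"
        else:
            niche, rule = "stroma", f"(c) dominant {lab!r} is stroma-class"
        rows.append(
            {
                "spot_id": sid,
                "label": niche,
                "dominant_type": lab,
                "dominant_prop": float(prop),
                "rule": rule,
            }
        )
    table = pd.DataFrame(rows).set_index("spot_id")
    return NicheLabels(table=table)


def niche_distance(
    coords: pd.DataFrame,
    labels: NicheLabels,
    reference: str,
) -> pd.Series:
    """Mean Euclidean distance (um) of every non-reference spot to all spots
    of the reference niche; reference spots are excluded from the output."""
    ref_ids = labels.spots_in(reference)
    if len(ref_ids) == 0:
        raise ValueError(f"reference niche {reference!r} is empty")
    query_ids = labels.table.index.difference(ref_ids, sort=False)
    ref_xy = coords.loc[ref_ids, ["x_um", "y_um"]].to_numpy(float)
    qry_xy = coords.loc[query_ids, ["x_um", "y_um"]].to_numpy(float)
    mean_d = cdist(qry_xy, ref_xy).mean(axis=1)
    return pd.Series(mean_d, index=query_ids, name=f"mean_dist_to_{reference}_um")
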