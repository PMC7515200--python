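"""End-to-end evaluation against a synthetic bundle's planted truth.

Convenience wrappers that run the pipeline stages in memory on a
:class:`~enhancerlink.simulate.FixtureBundle` and score the results against
the bundle's truth tables (link recall/precision, classification accuracy,
planted-TR ranks).  Used by the examples and the acceptance script; the
individual stages remain independently callable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import AtlasParams, build_atlas
from .classify import ClassificationCutoffs, classify_probes
from .io import MethylationMatrix
from .links import LinkParams, find_links, n_tests
from .network import RankingParams, rank_trs
from .simulate import FixtureBundle


def run_recovery(
    bundle: FixtureBundle,
    atlas_params: AtlasParams | None = None,
    cutoffs: ClassificationCutoffs | None = None,
    link_params: LinkParams | None = None,
    ranking_params: RankingParams | None = None,
) -> dict:
    """Run atlas -> classify -> link -> rank on an in-memory bundle.

    Returns a dict with the stage outputs (``atlas``, ``classes``,
    ``links``, ``ranks``) and the number of TR x probe tests performed.
    """
    atlas = build_atlas(
        bundle.enhancer_sets, bundle.open_sets, bundle.manifest, bundle.tss,
        atlas_params,
    )
    beta_sub = MethylationMatrix(beta=bundle.beta.beta.loc[atlas.probe_ids])
    classes = classify_probes(beta_sub, bundle.clinical, cutoffs)
    link_params = link_params or LinkParams(seed=bundle.config.seed)
    links = find_links(
        bundle.expr, bundle.beta, classes, bundle.trs, bundle.clinical,
        link_params,
    )
    ranks = rank_trs(links, ranking_params)
    tests = n_tests(
        bundle.beta, classes, bundle.trs, bundle.clinical, bundle.expr,
        link_params,
    )
    return {
        "atlas": atlas,
        "classes": classes,
        "links": links,
        "ranks": ranks,
        "n_tests": tests,
    }


def link_metrics(links: pd.DataFrame, truth_links: pd.DataFrame) -> dict:
    """Recall and precision of recovered (tr, probe) pairs vs planted truth."""
    found = set(map(tuple, links[["tr_gene", "probe_id"]].values))
    truth = set(map(tuple, truth_links[["tr_gene", "probe_id"]].values))
    recall = len(found & truth) / len(truth) if truth else float("nan")
    precision = len(found & truth) / len(found) if found else float("nan")
    return {"recall": recall, "precision": precision,
            "n_found": len(found), "n_truth": len(truth)}


def classification_accuracy(
    classes: pd.DataFrame, truth_probes: pd.DataFrame
) -> float:
    """Fraction of classified probes matching their generative class label."""
    truth = truth_probes.set_index("probe_id")["class"]
    common = classes.index.intersection(truth.index)
    return float((classes.loc[common, "class"] == truth.loc[common]).mean())


def planted_rank_positions(
    ranks: pd.DataFrame, planted_trs: list[str], direction: str = "activated"
) -> dict[str, int]:
    """Rank of each planted TR within its direction (NaN-free; missing TRs
    get a rank beyond the table)."""
    sub = ranks[ranks["direction"] == direction].set_index("tr_gene")
    worst = len(sub) + 1
    return {
        tr: int(sub.loc[tr, "rank"]) if tr in sub.index else worst
        for tr in planted_trs
    }


def per_tr_recall(links: pd.DataFrame, truth_links: pd.DataFrame) -> dict[str, float]:
    """Link recall computed separately for each planted TR."""
    out = {}
    for tr, sub_truth in truth_links.groupby("tr_gene"):
        truth = set(sub_truth["probe_id"])
        found = set(links.loc[links["tr_gene"] == tr, "probe_id"])
        out[tr] = len(found & truth) / len(truth)
    return out
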