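"""Pairwise interaction detection at feeders, contact-network construction,
centralities, and node-label permutation regression.

Two visits by different birds at the same station interact when either
(a) their co-presence (interval overlap) exceeds 11 s — a LONG interaction —
or (b) the gap from the end of the earlier visit to the start of the later
one is under 11 s — a TRANSIENT interaction.  Overlaps in (0, 11] fall
through the LONG rule into the gap rule (negative gap) and classify as
TRANSIENT.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .detections_io import BirdRecord
from .visits_metrics import Visit

LONG_OVERLAP_MIN_S = 11   # strict: overlap must exceed this
TRANSIENT_GAP_MAX_S = 11  # strict: gap must be below this


class InteractionKind(str, enum.Enum):
    TRANSIENT = "TRANSIENT"
    LONG = "LONG"


@dataclass(frozen=True)
class Interaction:
    bird_a: str  # canonical: bird_a < bird_b
    bird_b: str
    station_id: str
    kind: InteractionKind
    overlap_s: int
    gap_s: int  # end of earlier visit to start of later; negative if overlapping
    t_ref: datetime  # start of the later visit


def classify_visit_pair(v1: Visit, v2: Visit) -> Interaction | None:
    """Classify one pair of different-bird visits at the same station.

    Returns None when neither rule triggers (gap of exactly 11 s with no
    qualifying overlap is *not* an interaction).
    """
    if v1.tag_id == v2.tag_id or v1.station_id != v2.station_id:
        return None
    earlier, later = (v1, v2) if (v1.start, v1.end) <= (v2.start, v2.end) else (v2, v1)
    overlap = (min(v1.end, v2.end) - max(v1.start, v2.start)).total_seconds()
    overlap_s = max(0, int(overlap))
    gap_s = int((later.start - earlier.end).total_seconds())
    if overlap_s > LONG_OVERLAP_MIN_S:
        kind = InteractionKind.LONG
    elif gap_s < TRANSIENT_GAP_MAX_S:
        kind = InteractionKind.TRANSIENT
    else:
        return None
    a, b = sorted([v1.tag_id, v2.tag_id])
    return Interaction(
        bird_a=a,
        bird_b=b,
        station_id=v1.station_id,
        kind=kind,
        overlap_s=overlap_s,
        gap_s=gap_s,
        t_ref=later.start,
    )


def detect_interactions(visits: Sequence[Visit]) -> list[Interaction]:
    """All pairwise interactions among visits, station by station.

    Every pair of different-bird visits at a station whose overlap or gap
    triggers a rule counts once, so one long visit can interact with several
    partners.  Output order is deterministic (by station, time, pair).
    """
    by_station: dict[str, list[Visit]] = {}
    for v in visits:
        by_station.setdefault(v.station_id, []).append(v)

    out: list[Interaction] = []
    for station in sorted(by_station):
        vs = sorted(by_station[station], key=lambda v: (v.start, v.end, v.tag_id))
        for i, vi in enumerate(vs):
            # any interacting partner must start before vi.end + gap threshold
            limit = vi.end.timestamp() + TRANSIENT_GAP_MAX_S
            for vj in vs[i + 1:]:
                if vj.start.timestamp() >= limit:
                    break
                inter = classify_visit_pair(vi, vj)
                if inter is not None:
                    out.append(inter)
    out.sort(key=lambda x: (x.t_ref, x.station_id, x.bird_a, x.bird_b))
    return out


def build_network(
    interactions: Sequence[Interaction], roster: Sequence[BirdRecord] | None = None
) -> nx.Graph:
    """Undirected contact network: nodes are birds with >= 1 interaction,
    edge ``weight_s`` sums co-presence time and ``n_interactions`` counts
    interaction events for the pair."""
    g = nx.Graph()
    by_tag = {b.tag_id: b for b in (roster or [])}
    for it in interactions:
        for tag in (it.bird_a, it.bird_b):
            if tag not in g:
                attrs = {}
                if tag in by_tag:
                    b = by_tag[tag]
                    attrs = {
                        "species": b.species.value,
                        "sex": b.sex.value,
                        "age": b.age.value,
                    }
                g.add_node(tag, **attrs)
        if g.has_edge(it.bird_a, it.bird_b):
            g[it.bird_a][it.bird_b]["weight_s"] += it.overlap_s
            g[it.bird_a][it.bird_b]["n_interactions"] += 1
        else:
            g.add_edge(it.bird_a, it.bird_b, weight_s=it.overlap_s, n_interactions=1)
    return g


def centralities(network: nx.Graph, weighted: bool = False) -> pd.DataFrame:
    """Degree (distinct-neighbor count) and normalized betweenness per node.

    Betweenness uses unweighted shortest paths by default; ``weighted=True``
    uses distance 1/weight_s (zero-weight edges treated as distance 1).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    if weighted:
        for _, _, data in network.edges(data=True):
            w = data.get("weight_s", 0)
            data["_dist"] = 1.0 / w if w > 0 else 1.0
        btw = nx.betweenness_centrality(network, weight="_dist", normalized=True)
    else:
        btw = nx.betweenness_centrality(network, normalized=True)
    nodes = sorted(network.nodes)
    return pd.DataFrame(
        {
            "degree": [network.degree(n) for n in nodes],
            "betweenness": [btw[n] for n in nodes],
        },
        index=pd.Index(nodes, name="tag_id"),
    )


def components(network: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties by smallest member)."""
    comps = [set(c) for c in nx.connected_components(network)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


@dataclass
class PermutationGLMResult:
    response: str
    coefficients: dict[str, dict]  # name -> {beta, p_perm, defined}
    n_permutations: int
    seed: int


def _design_matrix(
    attributes: pd.DataFrame, predictors: Sequence[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + treatment-coded dummies for each categorical predictor.

    Returns (X, column names, names of dropped constant predictors).
    Constant (single-level) predictors yield no column and are reported as
    undefined rather than zero.
    """
    cols = [np.ones(len(attributes))]
    names = ["(Intercept)"]
    undefined: list[str] = []
    for pred in predictors:
        levels = sorted(attributes[pred].astype(str).unique())
        if len(levels) < 2:
            undefined.append(pred)
            continue
        for level in levels[1:]:  # first level is the reference
            cols.append((attributes[pred].astype(str) == level).to_numpy(float))
            names.append(f"{pred}[{level}]")
    return np.column_stack(cols), names, undefined


def permutation_glm(
    centrality: Sequence[float],
    attributes: pd.DataFrame,
    predictors: Sequence[str] = ("sex", "age"),
    n_perm: int = 10000,
    seed: int = 0,
    response_name: str = "centrality",
) -> PermutationGLMResult:
    """Node-label permutation regression of a centrality on node attributes.

    An ordinary least-squares fit gives observed coefficients; attribute rows
    are then jointly permuted across nodes ``n_perm`` times and the model
    refit each time.  Two-sided p-values use the add-one estimator
    ``p = (1 + #{|beta*| >= |beta_hat|}) / (1 + n_perm)``, which can never
    reach 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(centrality, dtype=float)
    if len(y) != len(attributes):
        raise ValueError("centrality and attributes must align")
    X, names, undefined = _design_matrix(attributes, predictors)
    pinv = np.linalg.pinv(X)

    rng = np.random.default_rng(seed)
    # Jointly permuting attribute rows with y fixed gives the same coefficient
    # as fixing X and permuting y by the inverse permutation, so we permute y.
    # The identity permutation rides along in column 0 so the observed and
    # permuted coefficients share one BLAS path (exact ties stay ties).
    perms = np.stack(
        [np.arange(len(y))] + [rng.permutation(len(y)) for _ in range(n_perm)]
    )
    betas = pinv @ y[perms].T  # (k, 1 + n_perm)
    beta_obs = betas[:, 0]
    beta_perm = betas[:, 1:]

    coefficients: dict[str, dict] = {}
    for j, name in enumerate(names):
        if name == "(Intercept)":
            continue
        tol = 1e-8 * (1.0 + abs(beta_obs[j]))
        exceed = int(np.sum(np.abs(beta_perm[j]) >= np.abs(beta_obs[j]) - tol))
        coefficients[name] = {
            "beta": float(beta_obs[j]),
            "p_perm": (1 + exceed) / (1 + n_perm),
            "defined": True,
        }
    for pred in undefined:
        coefficients[pred] = {"beta": float("nan"), "p_perm": float("nan"),
                              "defined": False}
    return PermutationGLMResult(
        response=response_name,
        coefficients=coefficients,
        n_permutations=n_perm,
        seed=seed,
    )


def network_attribute_frame(
    network: nx.Graph, exclude_unknown: bool = False
) -> pd.DataFrame:
    """Node attribute frame (sex, age, species) aligned to sorted node order."""
    nodes = sorted(network.nodes)
    df = pd.DataFrame(
        {
            "sex": [network.nodes[n].get("sex", "UNKNOWN") for n in nodes],
            "age": [network.nodes[n].get("age", "UNKNOWN") for n in nodes],
            "species": [network.nodes[n].get("species", "UNKNOWN") for n in nodes],
        },
        index=pd.Index(nodes, name="tag_id"),
    )
    if exclude_unknown:
        df = df[(df["sex"] != "UNKNOWN") & (df["age"] != "UNKNOWN")]
    return df


def write_interactions_csv(interactions: Sequence[Interaction], target) -> None:
    def _write(fh):
        w = csv.writer(fh)
        w.writerow(["bird_a", "bird_b", "station_id", "kind", "overlap_s",
                    "gap_s", "t_ref"])
        for it in interactions:
            w.writerow([it.bird_a, it.bird_b, it.station_id, it.kind.value,
                        it.overlap_s, it.gap_s,
                        it.t_ref.strftime("%Y-%m-%d %H:%M:%S")])

    if isinstance(target, (str, Path)):
        with open(target, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(target)


def write_edge_list_csv(network: nx.Graph, target) -> None:
    def _write(fh):
        w = csv.writer(fh)
        w.writerow(["bird_a", "bird_b", "weight_s", "n_interactions"])
        for a, b, data in sorted(network.edges(data=True)):
            w.writerow([a, b, data["weight_s"], data["n_interactions"]])

    if isinstance(target, (str, Path)):
        with open(target, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(target)
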