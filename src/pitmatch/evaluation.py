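"""Scoring, labeling, and group statistics for population matchings.

Against simulated ground truth, matchings are scored with precision /
recall / F1 over all predicted node correspondences (a predicted match is
correct iff both nodes descend from the same reference node; any match
touching an outlier is a false positive).  Without ground truth, the
unsupervised diagnostics are the cycle-consistency of the bulk matrix (per
node and per graph) and the silhouette of the clusters induced by label
propagation from a reference graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples

from .core import OUTLIER, UNLABELED, BulkAssignment, GraphPopulation


@dataclass
class MatchScore:
    """Correspondence-level confusion counts and the derived scores."""

    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def match_counts(
    pred: BulkAssignment,
    ground_truth: list[np.ndarray],
    pop: GraphPopulation,
) -> MatchScore:
    """Score predicted correspondences against simulated ground truth.

    Counts run over all unordered graph pairs and all predicted matches
    between real (non-dummy) nodes: a true positive shares a non-outlier
    reference identity across the pair, anything else predicted is a false
    positive, and a false negative is a true correspondence with no
    prediction.
    """
    N = pred.n_graphs
    if N != len(pop) or N != len(ground_truth):
        raise ValueError("prediction, ground truth and population sizes differ")
    tp = fp = fn = 0
    for i in range(N):
        gi = ground_truth[i]
        for j in range(i + 1, N):
            gj = ground_truth[j]
            X = pred.block(i, j)
            n_i, n_j = len(gi), len(gj)
            sub = X[:n_i, :n_j]   # real nodes occupy the leading indices
            us, vs = np.nonzero(sub)
            predicted = set(zip(us.tolist(), vs.tolist()))
            truth = set()
            idx_j = {ref: v for v, ref in enumerate(gj) if ref != OUTLIER}
            for u, ref in enumerate(gi):
                if ref != OUTLIER and ref in idx_j:
                    truth.add((u, idx_j[ref]))
            tp += len(predicted & truth)
            fp += len(predicted - truth)
            fn += len(truth - predicted)
    return MatchScore(tp, fp, fn)


def node_consistency(bulk: BulkAssignment, k: int) -> np.ndarray:
    """Cycle-consistency of every node of graph k, in (0, 1].

    For each unordered pair (i, j) the residual Y = X_kj - X_ki X_ij is
    formed; a node's consistency is 1 minus its average row norm of Y over
    pairs, halved.  Dummy rows are included (a padded matching can be
    consistent only jointly with its dummy nodes).
    """
    n, N = bulk.n_max, bulk.n_graphs
    acc = np.zeros(n)
    for i in range(N - 1):
        X_ki = bulk.block(k, i)
        for j in range(i + 1, N):
            Y = bulk.block(k, j) - X_ki @ bulk.block(i, j)
            acc += np.linalg.norm(Y, axis=1) / 2.0
    n_pairs = N * (N - 1) / 2
    return 1.0 - acc / n_pairs


def node_consistency_all(bulk: BulkAssignment) -> list[np.ndarray]:
    """Per-node consistency for every graph of the population."""
    return [node_consistency(bulk, k) for k in range(bulk.n_graphs)]


def graph_consistency(bulk: BulkAssignment, q: int) -> float:
    """Unitary consistency of the population relative to graph q.

    1 minus the average over pairs (i < j) of
    ||X_ij - X_iq X_qj||_F / (2 n_q), with n_q the padded graph size.
    """
    n, N = bulk.n_max, bulk.n_graphs
    total = 0.0
    for i in range(N - 1):
        X_iq = bulk.block(i, q)
        for j in range(i + 1, N):
            R = bulk.block(i, j) - X_iq @ bulk.block(q, j)
            total += np.linalg.norm(R) / (2.0 * n)
    return 1.0 - total / (N * (N - 1) / 2)


def propagate_labels(
    bulk: BulkAssignment, pop: GraphPopulation
) -> list[np.ndarray]:
    """Cluster labels induced by the matching, anchored to the largest graph.

    The graph with the most real nodes (ties: lowest index) is the
    reference; each of its real nodes defines a label (its own index).
    Node v of graph i receives label r iff the matching maps v onto the
    real reference node r; all other nodes, and all dummies, stay
    UNLABELED.
    """
    sizes = [g.n_real for g in pop]
    ref = int(np.argmax(sizes))
    labels = []
    for i, g in enumerate(pop):
        lab = np.full(g.n_nodes, UNLABELED, dtype=int)
        if i == ref:
            lab[~g.dummy] = np.nonzero(~g.dummy)[0]
        else:
            X = bulk.block(i, ref)
            vs, rs = np.nonzero(X)
            for v, r in zip(vs, rs):
                if not g.dummy[v] and not pop[ref].dummy[r]:
                    lab[v] = r
        labels.append(lab)
    return labels


def percent_unmatched(labeling: list[np.ndarray], pop: GraphPopulation) -> float:
    """Percentage of real nodes left UNLABELED, in [0, 100]."""
    total = unlabeled = 0
    for lab, g in zip(labeling, pop):
        real = ~g.dummy
        total += int(real.sum())
        unlabeled += int((lab[real] == UNLABELED).sum())
    return 100.0 * unlabeled / total if total else 0.0


@dataclass
class ClusterReport:
    """Per-cluster geometry and quality measures of an induced labeling."""

    n_clusters: int
    percent_unmatched: float
    mean_silhouette: float
    clusters: pd.DataFrame = field(repr=False)   # label, count, centroid, silhouette[, consistency]


def centroids_and_silhouette(
    labeling: list[np.ndarray],
    pop: GraphPopulation,
    consistency: list[np.ndarray] | None = None,
) -> ClusterReport:
    """Centroids and silhouette of the clusters of labeled nodes.

    Distances are 3D Euclidean (chordal); centroids are the normalized
    Euclidean means projected back onto the sphere.  Unlabeled nodes are
    excluded from all cluster averages but counted in percent_unmatched.
    """
    pts, labs, cons = [], [], []
    for q, (lab, g) in enumerate(zip(labeling, pop)):
        mask = (lab != UNLABELED) & ~g.dummy
        pts.append(g.coords[mask])
        labs.append(lab[mask])
        if consistency is not None:
            cons.append(consistency[q][mask])
    X = np.vstack(pts)
    y = np.concatenate(labs)
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 non-empty clusters")
    sil = silhouette_samples(X, y, metric="euclidean")
    c = np.concatenate(cons) if consistency is not None else None

    rows = []
    for label in uniq:
        m = y == label
        centroid = X[m].mean(axis=0)
        nrm = np.linalg.norm(centroid)
        centroid = centroid / nrm if nrm > 0 else centroid
        row = {
            "label": int(label),
            "count": int(m.sum()),
            "centroid_x": centroid[0],
            "centroid_y": centroid[1],
            "centroid_z": centroid[2],
            "silhouette": float(sil[m].mean()),
        }
        if c is not None:
            row["consistency"] = float(c[m].mean())
        rows.append(row)
    return ClusterReport(
        n_clusters=len(uniq),
        percent_unmatched=percent_unmatched(labeling, pop),
        mean_silhouette=float(sil.mean()),
        clusters=pd.DataFrame(rows),
    )


def group_ttest(
    labeling: list[np.ndarray],
    pop: GraphPopulation,
    groups: np.ndarray,
    attribute: str = "depth",
) -> pd.DataFrame:
    """Two-sample pooled-variance t-test per cluster label.

    ``groups`` assigns each graph (subject) to group 0 or 1; for every
    label, the attribute value of the labeled node of each contributing
    subject enters the test.  Subjects whose graph lacks the label are
    dropped, so the degrees of freedom are n1 + n2 - 2 of the contributing
    subjects.  The sign convention is t > 0 iff the group-0 mean exceeds
    the group-1 mean.  Labels where either group contributes fewer than 2
    subjects are skipped (note column).
    """
    groups = np.asarray(groups)
    if len(groups) != len(pop):
        raise ValueError("one group assignment per graph required")
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be coded 0/1")
    all_labels = sorted(
        set().union(*[set(lab[lab != UNLABELED].tolist()) for lab in labeling])
    )
    rows = []
    for label in all_labels:
        vals: dict[int, list[float]] = {0: [], 1: []}
        for lab, g, grp in zip(labeling, pop, groups):
            idx = np.nonzero(lab == label)[0]
            if len(idx):
                vals[int(grp)].append(float(g.node_attrs[attribute][idx[0]]))
        n1, n2 = len(vals[0]), len(vals[1])
        if n1 < 2 or n2 < 2:
            rows.append(
                {"label": label, "t": np.nan, "p": np.nan, "n1": n1, "n2": n2,
                 "note": "skipped: group with < 2 subjects"}
            )
            continue
        t, p = stats.ttest_ind(vals[0], vals[1], equal_var=True)
        rows.append(
            {"label": label, "t": float(t), "p": float(p), "n1": n1, "n2": n2,
             "note": ""}
        )
    return pd.DataFrame(rows)
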