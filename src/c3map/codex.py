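"""Multiplexed-imaging cell typing, niche detection and spatial statistics.

Cells arrive as segmented single-cell tables (core id, x, y, per-marker
intensities).  Typing proceeds by declarative intensity gating of a
training set, class balancing to a 2,500-cell cap, kNN classification
(200 neighbors, uniform weights, robust-scaled features), and a rescue
phase that re-classifies unresolved cells over 10 randomized rounds
(rescued immune cells are rejected).  Niches are k-means clusters of
per-cell neighborhood composition profiles (10 nearest neighbors within
distance 200, reference cell included); the number of niches is guided by
the mean holdout AUC of per-niche 1-vs-all logistic classifiers.  Niche
diversity is the Shannon entropy (natural log) of member subtypes.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import fisher_exact, mannwhitneyu
from skimage.segmentation import expand_labels
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import RobustScaler

from .containers import CellularNiche

# ---------------------------------------------------------------------------
# image-level feature extraction


def expand_masks(nuclear_mask: np.ndarray, radius: float) -> np.ndarray:
    """Membrane masks: dilate each nuclear label without overlaps.

    Contested pixels go to the nearest nucleus (Euclidean distance
    transform); radius 0 returns the input unchanged.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return nuclear_mask.copy()
    return expand_labels(nuclear_mask, distance=radius)


def ring_percentage(
    nuclear_mask: np.ndarray,
    intensity: dict[str, np.ndarray] | np.ndarray,
    markers: list[str] | None = None,
    positive_threshold: float = 20.0,
    ring_width: float = 3.0,
) -> pd.DataFrame:
    """Percent of ring pixels positive for each marker, per nucleus.

    The ring is the band just outside each nuclear contour, of width
    ``ring_width`` pixels, with contested pixels assigned to the nearest
    nucleus.  A pixel is positive when its intensity is strictly greater
    than ``positive_threshold``.
    """
    if isinstance(intensity, np.ndarray):
        intensity = {"marker": intensity}
        markers = ["marker"]
    markers = markers or list(intensity)
    ring_region = expand_labels(nuclear_mask, distance=ring_width)
    ring = np.where(nuclear_mask == 0, ring_region, 0)
    labels = np.unique(nuclear_mask)
    labels = labels[labels > 0]
    out = {}
    for m in markers:
        img = intensity[m]
        pct = []
        for lab in labels:
            px = img[ring == lab]
            pct.append(100.0 * float((px > positive_threshold).mean()) if px.size else np.nan)
        out[m] = pct
    return pd.DataFrame(out, index=pd.Index(labels, name="label"))


# ---------------------------------------------------------------------------
# cell typing


def gate_training_set(
    cells: pd.DataFrame, gates: dict[str, list[tuple[str, str, float]]]
) -> pd.Series:
    """Label cells by declarative intensity gates; ambiguous cells dropped.

    ``gates`` maps class -> list of (feature, op, threshold) with op in
    {">=", "<=", ">", "<"}; all conditions of a class must hold
    (conjunction).  Cells satisfying more than one class gate are excluded
    as ambiguous.  Returns labels indexed like ``cells`` for the gated
    subset only.
    """
    ops = {
        ">=": np.greater_equal,
        "<=": np.less_equal,
        ">": np.greater,
        "<": np.less,
    }
    hit = pd.DataFrame(index=cells.index)
    for cls, rules in gates.items():
        mask = np.ones(len(cells), dtype=bool)
        for feature, op, thr in rules:
            if op not in ops:
                raise ValueError(f"unknown gate operator {op!r}")
            mask &= ops[op](cells[feature].to_numpy(), thr)
        hit[cls] = mask
        if not mask.any():
            warnings.warn(f"gate for class {cls!r} matched no cells")
    n_hits = hit.sum(axis=1)
    unambiguous = n_hits == 1
    labels = hit.loc[unambiguous].idxmax(axis=1)
    return labels


def balance_classes(
    labels: pd.Series, cap: int = 2500, seed: int = 0
) -> pd.Series:
    """Uniformly subsample classes above ``cap``; smaller classes kept whole."""
    rng = np.random.default_rng([7, seed])
    keep_idx = []
    for cls, sub in labels.groupby(labels, sort=True):
        idx = np.asarray(sub.index)
        if len(idx) > cap:
            idx = idx[rng.choice(len(idx), size=cap, replace=False)]
        keep_idx.extend(idx.tolist())
    return labels.loc[keep_idx]


def knn_classify(
    train: pd.DataFrame,
    train_labels: pd.Series,
    query: pd.DataFrame,
    features: list[str],
    k: int = 200,
) -> np.ndarray:
    """kNN majority-vote classification in robust-scaled feature space.

    The scaler (median / IQR) is fitted on the training cells only; votes
    are uniform over the ``k`` Euclidean-nearest training cells, and ties
    resolve deterministically to the lexicographically first label.
    """
    k = min(k, len(train))
    scaler = RobustScaler().fit(train[features])
    clf = KNeighborsClassifier(n_neighbors=k, weights="uniform")
    clf.fit(scaler.transform(train[features]), train_labels.to_numpy())
    return clf.predict(scaler.transform(query[features]))


def rescue_classify(
    unresolved: pd.DataFrame,
    pool: pd.DataFrame,
    pool_labels: pd.Series,
    features: list[str],
    immune_labels: set[str] = frozenset(),
    rounds: int = 10,
    per_class: int = 500,
    k: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-classify unresolved cells over randomized training rounds.

    Each round samples up to ``per_class`` labeled cells per subtype and
    runs a kNN classifier; a cell receives the most frequent prediction
    across rounds (ties to the lexicographically first label).  Cells
    whose majority label is immune are rejected (``accepted`` False)
    rather than relabeled.
    """
    rng = np.random.default_rng([8, seed])
    votes = np.empty((len(unresolved), rounds), dtype=object)
    for rd in range(rounds):
        round_seed = int(rng.integers(0, 2**31 - 1))
        sub = balance_classes(pool_labels, cap=per_class, seed=round_seed)
        votes[:, rd] = knn_classify(
            pool.loc[sub.index], sub, unresolved, features, k=k
        )
    final, accepted = [], []
    for i in range(len(unresolved)):
        counts = Counter(votes[i])
        top = max(counts.values())
        label = min(l for l, c in counts.items() if c == top)
        final.append(label)
        accepted.append(label not in immune_labels)
    return pd.DataFrame(
        {"label": final, "accepted": accepted}, index=unresolved.index
    )


# ---------------------------------------------------------------------------
# niches


def neighborhood_profiles(
    cells: pd.DataFrame,
    broad_col: str = "broad_type",
    spot_col: str = "spot_id",
    k: int = 10,
    max_dist: float = 200.0,
    categories: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell composition of broad types among its spatial neighborhood.

    Within each core, up to ``k`` nearest cells within ``max_dist`` are
    collected and the reference cell itself is included, so fractions are
    over at most k + 1 cells (fewer near sparse edges).  Returns
    (profiles, neighbor counts used, excluding the reference).
    """
    cats = categories or sorted(cells[broad_col].unique())
    cat_idx = {c: i for i, c in enumerate(cats)}
    comp = np.zeros((len(cells), len(cats)))
    n_used = np.zeros(len(cells), dtype=int)
    type_codes = cells[broad_col].map(cat_idx).to_numpy()
    pos_all = cells[["x", "y"]].to_numpy(dtype=float)
    for _, idx in cells.groupby(spot_col, sort=False).indices.items():
        pos = pos_all[idx]
        tree = cKDTree(pos)
        kk = min(k + 1, len(idx))
        dist, nbr = tree.query(pos, k=kk)
        dist = np.atleast_2d(dist)
        nbr = np.atleast_2d(nbr)
        for row in range(len(idx)):
            within = (dist[row] <= max_dist) & np.isfinite(dist[row])
            chosen = nbr[row][within]
            # the query returns self at distance 0; keep it (reference cell)
            counts = np.bincount(type_codes[idx[chosen]], minlength=len(cats))
            comp[idx[row]] = counts / counts.sum()
            n_used[idx[row]] = len(chosen) - 1
    profiles = pd.DataFrame(comp, index=cells.index, columns=cats)
    return profiles, n_used


def _holdout_auc(profiles: np.ndarray, labels: np.ndarray, seed: int) -> float:
    """Mean holdout AUC of 1-vs-all logistic classifiers over clusters."""
    rng = np.random.default_rng([9, seed])
    order = rng.permutation(len(profiles))
    half = len(profiles) // 2
    tr, ho = order[:half], order[half:]
    aucs = []
    for cl in np.unique(labels):
        y_tr = (labels[tr] == cl).astype(int)
        y_ho = (labels[ho] == cl).astype(int)
        if y_tr.sum() in (0, len(y_tr)) or y_ho.sum() in (0, len(y_ho)):
            continue
        model = LogisticRegression(max_iter=500)
        model.fit(profiles[tr], y_tr)
        scores = model.decision_function(profiles[ho])
        aucs.append(roc_auc_score(y_ho, scores))
    return float(np.mean(aucs)) if aucs else np.nan


def select_k_niches(
    profiles: pd.DataFrame,
    k_grid: list[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Mean holdout AUC of per-niche classifiers for each candidate k.

    For each k: k-means cluster all profiles, split half/half, fit a
    1-vs-all L2 logistic classifier per cluster on the training half and
    evaluate its rank-based AUC on the holdout half; report the mean over
    clusters.  k = 1 is degenerate and skipped with a warning.
    """
    X = profiles.to_numpy(dtype=float)
    rows = []
    for k in k_grid:
        if k < 2:
            warnings.warn(f"k={k} is degenerate; skipped")
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        rows.append({"k": k, "mean_auc": _holdout_auc(X, labels, seed)})
    return pd.DataFrame(rows)


def detect_niches(
    profiles: pd.DataFrame,
    k: int,
    seed: int = 0,
    top_labels: int = 2,
) -> tuple[np.ndarray, list[CellularNiche]]:
    """k-means niche assignment with classifier-coefficient labels.

    Each niche's label joins the ``top_labels`` broad types with the
    largest positive coefficients of its 1-vs-all logistic classifier.
    """
    X = profiles.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assignment = km.fit_predict(X)
    cats = list(profiles.columns)
    niches = []
    for nid in range(k):
        members = np.where(assignment == nid)[0]
        y = (assignment == nid).astype(int)
        model = LogisticRegression(max_iter=500)
        model.fit(X, y)
        coef = model.coef_.ravel()
        order = np.argsort(-coef)
        tops = [cats[j] for j in order[:top_labels] if coef[j] > 0]
        centroid = X[members].mean(axis=0) if len(members) else np.zeros(len(cats))
        niches.append(
            CellularNiche(
                niche_id=nid,
                centroid=centroid,
                label="/".join(tops) if tops else "unlabelled",
                members=members,
            )
        )
    return assignment, niches


def merge_niches(
    assignment: np.ndarray,
    niches: list[CellularNiche],
    pair: tuple[int, int] | None = None,
    similarity_threshold: float | None = None,
) -> tuple[np.ndarray, list[CellularNiche]]:
    """Merge a named niche pair, or all pairs above a centroid correlation.

    Members are unioned into the lower niche id; centroids are recomputed
    as the member mean of the union.  Exactly one of ``pair`` /
    ``similarity_threshold`` must be given.
    """
    if (pair is None) == (similarity_threshold is None):
        raise ValueError("give exactly one of pair or similarity_threshold")
    by_id = {n.niche_id: n for n in niches}
    pairs: list[tuple[int, int]] = []
    if pair is not None:
        pairs = [tuple(sorted(pair))]
    else:
        ids = sorted(by_id)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                r = np.corrcoef(by_id[a].centroid, by_id[b].centroid)[0, 1]
                if r >= similarity_threshold:
                    pairs.append((a, b))
    assignment = assignment.copy()
    # resolve chains: map each id to its lowest partner
    target = {n.niche_id: n.niche_id for n in niches}
    for a, b in pairs:
        ra, rb = target[a], target[b]
        lo, hi = min(ra, rb), max(ra, rb)
        for key, val in target.items():
            if val == hi:
                target[key] = lo
    merged: dict[int, list[int]] = {}
    for n in niches:
        merged.setdefault(target[n.niche_id], []).append(n.niche_id)
    out = []
    for root, group in sorted(merged.items()):
        members = np.sort(np.concatenate([by_id[g].members for g in group]))
        assignment[np.isin(assignment, group)] = root
        cents = np.stack([by_id[g].centroid for g in group])
        sizes = np.array([len(by_id[g].members) for g in group], dtype=float)
        centroid = (
            (cents * sizes[:, None]).sum(axis=0) / sizes.sum()
            if sizes.sum() else cents.mean(axis=0)
        )
        label = "/".join(dict.fromkeys(sum((by_id[g].label.split("/") for g in group), [])))
        out.append(CellularNiche(niche_id=root, centroid=centroid, label=label, members=members))
    return assignment, out


def niche_entropy(subtypes) -> float:
    """Shannon entropy (nats) of the subtype frequencies of a niche.

    S = -sum_i P(x_i) ln P(x_i) over the unique member cells' subtype
    frequency vector: 0 for a pure niche, ln(n) for n equally frequent
    subtypes.
    """
    counts = pd.Series(list(subtypes)).value_counts().to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty niche")
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# enrichment and proximity statistics


def subtype_enrichment(
    cells: pd.DataFrame,
    niche_col: str = "niche",
    subtype_col: str = "broad_type",
) -> pd.DataFrame:
    """Fisher's exact test of subtype membership within each niche.

    One two-sided test per (niche, subtype) on the 2x2 table of (in niche
    vs not) x (is subtype vs not).  Empty niches are skipped with a
    warning.
    """
    rows = []
    niche_vals = cells[niche_col].to_numpy()
    sub_vals = cells[subtype_col].to_numpy()
    for niche in pd.unique(niche_vals):
        in_n = niche_vals == niche
        if in_n.sum() == 0:
            warnings.warn(f"niche {niche} is empty; skipped")
            continue
        for st in pd.unique(sub_vals):
            is_s = sub_vals == st
            table = [
                [int((in_n & is_s).sum()), int((in_n & ~is_s).sum())],
                [int((~in_n & is_s).sum()), int((~in_n & ~is_s).sum())],
            ]
            odds, p = fisher_exact(table, alternative="two-sided")
            rows.append(
                {"niche": niche, "subtype": st, "odds_ratio": odds, "pval": p}
            )
    return pd.DataFrame(rows)


def marker_enrichment(
    cells: pd.DataFrame,
    subtype: str,
    marker: str,
    niche,
    reference_niche=None,
    subtype_col: str = "broad_type",
    niche_col: str = "niche",
    min_cells: int = 3,
) -> dict | None:
    """Rank-sum test of marker intensity on one subtype, inside vs outside.

    Compares the marker intensities of ``subtype`` cells in ``niche``
    against the same subtype elsewhere (or in ``reference_niche``).
    Returns None (with a warning) when either side has fewer than
    ``min_cells`` cells.
    """
    sub = cells[cells[subtype_col] == subtype]
    inside = sub.loc[sub[niche_col] == niche, marker].to_numpy(dtype=float)
    if reference_niche is None:
        outside = sub.loc[sub[niche_col] != niche, marker].to_numpy(dtype=float)
    else:
        outside = sub.loc[sub[niche_col] == reference_niche, marker].to_numpy(dtype=float)
    if len(inside) < min_cells or len(outside) < min_cells:
        warnings.warn("too few cells on one side of the marker comparison; skipped")
        return None
    stat, p = mannwhitneyu(inside, outside, alternative="two-sided")
    return {
        "effect": float(np.median(inside) - np.median(outside)),
        "pval": float(p),
        "n_inside": len(inside),
        "n_outside": len(outside),
    }


def median_nearest_distances(
    cells: pd.DataFrame,
    query_subtype: str,
    target_type: str,
    query_col: str = "broad_type",
    target_col: str = "broad_type",
    spot_col: str = "spot_id",
    min_examples: int = 25,
) -> pd.Series:
    """Per-spot median distance from query cells to their nearest target.

    Only spots holding at least ``min_examples`` cells of both the query
    subtype and the target type are evaluated.  When query and target
    coincide, a cell is never its own nearest target.
    """
    medians = {}
    for spot, sub in cells.groupby(spot_col, sort=False):
        q = sub[sub[query_col] == query_subtype]
        t = sub[sub[target_col] == target_type]
        if len(q) < min_examples or len(t) < min_examples:
            continue
        tree = cKDTree(t[["x", "y"]].to_numpy(dtype=float))
        same = query_subtype == target_type and query_col == target_col
        kq = 2 if same else 1
        dist, _ = tree.query(q[["x", "y"]].to_numpy(dtype=float), k=kq)
        dist = np.atleast_2d(dist.reshape(len(q), -1))
        medians[spot] = float(np.median(dist[:, -1]))
    return pd.Series(medians, name=f"{query_subtype}->{target_type}")


def proximity_analysis(
    cells: pd.DataFrame,
    query_a: str,
    query_b: str,
    target_type: str,
    **kwargs,
) -> dict:
    """Compare two query subtypes' per-spot median distances to a target.

    Mann-Whitney (two-sided) across the spot-level medians of the two
    query subtypes; spots below the example minimum are excluded inside
    :func:`median_nearest_distances`.
    """
    da = median_nearest_distances(cells, query_a, target_type, **kwargs)
    db = median_nearest_distances(cells, query_b, target_type, **kwargs)
    if len(da) == 0 or len(db) == 0:
        raise ValueError("no spot passed the minimum-example filter")
    stat, p = mannwhitneyu(da.to_numpy(), db.to_numpy(), alternative="two-sided")
    return {
        "medians_a": da,
        "medians_b": db,
        "statistic": float(stat),
        "pval": float(p),
    }
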