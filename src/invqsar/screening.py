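"""Evaluation of optimized descriptor coordinates.

Two virtual-screening rankings are supported relative to a set of optimized
coordinates: by Euclidean distance in range-scaled descriptor space
(ascending) and by SVR-predicted potency (descending), both restricted to
compounds inside the applicability domain.  Rankings are scored by ROC AUC
and the true-positive ratio among the top-k compounds.  Additional
analyses: PCA projection of descriptor space, distance-activity profiles,
and a matched-molecular-pair (MMP) consistency ratio testing whether
analogs nearer the optimized coordinates are the more potent pair member.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from .compounds import CompoundRecord
from .models import ActivityRegressor, ApplicabilityDomain, RangeScaler


@dataclasses.dataclass
class RankedScreen:
    """A virtual-screening ranking (best candidate first)."""

    ids: list[str]
    scores: np.ndarray
    labels: Optional[np.ndarray]
    direction: str  # "ascending" (distance) or "descending" (potency)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if len(self.ids) != self.scores.shape[0]:
            raise ValueError("one score per id required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"compound_id": self.ids, "score": self.scores})
        if self.labels is not None:
            out["true_positive"] = self.labels
        out["rank"] = np.arange(1, len(self.ids) + 1)
        return out


@dataclasses.dataclass
class MMPRecord:
    """A matched molecular pair with potencies and scaled distances to the
    optimized coordinates."""

    id_a: str
    id_b: str
    core: str
    pki_a: float
    pki_b: float
    distance_a: float = float("nan")
    distance_b: float = float("nan")

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("an MMP must pair two different compounds")

    @property
    def delta_pki(self) -> float:
        return abs(self.pki_a - self.pki_b)


def scaled_distance(x, reference, scaler: RangeScaler) -> float:
    """Euclidean distance between two unscaled vectors, measured in
    [-1, 1]-scaled descriptor space."""
    a = scaler.transform(np.atleast_2d(np.asarray(x, dtype=float)))
    b = scaler.transform(np.atleast_2d(np.asarray(reference, dtype=float)))
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(a - b))


def rank_candidates(
    X,
    ids: Sequence[str],
    mode: str,
    *,
    scaler: RangeScaler,
    reference=None,
    regressor: Optional[ActivityRegressor] = None,
    ad_model: Optional[ApplicabilityDomain] = None,
    labels=None,
) -> RankedScreen:
    """Rank candidates by scaled distance or predicted potency.

    ``X`` is an (n, d) matrix in unscaled descriptor units.  Candidates
    outside the applicability domain are removed before ranking when an AD
    model is given.  Distance mode sorts ascending toward ``reference``
    (unscaled); potency mode sorts descending by SVR prediction.  Ties are
    stable in input order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = list(ids)
    labels = None if labels is None else np.asarray(labels, dtype=bool)
    Z = scaler.transform(X)
    if ad_model is not None:
        inside = ad_model.decision_function(Z) >= 0
        if not inside.any():
            raise ValueError("no candidate inside the applicability domain")
        X, Z = X[inside], Z[inside]
        ids = [i for i, ok in zip(ids, inside) if ok]
        labels = labels[inside] if labels is not None else None

    if mode == "distance":
        if reference is None:
            raise ValueError("distance mode requires reference coordinates")
        ref_z = scaler.transform(np.atleast_2d(np.asarray(reference, dtype=float)))
        scores = np.linalg.norm(Z - ref_z, axis=1)
        order = np.argsort(scores, kind="stable")
        direction = "ascending"
    elif mode == "potency":
        if regressor is None:
            raise ValueError("potency mode requires a fitted regressor")
        scores = regressor.predict(Z)
        order = np.argsort(-scores, kind="stable")
        direction = "descending"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return RankedScreen(
        ids=[ids[i] for i in order],
        scores=scores[order],
        labels=None if labels is None else labels[order],
        direction=direction,
    )


def roc_auc(scores, labels, direction: str = "descending") -> float:
    """ROC AUC of a score against boolean labels.

    Equals the Mann-Whitney statistic P(positive scored better than
    negative) + half credit for ties.  ``direction`` says whether larger
    ("descending" ranking) or smaller ("ascending") scores are better.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("roc_auc requires both classes")
    s = scores if direction == "descending" else -scores
    return float(roc_auc_score(labels, s))


def top_k_tp_ratio(ranking: RankedScreen, k: int = 30) -> float:
    """True-positive fraction among the k best-ranked compounds."""
    if ranking.labels is None:
        raise ValueError("ranking carries no labels")
    if k > len(ranking.ids):
        raise ValueError("k exceeds the ranking size")
    return float(np.mean(ranking.labels[:k]))


def pca_projection(
    X_train, points
) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto the first two PCs of the (scaled) training data.

    Returns (coords, explained_variance_fractions); the PCA basis is fitted
    on the training matrix only, so the training centroid maps to the
    origin.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    if X_train.shape[0] < 3:
        raise ValueError("need at least 3 training rows")
    n_comp = min(2, X_train.shape[1])
    pca = PCA(n_components=n_comp).fit(X_train)
    coords = pca.transform(np.atleast_2d(np.asarray(points, dtype=float)))
    frac = pca.explained_variance_ratio_
    if n_comp < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 1))])
        frac = np.append(frac, 0.0)
    return coords, frac


def distance_activity_profile(
    X,
    ids: Sequence[str],
    split_labels: Sequence[str],
    reference,
    regressor: ActivityRegressor,
    scaler: RangeScaler,
) -> pd.DataFrame:
    """Per-compound (scaled distance, predicted pKi, split) records, the
    table behind distance-versus-activity plots."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = scaler.transform(X)
    ref_z = scaler.transform(np.atleast_2d(np.asarray(reference, dtype=float)))
    return pd.DataFrame(
        {
            "compound_id": list(ids),
            "distance": np.linalg.norm(Z - ref_z, axis=1),
            "predicted_pki": regressor.predict(Z),
            "split": list(split_labels),
        }
    )


def top_n_selection(
    X,
    ids: Sequence[str],
    split_labels: Sequence[str],
    reference,
    scaler: RangeScaler,
    n: int = 30,
) -> pd.DataFrame:
    """The n nearest compounds (scaled distance) from each split, unioned."""
    prof = distance_activity_profile(
        X, ids, split_labels, reference, _IdentityRegressor(X.shape[1]), scaler
    ).drop(columns="predicted_pki")
    parts = []
    for split, grp in prof.groupby("split", sort=False):
        if n > len(grp):
            raise ValueError(f"n={n} exceeds split {split!r} size {len(grp)}")
        parts.append(grp.nsmallest(n, "distance", keep="first"))
    return pd.concat(parts, ignore_index=True)


class _IdentityRegressor:
    """Placeholder predictor used where only distances are needed."""

    def __init__(self, d: int):
        self._d = d

    def predict(self, Z):
        return np.zeros(np.atleast_2d(Z).shape[0])


# --- matched molecular pairs ------------------------------------------------


def _single_cut_fragments(mol: Chem.Mol) -> list[tuple[str, str]]:
    """All (core, substituent) pairs from cutting one acyclic single bond.

    Fragments are canonical SMILES with a [*] attachment point.  A cut
    qualifies when the core has at least twice the substituent's heavy
    atoms and the substituent has at most 13 heavy atoms.
    """
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        frag = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True)
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        if len(pieces) != 2:
            continue
        sizes = [
            sum(1 for a in p.GetAtoms() if a.GetAtomicNum() > 0) for p in pieces
        ]
        order = np.argsort(sizes)[::-1]
        core, subst = pieces[order[0]], pieces[order[1]]
        core_n, subst_n = sizes[order[0]], sizes[order[1]]
        if subst_n > 13 or core_n < 2 * subst_n:
            continue
        out.append(
            (
                Chem.MolToSmiles(core, canonical=True),
                Chem.MolToSmiles(subst, canonical=True),
            )
        )
    return out


def generate_mmp_pairs(
    records: Sequence[CompoundRecord],
    distances: Optional[dict[str, float]] = None,
) -> list[MMPRecord]:
    """Single-cut matched molecular pairs among a compound set.

    Two compounds form an MMP when one cut per molecule yields an identical
    core (canonical fragment with one attachment point) and differing
    substituents; each compound-id pair is reported once.  ``distances``
    optionally maps compound ids to scaled distances from the optimized
    coordinates.
    """
    by_core: dict[str, list[tuple[str, str, float]]] = {}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            continue
        pki = rec.pki if rec.pki is not None else float("nan")
        seen_here = set()
        for core, subst in _single_cut_fragments(mol):
            if (core, subst) in seen_here:
                continue
            seen_here.add((core, subst))
            by_core.setdefault(core, []).append((rec.compound_id, subst, pki))

    dist = distances or {}
    pairs: dict[tuple[str, str], MMPRecord] = {}
    for core, members in by_core.items():
        for (id_a, sub_a, pki_a), (id_b, sub_b, pki_b) in itertools.combinations(
            members, 2
        ):
            if id_a == id_b or sub_a == sub_b:
                continue
            key = tuple(sorted((id_a, id_b)))
            if key in pairs:
                continue
            pairs[key] = MMPRecord(
                id_a=id_a,
                id_b=id_b,
                core=core,
                pki_a=pki_a,
                pki_b=pki_b,
                distance_a=dist.get(id_a, float("nan")),
                distance_b=dist.get(id_b, float("nan")),
            )
    return list(pairs.values())


def consistency_ratio(
    mmps: Iterable[MMPRecord], min_delta: float = 1.0
) -> tuple[Optional[float], int]:
    """Fraction of qualifying MMPs where the nearer compound is more potent.

    Pairs qualify when |ΔpKi| >= ``min_delta`` (one order of magnitude in
    Ki by default).  A pair is consistent iff the member with strictly
    smaller scaled distance to the optimized coordinates has the higher
    pKi; distance ties count as inconsistent.  With zero qualifying pairs
    the ratio is None.
    """
    n_qualifying = 0
    n_consistent = 0
    for pair in mmps:
        if pair.delta_pki < min_delta:
            continue
        n_qualifying += 1
        near_is_a = pair.distance_a < pair.distance_b
        near_pki = pair.pki_a if near_is_a else pair.pki_b
        far_pki = pair.pki_b if near_is_a else pair.pki_a
        if pair.distance_a != pair.distance_b and near_pki > far_pki:
            n_consistent += 1
    if n_qualifying == 0:
        return None, 0
    return n_consistent / n_qualifying, n_qualifying


def mmp_table(mmps: Iterable[MMPRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "core": p.core,
                "pki_a": p.pki_a,
                "pki_b": p.pki_b,
                "distance_a": p.distance_a,
                "distance_b": p.distance_b,
                "delta_pki": p.delta_pki,
            }
            for p in mmps
        ]
    )


# --- plots ------------------------------------------------------------------


def plot_distance_profile(profile: pd.DataFrame, path) -> None:
    """Scatter of predicted pKi (y) against scaled distance (x), one color
    per split; the optimized coordinates sit at distance 0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for split, grp in profile.groupby("split", sort=False):
        ax.scatter(grp["distance"], grp["predicted_pki"], s=12, label=str(split))
    ax.set_xlabel("scaled distance to optimized coordinates")
    ax.set_ylabel("predicted pKi")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pca_map(
    train_coords: np.ndarray,
    optimized_coords: np.ndarray,
    explained: np.ndarray,
    path,
    test_coords: Optional[np.ndarray] = None,
) -> None:
    """PC1-PC2 map of descriptor space with the optimized point highlighted;
    axis labels carry the explained-variance percentages."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(train_coords[:, 0], train_coords[:, 1], s=12, label="train")
    if test_coords is not None:
        ax.scatter(test_coords[:, 0], test_coords[:, 1], s=12, label="test")
    opt = np.atleast_2d(optimized_coords)
    ax.scatter(opt[:, 0], opt[:, 1], s=80, marker="o", color="green", label="optimized")
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
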