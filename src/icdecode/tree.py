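"""C4.5-style decision tree with reduced-error pruning.

The interpretable reference model of the decoder: greedy binary splits chosen
by information-gain ratio, growth stopped at a minimum leaf size, then
bottom-up reduced-error pruning against a held-out pruning subset — any
internal node whose replacement by its training-majority leaf does not
increase pruning-set error is collapsed.  The fitted tree structure is a
plain nested dict (JSON-serializable) so it can be rendered and round-tripped
by the interpretation stage.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

__all__ = ["PrunedDecisionTree"]


def _entropy(counts: NDArray) -> NDArray:
    """Entropy (bits) from class-count arrays along the last axis."""
    n = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, counts / np.maximum(n, 1), 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=-1)


class PrunedDecisionTree(BaseEstimator, ClassifierMixin):
    """Binary-split decision tree with gain-ratio splits and REP.

    Parameters
    ----------
    min_samples_leaf : int
        Leaf-size floor; no split may create a child smaller than this.
    pruning_fraction : float
        Fraction of the training data held out (stratified, seeded) as the
        reduced-error pruning set; 0 disables pruning.
    max_depth : int or None
        Optional depth cap.
    random_state : int or None
        Seeds the pruning split; fits are deterministic.

    Attributes
    ----------
    tree_ : dict
        Nested node structure.  Internal nodes: ``{"feature", "threshold",
        "majority", "n", "left", "right"}`` (left branch is
        ``x[feature] <= threshold``); leaves: ``{"leaf": True, "label",
        "purity", "n"}``.
    pruning_record_ : list of dict
        One entry per collapsed node.
    """

    def __init__(self, min_samples_leaf: int = 40, pruning_fraction: float = 1 / 3,
                 max_depth: int | None = None, random_state: int | None = None):
        self.min_samples_leaf = min_samples_leaf
        self.pruning_fraction = pruning_fraction
        self.max_depth = max_depth
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: ArrayLike, y: ArrayLike) -> "PrunedDecisionTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n = len(y_enc)
        if n < 2 * self.min_samples_leaf and len(self.classes_) > 1:
            raise ValueError(
                f"need at least {2 * self.min_samples_leaf} exemplars "
                f"(2 x min_samples_leaf); got {n}"
            )
        if self.pruning_fraction > 0 and len(self.classes_) > 1:
            idx_grow, idx_prune = train_test_split(
                np.arange(n), test_size=self.pruning_fraction,
                random_state=self.random_state, stratify=y_enc,
            )
            idx_grow.sort(), idx_prune.sort()
        else:
            idx_grow, idx_prune = np.arange(n), np.array([], dtype=int)

        self.tree_ = self._grow(X[idx_grow], y_enc[idx_grow], depth=0)
        self.pruning_record_ = []
        if len(idx_prune):
            self._prune(self.tree_, X[idx_prune], y_enc[idx_prune], path="root")
        self.n_features_in_ = X.shape[1]
        return self

    # ------------------------------------------------------------------
    def _grow(self, X: NDArray, y: NDArray, depth: int) -> dict:
        n = len(y)
        counts = np.bincount(y, minlength=len(self.classes_))
        maj = int(np.argmax(counts))
        leaf = {
            "leaf": True,
            "label": str(self.classes_[maj]),
            "purity": float(counts[maj] / max(n, 1)),
            "n": int(n),
        }
        if (counts > 0).sum() <= 1 or n < 2 * self.min_samples_leaf:
            return leaf
        if self.max_depth is not None and depth >= self.max_depth:
            return leaf

        best = None  # (gain_ratio, gain, feature, threshold)
        h_parent = _entropy(counts.astype(float))
        for f in range(X.shape[1]):
            vals = X[:, f]
            order = np.argsort(vals, kind="stable")
            sv, sy = vals[order], y[order]
            # cumulative class counts ahead of each boundary
            onehot = np.zeros((n, len(self.classes_)))
            onehot[np.arange(n), sy] = 1.0
            cum = np.cumsum(onehot, axis=0)
            pos = np.arange(1, n)  # split after position pos-1
            valid = (sv[1:] > sv[:-1]) & (pos >= self.min_samples_leaf) & (
                n - pos >= self.min_samples_leaf
            )
            if not valid.any():
                continue
            left = cum[:-1][valid]
            right = counts[None, :] - left
            nl = left.sum(axis=1)
            nr = n - nl
            h_children = (nl * _entropy(left) + nr * _entropy(right)) / n
            gain = h_parent - h_children
            pl = nl / n
            split_info = -(pl * np.log2(pl) + (1 - pl) * np.log2(1 - pl))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(split_info > 0, gain / split_info, 0.0)
            ratio = np.where(gain > 1e-12, ratio, -np.inf)
            bi = int(np.argmax(ratio))
            if ratio[bi] == -np.inf:
                continue
            vpos = pos[valid][bi]
            thr = 0.5 * (sv[vpos - 1] + sv[vpos])
            cand = (float(ratio[bi]), float(gain[bi]), f, float(thr))
            if best is None or cand[0] > best[0] + 1e-15:
                best = cand
        if best is None:
            return leaf
        _, _, f, thr = best
        mask = X[:, f] <= thr
        return {
            "leaf": False,
            "feature": int(f),
            "threshold": float(thr),
            "majority": leaf["label"],
            "n": int(n),
            "left": self._grow(X[mask], y[mask], depth + 1),
            "right": self._grow(X[~mask], y[~mask], depth + 1),
        }

    # ------------------------------------------------------------------
    def _subtree_errors(self, node: dict, X: NDArray, y: NDArray) -> int:
        if node["leaf"]:
            lab = int(np.where(self.classes_ == node["label"])[0][0])
            return int((y != lab).sum())
        mask = X[:, node["feature"]] <= node["threshold"]
        return self._subtree_errors(node["left"], X[mask], y[mask]) + \
            self._subtree_errors(node["right"], X[~mask], y[~mask])

    def _prune(self, node: dict, X: NDArray, y: NDArray, path: str) -> None:
        """Bottom-up reduced-error pruning on the subset reaching ``node``."""
        if node["leaf"]:
            return
        mask = X[:, node["feature"]] <= node["threshold"]
        self._prune(node["left"], X[mask], y[mask], path + ".L")
        self._prune(node["right"], X[~mask], y[~mask], path + ".R")
        subtree_err = self._subtree_errors(node, X, y)
        lab = int(np.where(self.classes_ == node["majority"])[0][0])
        leaf_err = int((y != lab).sum())
        if leaf_err <= subtree_err:
            self.pruning_record_.append({
                "path": path,
                "feature": node["feature"],
                "leaf_errors": leaf_err,
                "subtree_errors": subtree_err,
                "n_pruning_samples": int(len(y)),
            })
            label = node["majority"]
            n = node["n"]
            node.clear()
            node.update({"leaf": True, "label": label, "purity": float("nan"),
                         "n": n})

    # ------------------------------------------------------------------
    def predict(self, X: ArrayLike) -> NDArray:
        check_is_fitted(self, "tree_")
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=self.classes_.dtype)

        def descend(node, idx):
            if node["leaf"]:
                out[idx] = node["label"]
                return
            mask = X[idx, node["feature"]] <= node["threshold"]
            descend(node["left"], idx[mask])
            descend(node["right"], idx[~mask])

        descend(self.tree_, np.arange(X.shape[0]))
        return out

    # ------------------------------------------------------------------
    @property
    def depth_(self) -> int:
        def d(node):
            return 0 if node["leaf"] else 1 + max(d(node["left"]), d(node["right"]))
        check_is_fitted(self, "tree_")
        return d(self.tree_)

    @property
    def n_leaves_(self) -> int:
        def c(node):
            return 1 if node["leaf"] else c(node["left"]) + c(node["right"])
        check_is_fitted(self, "tree_")
        return c(self.tree_)

    def used_features(self) -> list[int]:
        """Feature indices appearing at any internal node (root first)."""
        check_is_fitted(self, "tree_")
        feats: list[int] = []

        def walk(node):
            if not node["leaf"]:
                if node["feature"] not in feats:
                    feats.append(node["feature"])
                walk(node["left"])
                walk(node["right"])

        walk(self.tree_)
        return feats

    def to_dict(self) -> dict:
        check_is_fitted(self, "tree_")
        return {
            "classes": self.classes_.tolist(),
            "min_samples_leaf": self.min_samples_leaf,
            "pruning_fraction": self.pruning_fraction,
            "tree": self.tree_,
            "pruning_record": self.pruning_record_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PrunedDecisionTree":
        est = cls(min_samples_leaf=payload["min_samples_leaf"],
                  pruning_fraction=payload["pruning_fraction"])
        est.classes_ = np.asarray(payload["classes"])
        est.tree_ = payload["tree"]
        est.pruning_record_ = payload.get("pruning_record", [])
        return est
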