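"""Interpretation: tree rendering and IC-vs-GLM spatial overlap.

The decoder's interpretability story has two halves: (1) render the pruned
decision tree with the provenance of every node feature ("IC 5 @ 600 ms"),
and (2) quantify how much the diagnostic IC maps overlap with conventional
GLM contrast maps once both are thresholded at z >= 2.3 and binarized.  Dice
(2|A∩B| / (|A|+|B|)) and Jaccard (|A∩B| / |A∪B|) summarise each (IC,
contrast) pair; voxels in an IC mask that no GLM mask claims are reported as
unique-to-IC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fmri import BinaryMask, SpatialMap, threshold_binarize
from .tree import PrunedDecisionTree

__all__ = [
    "render_tree",
    "parse_tree",
    "overlap",
    "tree_node_overlap_table",
    "overlay_coding",
]

_INDENT = "|  "


def render_tree(tree: PrunedDecisionTree, feature_meta: list[dict]) -> str:
    """Plain-text rendering of a fitted tree with feature provenance labels.

    Internal nodes read ``split <feature id> <provenance> <= <threshold>``,
    leaves ``leaf <class> purity=<p> n=<count>``; indentation encodes depth.
    The rendering round-trips through :func:`parse_tree` byte-identically.
    """
    lines: list[str] = []

    def label_of(f: int) -> str:
        if f >= len(feature_meta):
            raise KeyError(f"feature {f} missing from feature_meta")
        m = feature_meta[f]
        if "label" in m:
            return m["label"]
        return f"{m.get('source', f'f{f}')} @ {m.get('sample_time_ms', '?')} ms"

    def walk(node: dict, depth: int) -> None:
        pad = _INDENT * depth
        if node["leaf"]:
            lines.append(
                f"{pad}leaf {node['label']} purity={node['purity']!r} n={node['n']}"
            )
            return
        lines.append(
            f"{pad}split {node['feature']} {label_of(node['feature'])} "
            f"<= {node['threshold']!r} n={node['n']} majority={node['majority']}"
        )
        walk(node["left"], depth + 1)
        walk(node["right"], depth + 1)

    walk(tree.tree_, 0)
    return "\n".join(lines) + "\n"


def parse_tree(text: str) -> dict:
    """Inverse of :func:`render_tree` (structure only; labels ignored)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    pos = 0

    def depth_of(ln: str) -> int:
        d = 0
        while ln.startswith(_INDENT):
            ln = ln[len(_INDENT):]
            d += 1
        return d

    def parse(depth: int) -> dict:
        nonlocal pos
        ln = lines[pos]
        if depth_of(ln) != depth:
            raise ValueError("malformed tree rendering (bad indentation)")
        body = ln[depth * len(_INDENT):]
        pos += 1
        if body.startswith("leaf "):
            _, label, purity_s, n_s = body.split()
            return {
                "leaf": True,
                "label": label,
                "purity": eval(purity_s.split("=", 1)[1], {"nan": float("nan")}),
                "n": int(n_s.split("=", 1)[1]),
            }
        parts = body.split()
        feature = int(parts[1])
        thr = float(parts[parts.index("<=") + 1])
        n = int([p for p in parts if p.startswith("n=")][0].split("=", 1)[1])
        majority = [p for p in parts if p.startswith("majority=")][0].split("=", 1)[1]
        left = parse(depth + 1)
        right = parse(depth + 1)
        return {
            "leaf": False, "feature": feature, "threshold": thr,
            "majority": majority, "n": n, "left": left, "right": right,
        }

    root = parse(0)
    if pos != len(lines):
        raise ValueError("trailing lines after tree rendering")
    return root


# ----------------------------------------------------------------------

def _pair_row(a: BinaryMask, b: BinaryMask) -> dict:
    if a.values.shape != b.values.shape:
        raise ValueError("mask grids do not match")
    na, nb = a.n_voxels, b.n_voxels
    inter = int((a.values & b.values).sum())
    union = int((a.values | b.values).sum())
    dice = 2 * inter / (na + nb) if (na + nb) else 0.0
    jacc = inter / union if union else 0.0
    return {
        "ic_id": a.parent_id, "contrast_id": b.parent_id,
        "n_A": na, "n_B": nb, "n_intersection": inter, "n_union": union,
        "dice": dice, "jaccard": jacc,
    }


def overlap(ic_masks: list[BinaryMask], glm_masks: list[BinaryMask]
            ) -> pd.DataFrame:
    """Overlap report: one row per (IC mask, GLM mask) pair.

    Adds ``n_unique_to_ic`` — voxels of the IC mask claimed by no GLM mask in
    the comparison set.
    """
    rows = []
    for m in list(ic_masks) + list(glm_masks):
        if m.values.shape != (ic_masks or glm_masks)[0].values.shape:
            raise ValueError("mask grids do not match")
    glm_union = None
    for g in glm_masks:
        glm_union = g.values if glm_union is None else (glm_union | g.values)
    for a in ic_masks:
        unique = int((a.values & ~glm_union).sum()) if glm_union is not None \
            else a.n_voxels
        for b in glm_masks:
            row = _pair_row(a, b)
            row["n_unique_to_ic"] = unique
            rows.append(row)
    return pd.DataFrame(rows)


def tree_node_overlap_table(
    tree: PrunedDecisionTree,
    feature_meta: list[dict],
    ic_maps: list[SpatialMap],
    glm_maps: list[SpatialMap],
    z_thresh: float = 2.3,
) -> pd.DataFrame:
    """Overlap report restricted to ICs appearing at tree decision nodes.

    The first feature of the walk (the root) is flagged.  A single-leaf tree
    yields an empty report carrying an ``empty_tree`` attribute.
    """
    used = tree.used_features()
    ics_in_tree: list[str] = []
    for f in used:
        src = feature_meta[f].get("source", "")
        if src.startswith("IC") and src not in ics_in_tree:
            ics_in_tree.append(src)
    if not ics_in_tree:
        df = pd.DataFrame(columns=["ic_id", "contrast_id", "n_A", "n_B",
                                   "n_intersection", "n_union", "dice",
                                   "jaccard", "n_unique_to_ic", "is_root"])
        df.attrs["empty_tree"] = True
        return df
    by_id = {m.map_id: m for m in ic_maps}
    ic_masks = [threshold_binarize(by_id[i], z_thresh) for i in ics_in_tree]
    glm_masks = [threshold_binarize(m, z_thresh) for m in glm_maps]
    df = overlap(ic_masks, glm_masks)
    df["is_root"] = df["ic_id"] == ics_in_tree[0]
    df.attrs["empty_tree"] = False
    return df


def overlay_coding(ic_mask: BinaryMask, glm_mask: BinaryMask) -> np.ndarray:
    """Three-class overlay volume: 1 = GLM only, 2 = IC only, 3 = both."""
    if ic_mask.values.shape != glm_mask.values.shape:
        raise ValueError("mask grids do not match")
    out = np.zeros(ic_mask.values.shape, dtype=np.uint8)
    out[glm_mask.values & ~ic_mask.values] = 1
    out[ic_mask.values & ~glm_mask.values] = 2
    out[ic_mask.values & glm_mask.values] = 3
    return out
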