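"""Concordance between a composition-based tree and a reference classification.

The headline metric is *best-clade Jaccard recovery*: for each annotated
family F, the maximum over all clades C of |F ∩ leaves(C)| / |F ∪ leaves(C)|.
A family forming exactly one clade scores 1; the score degrades smoothly as
family members scatter or bystanders intrude.  It is cut-free, matching how
families are read directly off a cladogram.  Singleton families trivially
score 1 (every leaf is a clade) and are excluded from the summary mean.

For flat partitions (e.g. a dendrogram cut versus simulated ground truth)
the adjusted Rand index is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .tree import TreeNode

__all__ = [
    "FamilyRecovery",
    "read_family_annotation",
    "write_recovery_report",
    "family_clade_recovery",
    "adjusted_rand",
]


@dataclass
class FamilyRecovery:
    """Per-family best-clade Jaccard scores plus summary statistics."""

    scores: dict[str, float]  # family -> best Jaccard over clades
    sizes: dict[str, int]  # family -> member count
    mean_score: float  # mean over evaluable (size >= 2) families
    frac_recovered: float  # fraction of evaluable families with score >= 0.5
    n_evaluable: int


def read_family_annotation(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (leaf label, family name)."""
    path = Path(path)
    annotation: dict[str, str] = {}
    with open(path, encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 2 or not cells[0] or not cells[1]:
                raise ValueError(f"{path}:{lineno}: expected 'label<TAB>family'")
            annotation[cells[0]] = cells[1]
    if not annotation:
        raise ValueError(f"{path}: empty annotation")
    return annotation


def family_clade_recovery(
    root: TreeNode, annotation: Mapping[str, str]
) -> FamilyRecovery:
    """Best Jaccard between each annotated family and any clade of ``root``."""
    leaf_labels = set(root.leaf_labels())
    missing = sorted(set(annotation) - leaf_labels)
    if missing:
        raise ValueError(f"annotated labels absent from tree: {missing!r}")

    families: dict[str, set[str]] = {}
    for label, family in annotation.items():
        if not family:
            raise ValueError(f"empty family name for label {label!r}")
        families.setdefault(family, set()).add(label)

    # leaf sets of every clade, computed bottom-up without recursion
    clades: list[frozenset[str]] = []
    post: list[TreeNode] = []
    stack = [root]
    while stack:
        node = stack.pop()
        post.append(node)
        stack.extend(node.children)
    sets: dict[int, frozenset[str]] = {}
    for node in reversed(post):
        if node.is_leaf:
            sets[id(node)] = frozenset([node.label])
        else:
            sets[id(node)] = frozenset().union(*(sets[id(c)] for c in node.children))
        clades.append(sets[id(node)])

    scores: dict[str, float] = {}
    for family, members in families.items():
        best = 0.0
        for clade in clades:
            inter = len(members & clade)
            if inter:
                best = max(best, inter / len(members | clade))
        scores[family] = best

    evaluable = [f for f, m in families.items() if len(m) >= 2]
    if not evaluable:
        raise ValueError("no evaluable family (all families have a single member)")
    ev_scores = np.array([scores[f] for f in evaluable])
    return FamilyRecovery(
        scores=scores,
        sizes={f: len(m) for f, m in families.items()},
        mean_score=float(ev_scores.mean()),
        frac_recovered=float((ev_scores >= 0.5).mean()),
        n_evaluable=len(evaluable),
    )


def write_recovery_report(result: FamilyRecovery, path: str | Path) -> None:
    """TSV report: one row per family plus a trailing summary line."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write("family\tsize\tbest_clade_jaccard\n")
        for family in sorted(result.scores):
            fh.write(
                f"{family}\t{result.sizes[family]}\t{result.scores[family]:.4f}\n"
            )
        fh.write(
            f"#summary\tmean_score={result.mean_score:.4f}\t"
            f"frac_recovered={result.frac_recovered:.4f}\t"
            f"n_evaluable={result.n_evaluable}\n"
        )


def _align(labels_a, labels_b):
    if isinstance(labels_a, Mapping) or isinstance(labels_b, Mapping):
        if not (isinstance(labels_a, Mapping) and isinstance(labels_b, Mapping)):
            raise ValueError("pass either two mappings or two sequences")
        if set(labels_a) != set(labels_b):
            raise ValueError("partitions cover different leaf sets")
        keys = sorted(labels_a)
        return [labels_a[k] for k in keys], [labels_b[k] for k in keys]
    a, b = list(labels_a), list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"partition lengths differ: {len(a)} vs {len(b)}")
    return a, b


def adjusted_rand(
    labels_a: Mapping[str, object] | Sequence,
    labels_b: Mapping[str, object] | Sequence,
) -> float:
    """Adjusted Rand index between two flat partitions of the same leaves.

    Accepts two label sequences (aligned by position) or two mappings
    leaf -> cluster (aligned by key).  1 iff the partitions are identical;
    0 in expectation under the permutation null.
    """
    a, b = _align(labels_a, labels_b)
    if len(a) < 2:
        raise ValueError("need at least 2 leaves")
    # factorize to integers for sklearn
    ai = {v: i for i, v in enumerate(dict.fromkeys(a))}
    bi = {v: i for i, v in enumerate(dict.fromkeys(b))}
    return float(adjusted_rand_score([ai[v] for v in a], [bi[v] for v in b]))
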