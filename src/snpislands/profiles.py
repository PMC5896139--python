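"""Pairwise comparison and clustering of zygosity profiles.

A profile is one sample's ordered vector of zygosity codes (1 = homozygous
reference, 2 = heterozygous, 3 = homozygous variant) over a fixed SNP panel.
Percent similarity between two profiles is the number of matching codes over
the number of positions where both carry a code; relatedness is summarized by
Euclidean distance over the code vectors followed by complete-linkage
agglomerative clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SnpProfile:
    """One sample's codes over a shared (chrom, pos) panel; None = no call."""

    sample: str
    panel: tuple[tuple[str, int], ...]
    codes: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if len(self.panel) != len(self.codes):
            raise ValueError("panel and codes must have equal length")


def build_profiles(calls: pd.DataFrame) -> list[SnpProfile]:
    """Assemble per-sample profiles over the union panel from a call table."""
    panel = sorted(
        {(str(c), int(p)) for c, p in zip(calls["chrom"], calls["pos"])}
    )
    index = {loc: i for i, loc in enumerate(panel)}
    profiles = []
    for sample, group in calls.groupby("sample", sort=True):
        codes: list[int | None] = [None] * len(panel)
        for rec in group.itertuples(index=False):
            code = rec.code
            if pd.notna(code):
                codes[index[(str(rec.chrom), int(rec.pos))]] = int(code)
        profiles.append(SnpProfile(str(sample), tuple(panel), tuple(codes)))
    return profiles


def _check_shared_panel(profiles: Sequence[SnpProfile]) -> None:
    if len({p.panel for p in profiles}) > 1:
        raise ValueError("profiles must share one panel in one order")


def similarity(a: SnpProfile, b: SnpProfile) -> tuple[int, int, float | None]:
    """(matched, total, fraction) over pairwise-complete panel positions."""
    _check_shared_panel([a, b])
    matched = total = 0
    for ca, cb in zip(a.codes, b.codes):
        if ca is None or cb is None:
            continue
        total += 1
        matched += ca == cb
    return matched, total, (matched / total if total else None)


@dataclass
class SimilarityMatrix:
    """Matched-call counts and similarity fractions for every sample pair."""

    samples: list[str]
    matched: pd.DataFrame
    total: pd.DataFrame
    fraction: pd.DataFrame

    def to_table(self) -> pd.DataFrame:
        """Counts above the diagonal, 2-decimal fractions below (report style)."""
        n = len(self.samples)
        out = pd.DataFrame("", index=self.samples, columns=self.samples)
        for i in range(n):
            for j in range(n):
                if i < j:
                    out.iat[i, j] = str(int(self.matched.iat[i, j]))
                elif i > j:
                    frac = self.fraction.iat[i, j]
                    out.iat[i, j] = "" if pd.isna(frac) else f"{frac:.2f}"
                else:
                    out.iat[i, j] = "-"
        return out


def similarity_matrix(profiles: Sequence[SnpProfile]) -> SimilarityMatrix:
    _check_shared_panel(profiles)
    samples = [p.sample for p in profiles]
    n = len(profiles)
    matched = np.zeros((n, n), dtype=int)
    total = np.zeros((n, n), dtype=int)
    frac = np.full((n, n), np.nan)
    for i in range(n):
        frac[i, i] = 1.0
        total[i, i] = sum(c is not None for c in profiles[i].codes)
        matched[i, i] = total[i, i]
        for j in range(i + 1, n):
            m, t, f = similarity(profiles[i], profiles[j])
            matched[i, j] = matched[j, i] = m
            total[i, j] = total[j, i] = t
            if f is not None:
                frac[i, j] = frac[j, i] = f
    mk = lambda a: pd.DataFrame(a, index=samples, columns=samples)
    return SimilarityMatrix(samples, mk(matched), mk(total), mk(frac))


def distance_matrix(
    profiles: Sequence[SnpProfile],
) -> tuple[list[str], np.ndarray]:
    """Euclidean distances over panel columns complete across all samples."""
    _check_shared_panel(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    complete = [
        i
        for i in range(len(profiles[0].panel))
        if all(p.codes[i] is not None for p in profiles)
    ]
    if len(complete) < 2:
        raise ValueError("fewer than 2 panel columns complete across all samples")
    mat = np.array(
        [[p.codes[i] for i in complete] for p in profiles], dtype=float
    )
    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return [p.sample for p in profiles], dist


# ---------------------------------------------------------------------------
# complete-linkage agglomeration with lexicographic tie-breaking


@dataclass
class DendrogramNode:
    """Binary merge tree; leaves carry a sample name and height 0."""

    height: float
    name: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None
    members: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()

    def to_newick(self, digits: int = 6) -> str:
        return self._newick_inner(self.height, digits) + ";"

    def _newick_inner(self, parent_height: float, digits: int) -> str:
        branch = f"{parent_height - self.height:.{digits}g}"
        if self.is_leaf:
            return f"{self.name}:{branch}"
        left, right = self.children
        inner = ",".join(c._newick_inner(self.height, digits) for c in (left, right))
        return f"({inner}):{branch}"


def cluster(samples: Sequence[str], distances: np.ndarray) -> DendrogramNode:
    """Complete-linkage agglomerative clustering of a distance matrix.

    Ties are broken deterministically: among minimal-distance pairs, merge the
    pair whose (lexicographically smallest member, other smallest member) sort
    key is least.  Merge heights are the complete-linkage (maximum pairwise)
    distances, which are non-decreasing along every root path.
    """
    n = len(samples)
    if distances.shape != (n, n):
        raise ValueError("distance matrix shape does not match samples")
    if n == 0:
        raise ValueError("need at least one sample")
    if not np.allclose(distances, distances.T):
        raise ValueError("distance matrix must be symmetric")
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(0.0, name=samples[i], members=(samples[i],))
        for i in range(n)
    }
    # complete-linkage distance between current clusters
    d = {frozenset((i, j)): float(distances[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best_key = None
        best_pair = None
        for pair, dist in d.items():
            i, j = sorted(pair)
            mins = sorted((min(nodes[i].members), min(nodes[j].members)))
            key = (dist, mins[0], mins[1])
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (i, j)
        i, j = best_pair  # type: ignore[misc]
        height = d[frozenset((i, j))]
        # left child = cluster holding the lexicographically smallest member
        left, right = (
            (i, j) if min(nodes[i].members) <= min(nodes[j].members) else (j, i)
        )
        merged = DendrogramNode(
            height,
            children=(nodes[left], nodes[right]),
            members=tuple(sorted(nodes[left].members + nodes[right].members)),
        )
        for k in list(active):
            if k in (i, j):
                continue
            dk = max(d[frozenset((i, k))], d[frozenset((j, k))])
            d[frozenset((next_id, k))] = dk
        for pair in [p for p in d if i in p or j in p]:
            del d[pair]
        active -= {i, j}
        active.add(next_id)
        nodes[next_id] = merged
        next_id += 1
    return nodes[active.pop()]


def heatmap_export(
    profiles: Sequence[SnpProfile],
    dendrogram: DendrogramNode,
    out_prefix: str | Path,
    image: bool = False,
) -> dict[str, Path]:
    """Write codes TSV in dendrogram leaf order, newick tree, optional PNG.

    The raster uses the conventional zygosity colors: green = homozygous
    reference (1), yellow = heterozygous (2), red = homozygous variant (3).
    """
    _check_shared_panel(profiles)
    out_prefix = Path(out_prefix)
    by_name = {p.sample: p for p in profiles}
    order = dendrogram.leaves()
    if set(order) != set(by_name):
        raise ValueError("dendrogram leaves do not match profile samples")

    tsv_path = out_prefix.with_suffix(".codes.tsv")
    with open(tsv_path, "w") as fh:
        header = "\t".join(f"{c}:{p}" for c, p in profiles[0].panel)
        fh.write(f"sample\t{header}\n")
        for name in order:
            codes = "\t".join(
                "." if c is None else str(c) for c in by_name[name].codes
            )
            fh.write(f"{name}\t{codes}\n")

    nwk_path = out_prefix.with_suffix(".nwk")
    nwk_path.write_text(dendrogram.to_newick() + "\n")

    written = {"codes": tsv_path, "tree": nwk_path}
    if image:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        mat = np.array(
            [[np.nan if c is None else c for c in by_name[name].codes] for name in order],
            dtype=float,
        )
        fig, ax = plt.subplots(
            figsize=(max(4, mat.shape[1] * 0.15), max(2, mat.shape[0] * 0.3))
        )
        cmap = ListedColormap(["#2ca02c", "#ffdf00", "#d62728"])  # 1, 2, 3
        ax.imshow(mat, cmap=cmap, vmin=1, vmax=3, aspect="auto", interpolation="none")
        ax.set_yticks(range(len(order)), labels=order, fontsize=7)
        ax.set_xticks([])
        ax.set_xlabel("panel SNPs")
        png_path = out_prefix.with_suffix(".png")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written["image"] = png_path
    return written
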