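"""Structure diagnostics: PCA, allele-sharing distances, Neighbor-Joining.

These are the visual/sanity checks run on reduced SNP panels: a PCA of the
centered dosage matrix should separate breeds into clusters, and a
Neighbor-Joining tree on pairwise allele-sharing distances should group
conspecific individuals, if the selected markers truly discriminate.

The allele-sharing distance between two individuals is one minus the mean
fraction of alleles shared per locus: at one biallelic locus two genotypes
share ``2 - |dosage_x - dosage_y|`` alleles (identical genotypes share 2,
het vs hom share 1, opposite homozygotes share 0), averaged over loci
called in both individuals (pairwise deletion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .genotype_io import MISSING, GenotypeMatrix
from .neuralnet import mean_impute

__all__ = [
    "PcaResult",
    "DistanceMatrix",
    "pca_scores",
    "allele_sharing_distance",
    "neighbor_joining",
]

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Sample coordinates on principal components of the dosage matrix."""

    samples: list[str]
    breeds: list[str]
    scores: np.ndarray  # samples x components
    explained_variance_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{k + 1}": self.scores[:, k] for k in range(self.scores.shape[1])}
        return pd.DataFrame({"sample_id": self.samples, "breed": self.breeds, **cols})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# explained_variance_fraction\t"
                + "\t".join(f"{v:.6g}" for v in self.explained_variance_fraction)
                + "\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square format (labels truncated/padded to 10 chars)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{lab[:10]:<10} {row}\n")


# ---------------------------------------------------------------------------
# PCA


def pca_scores(
    G: GenotypeMatrix,
    n_components: int = 2,
    snp_subset: Sequence[str] | None = None,
    scale: bool = False,
) -> PcaResult:
    """PCA of the (mean-imputed, centered) dosage matrix.

    Columns are always centered; ``scale`` additionally divides by the
    per-SNP standard deviation (constant columns are left unscaled and
    contribute nothing either way). The sign of each component is fixed by
    making its largest-magnitude loading positive, so scores are
    deterministic.
    """
    M = G if snp_subset is None else G.select_snp_ids(snp_subset)
    if M.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > min(M.n_samples, M.n_snps):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_snps)="
            f"{min(M.n_samples, M.n_snps)}"
        )
    X = mean_impute(M.dosages)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1.0
    return PcaResult(
        samples=list(M.samples),
        breeds=list(M.breeds),
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# allele-sharing distance


def allele_sharing_distance(
    G: GenotypeMatrix, snp_subset: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise 1 - mean shared-allele fraction over pairwise-called loci."""
    M = G if snp_subset is None else G.select_snp_ids(snp_subset)
    dos = M.dosages.astype(float)
    called = M.dosages != MISSING
    n = M.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        L = both.sum(axis=1)
        if np.any(L == 0):
            j = i + 1 + int(np.argmax(L == 0))
            raise ValueError(
                f"samples {M.samples[i]!r} and {M.samples[j]!r} share no called locus"
            )
        diff = np.abs(dos[i] - dos[i + 1 :])
        shared = np.where(both, 2.0 - diff, 0.0).sum(axis=1)
        d[i, i + 1 :] = 1.0 - shared / (2.0 * L)
    d = d + d.T
    return DistanceMatrix(list(M.samples), d)


# ---------------------------------------------------------------------------
# Neighbor-Joining


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None = None, children: list | None = None):
        self.label = label
        self.children = children or []  # list of (node, branch_length)

    def newick(self) -> str:
        if not self.children:
            return _quote(self.label or "")
        inner = ",".join(f"{c.newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"


_RESERVED = set("(),:;'\" \t\n[]")


def _quote(label: str) -> str:
    if any(ch in _RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def neighbor_joining(D: DistanceMatrix) -> str:
    """Saitou–Nei Neighbor-Joining; returns an unrooted Newick string.

    Iteratively joins the pair minimizing the Q-criterion
    ``(n-2) d_ij - r_i - r_j`` (ties broken by index order), assigns branch
    lengths by the standard three-point formulas, and reduces the matrix.
    A negative branch length is clamped to 0 with the deficit moved onto
    the sister branch (total preserved); clamps are logged. The final three
    lineages are joined at an unresolved root, giving the conventional
    unrooted (trifurcating) Newick.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least 3 taxa")
    d = D.d.astype(float).copy()
    nodes: list[_Node] = [_Node(lab) for lab in D.labels]

    def clamp(li: float, lj: float, what: str) -> tuple[float, float]:
        if li < 0:
            logger.warning("clamping negative NJ branch (%s): %.6g", what, li)
            lj += li
            li = 0.0
        return li, max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj, f"join of {nodes[i].label or 'internal'}")
        lj, li = clamp(lj, li, f"join of {nodes[j].label or 'internal'}")
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        du = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the last three lineages around an unrooted central node
    (a, b, c) = range(3)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = []
    for name, L in zip("abc", (la, lb, lc)):
        if L < 0:
            logger.warning("clamping negative terminal NJ branch (%s): %.6g", name, L)
            L = 0.0
        lens.append(L)
    root = _Node(children=list(zip(nodes, lens)))
    return root.newick() + ";"
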