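"""Persistent ensemble sets and the between-sample consensus map.

A marker pair belongs to a sample's persistent set σ*(k) for a class when it
votes that class for the sample in *every* realization; pairs that ever flip
belong to neither persistent set.  The consensus map τ counts shared
persistent pairs between samples: within-group cells intersect same-class
sets, between-group cells intersect the gingivitis sample's σg* with the
periodontitis sample's σp* — i.e. every sample contributes the persistent set
of its own clinical class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ensemble import SVAResult  # noqa: E402


@dataclass
class PersistentEnsembleSet:
    """Per-sample boolean indicators over the pair list, per vote class."""

    pairs: list[tuple[int, int]]
    sigma_g_star: np.ndarray  # (n, n_pairs) bool
    sigma_p_star: np.ndarray  # (n, n_pairs) bool

    def as_pair_lists(self) -> tuple[list[list[tuple[int, int]]], list[list[tuple[int, int]]]]:
        pairs = self.pairs
        g = [[pairs[j] for j in np.flatnonzero(row)] for row in self.sigma_g_star]
        p = [[pairs[j] for j in np.flatnonzero(row)] for row in self.sigma_p_star]
        return g, p


@dataclass
class ConsensusMap:
    """Symmetric n x n matrix of persistent-set overlap counts.

    ``tau[i, j]`` lies in [0, m(m−1)/2]; the diagonal holds |σ*(k)| of the
    sample's own clinical class (display only, excluded from statistics).
    """

    sample_ids: list[str]
    labels: np.ndarray
    tau: np.ndarray
    n_pairs: int

    def region(self, i: int, j: int) -> str:
        a, b = self.labels[i], self.labels[j]
        if a == b:
            return "GxG" if a == -1 else "PxP"
        return "GxP"


def persistent_sets(
    result: SVAResult, consistency_fraction: float = 1.0
) -> PersistentEnsembleSet:
    """Intersect ensemble sets across realizations, per sample and class.

    ``consistency_fraction`` relaxes the strict (default) intersection: a
    pair qualifies when it votes the class in at least that fraction of
    realizations.  1.0 reproduces the strict definition; anything lower is
    an explicit deviation for borderline samples at large N_b.
    """
    if not 0.0 < consistency_fraction <= 1.0:
        raise ValueError("consistency_fraction must lie in (0, 1]")
    if consistency_fraction == 1.0:
        star_g = result.sets_g.all(axis=0)
        star_p = result.sets_p.all(axis=0)
    else:
        nb = result.sets_g.shape[0]
        star_g = result.sets_g.sum(axis=0) >= consistency_fraction * nb
        star_p = result.sets_p.sum(axis=0) >= consistency_fraction * nb
        # a pair may clear the fraction for both classes only if < 1; keep disjoint
        both = star_g & star_p
        star_g &= ~both
        star_p &= ~both
    return PersistentEnsembleSet(pairs=list(result.pairs), sigma_g_star=star_g,
                                 sigma_p_star=star_p)


def consensus_map(
    psets: PersistentEnsembleSet,
    labels: np.ndarray,
    sample_ids: list[str] | None = None,
) -> ConsensusMap:
    """Overlap counts between the samples' own-class persistent sets.

    A gingivitis-labelled sample contributes σg*, a periodontitis-labelled
    sample σp*; τ(i, j) is the size of the intersection of the two
    contributed sets, which reproduces the within-group and between-group
    cell definitions simultaneously.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.shape[0]
    if psets.sigma_g_star.shape[0] != n:
        raise ValueError("labels length does not match persistent sets")
    own = np.where((labels == -1)[:, None], psets.sigma_g_star, psets.sigma_p_star)
    tau = own.astype(np.int64) @ own.astype(np.int64).T
    if sample_ids is None:
        sample_ids = [str(k) for k in range(n)]
    return ConsensusMap(sample_ids=list(sample_ids), labels=labels, tau=tau,
                        n_pairs=len(psets.pairs))


def export_heatmap(
    cmap: ConsensusMap,
    image_path: str | Path | None = None,
    matrix_path: str | Path | None = None,
) -> np.ndarray:
    """Write the consensus map as an upper-triangular heatmap and a TSV.

    Gingivitis samples are ordered first, then periodontitis (stable within
    group); only the upper triangle is rendered since τ is symmetric, with
    dashed lines demarcating the G x G, P x P and G x P regions.  The TSV
    stores the full symmetric matrix with sample IDs as headers.  Returns the
    reordered matrix.
    """
    order = np.argsort(cmap.labels, kind="stable")
    tau = cmap.tau[np.ix_(order, order)]
    ids = [cmap.sample_ids[k] for k in order]
    n_gin = int((cmap.labels == -1).sum())
    n = tau.shape[0]

    if matrix_path is not None:
        df = pd.DataFrame(tau, index=ids, columns=ids)
        df.to_csv(matrix_path, sep="\t", index_label="sample_id")

    if image_path is not None:
        shown = np.where(np.triu(np.ones_like(tau, dtype=bool)), tau, np.nan)
        fig, ax = plt.subplots(figsize=(7, 6))
        im = ax.imshow(shown, cmap="inferno", vmin=0, vmax=cmap.n_pairs,
                       interpolation="nearest")
        for pos in (n_gin - 0.5,):
            ax.axvline(pos, color="cyan", lw=0.8, ls="--")
            ax.axhline(pos, color="cyan", lw=0.8, ls="--")
        ax.set_title("Consensus map τ (upper triangle; G first, then P)")
        ax.set_xlabel(f"samples 1..{n_gin} gingivitis | {n_gin + 1}..{n} periodontitis")
        fig.colorbar(im, ax=ax, label="shared persistent pairs")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)

    return tau
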