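"""Synthetic two-group salivary-biomarker cohorts.

Real salivary concentrations of inflammatory markers are strictly positive
and strongly right-skewed, with standard deviations that can exceed the mean
(e.g. IL-1β in gingivitis).  A log-normal marginal captures all three
features and is consistent with the log transform applied downstream, so
each marker x group is drawn from a log-normal law moment-matched to the
target (mean M, SD S):

    sigma² = ln(1 + S²/M²),   mu = ln M − sigma²/2,

which makes the implied distribution's mean and SD equal M and S exactly.
A gamma marginal (shape M²/S², scale S²/M, sampled through a Gaussian
copula) is available as an alternative skewed family.

Default group moments match the reported cohort summaries for the four
markers (IL-1β, IL-6, MMP-8, MIP-1α) in gingivitis and periodontitis, with
40 subjects per group.  Optional "planted swaps" draw a fraction of samples
from the opposite group's distribution while keeping their nominal clinical
label — a ground-truth subpopulation for exercising mismatch detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GINGIVITIS, PERIODONTITIS, BiomarkerTable

DEFAULT_MARKERS = ("IL-1beta", "IL-6", "MMP-8", "MIP-1alpha")


@dataclass(frozen=True)
class GroupMoments:
    """Target raw-scale mean and SD per marker, per group (pg/mL scale)."""

    marker_names: tuple[str, ...] = DEFAULT_MARKERS
    gingivitis_mean: tuple[float, ...] = (29.6, 3.9, 208.2, 10.9)
    gingivitis_sd: tuple[float, ...] = (49.5, 5.9, 194.2, 14.5)
    periodontitis_mean: tuple[float, ...] = (157.6, 12.1, 397.9, 24.4)
    periodontitis_sd: tuple[float, ...] = (217.0, 10.2, 302.1, 29.8)

    def __post_init__(self) -> None:
        m = len(self.marker_names)
        for name in ("gingivitis_mean", "gingivitis_sd",
                     "periodontitis_mean", "periodontitis_sd"):
            vals = getattr(self, name)
            if len(vals) != m:
                raise ValueError(f"{name} must have one entry per marker")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} entries must be positive")

    def for_group(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        if label == GINGIVITIS:
            return np.asarray(self.gingivitis_mean), np.asarray(self.gingivitis_sd)
        return np.asarray(self.periodontitis_mean), np.asarray(self.periodontitis_sd)


DEFAULT_MOMENTS = GroupMoments()


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    swap_fraction
        Fraction of each group drawn from the *other* group's distribution
        (nominal label kept) — planted biological mismatches.
    correlation
        Optional m x m positive-definite between-marker correlation on the
        log scale (shared by both groups); identity when omitted.
    emit_clinical
        Also generate BOP/PPD/CAL parameters drawn uniformly inside the
        nominal label's defining region, to exercise clinical labelling.
    """

    n_gin: int = 40
    n_per: int = 40
    moments: GroupMoments = field(default_factory=GroupMoments)
    correlation: np.ndarray | None = None
    swap_fraction: float = 0.0
    marginal: str = "lognormal"
    emit_clinical: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_gin < 2 or self.n_per < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0.0 <= self.swap_fraction <= 0.5:
            raise ValueError("swap_fraction must lie in [0, 0.5]")
        if self.marginal not in ("lognormal", "gamma"):
            raise ValueError("marginal must be 'lognormal' or 'gamma'")


def lognormal_params_from_moments(M, S) -> tuple[np.ndarray, np.ndarray]:
    """Log-scale (mu, sigma) whose log-normal has mean M and SD S exactly."""
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if (M <= 0).any() or (S <= 0).any():
        raise ValueError("moments must be positive")
    sigma2 = np.log1p((S / M) ** 2)
    mu = np.log(M) - sigma2 / 2
    return mu, np.sqrt(sigma2)


def moments_from_lognormal_params(mu, sigma) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`lognormal_params_from_moments` (closed form)."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    M = np.exp(mu + sigma**2 / 2)
    S = M * np.sqrt(np.expm1(sigma**2))
    return M, S


def _cholesky(correlation: np.ndarray | None, m: int) -> np.ndarray:
    if correlation is None:
        return np.eye(m)
    corr = np.asarray(correlation, dtype=float)
    if corr.shape != (m, m) or not np.allclose(corr, corr.T):
        raise ValueError("correlation must be a symmetric m x m matrix")
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive-definite") from exc


def _draw_group(rng, n, gen_labels, moments, L, marginal):
    """Draw n samples; row k follows the law of group gen_labels[k]."""
    m = L.shape[0]
    z = rng.standard_normal((n, m)) @ L.T
    X = np.empty((n, m))
    for label in (GINGIVITIS, PERIODONTITIS):
        rows = gen_labels == label
        if not rows.any():
            continue
        M, S = moments.for_group(label)
        if marginal == "lognormal":
            mu, sigma = lognormal_params_from_moments(M, S)
            X[rows] = np.exp(mu[None, :] + sigma[None, :] * z[rows])
        else:  # gamma via Gaussian copula
            shape = (M / S) ** 2
            scale = S**2 / M
            u = stats.norm.cdf(z[rows])
            X[rows] = stats.gamma.ppf(u, shape[None, :], scale=scale[None, :])
    return X


def _clinical_block(rng, labels):
    """BOP/PPD/CAL drawn uniformly inside each nominal label's region."""
    n = labels.shape[0]
    bop = np.empty(n)
    ppd4 = np.empty(n)
    cal = np.empty(n, dtype=bool)
    gin = labels == GINGIVITIS
    bop[gin] = rng.uniform(20.0, 80.0, gin.sum())
    ppd4[gin] = rng.uniform(0.0, 9.5, gin.sum())
    cal[gin] = False
    per = ~gin
    bop[per] = rng.uniform(25.0, 80.0, per.sum())
    ppd4[per] = rng.uniform(10.5, 40.0, per.sum())
    cal[per] = True
    return bop, ppd4, cal


def generate_cohort(spec: CohortSpec) -> tuple[BiomarkerTable, pd.DataFrame]:
    """Draw a raw-scale cohort plus ground-truth annotations.

    Returns the table (markers x samples, strictly positive, unnormalized)
    and a DataFrame with one row per sample: ``sample_id``, nominal
    ``clinical_label``, ``generating_label`` (the distribution actually
    drawn from), a ``swapped`` flag, and optional clinical parameters.
    Deterministic for a fixed spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    m = len(spec.moments.marker_names)
    L = _cholesky(spec.correlation, m)

    blocks, ann_rows = [], []
    for label, n, prefix in ((GINGIVITIS, spec.n_gin, "G"),
                             (PERIODONTITIS, spec.n_per, "P")):
        n_swap = int(round(spec.swap_fraction * n))
        swap_idx = rng.choice(n, size=n_swap, replace=False)
        gen = np.full(n, label)
        gen[swap_idx] = -label
        X = _draw_group(rng, n, gen, spec.moments, L, spec.marginal)
        blocks.append(X)
        width = len(str(n))
        for k in range(n):
            ann_rows.append({
                "sample_id": f"{prefix}{k + 1:0{width}d}",
                "clinical_label": label,
                "generating_label": int(gen[k]),
                "swapped": bool(gen[k] != label),
            })

    X_all = np.vstack(blocks).T  # markers x samples
    annotations = pd.DataFrame(ann_rows)
    labels = annotations["clinical_label"].to_numpy()
    if spec.emit_clinical:
        bop, ppd4, cal = _clinical_block(rng, labels)
        annotations["bop_pct"] = bop
        annotations["ppd4_pct"] = ppd4
        annotations["cal2_any"] = cal

    table = BiomarkerTable(
        sample_ids=annotations["sample_id"].tolist(),
        marker_names=list(spec.moments.marker_names),
        X=X_all,
        labels=labels,
        normalized=False,
    )
    return table, annotations
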