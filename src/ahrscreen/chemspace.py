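"""PCA chemical-space models, applicability domain, and initial filtration.

The property space of a reference library is summarized by principal
components of the unit-variance-scaled descriptor matrix.  A component is
significant when its eigenvalue (score variance on scaled data) is at least
2.  Membership of a compound in the model's applicability domain (AD) is
decided jointly by Hotelling's T² on the significant scores and by DModX,
the normalized residual distance to the model plane, both at their 95%
limits derived from F-distribution quantiles.

The initial filtration of a candidate library runs two branches in
parallel: a "typical" branch keeping candidates inside the AD of a PCA
fitted on the reference binders, and an "atypical" branch keeping
candidates whose Euclidean distance in the significant-PC score space of a
joint (references ∪ candidates, log-transformed) PCA is at most 1.5 from
any of a small set of flexible reference ligands.  The union of the two
branches feeds the three parallel screening methods.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import DescriptorMatrix, log_transform

logger = logging.getLogger(__name__)

#: Eigenvalue threshold for a significant principal component.
SIGNIFICANT_EIGENVALUE = 2.0

#: Euclidean-distance cutoff of the atypical (log-transformed) filtration.
ED_CUTOFF_ATYPICAL = 1.5


@dataclass
class PCAModel:
    """Fitted PCA of a scaled descriptor matrix with AD statistics.

    Attributes
    ----------
    names : descriptor names actually used (constant columns dropped).
    column_means, column_scales : centering / unit-variance scaling vectors.
    loadings : orthonormal (p × A_retained) loading matrix.
    eigenvalues : score variances per retained PC, non-increasing.
    r2x : fraction of total (scaled) variance explained per PC.
    n_significant : number of PCs with eigenvalue ≥ 2 (at least one).
    t2_limit_95, dmodx_crit_95 : 95% applicability-domain limits.
    s0 : pooled residual standard deviation of the training set.
    n_train : training-set size.
    """

    names: list[str]
    column_means: np.ndarray
    column_scales: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    r2x: np.ndarray
    n_significant: int
    t2_limit_95: float
    dmodx_crit_95: float
    s0: float
    n_train: int

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loadings are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")
        if self.n_significant > self.loadings.shape[1]:
            raise ValueError("n_significant exceeds retained PCs")

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "names": self.names,
            "column_means": self.column_means.tolist(),
            "column_scales": self.column_scales.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "r2x": self.r2x.tolist(),
            "n_significant": self.n_significant,
            "t2_limit_95": self.t2_limit_95,
            "dmodx_crit_95": self.dmodx_crit_95,
            "s0": self.s0,
            "n_train": self.n_train,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            names=d["names"],
            column_means=np.array(d["column_means"]),
            column_scales=np.array(d["column_scales"]),
            loadings=np.array(d["loadings"]),
            eigenvalues=np.array(d["eigenvalues"]),
            r2x=np.array(d["r2x"]),
            n_significant=d["n_significant"],
            t2_limit_95=d["t2_limit_95"],
            dmodx_crit_95=d["dmodx_crit_95"],
            s0=d["s0"],
            n_train=d["n_train"],
        )

    def _scale(self, matrix: DescriptorMatrix) -> np.ndarray:
        missing = [n for n in self.names if n not in matrix.names]
        if missing:
            raise ValueError(f"descriptor columns missing from matrix: {missing}")
        cols = [matrix.names.index(n) for n in self.names]
        x = matrix.values[:, cols]
        return (x - self.column_means) / self.column_scales


@dataclass
class ScoreMatrix:
    """Compound coordinates in the significant-PC score space of one model."""

    ids: list[str]
    scores: np.ndarray
    model_tag: int

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape[0] != len(self.ids):
            raise ValueError("score rows do not match ids")

    def write_tsv(self, path: str | Path) -> None:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        pd.DataFrame(self.scores, index=self.ids, columns=cols) \
            .rename_axis("id").to_csv(path, sep="\t")


@dataclass
class ADResult:
    """Per-compound applicability-domain assessment."""

    ids: list[str]
    t2: np.ndarray
    dmodx: np.ndarray
    inside: np.ndarray

    def inside_ids(self) -> set[str]:
        return {i for i, ok in zip(self.ids, self.inside) if ok}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t2": self.t2, "dmodx": self.dmodx, "inside": self.inside},
            index=self.ids,
        ).rename_axis("id")


def fit_pca(
    matrix: DescriptorMatrix,
    scaling: str = "unit_variance",
    max_pcs: int | None = None,
) -> PCAModel:
    """Fit a PCA with SIMCA-style significance and AD bookkeeping.

    Constant descriptor columns are dropped with a warning before fitting.
    Eigenvalues are the score variances (n−1 denominator) of the scaled
    data; with unit-variance scaling they sum to the number of descriptors,
    and the eigenvalue-≥-2 significance rule applies on that scale.
    """
    if scaling not in ("unit_variance", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    n, p_all = matrix.values.shape
    if n < 3:
        raise ValueError("PCA requires at least 3 compounds")

    sd = matrix.values.std(axis=0, ddof=1)
    # relative tolerance: columns that are constant up to round-off are dropped
    scale_ref = np.maximum(np.abs(matrix.values).max(axis=0), 1.0)
    keep = sd > 1e-12 * scale_ref
    if not np.all(keep):
        dropped = [nm for nm, k in zip(matrix.names, keep) if not k]
        warnings.warn(f"dropping constant descriptor columns: {dropped}")
    names = [nm for nm, k in zip(matrix.names, keep) if k]
    if len(names) < 2:
        raise ValueError("PCA requires at least 2 non-constant descriptors")
    x = matrix.values[:, keep]
    means = x.mean(axis=0)
    scales = sd[keep] if scaling == "unit_variance" else np.ones(len(names))
    z = (x - means) / scales

    # SVD of the scaled matrix; eigenvalue_a = s_a^2 / (n - 1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    a_max = min(rank, max_pcs) if max_pcs else rank
    a_max = max(a_max, 1)
    loadings = vt[:a_max].T
    eigenvalues = (s[:a_max] ** 2) / (n - 1)
    total_ss = float(np.sum(z ** 2))
    r2x = (s[:a_max] ** 2) / total_ss

    n_sig = int(np.sum(eigenvalues >= SIGNIFICANT_EIGENVALUE))
    n_sig = max(n_sig, 1)
    n_sig = min(n_sig, a_max)

    # Hotelling T^2 95% limit on A significant PCs
    a = n_sig
    if n > a:
        f_crit = stats.f.ppf(0.95, a, n - a)
        t2_limit = a * (n - 1) / (n - a) * f_crit
    else:  # degenerate: too few observations for the F scaling
        t2_limit = np.inf

    # DModX: pooled residual SD s0 and F-based 95% limit
    p = len(names)
    scores_sig = z @ loadings[:, :a]
    resid = z - scores_sig @ loadings[:, :a].T
    dof_model = (n - a - 1) * (p - a)
    if dof_model > 0 and p > a:
        s0 = float(np.sqrt(np.sum(resid ** 2) / dof_model))
    else:
        s0 = 0.0
    if s0 > 1e-12:
        dmodx_crit = float(np.sqrt(stats.f.ppf(0.95, p - a, dof_model)))
    else:
        warnings.warn("zero residual variance; DModX limit computation skipped")
        dmodx_crit = 0.0

    return PCAModel(
        names=names,
        column_means=means,
        column_scales=scales,
        loadings=loadings,
        eigenvalues=eigenvalues,
        r2x=r2x,
        n_significant=n_sig,
        t2_limit_95=float(t2_limit),
        dmodx_crit_95=dmodx_crit,
        s0=s0,
        n_train=n,
    )


def project(model: PCAModel, matrix: DescriptorMatrix) -> ScoreMatrix:
    """Project compounds into the model's significant-PC score space."""
    z = model._scale(matrix)
    scores = z @ model.loadings[:, : model.n_significant]
    return ScoreMatrix(list(matrix.ids), scores, model_tag=id(model))


def applicability_domain(model: PCAModel, matrix: DescriptorMatrix) -> ADResult:
    """Hotelling T² and DModX for each compound, with 95% in/out decision.

    T² = Σ_a t_a²/λ_a over the significant PCs; DModX is the residual SD of
    the descriptor reconstruction normalized by the training pooled residual
    SD.  ``inside`` requires both statistics at or below their 95% limits.
    """
    z = model._scale(matrix)
    a = model.n_significant
    load = model.loadings[:, :a]
    scores = z @ load
    t2 = np.sum(scores ** 2 / model.eigenvalues[:a], axis=1)
    resid = z - scores @ load.T
    p = len(model.names)
    if model.s0 > 1e-12 and p > a:
        s_obs = np.sqrt(np.sum(resid ** 2, axis=1) / (p - a))
        dmodx = s_obs / model.s0
    else:
        dmodx = np.zeros(len(matrix.ids))
    inside = (t2 <= model.t2_limit_95) & (dmodx <= model.dmodx_crit_95 + 1e-12) \
        if model.dmodx_crit_95 > 0 else (t2 <= model.t2_limit_95)
    return ADResult(list(matrix.ids), t2, dmodx, inside)


@dataclass
class FiltrationResult:
    """Outcome of the dual typical/atypical initial filtration."""

    typical_hits: set[str]
    atypical_hits: set[str]

    @property
    def union(self) -> set[str]:
        return self.typical_hits | self.atypical_hits

    @property
    def overlap(self) -> set[str]:
        return self.typical_hits & self.atypical_hits


def initial_filtration(
    binder_matrix: DescriptorMatrix,
    atypical_matrix: DescriptorMatrix,
    candidate_matrix: DescriptorMatrix,
    ed_cutoff_atypical: float = ED_CUTOFF_ATYPICAL,
) -> FiltrationResult:
    """Run the dual initial filtration of a candidate library.

    Typical branch: candidates inside the 95% applicability domain of a PCA
    fitted on the binder reference set alone.  Atypical branch: candidates
    within ``ed_cutoff_atypical`` (inclusive) of any atypical reference in
    the significant-PC score space of a PCA fitted on the log-transformed
    descriptors of atypical references ∪ candidates.
    """
    if not binder_matrix.ids or not atypical_matrix.ids:
        raise ValueError("reference sets must be non-empty")
    if not candidate_matrix.ids:
        return FiltrationResult(set(), set())

    # typical branch: AD membership w.r.t. the binder model
    binder_model = fit_pca(binder_matrix, scaling="unit_variance")
    ad = applicability_domain(binder_model, candidate_matrix)
    typical = ad.inside_ids()

    # atypical branch: joint log-transformed PCA, ED to any atypical reference
    joint = DescriptorMatrix(
        list(atypical_matrix.ids) + list(candidate_matrix.ids),
        list(atypical_matrix.names),
        np.vstack([atypical_matrix.values, candidate_matrix.values]),
    )
    joint_logged = log_transform(joint)
    joint_model = fit_pca(joint_logged, scaling="unit_variance")
    scores = project(joint_model, joint_logged)
    n_ref = len(atypical_matrix.ids)
    ref_scores = scores.scores[:n_ref]
    cand_scores = scores.scores[n_ref:]
    d = np.sqrt(
        ((cand_scores[:, None, :] - ref_scores[None, :, :]) ** 2).sum(axis=2)
    )
    atypical = {
        mol_id
        for mol_id, row in zip(candidate_matrix.ids, d)
        if row.min() <= ed_cutoff_atypical
    }

    result = FiltrationResult(typical, atypical)
    logger.info(
        "initial filtration: typical=%d atypical=%d overlap=%d union=%d",
        len(typical), len(atypical), len(result.overlap), len(result.union),
    )
    return result
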