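"""Phylogenetic generalized least squares with ML estimation of Pagel's λ.

The expected trait covariance between two tips under Brownian motion is
the branch length shared on their root-to-tip paths, i.e. the depth of
their most recent common ancestor.  Pagel's λ rescales the off-diagonal
entries of this matrix; λ = 0 removes all phylogenetic signal, λ = 1 is
pure Brownian motion.  λ is profiled out by maximum likelihood on a
coarse grid followed by golden-section refinement, and the regression is
solved through a Cholesky factorization of the covariance (no explicit
inverse).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy import linalg, optimize

from .allometry import AllometricFit, delta_method_se_a, log10_transform
from .errors import DataValidationError, InsufficientDataError, NumericalError
from .io_tables import SpeciesRecord

LAMBDA_GRID_STEP = 0.01


def load_tree(source) -> dendropy.Tree:
    """Read a single Newick tree, treated as rooted at its first node.

    Underscores in labels are preserved verbatim; matching against
    species names normalizes them later.
    """
    path = str(source)
    tree = dendropy.Tree.get(
        path=path,
        schema="newick",
        preserve_underscores=True,
        rooting="default-rooted",
    )
    return tree


def normalize_label(label: str) -> str:
    """Canonical species label: trimmed, underscores mapped to spaces."""
    return " ".join(label.strip().replace("_", " ").split())


@dataclasses.dataclass
class PhyloCovariance:
    """Among-tip expected trait covariance from a tree, with λ scaling.

    ``matrix[i, j]`` is the root-to-MRCA depth of tips ``tip_order[i]``
    and ``tip_order[j]``; the diagonal holds root-to-tip distances.
    """

    tip_order: list[str]
    matrix: np.ndarray
    lam: float = 1.0

    def reorder(self, labels: Sequence[str]) -> "PhyloCovariance":
        """Return a copy with rows/columns permuted into ``labels`` order."""
        index = {t: i for i, t in enumerate(self.tip_order)}
        try:
            perm = [index[l] for l in labels]
        except KeyError as exc:
            raise DataValidationError(f"label not in covariance: {exc}") from exc
        return PhyloCovariance(list(labels), self.matrix[np.ix_(perm, perm)], self.lam)


def vcv_from_tree(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian-motion covariance matrix (λ = 1) from a rooted tree.

    Entry (i, j) is the depth (total branch length from the root) of the
    most recent common ancestor of tips i and j.  Polytomies are
    accepted; they simply flatten the covariance structure.
    """
    if tree.is_rooted is False:
        raise DataValidationError(
            "tree must be rooted; apply midpoint or outgroup rooting first"
        )
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise DataValidationError("tree must have at least 2 tips")
    labels = [lf.taxon.label if lf.taxon else str(id(lf)) for lf in leaves]
    if len(set(labels)) != len(labels):
        raise DataValidationError("tip labels must be unique")
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    cov = np.zeros((n, n))

    # Postorder sweep: at each internal node of depth d, every pair of
    # tips whose paths first meet there gets covariance d.
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        el = node.edge.length if node.edge.length is not None else 0.0
        if el < 0:
            raise DataValidationError("branch lengths must be non-negative")
        depth[id(node)] = depth[id(node.parent_node)] + el

    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            cov[i, i] = depth[id(node)]
            continue
        children = node.child_nodes()
        groups = [below.pop(id(c)) for c in children]
        d = depth[id(node)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    cov[i, groups[gj]] = d
                    cov[groups[gj], i] = d
        below[id(node)] = [i for g in groups for i in g]
    return PhyloCovariance(labels, cov, lam=1.0)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal covariances by λ ∈ [0, 1]; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    m = C.matrix * lam
    np.fill_diagonal(m, C.matrix.diagonal())
    return PhyloCovariance(list(C.tip_order), m, lam=lam)


@dataclasses.dataclass
class GLSResult:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    sigma2: float
    log_likelihood: float
    r2: float
    n: int


def _chol(C: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "phylogenetic covariance is singular; jitter zero-length branches "
            "or drop duplicate tips"
        ) from exc


def gls_fit(x, y, C: PhyloCovariance) -> GLSResult:
    """GLS regression of y on x with error covariance proportional to C.

    β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with X = [1, x]; σ² is profiled by ML as
    rᵀC⁻¹r / n.  The log-likelihood includes the log-determinant of C.
    R² is computed in the whitened (L⁻¹-transformed) space against the
    GLS-estimated mean of y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if C.matrix.shape != (n, n):
        raise ValueError("covariance dimension does not match data length")
    L = _chol(C.matrix)
    X = np.column_stack([np.ones(n), x])
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    try:
        beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise NumericalError("whitened design is singular") from exc
    resid_w = yw - Xw @ beta
    rss_w = float(resid_w @ resid_w)
    sigma2 = rss_w / n
    logdet = 2.0 * float(np.sum(np.log(L.diagonal())))
    if sigma2 <= 0:
        # exact interpolation: likelihood degenerates
        loglik = math.inf
    else:
        loglik = -0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet)
    cov_beta = linalg.inv(XtX) * (rss_w / (n - 2) if n > 2 else float("nan"))
    # whitened-space R^2 against the GLS mean of y
    ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = float((ones_w @ yw) / (ones_w @ ones_w))
    tss_w = float(np.sum((yw - mu * ones_w) ** 2))
    r2 = 1.0 - rss_w / tss_w if tss_w > 0 else 1.0
    return GLSResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_slope=float(np.sqrt(cov_beta[1, 1])),
        se_intercept=float(np.sqrt(cov_beta[0, 0])),
        sigma2=sigma2,
        log_likelihood=loglik,
        r2=r2,
        n=n,
    )


def profile_lambda_ml(x, y, C: PhyloCovariance, tol: float = 1e-6
                      ) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """ML estimate of Pagel's λ on [0, 1] by grid search plus refinement.

    A coarse grid (step 0.01) locates the mode; golden-section search
    then refines it to ``tol``.  Boundary values 0 and 1 are admissible.
    Returns (λ̂, (grid, log-likelihood at each grid point)).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("need at least 4 tips to profile lambda")
    grid = np.arange(0.0, 1.0 + LAMBDA_GRID_STEP / 2, LAMBDA_GRID_STEP)

    def nll(lam: float) -> float:
        return -gls_fit(x, y, lambda_transform(C, lam)).log_likelihood

    values = np.array([-nll(l) for l in grid])
    if not np.all(np.isfinite(values)):
        bad = grid[~np.isfinite(values)][0]
        raise NumericalError(f"non-finite log-likelihood at lambda = {bad:.2f}")
    best = int(np.argmax(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded",
            options={"xatol": tol},
        )
        lam_hat = float(res.x)
        if -res.fun < values[best]:
            lam_hat = float(grid[best])
    else:
        lam_hat = float(grid[best])
    return lam_hat, (grid, values)


def prune_and_match(records: Iterable[SpeciesRecord], tree: dendropy.Tree
                    ) -> tuple[list[SpeciesRecord], dendropy.Tree, dict]:
    """Intersect species records with tree tips; order records to tips.

    Matching is exact after normalization (trim, underscores ↔ spaces).
    Returns (aligned records, pruned tree copy, report) where the report
    lists ``dropped_records`` and ``dropped_tips`` by name.
    """
    records = list(records)
    by_name = {}
    for r in records:
        by_name[normalize_label(r.species)] = r
    taxa = [t for t in tree.taxon_namespace if t.label]
    tip_norm = {t: normalize_label(t.label) for t in taxa}
    keep_taxa = [t for t in taxa if tip_norm[t] in by_name]
    matched_names = {tip_norm[t] for t in keep_taxa}
    report = {
        "dropped_records": sorted(
            r.species for r in records if normalize_label(r.species) not in matched_names
        ),
        "dropped_tips": sorted(
            t.label for t in taxa if tip_norm[t] not in by_name
        ),
        "n_matched": len(keep_taxa),
    }
    if not keep_taxa:
        raise DataValidationError(
            "no overlap between species table and tree tip labels"
        )
    pruned = tree.extract_tree_with_taxa(taxa=keep_taxa)
    aligned = [by_name[normalize_label(lf.taxon.label)]
               for lf in pruned.leaf_node_iter()]
    return aligned, pruned, report


def pgls_allometry(records: Iterable[SpeciesRecord], tree: dendropy.Tree,
                   group_label: str = "", jitter: float = 1e-8
                   ) -> AllometricFit:
    """PGLS allometric fit: match tips, build the covariance, profile λ,
    and report the fit at λ̂ with a delta-method SE for the coefficient.

    Zero diagonal entries (zero-length terminal paths) are jittered by
    ``jitter`` × tree depth with a warning before inversion.
    """
    aligned, pruned, report = prune_and_match(records, tree)
    if len(aligned) < 4:
        raise InsufficientDataError(
            f"PGLS needs at least 4 matched species, got {len(aligned)} "
            f"(unmatched records: {report['dropped_records']})"
        )
    x, y = log10_transform(aligned)
    C = vcv_from_tree(pruned)
    depth = float(C.matrix.diagonal().max())
    zero_diag = C.matrix.diagonal() == 0
    if np.any(zero_diag):
        warnings.warn("jittering zero-length root-to-tip paths before inversion")
        m = C.matrix.copy()
        m[np.diag_indices_from(m)] += jitter * max(depth, 1.0) * zero_diag
        C = PhyloCovariance(C.tip_order, m, C.lam)
    lam_hat, _ = profile_lambda_ml(x, y, C)
    res = gls_fit(x, y, lambda_transform(C, lam_hat))
    return AllometricFit(
        group_label=group_label,
        a=10.0 ** res.intercept,
        b=res.slope,
        se_a=delta_method_se_a(res.intercept, res.se_intercept),
        se_b=res.se_slope,
        intercept_log10=res.intercept,
        se_intercept_log10=res.se_intercept,
        r2=res.r2,
        n=res.n,
        method="PGLS",
        lambda_hat=lam_hat,
    )
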