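"""Community structure: diversity, Bray–Curtis distances, partial dbRDA,
and predator–prey co-occurrence screens.

The ordination follows the classical distance-based redundancy analysis
recipe: principal-coordinates embedding of the Bray–Curtis matrix (axes with
positive eigenvalues only; discarded negative inertia is recorded), optional
partialling-out of a conditioning factor (site), then redundancy analysis on
the habitat constraint with a pseudo-F tested by reduced-model residual
permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from skbio import DistanceMatrix as SkbioDistanceMatrix

from .data_model import DensityMatrix
from .resampling import bootstrap_mean, permutation_probability


def log_transform(matrix, base: float = 2.0):
    """Zero-preserving logarithmic abundance transform.

    Positive entries x map to log_base(x / m) + 1 where m is the smallest
    positive entry of the whole matrix; zeros stay zero. Hence the smallest
    positive value maps to exactly 1, and doubling a value raises its
    transform by exactly 1 at base 2. (For matrices whose minimum positive
    entry is >= 1 the division is skipped, so integer counts transform as
    log_base(x) + 1.) Accepts a DataFrame, ndarray or DensityMatrix and
    returns the same type.
    """
    if isinstance(matrix, DensityMatrix):
        return DensityMatrix(
            data=log_transform(matrix.data, base=base), habitat=matrix.habitat
        )
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if (values < 0).any():
        raise ValueError("log transform requires non-negative entries")
    positive = values[values > 0]
    out = np.zeros_like(values)
    if positive.size:
        m = positive.min()
        scale = m if m < 1 else 1.0
        mask = values > 0
        out[mask] = np.log(values[mask] / scale) / np.log(base) + 1.0
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def bray_curtis(matrix) -> SkbioDistanceMatrix:
    """Bray–Curtis dissimilarities between tows.

    ``matrix`` is a DensityMatrix (groups x tows; transposed internally) or
    a tows x groups DataFrame/array. Pairs of all-zero tows are undefined
    (0/0); they are set to 0 and reported with a warning.
    """
    if isinstance(matrix, DensityMatrix):
        table = matrix.data.T
    elif isinstance(matrix, pd.DataFrame):
        table = matrix
    else:
        table = pd.DataFrame(np.asarray(matrix, dtype=float))
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    empty = ~X.any(axis=1)
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    if empty.sum() >= 2:
        warnings.warn(
            f"{int(empty.sum())} all-zero tows: their pairwise distances are "
            "undefined and set to 0"
        )
    D = np.nan_to_num(D, nan=0.0)
    np.fill_diagonal(D, 0.0)
    return SkbioDistanceMatrix(D, ids=[str(i) for i in table.index])


@dataclass
class RdaResult:
    pseudo_F: float
    p_value: float
    df_model: int
    df_residual: int
    site_scores: pd.DataFrame            # tows x (CAP1, Residual1)
    constrained_axis_variance: float     # share of (conditioned) inertia
    n_permutations: int
    negative_inertia: float              # discarded PCoA inertia
    permuted_F: np.ndarray = field(repr=False, default=None)


def _indicator(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Full-rank dummy coding (first level dropped), float matrix."""
    dummies = pd.get_dummies(pd.Series(np.asarray(labels)), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _orthonormal_basis(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of M (may be empty)."""
    if M.size == 0:
        return np.zeros((M.shape[0], 0))
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def pcoa_embedding(D: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal coordinates of a distance matrix.

    Returns (coordinates on positive-eigenvalue axes, all eigenvalues,
    total negative inertia discarded).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = J @ A @ J
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-12
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    negative_inertia = float(-evals[evals < -tol].sum())
    return coords, evals, negative_inertia


def db_rda(
    distances,
    constraint,
    condition=None,
    n_perm: int = 10_000,
    seed=None,
) -> RdaResult:
    """Partial distance-based redundancy analysis with permutation test.

    Parameters
    ----------
    distances : skbio DistanceMatrix or square array of dissimilarities.
    constraint : habitat labels (one per tow); must have >= 2 levels.
    condition : optional site labels partialled out of both the embedded
        coordinates and the constraint before the F computation.
    n_perm : permutations for the reduced-model residual test; the p-value
        is (1 + #{F_perm >= F_obs}) / (1 + n_perm) and can never be 0.

    Under the hood: PCoA of the distances (positive axes), residualization
    of coordinates and constraint dummies on [intercept | condition
    dummies], projection of the residualized coordinates onto the
    residualized constraint, and pseudo-F =
    (SS_constrained / df_model) / (SS_residual / df_residual).
    """
    if isinstance(distances, SkbioDistanceMatrix):
        D = distances.data
        ids = list(distances.ids)
    else:
        D = np.asarray(distances, dtype=float)
        ids = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    constraint = pd.Series(np.asarray(constraint))
    if constraint.nunique() < 2:
        raise ValueError("constraint must have at least two levels")
    if len(constraint) != n:
        raise ValueError("constraint length does not match distance matrix")

    Y, _, negative_inertia = pcoa_embedding(D)

    Z = np.ones((n, 1))
    if condition is not None:
        Z = np.hstack([Z, _indicator(condition)])
    Qz = _orthonormal_basis(Z)

    X = _indicator(constraint)
    X_res = X - Qz @ (Qz.T @ X)
    Qx = _orthonormal_basis(X_res)
    if Qx.shape[1] == 0:
        raise ValueError("constraint is collinear with the condition")
    df_model = Qx.shape[1]
    df_residual = n - Qz.shape[1] - df_model
    if df_residual <= 0:
        raise ValueError("no residual degrees of freedom")

    Y_res = Y - Qz @ (Qz.T @ Y)
    total_ss = float((Y_res**2).sum())
    proj = Qx.T @ Y_res
    ss_model = float((proj**2).sum())
    ss_resid = total_ss - ss_model
    F_obs = (ss_model / df_model) / (ss_resid / df_residual)

    # reduced-model residual permutation: shuffle rows of the conditioned
    # coordinates, re-partial the condition, recompute F
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_Y_ss = float((Y_res**2).sum())
    F_perm = np.empty(n_perm)
    B = np.hstack([Qx, Qz])  # projections needed per permutation
    kx = Qx.shape[1]
    for i in range(n_perm):
        perm = rng.permutation(n)
        Yp = Y_res[perm]
        P = B.T @ Yp
        ssm = float((P[:kx] ** 2).sum())
        ssz = float((P[kx:] ** 2).sum())
        sst = all_Y_ss - ssz        # total after re-partialling the condition
        ssr = sst - ssm
        F_perm[i] = (ssm / df_model) / (ssr / df_residual)
    p_value = (1.0 + float(np.sum(F_perm >= F_obs))) / (1.0 + n_perm)

    # scores: first constrained axis and first residual axis
    fitted = Qx @ proj
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    cap1 = Y_res @ vt[0]                     # sample scores on CAP1
    resid = Y_res - fitted
    ur, sr, vtr = np.linalg.svd(resid, full_matrices=False)
    res1 = resid @ vtr[0]
    scores = pd.DataFrame({"CAP1": cap1, "Residual1": res1}, index=ids)

    return RdaResult(
        pseudo_F=float(F_obs), p_value=float(p_value),
        df_model=int(df_model), df_residual=int(df_residual),
        site_scores=scores,
        constrained_axis_variance=float(ss_model / total_ss),
        n_permutations=int(n_perm), negative_inertia=negative_inertia,
        permuted_F=F_perm,
    )


@dataclass
class DiversityResult:
    per_tow: pd.DataFrame                 # tow_id, habitat, shannon_H, richness_S
    group_means: pd.DataFrame             # habitat x (H mean/BI, S mean/BI)
    prob_H: float                         # P(H̄_slick > H̄_ambient)
    prob_S: float


def shannon_index(abundances, base: float | None = None) -> float:
    """Shannon diversity H' = -Σ p ln p of one tow's abundance vector.

    Natural log by default; invariant to rescaling counts to densities.
    """
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        return float("nan")
    p = x / x.sum()
    H = float(-(p * np.log(p)).sum())
    if base is not None:
        H /= np.log(base)
    return H


def diversity_contrast(
    matrix: DensityMatrix,
    nboot: int = 10_000,
    nperm: int = 10_000,
    seed=None,
    base: float | None = None,
) -> DiversityResult:
    """Per-tow Shannon H' and richness S, contrasted between habitats.

    Tows with no organisms at all have undefined H'; they are excluded from
    the H' contrast with a warning (richness 0 is kept for S).
    """
    rng = np.random.default_rng(seed)
    H = matrix.data.apply(lambda col: shannon_index(col.to_numpy(), base=base), axis=0)
    S = (matrix.data > 0).sum(axis=0).astype(int)
    per_tow = pd.DataFrame({
        "habitat": matrix.habitat, "shannon_H": H, "richness_S": S,
    })
    empty = per_tow["shannon_H"].isna()
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty tows excluded from the H' contrast"
        )
    rows = {}
    for stat, drop_na in (("shannon_H", True), ("richness_S", False)):
        for hab in ("slick", "ambient"):
            vals = per_tow.loc[per_tow["habitat"] == hab, stat]
            if drop_na:
                vals = vals.dropna()
            b = bootstrap_mean(vals.to_numpy(dtype=float), nboot=nboot, seed=rng)
            rows[(stat, hab)] = {
                "mean": b.point_mean, "bi_low": b.bi_low, "bi_high": b.bi_high,
            }
    group_means = pd.DataFrame(rows).T
    ok = per_tow.dropna(subset=["shannon_H"])
    prob_H = permutation_probability(
        ok.loc[ok["habitat"] == "slick", "shannon_H"],
        ok.loc[ok["habitat"] == "ambient", "shannon_H"],
        nperm=nperm, seed=rng,
    )
    prob_S = permutation_probability(
        per_tow.loc[per_tow["habitat"] == "slick", "richness_S"],
        per_tow.loc[per_tow["habitat"] == "ambient", "richness_S"],
        nperm=nperm, seed=rng,
    )
    return DiversityResult(per_tow=per_tow, group_means=group_means,
                           prob_H=prob_H, prob_S=prob_S)


def spearman_overlap(
    fish_density: pd.Series,
    prey_matrix: pd.DataFrame,
    habitat: pd.Series,
    alpha: float = 0.05,
    log: bool = True,
) -> pd.DataFrame:
    """Spearman correlation of larval-fish density against each prey group,
    computed separately inside each habitat.

    ``fish_density`` and the columns of ``prey_matrix`` are per-tow density
    vectors (indexed by tow_id); densities are log-transformed first by
    default (rank correlations are unchanged by the monotone transform, but
    the option mirrors the analysis convention). Requires >= 5 tows per
    habitat. Constant vectors give undefined r, flagged as NaN.
    """
    habitat = habitat.reindex(fish_density.index)
    rows = []
    for hab in ("slick", "ambient"):
        tows = habitat.index[habitat == hab]
        if len(tows) < 5:
            raise ValueError(f"need >= 5 tows per habitat, {hab} has {len(tows)}")
        f = fish_density.reindex(tows).to_numpy(dtype=float)
        for prey in prey_matrix.columns:
            y = prey_matrix[prey].reindex(tows).to_numpy(dtype=float)
            if log:
                fv, yv = np.log1p(f), np.log1p(y)
            else:
                fv, yv = f, y
            if np.all(fv == fv[0]) or np.all(yv == yv[0]):
                r, p = float("nan"), float("nan")
                warnings.warn(f"constant vector for {prey} in {hab}; r undefined")
            else:
                r, p = spearmanr(fv, yv)
            rows.append({
                "habitat": hab, "prey_group": prey, "r": float(r),
                "p": float(p), "significant": bool(p < alpha) if p == p else False,
            })
    table = pd.DataFrame(rows)
    table.attrs["mean_r"] = table.groupby("habitat")["r"].mean().to_dict()
    table.attrs["n_significant"] = (
        table.groupby("habitat")["significant"].sum().astype(int).to_dict()
    )
    return table
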