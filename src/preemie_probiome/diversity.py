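"""Alpha/beta diversity, NMDS ordination, and the mixed-effects diversity model.

Shannon diversity is computed in nats. Between-sample dissimilarity is
Bray-Curtis on relative abundances, held in a :class:`skbio.DistanceMatrix`.
Ordination is non-metric multidimensional scaling (Kruskal stress-1,
SMACOF majorization with isotonic regression, best of several seeded
restarts). The group comparison of Shannon diversity is a Gaussian linear
mixed model with a random intercept per infant, with a seeded
infant-level permutation fallback when the REML fit is degenerate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def _as_composition(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("composition has negative entries")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"composition sums to {total}, expected 1")
    return p


def shannon(p) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats), zero terms dropped."""
    p = _as_composition(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b) between two compositions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"taxon sets differ: {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative abundances")
    denom = (a + b).sum()
    if denom == 0:
        return 0.0
    return float(np.abs(a - b).sum() / denom)


def distance_matrix(profiles) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances for a :class:`TaxonProfileMatrix`."""
    if profiles.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    condensed = pdist(profiles.values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(profiles.sample_ids))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.write(str(path))


def read_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path))


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling of a precomputed dissimilarity matrix.

    Parameters
    ----------
    n_components : embedding dimensionality (default 2).
    n_init : random restarts; the lowest-stress solution is kept.
    max_iter : SMACOF iteration cap per restart.
    eps : relative stress-change convergence tolerance.
    random_state : seed; fixed seed gives identical coordinates across runs.

    Attributes (after ``fit``)
    --------------------------
    embedding_ : (n_samples, n_components) coordinates, column-centered.
    stress_ : Kruskal stress-1 of the returned configuration, in [0, 1].
    converged_ : whether the winning restart stopped before ``max_iter``.
    n_iter_ : iterations used by the winning restart.
    """

    def __init__(self, n_components=2, n_init=20, max_iter=300, eps=1e-7, random_state=None):
        self.n_components = n_components
        self.n_init = n_init
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, D, y=None):
        if isinstance(D, DistanceMatrix):
            self.ids_ = list(D.ids)
            mat = D.data
        else:
            mat = np.asarray(D, dtype=float)
            self.ids_ = list(range(mat.shape[0]))
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("D must be a square dissimilarity matrix")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        mds = MDS(
            n_components=self.n_components,
            metric=False,
            n_init=self.n_init,
            max_iter=self.max_iter,
            eps=self.eps,
            dissimilarity="precomputed",
            normalized_stress=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = mds.fit_transform(mat)
        coords = coords - coords.mean(axis=0, keepdims=True)
        self.embedding_ = coords
        self.stress_ = float(mds.stress_)
        self.n_iter_ = int(mds.n_iter_)
        self.converged_ = self.n_iter_ < self.max_iter
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_

    def coordinates_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "embedding_")
        cols = [f"NMDS{i + 1}" for i in range(self.embedding_.shape[1])]
        return pd.DataFrame(self.embedding_, index=self.ids_, columns=cols)


def nmds(D, k: int = 2, restarts: int = 20, max_iter: int = 300, tol: float = 1e-7, seed=None) -> NMDS:
    """Functional wrapper over :class:`NMDS` (returns the fitted estimator)."""
    return NMDS(
        n_components=k, n_init=restarts, max_iter=max_iter, eps=tol, random_state=seed
    ).fit(D)


def group_centroids(coords, labels) -> pd.DataFrame:
    """Per-group mean ordination coordinate (one row per group)."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != coords.shape[0]:
        raise ValueError("one label per sample required")
    rows = {}
    for g in pd.unique(labels):
        mask = labels == g
        if not mask.any():
            logger.warning("group %r empty; centroid omitted", g)
            continue
        rows[g] = coords[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class MixedModelResult:
    """Group effect on Shannon diversity from the mixed (or fallback) model."""

    effect: float
    p_value: float
    method: str  # "reml" or "permutation"
    n_infants: int
    n_samples: int
    summary: str = ""


DEFAULT_DIVERSITY_COVARIATES = (
    "probiotic",
    "mom",
    "bmf",
    "formula",
    "antibiotics_7d",
    "season",
    "birth_mode",
    "sex",
)


def diversity_mixed_model(
    data: pd.DataFrame,
    response: str = "shannon",
    group_col: str = "group",
    infant_col: str = "infant_id",
    covariates=DEFAULT_DIVERSITY_COVARIATES,
    n_perm: int = 999,
    seed=None,
) -> MixedModelResult:
    """Test a group difference in diversity while adjusting for covariates.

    Fits ``response ~ group + covariates`` with a random intercept per
    infant by REML and reports the group coefficient with its two-sided
    Wald p-value. If the fit is singular or fails to converge, falls back
    to a seeded infant-level permutation test on infant-mean diversity
    (group labels permuted across infants).
    """
    import statsmodels.formula.api as smf

    df = data.copy()
    groups = pd.unique(df[group_col])
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {list(groups)}")
    counts = df.groupby(group_col)[infant_col].nunique()
    if (counts < 2).any():
        raise ValueError("need at least 2 infants per group")

    usable = [c for c in covariates if c in df.columns and df[c].nunique() > 1]
    terms = [f"C({group_col})"] + [
        f"C({c})" if df[c].dtype == object or df[c].dtype == bool else c for c in usable
    ]
    formula = f"{response} ~ " + " + ".join(terms)

    result = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df[infant_col])
            fit = model.fit(reml=True)
        coef_name = next(n for n in fit.params.index if n.startswith(f"C({group_col})"))
        effect = float(fit.params[coef_name])
        p = float(fit.pvalues[coef_name])
        if np.isfinite(effect) and np.isfinite(p):
            result = MixedModelResult(
                effect=effect,
                p_value=p,
                method="reml",
                n_infants=int(df[infant_col].nunique()),
                n_samples=len(df),
                summary=str(fit.summary()),
            )
    except Exception as exc:  # singular / non-converged fits
        logger.info("mixed model fit failed (%s); using permutation fallback", exc)

    if result is None or not np.isfinite(result.p_value):
        result = _permutation_group_test(df, response, group_col, infant_col, n_perm, seed)
    return result


def _permutation_group_test(df, response, group_col, infant_col, n_perm, seed) -> MixedModelResult:
    """Infant-level permutation test on the difference of infant-mean diversity."""
    logger.info("running infant-level permutation test (%d permutations)", n_perm)
    per_infant = df.groupby(infant_col).agg({response: "mean", group_col: "first"})
    values = per_infant[response].to_numpy(dtype=float)
    labels = per_infant[group_col].to_numpy()
    gnames = pd.unique(labels)
    mask = labels == gnames[0]

    def stat(m):
        return values[m].mean() - values[~m].mean()

    obs = stat(mask)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(mask)
        if abs(stat(perm)) >= abs(obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MixedModelResult(
        effect=float(obs),
        p_value=float(p),
        method="permutation",
        n_infants=len(per_infant),
        n_samples=len(df),
    )


def shannon_table(profiles, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon diversity joined onto the covariate table."""
    H = [shannon(row) for row in profiles.values]
    out = covariates.loc[list(profiles.sample_ids)].copy()
    out["shannon"] = H
    return out
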