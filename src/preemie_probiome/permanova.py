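"""Permutational multivariate ANOVA (PERMANOVA) on a distance matrix.

Implements the classical partition of a squared-distance matrix: the
Gower-centered inner-product matrix ``G = -1/2 * C * D^2 * C`` has total
sum of squares ``trace(G)``, and each model term's sum of squares is the
trace of ``G`` projected onto the span added by that term's design columns
(sequential, Type I, in user-given order — the behaviour of vegan's
``adonis``). Pseudo-F statistics are referenced to a permutation null in
which rows/columns of ``D`` are permuted simultaneously; p-values use the
``(1 + more-extreme) / (1 + n_perm)`` convention, or exhaustive
enumeration of all permutations when requested.

Also provides the per-timepoint covariate variance grid (one cross-
sectional PERMANOVA per window with one sample per infant) and
Benjamini-Hochberg FDR control across the whole grid.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .cohort_io import TIME_WINDOWS, covariate_table, select_one_sample_per_infant, window_label
from .diversity import distance_matrix

logger = logging.getLogger(__name__)

#: Grid covariates, in model order (the exposures and demographics
#: recorded per sample, led by probiotic receipt).
DEFAULT_COVARIATES = (
    "probiotic",
    "mom",
    "bmf",
    "formula",
    "antibiotics_7d",
    "season",
    "birth_mode",
    "sex",
)


class RankDeficiencyError(ValueError):
    """A term adds no residual degrees of freedom (confounded with earlier terms)."""


@dataclass
class PermanovaTerm:
    covariate: str
    timepoint: str | None
    df: int
    ss: float
    r2: float
    pseudo_f: float
    p_value: float
    q_value: float | None = None
    n_samples: int = 0
    n_permutations: int = 0


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    residual_ss: float
    residual_df: int
    total_ss: float
    n_samples: int

    @property
    def residual_r2(self) -> float:
        return self.residual_ss / self.total_ss

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "covariate": t.covariate,
                "df": t.df,
                "ss": t.ss,
                "R2": t.r2,
                "F": t.pseudo_f,
                "p": t.p_value,
            }
            for t in self.terms
        ]
        rows.append(
            {
                "covariate": "Residual",
                "df": self.residual_df,
                "ss": self.residual_ss,
                "R2": self.residual_r2,
                "F": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _design_columns(design: pd.DataFrame, name: str) -> np.ndarray:
    col = design[name]
    if col.dtype.kind in "ifu" and col.nunique() > 2 and not isinstance(col.dtype, pd.CategoricalDtype):
        x = col.to_numpy(dtype=float)[:, None]
        return x
    dummies = pd.get_dummies(col.astype(str), drop_first=True)
    if dummies.shape[1] == 0:
        raise ValueError(f"covariate {name!r} has fewer than 2 levels present")
    return dummies.to_numpy(dtype=float)


def _hat(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(
    dm,
    design: pd.DataFrame,
    order=None,
    n_perm: int | None = 999,
    seed=None,
) -> PermanovaResult:
    """Sequential (Type I) PERMANOVA of ``design`` covariates on distances ``dm``.

    Parameters
    ----------
    dm : skbio.DistanceMatrix or square ndarray, aligned with ``design`` rows
        (by sample id when both carry ids).
    design : per-sample covariate table.
    order : covariate order for the sequential decomposition
        (default: ``design`` column order).
    n_perm : number of random permutations; ``None`` enumerates all
        permutations exhaustively (only feasible for small n) and reports
        the exact proportion of arrangements at least as extreme.
    seed : RNG seed for the permutation sampler.
    """
    if isinstance(dm, DistanceMatrix):
        ids = list(dm.ids)
        d = dm.data
        if set(map(str, design.index)) == set(map(str, ids)):
            design = design.set_axis(design.index.map(str)).loc[ids]
        elif len(design) != len(ids):
            raise ValueError("design rows do not match distance-matrix ids")
    else:
        d = np.asarray(dm, dtype=float)
        ids = list(design.index)
    n = d.shape[0]
    if len(design) != n:
        raise ValueError("design and distance matrix are not aligned")
    if n < 3:
        raise ValueError("need at least 3 samples")

    order = list(order) if order is not None else list(design.columns)
    g = _gower_center(d)
    total_ss = float(np.trace(g))
    if total_ss <= 1e-12:
        raise ValueError("total sum of squares is zero (all samples identical)")

    # nested hat matrices for the sequential decomposition
    ones = np.ones((n, 1))
    X = ones
    hats = [_hat(X)]
    dfs = []
    for name in order:
        cols = _design_columns(design, name)
        X = np.hstack([X, cols])
        h = _hat(X)
        df_term = int(round(np.trace(h) - np.trace(hats[-1])))
        if df_term == 0:
            raise RankDeficiencyError(
                f"covariate {name!r} is confounded with preceding terms (adds 0 df)"
            )
        dfs.append(df_term)
        hats.append(h)
    resid_df = n - int(round(np.trace(hats[-1])))
    if resid_df <= 0:
        raise RankDeficiencyError("model saturates the data (no residual df)")

    delta_hats = np.stack([hats[i + 1] - hats[i] for i in range(len(order))])
    h_full = hats[-1]

    def term_stats(gmat):
        ss = np.tensordot(delta_hats, gmat, axes=([1, 2], [0, 1]))
        ss_resid = float(np.trace(gmat) - np.sum(h_full * gmat))
        f = (ss / np.asarray(dfs)) / (ss_resid / resid_df)
        return ss, ss_resid, f

    ss_obs, ss_resid, f_obs = term_stats(g)

    if n_perm is None:
        perms = np.array(list(itertools.permutations(range(n))))
        f_perm = np.empty((len(perms), len(order)))
        for i, p in enumerate(perms):
            _, _, f_perm[i] = term_stats(g[np.ix_(p, p)])
        # exact: proportion of arrangements with F at least as extreme
        p_values = (f_perm >= f_obs[None, :] - 1e-12).mean(axis=0)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(order))
        for _ in range(n_perm):
            p = rng.permutation(n)
            _, _, f_p = term_stats(g[np.ix_(p, p)])
            exceed += f_p >= f_obs - 1e-12
        p_values = (1.0 + exceed) / (1.0 + n_perm)
        n_used = n_perm

    terms = [
        PermanovaTerm(
            covariate=name,
            timepoint=None,
            df=dfs[i],
            ss=float(ss_obs[i]),
            r2=float(ss_obs[i] / total_ss),
            pseudo_f=float(f_obs[i]),
            p_value=float(p_values[i]),
            n_samples=n,
            n_permutations=n_used,
        )
        for i, name in enumerate(order)
    ]
    return PermanovaResult(
        terms=terms,
        residual_ss=float(ss_resid),
        residual_df=resid_df,
        total_ss=total_ss,
        n_samples=n,
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def variance_grid(
    profiles,
    infants,
    samples,
    windows=TIME_WINDOWS,
    covariates=DEFAULT_COVARIATES,
    n_perm: int = 999,
    seed=None,
    min_n: int = 15,
    mode: str = "sequential",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timepoint PERMANOVA variance grid with grid-wide BH-FDR.

    For each time window: keep one sample per infant (closest to the
    window midpoint), drop covariates with fewer than 2 levels present,
    and run a PERMANOVA — jointly sequential in the given order
    (``mode="sequential"``) or one single-covariate model per covariate
    (``mode="marginal"``). All (covariate, timepoint) p-values are then
    adjusted together by Benjamini-Hochberg.

    Returns a long-format frame with columns covariate, timepoint, n, df,
    R2, F, p, q, significant.
    """
    if mode not in ("sequential", "marginal"):
        raise ValueError("mode must be 'sequential' or 'marginal'")
    cov_df = covariate_table(infants, samples)
    rng = np.random.default_rng(seed)
    cells: list[PermanovaTerm] = []
    for window in windows:
        label = window_label(window) if not isinstance(window, str) else window
        chosen = select_one_sample_per_infant(samples, label)
        if len(chosen) < min_n:
            logger.warning(
                "window %s has %d samples (< %d); skipped", label, len(chosen), min_n
            )
            continue
        ids = [s.sample_id for s in chosen]
        sub_profiles = profiles.subset(ids)
        design = cov_df.loc[ids, list(covariates)]
        usable = [c for c in covariates if design[c].nunique() > 1]
        dropped = set(covariates) - set(usable)
        if dropped:
            logger.info("window %s: dropping single-level covariates %s", label, sorted(dropped))
        if not usable:
            continue
        dm = distance_matrix(sub_profiles)
        window_seed = int(rng.integers(2**31 - 1))
        try:
            if mode == "sequential":
                res = permanova(dm, design[usable], order=usable, n_perm=n_perm, seed=window_seed)
                terms = res.terms
            else:
                terms = []
                for c in usable:
                    res = permanova(dm, design[[c]], order=[c], n_perm=n_perm, seed=window_seed)
                    terms.extend(res.terms)
        except RankDeficiencyError as exc:
            logger.warning("window %s: %s; skipped", label, exc)
            continue
        for t in terms:
            t.timepoint = label
            cells.append(t)

    if not cells:
        return pd.DataFrame(
            columns=["covariate", "timepoint", "n", "df", "R2", "F", "p", "q", "significant"]
        )
    q = fdr_bh([t.p_value for t in cells])
    for t, qv in zip(cells, q):
        t.q_value = float(qv)
    return pd.DataFrame(
        {
            "covariate": [t.covariate for t in cells],
            "timepoint": [t.timepoint for t in cells],
            "n": [t.n_samples for t in cells],
            "df": [t.df for t in cells],
            "R2": [t.r2 for t in cells],
            "F": [t.pseudo_f for t in cells],
            "p": [t.p_value for t in cells],
            "q": [t.q_value for t in cells],
            "significant": [t.q_value < alpha for t in cells],
        }
    )


def plot_variance_grid(grid: pd.DataFrame, path=None, alpha: float = 0.05):
    """Bubble chart of the variance grid (R2 as bubble area, FDR hits boxed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    covs = list(pd.unique(grid["covariate"]))
    tps = list(pd.unique(grid["timepoint"]))
    fig, ax = plt.subplots(figsize=(1.1 * len(tps) + 2, 0.5 * len(covs) + 1.5))
    for _, row in grid.iterrows():
        x = tps.index(row["timepoint"])
        y = covs.index(row["covariate"])
        ax.scatter(x, y, s=2500 * row["R2"], c="steelblue", alpha=0.7)
        if row["significant"]:
            ax.scatter(x, y, s=2700 * row["R2"] + 80, facecolors="none", edgecolors="red")
    ax.set_xticks(range(len(tps)), tps, rotation=45)
    ax.set_yticks(range(len(covs)), covs)
    ax.set_xlabel("day-of-life window")
    ax.set_title("Variance explained per covariate and timepoint (PERMANOVA R²)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
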