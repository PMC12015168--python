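"""Probiotic engraftment quantification and responder classification.

For every infant receiving a probiotic, the relative abundance of that
product's species is summed per sample and integrated (trapezoid rule)
over the days sampled during probiotic use. The raw AUC (relative
abundance x days) is normalized by the infant's sampled time span to a
time-averaged relative abundance in [0, 1]. Within a threshold stratum
(per product, or all products combined), infants falling below one
standard deviation under the stratum mean are non-responders; z-scores
are the standardized normalized AUCs. Group comparisons use a two-sided
Fisher exact test on the responder 2x2 table and a two-sided
Mann-Whitney test on z-scores (exact enumeration for small groups,
tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cohort_io import PRODUCT_SPECIES

logger = logging.getLogger(__name__)


class NoDataError(ValueError):
    """An infant has no usable samples during probiotic use."""


def probiotic_abundance(profile, taxa, product: str, species_map=None) -> float:
    """Summed relative abundance of the product's species in one profile.

    Species absent from the taxon list contribute 0 (warned once per run).
    """
    species_map = species_map or PRODUCT_SPECIES
    if product not in species_map:
        raise ValueError(f"unknown probiotic product {product!r}")
    profile = np.asarray(profile, dtype=float)
    taxa = list(taxa)
    total = 0.0
    for sp in species_map[product]:
        if sp in taxa:
            total += float(profile[taxa.index(sp)])
        else:
            _warn_missing_species(sp)
    return total


_warned_species: set[str] = set()


def _warn_missing_species(name: str) -> None:
    if name not in _warned_species:
        _warned_species.add(name)
        logger.warning("probiotic species %r not found in taxa; treated as 0", name)


def engraftment_auc(points) -> tuple[float, float]:
    """Raw and time-normalized AUC of (day, relative abundance) points.

    Duplicate days are averaged first; the trapezoid rule integrates over
    ascending days. With a single point (or zero span) the normalized AUC
    is that point's value and the raw AUC is 0.
    """
    pts = list(points)
    if not pts:
        raise NoDataError("no samples during probiotic use")
    frame = pd.DataFrame(pts, columns=["day", "value"]).groupby("day", sort=True).mean()
    days = frame.index.to_numpy(dtype=float)
    values = frame["value"].to_numpy(dtype=float)
    span = days[-1] - days[0]
    if span == 0:
        return 0.0, float(values.mean())
    raw = float(np.trapezoid(values, days))
    return raw, raw / span


def responder_threshold(norm_aucs, ddof: int = 1) -> float:
    """Mean minus one (sample) standard deviation, floored at zero."""
    v = np.asarray(norm_aucs, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 infants in a stratum")
    return max(float(v.mean() - v.std(ddof=ddof)), 0.0)


#: Absolute tolerance for the >= threshold rule (ties count as responders,
#: and must not flip on floating-point round-off of mean - SD).
_TIE_EPS = 1e-12


def classify_responders(norm_aucs, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Responder flags (normalized AUC >= threshold) and z-scores."""
    v = np.asarray(norm_aucs, dtype=float)
    flags = v >= threshold - _TIE_EPS
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd <= _TIE_EPS * max(1.0, np.abs(v).max()):
        logger.info("zero variance in stratum; all z-scores set to 0")
        z = np.zeros_like(v)
    else:
        z = (v - v.mean()) / sd
    return flags, z


class ResponderClassifier(BaseEstimator):
    """Threshold-based responder classification of normalized engraftment AUCs.

    ``fit`` learns the mean - 1 SD threshold per stratum (the probiotic
    product, or a single combined stratum); ``predict`` returns responder
    flags, ``transform`` the within-stratum z-scores.
    """

    def __init__(self, stratum: str = "product", ddof: int = 1):
        self.stratum = stratum
        self.ddof = ddof

    def _strata(self, products) -> np.ndarray:
        products = np.asarray(products, dtype=object)
        if self.stratum == "combined":
            return np.full(products.shape, "combined", dtype=object)
        return products

    def fit(self, norm_aucs, products):
        v = np.asarray(norm_aucs, dtype=float)
        strata = self._strata(products)
        self.thresholds_ = {}
        self.means_ = {}
        self.sds_ = {}
        small = [s for s in pd.unique(strata) if (strata == s).sum() < 2]
        if small and self.stratum != "combined":
            logger.warning(
                "strata %s have < 2 infants; falling back to the combined stratum", small
            )
            strata = np.full(strata.shape, "combined", dtype=object)
        self.fitted_strata_ = strata
        for s in pd.unique(strata):
            vals = v[strata == s]
            self.thresholds_[s] = responder_threshold(vals, ddof=self.ddof)
            self.means_[s] = float(vals.mean())
            self.sds_[s] = float(vals.std(ddof=self.ddof)) if vals.size > 1 else 0.0
        return self

    def _stratum_of(self, products) -> np.ndarray:
        strata = self._strata(products)
        if any(s not in self.thresholds_ for s in pd.unique(strata)):
            strata = np.full(strata.shape, "combined", dtype=object)
            if "combined" not in self.thresholds_:
                raise ValueError("stratum not seen during fit")
        return strata

    def predict(self, norm_aucs, products) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        v = np.asarray(norm_aucs, dtype=float)
        strata = self._stratum_of(products)
        return np.array(
            [v[i] >= self.thresholds_[strata[i]] - _TIE_EPS for i in range(v.size)]
        )

    def transform(self, norm_aucs, products) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        v = np.asarray(norm_aucs, dtype=float)
        strata = self._stratum_of(products)
        z = np.zeros_like(v)
        for s in pd.unique(strata):
            mask = strata == s
            sd = self.sds_[s]
            if sd <= _TIE_EPS * max(1.0, abs(self.means_[s])):
                z[mask] = 0.0
            else:
                z[mask] = (v[mask] - self.means_[s]) / sd
        return z


def engraftment_table(profiles, infants, samples, stratum: str = "product") -> pd.DataFrame:
    """Per-infant engraftment results for all probiotic-receiving infants.

    Columns: infant_id, group, product, n_samples, first_day, last_day,
    span_days, raw_auc, norm_auc, z, threshold, stratum, responder.
    Infants with no sample during probiotic use are excluded (logged).
    """
    taxa = list(profiles.taxa)
    prof = profiles.to_frame()
    by_infant: dict[str, list] = {}
    for s in samples:
        by_infant.setdefault(s.infant_id, []).append(s)

    rows = []
    for inf in infants:
        if inf.probiotic_product == "none":
            continue
        pts = []
        for s in by_infant.get(inf.infant_id, []):
            if not s.during_probiotic_use:
                continue
            ab = probiotic_abundance(
                prof.loc[s.sample_id].to_numpy(), taxa, inf.probiotic_product
            )
            pts.append((s.day_of_life, ab))
        if not pts:
            logger.info("infant %s has no samples during probiotic use; excluded", inf.infant_id)
            continue
        raw, norm = engraftment_auc(pts)
        days = sorted(p[0] for p in pts)
        rows.append(
            {
                "infant_id": inf.infant_id,
                "group": inf.group,
                "product": inf.probiotic_product,
                "n_samples": len(pts),
                "first_day": days[0],
                "last_day": days[-1],
                "span_days": days[-1] - days[0],
                "raw_auc": raw,
                "norm_auc": norm,
            }
        )
    if not rows:
        raise NoDataError("no probiotic-receiving infants with usable samples")
    df = pd.DataFrame(rows)

    clf = ResponderClassifier(stratum=stratum).fit(df["norm_auc"], df["product"])
    strata = clf._stratum_of(df["product"].to_numpy(dtype=object))
    df["stratum"] = strata
    df["threshold"] = [clf.thresholds_[s] for s in strata]
    df["responder"] = clf.predict(df["norm_auc"], df["product"])
    df["z"] = clf.transform(df["norm_auc"], df["product"])
    return df


def _exact_mannwhitney(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of group assignments.

    Handles ties through midranks; the null distribution of the rank sum
    is enumerated over all C(n, nx) assignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = pooled.size, x.size
    obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    dev = abs(obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), nx):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-9:
            count += 1
    return count / total


@dataclass
class GroupComparison:
    table: pd.DataFrame  # 2x2 responder counts (groups x {responder, non})
    fisher_p: float
    ranksum_p: float
    responder_proportions: pd.Series
    z_medians: pd.Series
    ranksum_method: str


def compare_groups(results: pd.DataFrame, max_exact: int = 20) -> GroupComparison:
    """Between-group comparison of responder calls and z-scores."""
    groups = sorted(results["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups among classified infants, got {groups}")
    table = pd.crosstab(results["group"], results["responder"]).reindex(
        index=groups, columns=[True, False], fill_value=0
    )
    table.columns = ["responder", "non_responder"]
    _, fisher_p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")

    z0 = results.loc[results["group"] == groups[0], "z"].to_numpy()
    z1 = results.loc[results["group"] == groups[1], "z"].to_numpy()
    if min(z0.size, z1.size) == 0:
        raise ValueError("a group has no classified infants")
    if z0.size + z1.size <= max_exact:
        ranksum_p = _exact_mannwhitney(z0, z1)
        method = "exact"
    else:
        _, ranksum_p = stats.mannwhitneyu(z0, z1, alternative="two-sided", method="asymptotic")
        method = "normal-approximation"

    props = results.groupby("group")["responder"].mean()
    z_med = results.groupby("group")["z"].median()
    return GroupComparison(
        table=table,
        fisher_p=float(fisher_p),
        ranksum_p=float(ranksum_p),
        responder_proportions=props,
        z_medians=z_med,
        ranksum_method=method,
    )
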