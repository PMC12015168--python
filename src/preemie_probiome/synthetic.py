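"""Synthetic preterm-infant cohort generator.

Emulates the statistical structure of a two-group NICU cohort: 91 EP/ELBW
infants (<28 weeks and/or <1000 g) and 32 VP/VLBW infants, each sampled
~10-15 times over days of life 0-120, on one of three probiotic arms
(none / Infloran / Labinic). Probiotic-arm infants carry a planted
engraftment trajectory — a saturating-exponential rise of probiotic-species
relative abundance toward a responder or non-responder plateau during the
recorded use interval — on top of an infant-specific background community
drawn from one of K Dirichlet "community type" components. Per-sample
compositions are Dirichlet draws around the expected composition, giving
compositional noise with configurable concentration.

Ground truth (responder flags, per-sample community type, covariate effect
sizes) is returned alongside the tables so downstream estimators can be
tested for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .cohort_io import (
    EP_ELBW,
    VP_VLBW,
    EXPOSURES,
    PROBIOTIC_SPECIES,
    PRODUCT_SPECIES,
    InfantRecord,
    SampleRecord,
    TaxonProfileMatrix,
    classify_group,
    derive_sample_record,
)

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal

DEFAULT_BACKGROUND_TAXA: tuple[str, ...] = (
    "Escherichia_coli",
    "Klebsiella_pneumoniae",
    "Klebsiella_oxytoca",
    "Enterococcus_faecalis",
    "Staphylococcus_epidermidis",
    "Staphylococcus_haemolyticus",
    "Enterobacter_cloacae",
    "Clostridium_perfringens",
    "Veillonella_parvula",
    "Streptococcus_agalactiae",
    "Bacteroides_fragilis",
    "Bifidobacterium_breve",
)


def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """Mean/sigma of a log-normal matched to a printed median and IQR."""
    q1, q3 = iqr
    sigma = math.log(q3 / q1) / (2 * _Z75)
    return math.log(median), max(sigma, 1e-6)


@dataclass
class GroupParams:
    """Demographics for one gestational/weight group (medians and IQRs)."""

    n: int
    ga_median: float
    ga_iqr: tuple[float, float]
    bw_median: float
    bw_iqr: tuple[float, float]
    arm_probs: dict[str, float]  # over none / infloran / labinic
    start_day_median: float
    start_day_iqr: tuple[float, float]
    last_day_median: float
    last_day_iqr: tuple[float, float]
    male_prob: float
    caesarean_prob: float


#: Share of the engrafted probiotic load carried by each product species,
#: aligned with PRODUCT_SPECIES order. Engrafted infants are typically
#: dominated by B. bifidum rather than an even split across the product's
#: species.
PRODUCT_SPECIES_SHARES: dict[str, tuple[float, ...]] = {
    "infloran": (0.6, 0.4),
    "labinic": (0.5, 0.3, 0.2),
}


@dataclass
class EngraftmentParams:
    """Planted engraftment trajectory parameters.

    The responder plateau defaults to 0.5 summed relative abundance:
    engrafted preterm infants commonly carry the administered
    Bifidobacterium/Lactobacillus species as the dominant community
    fraction during supplementation.
    """

    responder_plateau: float = 0.50
    nonresponder_plateau: float = 0.01
    rise_rate: float = 0.20  # per day
    responder_prob: float = 0.86
    baseline: float = 0.002
    washout_rate: float = 0.10  # decay back to baseline after the last dose


@dataclass
class SamplingParams:
    samples_median: float = 11.0
    samples_iqr: tuple[float, float] = (9.0, 14.0)
    day_min: int = 0
    day_max: int = 120
    day_beta: tuple[float, float] = (1.2, 2.2)  # early-weighted sampling days
    min_samples_during_use: int = 4


@dataclass
class CohortConfig:
    """Full generator configuration; defaults emulate the study cohort shape."""

    ep_elbw: GroupParams = field(
        default_factory=lambda: GroupParams(
            n=91,
            ga_median=26.0,
            ga_iqr=(25.0, 27.0),
            bw_median=840.0,
            bw_iqr=(660.0, 945.0),
            arm_probs={"none": 19 / 91, "infloran": 23 / 91, "labinic": 49 / 91},
            start_day_median=7.0,
            start_day_iqr=(6.0, 9.0),
            last_day_median=50.0,
            last_day_iqr=(45.0, 61.0),
            male_prob=44 / 91,
            caesarean_prob=48 / 91,
        )
    )
    vp_vlbw: GroupParams = field(
        default_factory=lambda: GroupParams(
            n=32,
            ga_median=29.0,
            ga_iqr=(28.0, 30.0),
            bw_median=1315.0,
            bw_iqr=(1170.0, 1580.0),
            arm_probs={"none": 9 / 32, "infloran": 1 / 32, "labinic": 22 / 32},
            start_day_median=6.0,
            start_day_iqr=(3.0, 9.0),
            last_day_median=28.0,
            last_day_iqr=(25.0, 35.0),
            male_prob=24 / 32,
            caesarean_prob=19 / 32,
        )
    )
    season_probs: dict[str, float] = field(
        default_factory=lambda: {"winter": 0.28, "autumn": 0.33, "summer": 0.25, "spring": 0.22}
    )
    taxa: tuple[str, ...] = PROBIOTIC_SPECIES + DEFAULT_BACKGROUND_TAXA
    engraftment: EngraftmentParams = field(default_factory=EngraftmentParams)
    sampling: SamplingParams = field(default_factory=SamplingParams)
    n_community_types: int = 5
    type_concentration: float = 0.7  # Dirichlet parameter for component means
    type_stickiness: float = 0.8  # P(sample keeps the previous sample's type)
    infant_sigma: float = 1.0  # SD of infant-level background log-weights
    covariate_effects: dict[str, float] = field(default_factory=dict)
    dirichlet_concentration: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        for gp in (self.ep_elbw, self.vp_vlbw):
            if gp.n < 0:
                raise ValueError("group sizes must be non-negative")
            if abs(sum(gp.arm_probs.values()) - 1.0) > 1e-9:
                raise ValueError("probiotic arm probabilities must sum to 1")
        if self.ep_elbw.n + self.vp_vlbw.n == 0:
            raise ValueError("cohort must contain at least one infant")
        total_season = sum(self.season_probs.values())
        if total_season <= 0:
            raise ValueError("season probabilities must be positive")
        if not self.taxa:
            raise ValueError("taxa list must be non-empty")
        if not set(PROBIOTIC_SPECIES) <= set(self.taxa):
            raise ValueError("taxa must include the probiotic species")
        eng = self.engraftment
        if not (0 <= eng.nonresponder_plateau <= eng.responder_plateau < 1):
            raise ValueError("require 0 <= non-responder plateau <= responder plateau < 1")
        if eng.rise_rate < 0:
            raise ValueError("rise rate must be non-negative")
        if not (0 <= eng.responder_prob <= 1):
            raise ValueError("responder probability must be in [0, 1]")
        sp = self.sampling
        if not (0 <= sp.day_min <= sp.day_max <= 120):
            raise ValueError("sampling day range must lie within [0, 120]")
        if self.dirichlet_concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.n_community_types < 1:
            raise ValueError("need at least one community type")

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        kwargs = dict(raw)
        for key in ("ep_elbw", "vp_vlbw"):
            if key in kwargs and isinstance(kwargs[key], dict):
                d = dict(kwargs[key])
                for k in ("ga_iqr", "bw_iqr", "start_day_iqr", "last_day_iqr"):
                    if k in d:
                        d[k] = tuple(d[k])
                kwargs[key] = GroupParams(**d)
        if "engraftment" in kwargs and isinstance(kwargs["engraftment"], dict):
            kwargs["engraftment"] = EngraftmentParams(**kwargs["engraftment"])
        if "sampling" in kwargs and isinstance(kwargs["sampling"], dict):
            d = dict(kwargs["sampling"])
            for k in ("samples_iqr", "day_beta"):
                if k in d:
                    d[k] = tuple(d[k])
            kwargs["sampling"] = SamplingParams(**d)
        if "taxa" in kwargs:
            kwargs["taxa"] = tuple(kwargs["taxa"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class GroundTruth:
    """Planted parameters recorded for recovery tests."""

    responder: dict[str, bool]  # infant id -> flag (probiotic arms only)
    sample_type: dict[str, int]  # sample id -> community type index
    type_means: np.ndarray  # K x n_background_taxa component means
    covariate_effects: dict[str, float]


def engraftment_curve(t, start: float, plateau: float, rate: float, baseline: float = 0.0):
    """Saturating-exponential engraftment trajectory.

    Returns ``baseline`` before ``start`` and
    ``baseline + (plateau - baseline) * (1 - exp(-rate * (t - start)))``
    afterwards; monotone non-decreasing in ``t``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if not (0 <= baseline <= plateau < 1):
        raise ValueError("require 0 <= baseline <= plateau < 1")
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - start, 0.0)
    out = baseline + (plateau - baseline) * (1.0 - np.exp(-rate * dt))
    return float(out) if out.ndim == 0 else out


def _draw_lognormal(rng, median, iqr, lo=None, hi=None, max_tries=1000):
    mu, sigma = _lognormal_params(median, iqr)
    for _ in range(max_tries):
        x = float(rng.lognormal(mu, sigma))
        if (lo is None or x >= lo) and (hi is None or x <= hi):
            return x
    return float(np.clip(math.exp(mu), lo, hi))


def _draw_demographics(rng, gp: GroupParams, group: str, max_tries=1000):
    # rejection-sample until GA/BW land in the group they are labelled with
    for _ in range(max_tries):
        ga = _draw_lognormal(rng, gp.ga_median, gp.ga_iqr, lo=22.0, hi=33.0)
        bw = _draw_lognormal(rng, gp.bw_median, gp.bw_iqr, lo=350.0, hi=2200.0)
        if classify_group(ga, bw) == group:
            return round(ga, 1), round(bw)
    raise RuntimeError(f"could not draw demographics consistent with group {group}")


def _sample_days(rng, cfg: CohortConfig, infant: InfantRecord) -> list[int]:
    sp = cfg.sampling
    n = int(round(_draw_lognormal(rng, sp.samples_median, sp.samples_iqr, lo=4, hi=25)))
    span = sp.day_max - sp.day_min
    days = sorted(
        {sp.day_min + int(round(span * b)) for b in rng.beta(*sp.day_beta, size=n)}
    )
    if infant.probiotic_product != "none" and sp.min_samples_during_use > 0:
        lo = int(math.ceil(infant.probiotic_start_day))
        hi = int(math.floor(infant.probiotic_last_day))
        in_use = [d for d in days if lo <= d <= hi]
        need = sp.min_samples_during_use - len(in_use)
        if need > 0 and hi >= lo:
            candidates = [d for d in range(lo, hi + 1) if d not in days]
            extra = rng.choice(candidates, size=min(need, len(candidates)), replace=False)
            days = sorted(set(days) | {int(d) for d in np.atleast_1d(extra)})
    return days


def _interval_plan(rng, n_days: int) -> dict[str, tuple[tuple[float, float], ...]]:
    """Feeding/antibiotic exposure intervals with realistic NICU timing."""
    plan: dict[str, tuple[tuple[float, float], ...]] = {}
    # mother's own milk: nearly universal from the first days, may stop early
    if rng.random() < 0.92:
        start = int(rng.integers(0, 4))
        if rng.random() < 0.15:
            end = int(rng.integers(start + 10, 60))
        else:
            end = n_days
        plan["mom"] = ((start, end),)
    else:
        plan["mom"] = ()
    # breast milk fortifier: introduced mid-course in roughly two-thirds
    if rng.random() < 0.65:
        start = int(rng.integers(10, 25))
        end = int(rng.integers(start + 10, max(start + 11, 95)))
        plan["bmf"] = ((start, end),)
    else:
        plan["bmf"] = ()
    # formula: about 60% ever, often later and continuing
    if rng.random() < 0.6:
        start = int(rng.integers(5, 45))
        plan["formula"] = ((start, n_days),)
    else:
        plan["formula"] = ()
    # antibiotics: an early empirical course, sometimes a later second course
    courses = [(0, int(rng.integers(2, 7)))]
    if rng.random() < 0.35:
        s = int(rng.integers(15, 80))
        courses.append((s, s + int(rng.integers(2, 8))))
    plan["antibiotics"] = tuple(sorted(courses))
    return plan


def _covariate_multiplier(cfg, cov_dirs, covariates_row, n_taxa):
    """Multiplicative composition shift for the active covariate levels."""
    log_shift = np.zeros(n_taxa)
    for cov, eff in cfg.covariate_effects.items():
        if eff == 0:
            continue
        active = covariates_row.get(cov)
        if active:
            log_shift += eff * cov_dirs[cov]
    return np.exp(log_shift)


def generate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[list[InfantRecord], list[SampleRecord], TaxonProfileMatrix, GroundTruth]:
    """Generate infants, samples, a profile matrix and the planted ground truth.

    Deterministic given ``(config, seed)``; ``seed`` overrides ``config.seed``
    when given.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    taxa = tuple(cfg.taxa)
    probiotic_idx = {t: taxa.index(t) for t in PROBIOTIC_SPECIES if t in taxa}
    background = [t for t in taxa if t not in PROBIOTIC_SPECIES]
    bg_idx = np.array([taxa.index(t) for t in background])
    n_bg = len(background)
    if n_bg == 0:
        raise ValueError("need at least one non-probiotic background taxon")

    # community-type components over background taxa
    K = cfg.n_community_types
    type_means = rng.dirichlet(np.full(n_bg, cfg.type_concentration), size=K)
    type_means = np.maximum(type_means, 1e-6)
    type_means /= type_means.sum(axis=1, keepdims=True)

    # one fixed random direction per covariate with a planted effect
    cov_dirs = {
        cov: rng.normal(size=n_bg) for cov in sorted(cfg.covariate_effects)
    }

    seasons = list(cfg.season_probs)
    season_p = np.array([cfg.season_probs[s] for s in seasons], dtype=float)
    season_p /= season_p.sum()

    infants: list[InfantRecord] = []
    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    responder: dict[str, bool] = {}
    sample_type: dict[str, int] = {}

    group_specs = [(EP_ELBW, cfg.ep_elbw), (VP_VLBW, cfg.vp_vlbw)]
    idx = 0
    for group, gp in group_specs:
        arms = list(gp.arm_probs)
        arm_p = np.array([gp.arm_probs[a] for a in arms], dtype=float)
        for _ in range(gp.n):
            idx += 1
            iid = f"I{idx:03d}"
            ga, bw = _draw_demographics(rng, gp, group)
            product = arms[int(rng.choice(len(arms), p=arm_p))]
            if product == "none":
                start_day = last_day = None
            else:
                start_day = float(
                    round(_draw_lognormal(rng, gp.start_day_median, gp.start_day_iqr, lo=0, hi=30))
                )
                last_day = float(
                    round(
                        _draw_lognormal(
                            rng, gp.last_day_median, gp.last_day_iqr, lo=start_day + 7, hi=110
                        )
                    )
                )
            infant = InfantRecord(
                infant_id=iid,
                gestational_age=ga,
                birthweight=bw,
                sex="male" if rng.random() < gp.male_prob else "female",
                birth_mode="caesarean" if rng.random() < gp.caesarean_prob else "vaginal",
                season=seasons[int(rng.choice(len(seasons), p=season_p))],
                probiotic_product=product,
                probiotic_start_day=start_day,
                probiotic_last_day=last_day,
                intervals=_interval_plan(rng, cfg.sampling.day_max),
            )
            infants.append(infant)

            if product != "none":
                responder[iid] = bool(rng.random() < cfg.engraftment.responder_prob)

            # infant-level background log-weights (repeated-measures structure)
            infant_w = np.exp(rng.normal(0.0, cfg.infant_sigma, size=n_bg))

            days = _sample_days(rng, cfg, infant)
            cur_type = int(rng.integers(K))
            for j, day in enumerate(days):
                sid = f"{iid}_S{j:02d}"
                rec = derive_sample_record(sid, infant, float(day))
                samples.append(rec)
                sample_ids.append(sid)
                if j > 0 and rng.random() >= cfg.type_stickiness:
                    cur_type = int(rng.integers(K))
                sample_type[sid] = cur_type

                cov_row = {
                    "antibiotics_7d": rec.antibiotics_last_7_days,
                    "mom": rec.exposure_states["mom"] == "during",
                    "bmf": rec.exposure_states["bmf"] == "during",
                    "formula": rec.exposure_states["formula"] == "during",
                    "group": group == EP_ELBW,
                    "sex": infant.sex == "male",
                    "birth_mode": infant.birth_mode == "caesarean",
                }
                mult = (
                    _covariate_multiplier(cfg, cov_dirs, cov_row, n_bg)
                    if cfg.covariate_effects
                    else 1.0
                )
                bg = type_means[cur_type] * infant_w * mult
                bg = bg / bg.sum()

                # expected probiotic load at this day
                eng = cfg.engraftment
                expected = np.full(len(taxa), 1e-6)
                if product != "none":
                    plateau = (
                        eng.responder_plateau if responder[iid] else eng.nonresponder_plateau
                    )
                    if day <= last_day:
                        p_t = engraftment_curve(
                            day, start_day, plateau, eng.rise_rate, eng.baseline
                        )
                    else:
                        level = engraftment_curve(
                            last_day, start_day, plateau, eng.rise_rate, eng.baseline
                        )
                        p_t = eng.baseline + (level - eng.baseline) * math.exp(
                            -eng.washout_rate * (day - last_day)
                        )
                    species = PRODUCT_SPECIES[product]
                    shares = PRODUCT_SPECIES_SHARES[product]
                    for sp_name, share in zip(species, shares):
                        expected[probiotic_idx[sp_name]] += p_t * share
                else:
                    p_t = eng.baseline
                    for sp_name, k in probiotic_idx.items():
                        expected[k] += p_t / len(probiotic_idx)
                expected[bg_idx] += bg * max(1.0 - expected.sum(), 1e-6)
                expected = np.maximum(expected, 1e-8)
                expected /= expected.sum()

                comp = rng.dirichlet(cfg.dirichlet_concentration * expected)
                comp = np.maximum(comp, 0.0)
                comp /= comp.sum()
                rows.append(comp)

    profiles = TaxonProfileMatrix(tuple(sample_ids), taxa, np.array(rows))
    truth = GroundTruth(
        responder=responder,
        sample_type=sample_type,
        type_means=type_means,
        covariate_effects=dict(cfg.covariate_effects),
    )
    return infants, samples, profiles, truth


def null_group_config(
    n_per_group: int = 250, seed: int = 0, arm_probs=None
) -> CohortConfig:
    """A cohort config in which group labels carry no composition signal.

    The two groups keep their distinct gestational-age/birthweight
    demographics but share probiotic-arm probabilities, start/last-day
    distributions, responder probability and all effect parameters, with
    no planted covariate effects — so any between-group difference found
    downstream is sampling noise. Used for type-I-error style checks of
    the whole pipeline.
    """
    cfg = CohortConfig(seed=seed)
    arm_probs = dict(arm_probs or {"none": 0.2, "infloran": 0.25, "labinic": 0.55})
    for gp in (cfg.ep_elbw, cfg.vp_vlbw):
        gp.n = n_per_group
        gp.arm_probs = dict(arm_probs)
        gp.start_day_median, gp.start_day_iqr = 7.0, (6.0, 9.0)
        gp.last_day_median, gp.last_day_iqr = 45.0, (38.0, 55.0)
    cfg.covariate_effects = {}
    cfg.validate()
    return cfg
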