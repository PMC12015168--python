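"""Cohort tables: taxonomic profiles, infant/sample metadata, and derived exposure states.

The analyses operate on three tables:

* a MetaPhlAn-style merged relative-abundance table (taxa as rows, one
  column per sample),
* an infant metadata table with fixed covariates (gestational age,
  birthweight, sex, birth mode, season, probiotic product and start/last
  day) plus time-varying exposure intervals (mother's own milk, breast
  milk fortifier, formula, antibiotics), and
* a sample metadata table (sample id, infant id, day of life).

This module reads and validates those tables, classifies infants into the
EP/ELBW vs VP/VLBW gestational/weight groups, bins samples into the nine
cross-sectional time windows spanning days 0-69, and derives per-sample
exposure states (never / before / during / after) from the intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EP_ELBW = "EP/ELBW"
VP_VLBW = "VP/VLBW"

#: Nine cross-sectional analysis windows (closed day-of-life ranges).
TIME_WINDOWS: tuple[tuple[int, int], ...] = (
    (0, 9),
    (10, 14),
    (15, 19),
    (20, 24),
    (25, 29),
    (30, 34),
    (35, 39),
    (40, 49),
    (50, 69),
)

EXPOSURES = ("mom", "bmf", "formula", "antibiotics")

#: Species matched when summing "probiotic species" abundance, per product.
PRODUCT_SPECIES: dict[str, tuple[str, ...]] = {
    "infloran": ("Bifidobacterium_bifidum", "Lactobacillus_acidophilus"),
    "labinic": (
        "Bifidobacterium_bifidum",
        "Bifidobacterium_longum",
        "Lactobacillus_acidophilus",
    ),
}

PROBIOTIC_SPECIES: tuple[str, ...] = (
    "Bifidobacterium_bifidum",
    "Bifidobacterium_longum",
    "Lactobacillus_acidophilus",
)


class ReconciliationError(ValueError):
    """Profiles and metadata disagree on the sample universe."""


def window_label(window: tuple[int, int]) -> str:
    return f"{window[0]}-{window[1]}"


WINDOW_LABELS: tuple[str, ...] = tuple(window_label(w) for w in TIME_WINDOWS)


@dataclass(frozen=True)
class TaxonProfileMatrix:
    """Samples x taxa relative-abundance matrix (rows sum to 1)."""

    sample_ids: tuple[str, ...]
    taxa: tuple[str, ...]
    values: np.ndarray  # shape (n_samples, n_taxa)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.sample_ids), len(self.taxa)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxa)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if np.any(values < -1e-12):
            raise ValueError("negative abundances")
        sums = values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("profile rows must sum to 1 (call normalize_profiles)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.taxa))

    def subset(self, sample_ids) -> "TaxonProfileMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return TaxonProfileMatrix(tuple(sample_ids), self.taxa, self.values[rows])

    def abundance(self, sample_id: str, taxon: str) -> float:
        return float(
            self.values[self.sample_ids.index(sample_id), self.taxa.index(taxon)]
        )


def normalize_profiles(frame: pd.DataFrame, tol: float = 1e-3) -> TaxonProfileMatrix:
    """Build a :class:`TaxonProfileMatrix` from a samples x taxa frame.

    Rows are renormalized to sum to 1; a deviation beyond ``tol`` (e.g. a
    percent-scale table summing to 100) triggers a logged warning rather
    than an error, matching how merged profiler outputs vary in the wild.
    """
    values = frame.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative abundance in profile table")
    sums = values.sum(axis=1)
    if np.any(sums <= 0):
        bad = list(frame.index[sums <= 0][:5])
        raise ValueError(f"profile rows with zero total abundance: {bad}")
    if np.any(np.abs(sums - 1.0) > tol):
        logger.warning(
            "%d profile rows deviate from unit sum by more than %g; renormalizing",
            int(np.sum(np.abs(sums - 1.0) > tol)),
            tol,
        )
    values = values / sums[:, None]
    return TaxonProfileMatrix(tuple(map(str, frame.index)), tuple(map(str, frame.columns)), values)


@dataclass(frozen=True)
class InfantRecord:
    """Per-infant fixed covariates and exposure intervals.

    ``intervals`` maps each exposure name in :data:`EXPOSURES` to a sorted
    tuple of closed ``(start_day, end_day)`` intervals.
    """

    infant_id: str
    gestational_age: float  # weeks
    birthweight: float  # grams
    sex: str
    birth_mode: str
    season: str
    probiotic_product: str  # none | infloran | labinic
    probiotic_start_day: float | None = None
    probiotic_last_day: float | None = None
    intervals: dict[str, tuple[tuple[float, float], ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.probiotic_product not in ("none", "infloran", "labinic"):
            raise ValueError(f"unknown probiotic product {self.probiotic_product!r}")
        if self.probiotic_product == "none":
            if self.probiotic_start_day is not None or self.probiotic_last_day is not None:
                raise ValueError("probiotic days set for a none-arm infant")
        else:
            if self.probiotic_start_day is None or self.probiotic_last_day is None:
                raise ValueError("probiotic-arm infant missing start/last day")
            if self.probiotic_start_day > self.probiotic_last_day:
                raise ValueError("probiotic start day after last day")
        for name, ivs in self.intervals.items():
            _check_intervals(ivs, name)

    @property
    def group(self) -> str:
        return classify_group(self.gestational_age, self.birthweight)


@dataclass(frozen=True)
class SampleRecord:
    """One stool sample with its derived, time-resolved exposure states."""

    sample_id: str
    infant_id: str
    day_of_life: float
    timepoint: str | None = None
    exposure_states: dict[str, str] = field(default_factory=dict)
    antibiotics_last_7_days: bool = False
    during_probiotic_use: bool = False


def classify_group(ga: float, bw: float) -> str:
    """Classify an infant by gestational age (weeks) and birthweight (g).

    EP/ELBW if born before 28 weeks or under 1000 g; VP/VLBW otherwise.
    """
    if not (ga > 0 and bw > 0):
        raise ValueError(f"gestational age and birthweight must be positive, got ({ga}, {bw})")
    return EP_ELBW if (ga < 28 or bw < 1000) else VP_VLBW


def assign_timepoint(dol: float) -> str | None:
    """Map a day of life onto one of the nine analysis windows (or None past day 69)."""
    if dol < 0:
        raise ValueError(f"negative day of life: {dol}")
    for lo, hi in TIME_WINDOWS:
        if lo <= dol <= hi:
            return window_label((lo, hi))
    return None


def _check_intervals(intervals, name: str = "exposure"):
    prev_end = None
    for iv in intervals:
        if len(iv) != 2:
            raise ValueError(f"{name}: interval {iv!r} is not a (start, end) pair")
        start, end = iv
        if start < 0 or end < start:
            raise ValueError(f"{name}: invalid interval {iv!r}")
        if prev_end is not None and start <= prev_end:
            raise ValueError(f"{name}: overlapping or unsorted intervals at {iv!r}")
        prev_end = end


def derive_exposure_state(intervals, dol: float) -> str:
    """State of one exposure at a sampling day: never / before / during / after."""
    _check_intervals(intervals)
    if not intervals:
        return "never"
    for start, end in intervals:
        if start <= dol <= end:
            return "during"
    if dol < intervals[0][0]:
        return "before"
    return "after"


def antibiotics_within_7_days(intervals, dol: float) -> bool:
    """True if any antibiotic-exposed day falls within the closed window [dol-7, dol]."""
    _check_intervals(intervals, "antibiotics")
    lo = dol - 7
    return any(start <= dol and end >= lo for start, end in intervals)


def derive_sample_record(sample_id: str, infant: InfantRecord, dol: float) -> SampleRecord:
    """Attach window label and exposure states to a raw (sample, infant, day) row."""
    states = {
        exp: derive_exposure_state(infant.intervals.get(exp, ()), dol) for exp in EXPOSURES
    }
    during_probiotic = (
        infant.probiotic_product != "none"
        and infant.probiotic_start_day <= dol <= infant.probiotic_last_day
    )
    return SampleRecord(
        sample_id=sample_id,
        infant_id=infant.infant_id,
        day_of_life=dol,
        timepoint=assign_timepoint(dol),
        exposure_states=states,
        antibiotics_last_7_days=antibiotics_within_7_days(
            infant.intervals.get("antibiotics", ()), dol
        ),
        during_probiotic_use=during_probiotic,
    )


def select_one_sample_per_infant(samples, window: str) -> list[SampleRecord]:
    """Pick at most one sample per infant inside a window.

    Repeated measures within an infant would break exchangeability of the
    per-window permutation tests, so each window keeps the sample closest
    to the window midpoint; ties break toward the earlier day, then the
    lexicographically smaller sample id. Deterministic and insensitive to
    input order.
    """
    try:
        lo, hi = (int(x) for x in window.split("-"))
    except Exception as exc:
        raise ValueError(f"malformed window label {window!r}") from exc
    mid = (lo + hi) / 2.0
    best: dict[str, SampleRecord] = {}
    for s in samples:
        if not (lo <= s.day_of_life <= hi):
            continue
        key = (abs(s.day_of_life - mid), s.day_of_life, s.sample_id)
        cur = best.get(s.infant_id)
        if cur is None or key < (abs(cur.day_of_life - mid), cur.day_of_life, cur.sample_id):
            best[s.infant_id] = s
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_profiles(matrix: TaxonProfileMatrix, path) -> None:
    """Write a MetaPhlAn-style merged table (taxa as rows, samples as columns)."""
    frame = matrix.to_frame().T
    frame.index.name = "clade_name"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_profiles(path) -> TaxonProfileMatrix:
    """Read a merged species-level abundance TSV (first column taxon names)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if frame.empty:
        raise ValueError(f"empty profile table: {path}")
    return normalize_profiles(frame.T)


def _format_intervals(intervals) -> str:
    return ";".join(f"{s:g}-{e:g}" for s, e in intervals)


def _parse_intervals(text) -> tuple[tuple[float, float], ...]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or str(text).strip() == "":
        return ()
    out = []
    for token in str(text).split(";"):
        parts = token.split("-")
        if len(parts) != 2:
            raise ValueError(f"malformed interval token {token!r}")
        out.append((float(parts[0]), float(parts[1])))
    return tuple(out)


INFANT_COLUMNS = [
    "infant_id",
    "gestational_age_weeks",
    "birthweight_g",
    "sex",
    "birth_mode",
    "season",
    "probiotic_product",
    "probiotic_start_day",
    "probiotic_last_day",
    "mom_intervals",
    "bmf_intervals",
    "formula_intervals",
    "antibiotics_intervals",
]

SAMPLE_COLUMNS = ["sample_id", "infant_id", "day_of_life"]


def write_metadata(infants, samples, infants_path, samples_path) -> None:
    rows = []
    for inf in infants:
        rows.append(
            {
                "infant_id": inf.infant_id,
                "gestational_age_weeks": inf.gestational_age,
                "birthweight_g": inf.birthweight,
                "sex": inf.sex,
                "birth_mode": inf.birth_mode,
                "season": inf.season,
                "probiotic_product": inf.probiotic_product,
                "probiotic_start_day": inf.probiotic_start_day,
                "probiotic_last_day": inf.probiotic_last_day,
                **{
                    f"{exp}_intervals": _format_intervals(inf.intervals.get(exp, ()))
                    for exp in EXPOSURES
                },
            }
        )
    pd.DataFrame(rows, columns=INFANT_COLUMNS).to_csv(infants_path, index=False)
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "infant_id": s.infant_id, "day_of_life": s.day_of_life}
            for s in samples
        ],
        columns=SAMPLE_COLUMNS,
    ).to_csv(samples_path, index=False)


def read_metadata(infants_path, samples_path) -> tuple[list[InfantRecord], list[SampleRecord]]:
    """Read infant + sample CSVs and derive per-sample exposure states."""
    inf_df = pd.read_csv(infants_path)
    missing = set(INFANT_COLUMNS) - set(inf_df.columns)
    if missing:
        raise ValueError(f"infant metadata missing columns: {sorted(missing)}")
    infants = []
    for _, row in inf_df.iterrows():
        product = str(row["probiotic_product"])
        def _day(v):
            return None if pd.isna(v) else float(v)
        infants.append(
            InfantRecord(
                infant_id=str(row["infant_id"]),
                gestational_age=float(row["gestational_age_weeks"]),
                birthweight=float(row["birthweight_g"]),
                sex=str(row["sex"]),
                birth_mode=str(row["birth_mode"]),
                season=str(row["season"]),
                probiotic_product=product,
                probiotic_start_day=None if product == "none" else _day(row["probiotic_start_day"]),
                probiotic_last_day=None if product == "none" else _day(row["probiotic_last_day"]),
                intervals={
                    exp: _parse_intervals(row[f"{exp}_intervals"]) for exp in EXPOSURES
                },
            )
        )
    by_id = {inf.infant_id: inf for inf in infants}

    smp_df = pd.read_csv(samples_path)
    missing = set(SAMPLE_COLUMNS) - set(smp_df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    samples = []
    unknown = []
    for _, row in smp_df.iterrows():
        iid = str(row["infant_id"])
        if iid not in by_id:
            unknown.append(str(row["sample_id"]))
            continue
        samples.append(
            derive_sample_record(str(row["sample_id"]), by_id[iid], float(row["day_of_life"]))
        )
    if unknown:
        raise ReconciliationError(f"samples reference unknown infants: {unknown[:10]}")
    return infants, samples


def reconcile(matrix: TaxonProfileMatrix, samples) -> None:
    """Check that profiles and sample metadata describe the same samples."""
    profile_ids = set(matrix.sample_ids)
    meta_ids = {s.sample_id for s in samples}
    missing = sorted(meta_ids - profile_ids)
    extra = sorted(profile_ids - meta_ids)
    if missing or extra:
        raise ReconciliationError(
            f"sample id mismatch: {len(missing)} in metadata only ({missing[:5]}), "
            f"{len(extra)} in profiles only ({extra[:5]})"
        )


def covariate_table(infants, samples) -> pd.DataFrame:
    """Long per-sample covariate table used by the variance grid and mixed model.

    Columns: group, probiotic, mom, bmf, formula, antibiotics_7d, season,
    birth_mode, sex, plus bookkeeping (infant_id, day_of_life, timepoint).
    """
    by_id = {inf.infant_id: inf for inf in infants}
    rows = []
    for s in samples:
        inf = by_id[s.infant_id]
        rows.append(
            {
                "sample_id": s.sample_id,
                "infant_id": inf.infant_id,
                "day_of_life": s.day_of_life,
                "timepoint": s.timepoint,
                "group": inf.group,
                "probiotic": inf.probiotic_product,
                "mom": s.exposure_states.get("mom", "never"),
                "bmf": s.exposure_states.get("bmf", "never"),
                "formula": s.exposure_states.get("formula", "never"),
                "antibiotics_7d": "yes" if s.antibiotics_last_7_days else "no",
                "season": inf.season,
                "birth_mode": inf.birth_mode,
                "sex": inf.sex,
                "during_probiotic_use": s.during_probiotic_use,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
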