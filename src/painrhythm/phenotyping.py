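"""Pain-rhythmicity phenotyping of 7-day EMA symptom diaries.

Chronic low back pain participants complete an electronic diary three times a
day (08:00, 14:00, 20:00) for seven days, rating pain (or mood / fatigue) on an
11-point numeric rating scale (NRS, integers 0-10).  Entries time-stamped more
than one hour from a scheduled slot are discarded.  Participants are then
assigned one of four phenotypes:

* low within-day variability, split at the median of mean intensity into
  ``constant_low`` and ``constant_high``;
* high variability with a >=30 % relative increase from 08:00 to 20:00 on at
  least 4 of the 7 scheduled days -> ``rhythmic_up`` (symmetrically
  ``rhythmic_down`` for decreases);
* high variability meeting neither rhythmic rule -> ``mixed``.

Participants with no day offering at least two retained entries cannot be
scored for variability and are labelled ``unclassifiable``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical diary slots (hour of day) and the retention window around them
SLOT_HOURS = (8, 14, 20)
TOLERANCE_MIN = 60

N_DAYS = 7

PHENOTYPES = (
    "constant_low",
    "constant_high",
    "rhythmic_up",
    "rhythmic_down",
    "mixed",
    "unclassifiable",
)

REQUIRED_COLUMNS = ("participant_id", "timestamp", "scale", "score")


class DiarySchemaError(ValueError):
    """Raised when a diary table is missing required columns."""


@dataclass
class EmaGrid:
    """Per-participant 7 x 3 grid of NRS scores.

    ``scores[d, s]`` is the retained score for day ``d`` (0-6, counted from the
    participant's first diary date) and slot ``s`` (08:00 / 14:00 / 20:00);
    missing slots are NaN.  ``source_minutes`` records the signed offset (in
    minutes) of the retained entry from its slot time.
    """

    participant_id: str
    scores: np.ndarray  # (7, 3) float, NaN = missing
    source_minutes: np.ndarray  # (7, 3) float, NaN = missing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (N_DAYS, len(SLOT_HOURS)):
            raise ValueError(f"grid must be {N_DAYS}x{len(SLOT_HOURS)}")


@dataclass
class VariabilityMetrics:
    """Within-day variability and mean-intensity summaries for one grid."""

    participant_id: str
    day_means: np.ndarray
    day_sds: np.ndarray  # NaN where <2 slots present
    variability: float  # mean of SD-evaluable days (or pooled SD, see mode)
    mean_intensity: float
    n_evaluable_days: int

    @property
    def classifiable(self) -> bool:
        return self.n_evaluable_days > 0


@dataclass
class PhenotypeAssignment:
    participant_id: str
    label: str
    metrics: VariabilityMetrics | None = None
    n_increase_days: int = 0
    n_decrease_days: int = 0
    excluded: bool = field(default=False)  # rhythmic_down exclusion flag


def read_diary(path, scale: str | None = None) -> pd.DataFrame:
    """Read a long-format diary CSV, dropping malformed rows.

    Required columns: participant_id, timestamp (ISO-8601), scale, score.
    Rows whose timestamp does not parse or whose score is not an integer in
    0-10 are rejected and logged with their (0-based, data) row numbers.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DiarySchemaError(f"diary file {path} missing columns: {missing}")
    if df.empty:
        logger.warning("diary file %s is empty", path)
        return df.assign(timestamp=pd.to_datetime(df["timestamp"], errors="coerce"))

    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    score = pd.to_numeric(df["score"], errors="coerce")
    ok = ts.notna() & score.notna() & (score >= 0) & (score <= 10) & (score % 1 == 0)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "rejected %d diary rows (bad timestamp or score): rows %s",
            n_rejected,
            df.index[~ok].tolist(),
        )
    out = df.loc[ok].copy()
    out["timestamp"] = ts[ok]
    out["score"] = score[ok].astype(int)
    out.attrs["n_rejected"] = n_rejected
    if scale is not None:
        out = out[out["scale"] == scale].copy()
        out.attrs["n_rejected"] = n_rejected
    return out


def window_filter(
    entries: pd.DataFrame,
    slot_hours: tuple[int, ...] = SLOT_HOURS,
    tolerance_min: float = TOLERANCE_MIN,
) -> dict[str, EmaGrid]:
    """Assign diary entries to scheduled slots, one grid per participant.

    Each entry goes to the nearest slot if within ``tolerance_min`` minutes of
    it, otherwise it is discarded.  When several entries compete for one slot
    the entry closest to the slot time wins; ties go to the earliest entry.
    Day 0 is the participant's first diary date; entries after day 6 are
    dropped (the protocol is 7 days).
    """
    grids: dict[str, EmaGrid] = {}
    if entries.empty:
        return grids
    slot_minutes = np.array([h * 60 for h in slot_hours], dtype=float)

    for pid, sub in entries.groupby("participant_id", sort=True):
        scores = np.full((N_DAYS, len(slot_hours)), np.nan)
        offsets = np.full((N_DAYS, len(slot_hours)), np.nan)
        # |offset| of the current occupant, for closest-wins resolution
        best = np.full((N_DAYS, len(slot_hours)), np.inf)
        first_date = sub["timestamp"].dt.normalize().min()
        for ts, score in zip(sub["timestamp"], sub["score"]):
            day = (ts.normalize() - first_date).days
            if not 0 <= day < N_DAYS:
                continue
            tod = ts.hour * 60 + ts.minute + ts.second / 60.0
            slot = int(np.argmin(np.abs(slot_minutes - tod)))
            delta = tod - slot_minutes[slot]
            if abs(delta) > tolerance_min:
                continue
            # closest wins; exact tie -> earliest, i.e. keep current occupant
            # unless the challenger is strictly closer or earlier at equal |d|
            if abs(delta) < best[day, slot] or (
                abs(delta) == best[day, slot] and delta < offsets[day, slot]
            ):
                best[day, slot] = abs(delta)
                scores[day, slot] = score
                offsets[day, slot] = delta
        grids[str(pid)] = EmaGrid(str(pid), scores, offsets)
    return grids


def daily_stats(grid: EmaGrid, variability_mode: str = "mean_daily_sd") -> VariabilityMetrics:
    """Per-day means/SDs and the participant-level variability metric.

    A day is SD-evaluable only when at least two of its three slots are
    present; its SD is the sample SD (n-1 denominator).  The participant
    variability is the unweighted mean of evaluable days' SDs
    (``mean_daily_sd``, default) or the pooled SD of day-centred scores
    (``pooled``).  Mean intensity averages every available score.
    """
    s = grid.scores
    n_per_day = np.sum(~np.isnan(s), axis=1)
    day_means = np.full(N_DAYS, np.nan)
    day_sds = np.full(N_DAYS, np.nan)
    for d in range(N_DAYS):
        vals = s[d][~np.isnan(s[d])]
        if len(vals) >= 1:
            day_means[d] = vals.mean()
        if len(vals) >= 2:
            day_sds[d] = np.std(vals, ddof=1)
    evaluable = ~np.isnan(day_sds)
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        variability = np.nan
    elif variability_mode == "mean_daily_sd":
        variability = float(np.mean(day_sds[evaluable]))
    elif variability_mode == "pooled":
        resid = []
        for d in range(N_DAYS):
            vals = s[d][~np.isnan(s[d])]
            if len(vals) >= 2:
                resid.extend(vals - vals.mean())
        k = int(np.sum(n_per_day[evaluable]))  # observations on evaluable days
        variability = float(np.sqrt(np.sum(np.square(resid)) / (k - n_eval)))
    else:
        raise ValueError(f"unknown variability_mode {variability_mode!r}")
    mean_intensity = float(np.nanmean(s)) if np.any(~np.isnan(s)) else np.nan
    return VariabilityMetrics(grid.participant_id, day_means, day_sds, variability, mean_intensity, n_eval)


def split_variability(metrics: list[VariabilityMetrics], percentile: float = 50.0) -> dict[str, str]:
    """Median split of the cohort on the variability metric.

    Participants at or below the cohort percentile (linear-interpolation
    median) are 'low', strictly above are 'high'.  Unclassifiable metrics are
    skipped.  With all-identical variabilities everyone is low (warned).
    """
    usable = [m for m in metrics if m.classifiable]
    if len(usable) < 2:
        raise ValueError("need >=2 classifiable participants to split on variability")
    values = np.array([m.variability for m in usable])
    cut = float(np.percentile(values, percentile))
    if np.all(values == values[0]):
        logger.warning("all variabilities identical (%.3g): everyone assigned low", values[0])
    return {m.participant_id: ("low" if m.variability <= cut else "high") for m in usable}


def classify_constant(metrics: list[VariabilityMetrics], percentile: float = 50.0) -> dict[str, str]:
    """Split low-variability participants at the median of mean intensity.

    The median is computed within the low-variability subset; at-or-below the
    median is constant_low.
    """
    if not metrics:
        raise ValueError("empty low-variability subset")
    means = np.array([m.mean_intensity for m in metrics])
    cut = float(np.percentile(means, percentile))
    return {
        m.participant_id: ("constant_low" if m.mean_intensity <= cut else "constant_high")
        for m in metrics
    }


def day_change_flags(
    grid: EmaGrid,
    rel_threshold: float = 0.30,
    inclusive: bool = True,
    morning_slot: int = 0,
    evening_slot: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean per-day (increasing, decreasing) qualification flags.

    A day qualifies only when both the 08:00 and 20:00 entries are present.
    Relative change uses the morning score as denominator:
    ``(s20 - s08)/s08 >= rel_threshold`` marks an increase, ``<= -rel_threshold``
    a decrease.  A zero morning score with a positive evening score counts as
    an increase; two zero scores count as no change.
    """
    s08 = grid.scores[:, morning_slot]
    s20 = grid.scores[:, evening_slot]
    inc = np.zeros(N_DAYS, bool)
    dec = np.zeros(N_DAYS, bool)
    cmp_up = np.greater_equal if inclusive else np.greater
    cmp_dn = np.less_equal if inclusive else np.less
    for d in range(N_DAYS):
        a, b = s08[d], s20[d]
        if np.isnan(a) or np.isnan(b):
            continue
        if a == 0:
            inc[d] = b > 0
            continue
        rel = (b - a) / a
        inc[d] = bool(cmp_up(rel, rel_threshold))
        dec[d] = bool(cmp_dn(rel, -rel_threshold))
    return inc, dec


def detect_rhythmic(
    grid: EmaGrid,
    rel_threshold: float = 0.30,
    min_days: int = 4,
    inclusive: bool = True,
) -> tuple[str | None, int, int]:
    """Apply the >=30 % over-12-h rule on >= ``min_days`` of 7 scheduled days.

    Returns ``(label, n_increase_days, n_decrease_days)`` with label one of
    'rhythmic_up', 'rhythmic_down' or None.  Days missing either terminal
    entry never qualify and the ``min_days`` denominator stays the 7 scheduled
    days.
    """
    inc, dec = day_change_flags(grid, rel_threshold, inclusive)
    n_inc, n_dec = int(inc.sum()), int(dec.sum())
    if n_inc >= min_days:
        return "rhythmic_up", n_inc, n_dec
    if n_dec >= min_days:
        return "rhythmic_down", n_inc, n_dec
    return None, n_inc, n_dec


def phenotype_cohort(
    diary: pd.DataFrame,
    scale: str = "pain",
    rel_threshold: float = 0.30,
    min_days: int = 4,
    inclusive: bool = True,
    tolerance_min: float = TOLERANCE_MIN,
    variability_mode: str = "mean_daily_sd",
    exclude_rhythmic_down: bool = True,
) -> pd.DataFrame:
    """Full phenotyping pipeline for one symptom scale of a diary table.

    Composition: window-filter -> daily stats -> cohort median variability
    split; low-variability participants split on median mean intensity into
    constant_low / constant_high; high-variability participants tested with
    the rhythmic rule, the remainder labelled mixed.  ``rhythmic_down``
    participants are flagged ``excluded`` by default, mirroring their removal
    from downstream analysis in small cohorts.

    Returns one row per participant with the label and all driving metrics.
    """
    sub = diary[diary["scale"] == scale]
    if sub["participant_id"].nunique() < 2:
        raise ValueError("phenotyping needs at least 2 participants")
    grids = window_filter(sub, tolerance_min=tolerance_min)
    metrics = {pid: daily_stats(g, variability_mode) for pid, g in grids.items()}

    assignments: dict[str, PhenotypeAssignment] = {}
    classifiable = [m for m in metrics.values() if m.classifiable]
    for pid, m in metrics.items():
        if not m.classifiable:
            assignments[pid] = PhenotypeAssignment(pid, "unclassifiable", m)
    var_split = split_variability(classifiable)
    low = [m for m in classifiable if var_split[m.participant_id] == "low"]
    high = [m for m in classifiable if var_split[m.participant_id] == "high"]
    if low:
        for pid, lab in classify_constant(low).items():
            assignments[pid] = PhenotypeAssignment(pid, lab, metrics[pid])
    for m in high:
        lab, n_inc, n_dec = detect_rhythmic(
            grids[m.participant_id], rel_threshold, min_days, inclusive
        )
        label = lab if lab is not None else "mixed"
        excluded = exclude_rhythmic_down and label == "rhythmic_down"
        assignments[m.participant_id] = PhenotypeAssignment(
            m.participant_id, label, m, n_inc, n_dec, excluded
        )

    rows = []
    for pid in sorted(assignments):
        a = assignments[pid]
        m = a.metrics
        rows.append(
            {
                "participant_id": pid,
                "label": a.label,
                "variability": m.variability if m else np.nan,
                "mean_intensity": m.mean_intensity if m else np.nan,
                "n_evaluable_days": m.n_evaluable_days if m else 0,
                "n_increase_days": a.n_increase_days,
                "n_decrease_days": a.n_decrease_days,
                "excluded": a.excluded,
            }
        )
    return pd.DataFrame(rows)
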